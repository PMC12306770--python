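import pytest

import epsdigest as ed


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default 3-digest scenario without observation noise, with truth."""
    scenario = ed.default_scenario(noise_cv=0.0, seed=11)
    table, truth = ed.generate_dataset(scenario)
    return scenario, table, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default 3-digest scenario at CV 0.2 (~1,000 planted ions)."""
    scenario = ed.default_scenario(noise_cv=0.2, seed=11)
    table, truth = ed.generate_dataset(scenario)
    return scenario, table, truth


@pytest.fixture(scope="session")
def peptide_catalog():
    return ed.enumerate_peptides(max_len=4)
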