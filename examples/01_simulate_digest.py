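"""Simulate a 24 h multi-digest EPS degradation experiment.

Builds the default three-digest scenario (sequential substrate ->
intermediate -> terminal chains with shared low-mass products), generates
the noisy ion table, and prints its shape and a preview.
"""

import epsdigest as ed

scenario = ed.default_scenario(noise_cv=0.2, seed=42)
table, truth = ed.generate_dataset(scenario)

print(f"digests:       {scenario.digests}")
print(f"reported rows: {len(table)}  (one per detected ion x digest x timepoint)")
print(f"ion features:  {table['ion_id'].nunique()}")
print(truth["true_category"].value_counts().to_string())
print("\nfirst observations:")
print(table.head(5).to_string(index=False))
# Each ion carries an m/z ([M-H]- of its stage mass), a retention time, and
# an hourly intensity trace; planted categories live in the truth table.
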