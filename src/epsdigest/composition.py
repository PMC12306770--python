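"""Carbon budgets, EPS yields, composition arithmetic, and EEM Coble peaks.

Bookkeeping for a closed carbon balance on a polysaccharide-degrading
culture: input substrate carbon partitions into biomass, high-molecular-
weight EPS (>3 kDa), low-molecular-weight metabolites (<3 kDa), and the
unrecovered remainder attributed to respired CO2.  Also: dry-mass EPS
yields, monosaccharide weight fractions from hydrolysate concentrations,
mock-medium formulation, and Coble-peak extraction from excitation-
emission fluorescence matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

__all__ = [
    "CarbonBudget",
    "EEMatrix",
    "MONOSACCHARIDE_MASSES",
    "carbon_budget",
    "eps_yield",
    "monosaccharide_mass_fractions",
    "combined_polymer_fraction",
    "mock_medium",
    "coble_peaks",
    "COBLE_M_WINDOW",
    "COBLE_C_WINDOW",
]

_WATER = float(_pt_mass.calculate_mass(formula="H2O"))

_SUGAR_CLASS_FORMULAS = {
    "hexose": "C6H12O6",
    "pentose": "C5H10O5",
    "deoxyhexose": "C6H12O5",
    "hexosamine": "C6H13NO5",
    "N-acetylhexosamine": "C8H15NO6",
    "hexuronic acid": "C6H10O7",
}
_STANDARDS = {
    # the 17 calibration standards -> structural class
    "galacturonic acid": "hexuronic acid",
    "glucuronic acid": "hexuronic acid",
    "mannuronic acid": "hexuronic acid",
    "guluronic acid": "hexuronic acid",
    "xylose": "pentose",
    "arabinose": "pentose",
    "ribose": "pentose",
    "glucosamine": "hexosamine",
    "galactosamine": "hexosamine",
    "fucose": "deoxyhexose",
    "rhamnose": "deoxyhexose",
    "glucose": "hexose",
    "galactose": "hexose",
    "mannose": "hexose",
    "N-acetylglucosamine": "N-acetylhexosamine",
    "N-acetylgalactosamine": "N-acetylhexosamine",
    "N-acetylmannosamine": "N-acetylhexosamine",
}

#: free monoisotopic masses (g/mol) of the bundled monosaccharide standards,
#: plus the structural class names themselves (usable for class-level sums)
MONOSACCHARIDE_MASSES: dict[str, float] = {
    **{
        name: float(_pt_mass.calculate_mass(formula=_SUGAR_CLASS_FORMULAS[cls]))
        for name, cls in _STANDARDS.items()
    },
    **{
        cls: float(_pt_mass.calculate_mass(formula=f))
        for cls, f in _SUGAR_CLASS_FORMULAS.items()
    },
}


def anhydro_mass(free_mass: float) -> float:
    """Residue (anhydro) mass of a sugar inside a polymer: free mass - water."""
    return free_mass - _WATER


@dataclass(frozen=True)
class CarbonBudget:
    """Partition of input substrate carbon, in percent.

    ``co2_pct`` is the unrecovered remainder; ``eps_share_of_exudate`` is
    EPS carbon as a percentage of total exuded carbon (EPS + LMW), NaN when
    nothing was exuded.
    """

    biomass_pct: float
    eps_pct: float
    lmw_pct: float
    co2_pct: float
    eps_share_of_exudate: float

    @property
    def degenerate(self) -> bool:
        """True when the exudate share is undefined (no exuded carbon)."""
        return np.isnan(self.eps_share_of_exudate)


def carbon_budget(biomass_pct: float, eps_pct: float, lmw_pct: float) -> CarbonBudget:
    """Close the carbon balance: CO2 takes the unrecovered remainder.

    All inputs are percent of input substrate carbon and must be
    non-negative with sum <= 100.
    """
    vals = (biomass_pct, eps_pct, lmw_pct)
    if any(v < 0 for v in vals):
        raise ValueError("carbon fractions must be non-negative")
    recovered = sum(vals)
    if recovered > 100:
        raise ValueError(f"recovered carbon {recovered}% exceeds 100%")
    exudate = eps_pct + lmw_pct
    share = 100.0 * eps_pct / exudate if exudate > 0 else float("nan")
    return CarbonBudget(biomass_pct, eps_pct, lmw_pct, 100.0 - recovered, share)


def eps_yield(dried_eps_mg: float, chitin_consumed_g: float) -> tuple[float, float]:
    """Dry-mass EPS yield as (mg per g substrate, percent w/w)."""
    if chitin_consumed_g <= 0:
        raise ValueError("consumed substrate mass must be positive")
    if dried_eps_mg < 0:
        raise ValueError("EPS mass must be non-negative")
    y = dried_eps_mg / chitin_consumed_g
    return y, y / 10.0


def monosaccharide_mass_fractions(
    concentrations_uM: dict[str, float] | pd.Series,
    masses: dict[str, float] | None = None,
    anhydro: bool = False,
) -> pd.Series:
    """Weight fraction of each monosaccharide in a hydrolysate.

    fraction_i = c_i * MW_i / sum_j c_j * MW_j.  Masses default to the
    bundled free-monosaccharide table; ``anhydro=True`` uses in-polymer
    residue masses instead.
    """
    conc = pd.Series(concentrations_uM, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    table = dict(MONOSACCHARIDE_MASSES if masses is None else masses)
    missing = [s for s in conc.index if s not in table]
    if missing:
        raise KeyError(f"no molecular mass for: {missing}")
    mw = pd.Series({s: table[s] for s in conc.index})
    if anhydro:
        mw = mw - _WATER
    weights = conc * mw
    total = weights.sum()
    if total <= 0:
        raise ValueError("all concentrations are zero")
    return weights / total


def combined_polymer_fraction(
    protein_range: tuple[float, float], polysaccharide_range: tuple[float, float]
) -> tuple[float, float]:
    """Elementwise sum of (low, high) mass-fraction ranges, percent g/g."""
    for lo, hi in (protein_range, polysaccharide_range):
        if lo > hi:
            raise ValueError("range low must not exceed high")
    return (
        protein_range[0] + polysaccharide_range[0],
        protein_range[1] + polysaccharide_range[1],
    )


def mock_medium(
    sugar_uM: dict[str, float],
    protein_mg_per_L: float = 0.0,
    include_threshold_uM: float = 1.0,
    protein_name: str = "bovine serum albumin",
) -> pd.DataFrame:
    """Formulate a defined medium mimicking an EPS's measurable content.

    Sugars at or above ``include_threshold_uM`` are included at their
    measured concentration; a protein supplement is added when
    ``protein_mg_per_L`` > 0.  Returns a recipe table with columns
    ``component, amount, unit``.
    """
    if include_threshold_uM < 0:
        raise ValueError("threshold must be non-negative")
    if protein_mg_per_L < 0:
        raise ValueError("protein amount must be non-negative")
    rows = [
        (name, float(c), "uM")
        for name, c in sugar_uM.items()
        if c >= include_threshold_uM
    ]
    rows.sort()
    if protein_mg_per_L > 0:
        rows.append((protein_name, float(protein_mg_per_L), "mg/L"))
    return pd.DataFrame(rows, columns=["component", "amount", "unit"])


# Coble fluorescence windows, (ex_low, ex_high, em_low, em_high) in nm:
# peak M marks marine humic-like material, peak C visible humic-like.
COBLE_M_WINDOW = (290.0, 310.0, 370.0, 410.0)
COBLE_C_WINDOW = (320.0, 360.0, 420.0, 460.0)


@dataclass(frozen=True)
class EEMatrix:
    """Excitation-emission fluorescence matrix.

    ``grid[i, j]`` is fluorescence at excitation ``excitation[i]`` and
    emission ``emission[j]`` (wavelengths in nm, ascending).
    """

    excitation: np.ndarray
    emission: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        g = np.asarray(self.grid, dtype=float)
        if (np.diff(ex) <= 0).any() or (np.diff(em) <= 0).any():
            raise ValueError("wavelength axes must be strictly ascending")
        if g.shape != (ex.size, em.size):
            raise ValueError("grid shape must match wavelength axes")
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "grid", g)


def _window_stat(eem: EEMatrix, window, statistic: str) -> float:
    ex_lo, ex_hi, em_lo, em_hi = window
    if ex_lo < eem.excitation[0] or ex_hi > eem.excitation[-1] \
            or em_lo < eem.emission[0] or em_hi > eem.emission[-1]:
        raise ValueError("Coble window falls outside the acquired grid")
    ex_mask = (eem.excitation >= ex_lo) & (eem.excitation <= ex_hi)
    em_mask = (eem.emission >= em_lo) & (eem.emission <= em_hi)
    block = eem.grid[np.ix_(ex_mask, em_mask)]
    return float(block.sum() if statistic == "sum" else block.mean())


def coble_peaks(eem: EEMatrix, statistic: str = "mean") -> dict[str, float]:
    """Coble peak M and C values of an EEM.

    Each peak is the mean (or, with ``statistic='sum'``, the sum) of the
    fluorescence over its rectangular excitation/emission window, bounds
    inclusive on the acquisition grid.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    return {
        "peak_M": _window_stat(eem, COBLE_M_WINDOW, statistic),
        "peak_C": _window_stat(eem, COBLE_C_WINDOW, statistic),
    }
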