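"""Exact-mass annotation of ions against combinatorial compound catalogs.

Candidate neutral masses come from three sources: all peptide compositions
of up to four proteinogenic amino-acid residues, amino-sugar monomers and
their glycosidic dimers, and user-supplied compound tables (label +
elemental formula or mass).  An observed m/z is converted to a neutral
mass through the protonation adduct ([M+H]+ or [M-H]-) and matched within
a parts-per-million tolerance.  Matches are putative: exact mass cannot
distinguish isomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb, factorial

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

__all__ = [
    "MassCatalog",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "enumerate_peptides",
    "peptide_sequence_count",
    "composition_count",
    "neutral_mass",
    "sugar_masses",
    "annotate_ions",
    "filter_class_predictions",
    "read_compound_table",
]

PROTON_MASS = 1.007276
WATER_MASS = float(_pt_mass.calculate_mass(formula="H2O"))

#: monoisotopic residue masses of the 20 canonical amino acids
RESIDUE_MASSES: dict[str, float] = {
    aa: float(_pt_mass.std_aa_mass[aa]) for aa in "ACDEFGHIKLMNPQRSTVWY"
}

_SUGAR_FORMULAS = {
    "hexosamine": "C6H13NO5",
    "N-acetylhexosamine": "C8H15NO6",
}


@dataclass(frozen=True)
class MassCatalog:
    """Neutral monoisotopic mass catalog.

    ``entries`` has columns ``label, mass, source`` with source one of
    peptide / sugar / user; labels are unique within a source.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.entries["mass"] <= 0).any():
            raise ValueError("catalog masses must be positive")
        if self.entries.duplicated(["label", "source"]).any():
            raise ValueError("labels must be unique within a source")

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def combine(*catalogs: "MassCatalog") -> "MassCatalog":
        return MassCatalog(
            pd.concat([c.entries for c in catalogs], ignore_index=True)
        )


def enumerate_peptides(max_len: int = 4) -> MassCatalog:
    """Catalog of peptide compositions of length <= ``max_len``.

    One entry per amino-acid *multiset* (mass is order-independent), labelled
    by the sorted one-letter composition; mass = sum of residue masses +
    water.  At the default length 4 this yields 10,625 compositions.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rows = []
    letters = sorted(RESIDUE_MASSES)
    for n in range(1, max_len + 1):
        for combo in combinations_with_replacement(letters, n):
            m = sum(RESIDUE_MASSES[a] for a in combo) + WATER_MASS
            rows.append(("".join(combo), m, "peptide"))
    return MassCatalog(pd.DataFrame(rows, columns=["label", "mass", "source"]))


def peptide_sequence_count(max_len: int = 4, n_residues: int = 20) -> int:
    """Number of ordered peptide sequences of length <= ``max_len``.

    Counted by summing distinct permutations of every composition, which
    equals sum_k n_residues**k.
    """
    total = 0
    letters = list(range(n_residues))
    for n in range(1, max_len + 1):
        for combo in combinations_with_replacement(letters, n):
            counts: dict[int, int] = {}
            for a in combo:
                counts[a] = counts.get(a, 0) + 1
            perms = factorial(n)
            for c in counts.values():
                perms //= factorial(c)
            total += perms
    return total


def composition_count(max_len: int, n_residues: int = 20) -> int:
    """Number of amino-acid multisets of size 1..max_len (stars and bars)."""
    return sum(comb(n_residues + n - 1, n) for n in range(1, max_len + 1))


def sugar_masses() -> MassCatalog:
    """Amino-sugar monomers and glycosidic dimers.

    Hexosamine (C6H13NO5), N-acetylhexosamine (C8H15NO6), their homodimers
    and the mixed dimer; a glycosidic bond condenses out one water
    (dimer mass = sum of monomers - water).
    """
    mono = {k: float(_pt_mass.calculate_mass(formula=v)) for k, v in _SUGAR_FORMULAS.items()}
    rows = [(k, m, "sugar") for k, m in mono.items()]
    names = list(mono)
    for i, a in enumerate(names):
        for b in names[i:]:
            rows.append((f"{a}+{b} dimer", mono[a] + mono[b] - WATER_MASS, "sugar"))
    return MassCatalog(pd.DataFrame(rows, columns=["label", "mass", "source"]))


def read_compound_table(path_or_df) -> MassCatalog:
    """User compound table (CSV or DataFrame) with ``label`` and either a
    ``formula`` column (parsed to monoisotopic mass) or a ``mass`` column."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if "mass" in df.columns:
        masses = df["mass"].astype(float)
    elif "formula" in df.columns:
        masses = df["formula"].map(lambda f: float(_pt_mass.calculate_mass(formula=f)))
    else:
        raise ValueError("compound table needs a 'formula' or 'mass' column")
    out = pd.DataFrame({"label": df["label"], "mass": masses, "source": "user"})
    return MassCatalog(out)


def neutral_mass(mz: float, mode: str) -> float:
    """Neutral monoisotopic mass implied by an m/z under [M+H]+ / [M-H]-."""
    if mode == "positive":
        return mz - PROTON_MASS
    if mode == "negative":
        return mz + PROTON_MASS
    raise ValueError("mode must be 'positive' or 'negative'")


def annotate_ions(mz_values, mode: str, catalog: MassCatalog, ppm_tol: float = 5.0) -> pd.DataFrame:
    """Match observed m/z values to catalog entries by exact mass.

    For each ion, every catalog entry whose neutral mass lies within
    ``ppm_tol`` ppm of the adduct-corrected neutral mass is returned,
    sorted by ascending |ppm error| within the ion.  Columns:
    ``mz, label, source, catalog_mass, ppm_error``.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    cat = catalog.entries.sort_values("mass", kind="mergesort", ignore_index=True)
    cat_masses = cat["mass"].to_numpy()
    rows = []
    for mz in np.atleast_1d(np.asarray(mz_values, dtype=float)):
        target = neutral_mass(float(mz), mode)
        delta = target * ppm_tol * 1e-6
        lo = np.searchsorted(cat_masses, target - delta, side="left")
        hi = np.searchsorted(cat_masses, target + delta, side="right")
        hits = []
        for i in range(lo, hi):
            ppm = (target - cat_masses[i]) / cat_masses[i] * 1e6
            if abs(ppm) <= ppm_tol:
                hits.append((float(mz), cat.at[i, "label"], cat.at[i, "source"],
                             float(cat_masses[i]), float(ppm)))
        hits.sort(key=lambda h: (abs(h[4]), h[1]))
        rows.extend(hits)
    return pd.DataFrame(
        rows, columns=["mz", "label", "source", "catalog_mass", "ppm_error"]
    )


def filter_class_predictions(rows: pd.DataFrame) -> pd.DataFrame:
    """Retain compound-class predictions passing quality thresholds.

    A row is kept iff intensity_explained >= 0.5, the isotope score is
    absent or >= 5, and the most specific class probability >= 0.75.
    """
    df = rows.copy()
    for col in ("intensity_explained", "class_probability"):
        vals = df[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    iso = df["isotope_score"] if "isotope_score" in df.columns else pd.Series(np.nan, index=df.index)
    keep = (
        (df["intensity_explained"].astype(float) >= 0.5)
        & (iso.isna() | (iso.astype(float) >= 5))
        & (df["class_probability"].astype(float) >= 0.75)
    )
    return df[keep].reset_index(drop=True)
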