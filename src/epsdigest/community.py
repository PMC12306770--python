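"""Community composition comparison from 16S relative abundances.

Species-by-sample relative-abundance tables are compared by Bray-Curtis
dissimilarity, expressed as log2 fold changes against an inoculum sample
(with a detection-limit floor and explicit masking of species absent from
a condition), clustered with Ward's minimum-variance method, and
summarised as per-sample top-N compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import braycurtis as _sp_braycurtis

__all__ = [
    "DEFAULT_ABUNDANCE_FLOOR",
    "FoldChangeMatrix",
    "load_abundance_table",
    "bray_curtis",
    "fold_changes",
    "ward_cluster",
    "top_n",
]

#: detection floor for relative abundances: one read at the ~30,000-read
#: per-sample filtered depth of the 16S workflow
DEFAULT_ABUNDANCE_FLOOR = 1.0 / 30_000


def load_abundance_table(table: pd.DataFrame | str, renormalize: bool = True) -> pd.DataFrame:
    """Load a species (rows) x sample (columns) relative-abundance table.

    Accepts a DataFrame, CSV/TSV path, or XLSX path (first column = species
    names).  Abundances must be non-negative with positive per-sample sums;
    columns are renormalized to sum to 1 by default.
    """
    if isinstance(table, str):
        if table.endswith((".xlsx", ".xls")):
            df = pd.read_excel(table, index_col=0)
        else:
            sep = "\t" if table.endswith((".tsv", ".txt")) else ","
            df = pd.read_csv(table, index_col=0, sep=sep)
    else:
        df = table.copy()
    df = df.astype(float)
    if (df < 0).to_numpy().any():
        raise ValueError("abundances must be non-negative")
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    if (sums > 1 + 1e-9).any():
        raise ValueError("per-sample abundance sums must not exceed 1")
    return df / sums if renormalize else df


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) between two samples."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share the species universe")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if u.sum() + v.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_sp_braycurtis(u, v))


@dataclass
class FoldChangeMatrix:
    """log2 fold changes vs. the inoculum with an absence mask.

    ``values`` is species x condition; ``mask`` is True where the species
    was not detected in that condition (those cells carry NaN, matching the
    grayed-out cells of a fold-change heatmap).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    inoculum: str
    floor: float


def fold_changes(
    table: pd.DataFrame,
    inoculum_sample: str,
    floor: float = DEFAULT_ABUNDANCE_FLOOR,
) -> FoldChangeMatrix:
    """Per-species log2 fold change of each condition vs. the inoculum.

    FC = log2(a_condition / max(a_inoculum, floor)); the floor caps the
    denominator at the detection limit so species absent from the inoculum
    yield large finite enrichments.  Species with zero abundance in a
    condition are masked (NaN), not scored as depleted.
    """
    if inoculum_sample not in table.columns:
        raise KeyError(f"unknown inoculum sample {inoculum_sample!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    conditions = [c for c in table.columns if c != inoculum_sample]
    ref = np.maximum(table[inoculum_sample].to_numpy(dtype=float), floor)
    vals = {}
    for c in conditions:
        a = table[c].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            vals[c] = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0) / ref), np.nan)
    values = pd.DataFrame(vals, index=table.index)
    mask = values.isna()
    return FoldChangeMatrix(values, mask, inoculum_sample, floor)


def ward_cluster(
    fc: FoldChangeMatrix | pd.DataFrame, impute: str = "min"
) -> tuple[np.ndarray, list]:
    """Ward's-method hierarchy over species fold-change rows.

    Masked cells are imputed (``'min'``: the matrix minimum, preserving
    absent-means-depleted ordering; ``'zero'``: 0) before Euclidean
    distances feed Ward's minimum-variance linkage.  Returns the SciPy
    linkage matrix and the leaf order (species labels) for heatmap display.
    A species row that is entirely masked cannot be placed and raises.
    """
    values = fc.values if isinstance(fc, FoldChangeMatrix) else fc
    if len(values) < 2:
        raise ValueError("need at least 2 species rows to cluster")
    X = values.to_numpy(dtype=float)
    all_masked = np.isnan(X).all(axis=1)
    if all_masked.any():
        bad = list(values.index[all_masked])
        raise ValueError(f"species with no observed fold change: {bad}")
    if np.isnan(X).any():
        fill = np.nanmin(X) if impute == "min" else 0.0
        X = np.where(np.isnan(X), fill, X)
    Z = linkage(X, method="ward")
    order = [values.index[i] for i in leaves_list(Z)]
    return Z, order


def top_n(table: pd.DataFrame, n: int = 6) -> pd.DataFrame:
    """Per-sample top-``n`` species plus an 'other' remainder row.

    Species are ranked per sample by abundance, ties broken by species
    name (lexicographic); the remainder is 1 minus the top-n sum.  The
    output keeps the union of selected species as rows (zero-filled where
    a species is outside a sample's top n) with 'other' last.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    selected: dict[str, pd.Series] = {}
    union: list[str] = []
    for sample in table.columns:
        col = table[sample]
        ranked = col.sort_values(ascending=False, kind="mergesort")
        # stable sort on (-abundance, name): sort names first, then value
        ranked = col.loc[sorted(col.index)].sort_values(
            ascending=False, kind="mergesort"
        )
        top = ranked.iloc[: min(n, len(ranked))]
        selected[sample] = top
        union.extend(s for s in top.index if s not in union)
    out = pd.DataFrame(0.0, index=union + ["other"], columns=table.columns)
    for sample, top in selected.items():
        out.loc[top.index, sample] = top.to_numpy()
        out.loc["other", sample] = max(0.0, float(table[sample].sum() - top.sum()))
    return out
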