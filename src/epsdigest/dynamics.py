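"""Temporal classification and cross-digest analysis of LC-MS ion features.

Ions observed over a 24 h enzyme digest fall into three temporal classes:

* ``decreased`` — substrate-like, intensity falls steadily;
* ``bell`` — transient intermediate, rises then falls;
* ``increased`` — terminal product, accumulates (log2 fold change of the
  final versus initial timepoint of at least 10, reflecting products that
  appear from a near-zero baseline);
* ``unclassified`` — none of the rules fire.

Rule order is increased, then bell, then decreased.  Missing observations
(below the detection limit) are imputed at a low quantile of the nonzero
intensities before log-ratios are formed, which reproduces the very large
fold changes that censored baselines generate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierParams",
    "CategoryResult",
    "classify_profile",
    "classify_table",
    "mz_category_distribution",
    "align_ions",
    "sharing_by_mz",
    "DEFAULT_BIN_EDGES",
]

CATEGORIES = ("decreased", "bell", "increased")

#: m/z bin edges: 50, then 200-step bins up to the 1,800 m/z detection limit
DEFAULT_BIN_EDGES = (50.0,) + tuple(float(x) for x in range(200, 1801, 200))


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the temporal-profile classifier.

    tau_increase is the log2 fold-change (final vs. initial timepoint)
    required to call an ion increased; tau_decrease the magnitude of the
    negative log2 fold-change for decreased; bell_prominence the factor by
    which the smoothed interior maximum must exceed both endpoints;
    floor_quantile the quantile of nonzero intensities used as the
    imputation floor; smooth_window the (odd) moving-median width applied
    before bell detection.
    """

    tau_increase: float = 10.0
    tau_decrease: float = 1.0
    bell_prominence: float = 2.0
    floor_quantile: float = 0.01
    smooth_window: int = 3

    def __post_init__(self) -> None:
        if min(self.tau_increase, self.tau_decrease, self.bell_prominence) <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.floor_quantile <= 1):
            raise ValueError("floor_quantile must lie in [0, 1]")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


@dataclass
class CategoryResult:
    """Classification output: per-ion categories and count summaries."""

    per_ion: pd.DataFrame  # columns ion_id, category, mz
    per_digest: pd.DataFrame  # columns ion_id, digest, category
    counts_overall: dict[str, int] = field(default_factory=dict)
    counts_per_digest: pd.DataFrame | None = None
    params: ClassifierParams = field(default_factory=ClassifierParams)


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def classify_profile(
    hours, intensity, params: ClassifierParams | None = None, floor: float | None = None
) -> str:
    """Classify one intensity-by-hours series.

    ``hours`` must include 0 and the series' final time with at least three
    points.  NaN / nonpositive intensities are imputed at ``floor`` (default:
    the params.floor_quantile quantile of the series' own nonzero values).
    """
    params = params or ClassifierParams()
    t = np.asarray(hours, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.size != y.size:
        raise ValueError("hours and intensity must have equal length")
    if t.size < 3 or t[0] != 0:
        raise ValueError("series must have >= 3 timepoints starting at 0")
    order = np.argsort(t)
    t, y = t[order], y[order]

    observed = np.nan_to_num(y, nan=0.0)
    positive = observed[observed > 0]
    if positive.size == 0:
        return "unclassified"
    if floor is None:
        floor = float(np.quantile(positive, params.floor_quantile))
    y = np.where(np.isnan(y) | (y < floor), floor, y)

    log2fc = float(np.log2(y[-1] / y[0]))
    if log2fc >= params.tau_increase:
        return "increased"
    # median-smooth only when the series is long enough to retain genuine
    # interior structure; a 3-point series IS its own interior
    smooth = y if y.size < params.smooth_window + 2 else _moving_median(y, params.smooth_window)
    interior_max = float(smooth[1:-1].max())
    if interior_max >= params.bell_prominence * max(y[0], y[-1]):
        return "bell"
    if log2fc <= -params.tau_decrease:
        return "decreased"
    return "unclassified"


def classify_table(table: pd.DataFrame, params: ClassifierParams | None = None) -> CategoryResult:
    """Classify every ion of a long-format ion table.

    Each ion is classified within each digest on that digest's full
    timepoint grid (unobserved timepoints are censored values, imputed at
    the digest-wide floor).  An ion's overall category is assigned when a
    rule fires in at least one digest; conflicting per-digest calls are
    resolved by the precedence increased > bell > decreased.
    """
    params = params or ClassifierParams()
    if table.empty:
        empty = pd.DataFrame(columns=["ion_id", "category", "mz"])
        return CategoryResult(
            per_ion=empty,
            per_digest=pd.DataFrame(columns=["ion_id", "digest", "category"]),
            counts_overall={c: 0 for c in CATEGORIES},
            counts_per_digest=pd.DataFrame(columns=["digest", *CATEGORIES]),
            params=params,
        )

    digest_rows = []
    for digest, sub in table.groupby("digest", sort=True):
        grid = np.sort(sub["hours"].unique())
        pos = sub.loc[sub["intensity"] > 0, "intensity"]
        floor = float(np.quantile(pos, params.floor_quantile)) if len(pos) else np.nan
        wide = sub.pivot_table(
            index="ion_id", columns="hours", values="intensity", aggfunc="sum"
        ).reindex(columns=grid)
        for ion_id, row in wide.iterrows():
            cat = classify_profile(grid, row.to_numpy(), params, floor=floor)
            digest_rows.append((ion_id, digest, cat))
    per_digest = pd.DataFrame(digest_rows, columns=["ion_id", "digest", "category"])

    precedence = {"increased": 0, "bell": 1, "decreased": 2, "unclassified": 3}
    overall = (
        per_digest.groupby("ion_id")["category"]
        .agg(lambda cats: min(cats, key=precedence.get))
        .rename("category")
        .reset_index()
    )
    mz = table.groupby("ion_id")["mz"].first().rename("mz")
    per_ion = overall.merge(mz, on="ion_id")

    counts_overall = {
        c: int((per_ion["category"] == c).sum()) for c in (*CATEGORIES, "unclassified")
    }
    counts_per_digest = (
        per_digest[per_digest["category"] != "unclassified"]
        .groupby(["digest", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reset_index()
    )
    return CategoryResult(per_ion, per_digest, counts_overall, counts_per_digest, params)


def mz_category_distribution(result: CategoryResult, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Fraction of categorized ions per m/z bin falling in each category.

    Bins are half-open ``[low, high)``; per-bin fractions over the three
    categories sum to 1 (bins with no categorized ions are omitted).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly ascending")
    ions = result.per_ion[result.per_ion["category"].isin(CATEGORIES)].copy()
    if ions.empty:
        return pd.DataFrame(columns=["bin_low", "bin_high", *CATEGORIES, "n_ions"])
    idx = np.digitize(ions["mz"].to_numpy(), edges) - 1
    ions["bin"] = idx
    ions = ions[(idx >= 0) & (idx < edges.size - 1)]
    out = []
    for b, sub in ions.groupby("bin"):
        frac = sub["category"].value_counts(normalize=True)
        out.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                **{c: float(frac.get(c, 0.0)) for c in CATEGORIES},
                "n_ions": len(sub),
            }
        )
    return pd.DataFrame(out).sort_values("bin_low", ignore_index=True)


def align_ions(
    features: pd.DataFrame,
    ppm_tol: float = 8.0,
    rt_tol: float = 0.1,
    allow_mixed_modes: bool = False,
) -> pd.DataFrame:
    """Cluster ion features across digests by m/z and retention time.

    Two features co-cluster when their m/z difference is within ``ppm_tol``
    parts per million of their mean m/z and their retention times differ by
    at most ``rt_tol`` minutes; clusters are closed transitively
    (single linkage).  ``features`` needs columns ``digest, mz, rt_min``
    (plus ``mode``; comparing mixed ionization modes raises unless
    ``allow_mixed_modes``).  Returns the input with a ``cluster`` column;
    cluster ids are ordered by ascending (m/z, RT) of each cluster's first
    member, so the labelling is independent of input row order.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    feats = features.reset_index(drop=True).copy()
    if "mode" in feats.columns and feats["mode"].nunique() > 1 and not allow_mixed_modes:
        raise ValueError("features mix ionization modes; pass allow_mixed_modes=True")
    # deterministic processing order: ascending m/z, ties by RT
    order = np.lexsort((feats["rt_min"].to_numpy(), feats["mz"].to_numpy()))
    mz = feats["mz"].to_numpy()[order]
    rt = feats["rt_min"].to_numpy()[order]
    n = len(feats)

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # sliding window over the m/z-sorted list; the pair condition
    # |dmz| <= ppm * mean(mz) * 1e-6 bounds dmz by ppm * mz_j * 1e-6 for the
    # larger member, so scanning until that bound is exceeded is exhaustive
    for i in range(n):
        j = i + 1
        while j < n and (mz[j] - mz[i]) <= ppm_tol * 1e-6 * 0.5 * (mz[i] + mz[j]):
            if abs(rt[j] - rt[i]) <= rt_tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
            j += 1

    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    cluster_sorted = np.empty(n, dtype=int)
    cluster_sorted[:] = labels
    cluster = np.empty(n, dtype=int)
    cluster[order] = cluster_sorted
    feats["cluster"] = cluster
    return feats


def sharing_by_mz(
    aligned: pd.DataFrame, bin_edges=DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Per-m/z-bin fraction of ions detected in more than one digest.

    Operates on the output of :func:`align_ions` (typically restricted to
    increased-category ions).  An ion cluster is *shared* when its members
    span at least two digests; each cluster counts once, binned by its mean
    m/z.  Bins without ions are absent from the output.  The upper edge may
    be ``inf`` to express open ranges such as ">1,400 m/z".
    """
    edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly ascending")
    clusters = aligned.groupby("cluster").agg(
        mz=("mz", "mean"), n_digests=("digest", "nunique")
    )
    idx = np.digitize(clusters["mz"].to_numpy(), edges) - 1
    clusters = clusters[(idx >= 0) & (idx < edges.size - 1)]
    clusters["bin"] = idx[(idx >= 0) & (idx < edges.size - 1)]
    out = []
    for b, sub in clusters.groupby("bin"):
        out.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "shared_fraction": float((sub["n_digests"] >= 2).mean()),
                "n_ions": len(sub),
            }
        )
    return pd.DataFrame(out).sort_values("bin_low", ignore_index=True)
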