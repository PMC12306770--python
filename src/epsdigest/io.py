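"""Readers and writers for ion tables and EEM grids.

The native on-disk form is a long-format CSV with columns
``ion_id, digest, mz, rt_min, mode, hours, intensity``.  Supplementary-style
spreadsheets with the header ``m/z, retention_time, Degrader, hours, mode,
annotation, intensity`` are accepted and mapped onto the native schema
(ion identity is taken per unique (m/z, retention_time, mode) feature when
no id column is present).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import EEMatrix

__all__ = ["read_ion_table", "write_ion_table", "read_eem_csv", "validate_ion_table"]

NATIVE_COLUMNS = ["ion_id", "digest", "mz", "rt_min", "mode", "hours", "intensity"]

_SUPPLEMENTARY_RENAME = {
    "m/z": "mz",
    "retention_time": "rt_min",
    "Degrader": "digest",
}


def validate_ion_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check ion-table invariants: positive m/z, hours in [0, 24], unique
    (ion_id, digest, hours)."""
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns and c != "intensity"]
    if missing:
        raise ValueError(f"ion table missing columns: {missing}")
    if (df["mz"] <= 0).any():
        raise ValueError("m/z values must be positive")
    if ((df["hours"] < 0) | (df["hours"] > 24)).any():
        raise ValueError("hours must lie within [0, 24]")
    if df.duplicated(["ion_id", "digest", "hours"]).any():
        raise ValueError("(ion_id, digest, hours) must be unique")
    return df


def read_ion_table(path: str) -> pd.DataFrame:
    """Read an ion table from CSV/TSV or a supplementary-layout XLSX.

    Returns the native long-format schema.  Rows with missing intensity are
    dropped (they encode censored observations).
    """
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.endswith((".tsv", ".txt")) else ",")
    df = df.rename(columns=_SUPPLEMENTARY_RENAME)
    if "ion_id" not in df.columns:
        # supplementary layout: a feature is a unique (m/z, RT, mode) triple
        key = df[["mz", "rt_min", "mode"]].apply(tuple, axis=1)
        codes, _ = pd.factorize(key, sort=True)
        df["ion_id"] = [f"ion{c:05d}" for c in codes]
    keep = [c for c in NATIVE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in keep and c == "annotation"]
    df = df[keep + extra].dropna(subset=["intensity"])
    df["hours"] = df["hours"].astype(float)
    df["intensity"] = df["intensity"].astype(float)
    return validate_ion_table(df.reset_index(drop=True))


def write_ion_table(df: pd.DataFrame, path: str) -> None:
    validate_ion_table(df)
    df.to_csv(path, index=False)


def read_eem_csv(path: str) -> EEMatrix:
    """Read a wide EEM CSV: first column excitation nm, header emission nm."""
    df = pd.read_csv(path, index_col=0)
    return EEMatrix(
        excitation=df.index.to_numpy(dtype=float),
        emission=np.array([float(c) for c in df.columns]),
        grid=df.to_numpy(dtype=float),
    )
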