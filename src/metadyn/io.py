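"""Measurement-file readers and validation.

CSV dialect: comma-separated, UTF-8, header row required.  Times in I/O
files are days relative to diagnosis (clinicians' data are anchored at
diagnosis); the internal clock starting at the first PT cell is a hidden
convention, converted at the boundary.  Diameters are always in mm in
files; cell counts are never serialized in measurement files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_pt_measurements", "read_bm_measurements", "read_cohort_table"]

_PT_COLUMNS = ("time_days_from_diagnosis", "diameter_mm")
_BM_COLUMNS = ("time_days_from_diagnosis", "lesion_id", "diameter_mm")
_COHORT_COLUMNS = ("d_min_mm", "d_max_mm", "n_patients", "n_with_bm")

#: header fragments that indicate non-supported units; rejected explicitly
#: rather than silently converted
_BAD_UNIT_HINTS = ("_cm", "cm_", "diameter_cm", "_inches", "time_months")


class MeasurementError(ValueError):
    """Raised on malformed measurement files, naming the row/column."""


def _check_schema(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    for col in df.columns:
        low = str(col).lower()
        if any(hint in low for hint in _BAD_UNIT_HINTS):
            raise MeasurementError(
                f"{path}: column {col!r} suggests unsupported units; "
                "expected diameters in mm and times in days (no silent conversion)"
            )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MeasurementError(f"{path}: missing required column(s) {missing}")


def _check_diameters(df: pd.DataFrame, path) -> None:
    bad = df.index[df["diameter_mm"] <= 0]
    if len(bad):
        raise MeasurementError(
            f"{path}: non-positive diameter_mm at row(s) {list(bad[:5])}"
        )


def read_pt_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a primary-tumor measurement CSV."""
    df = pd.read_csv(path)
    _check_schema(df, _PT_COLUMNS, path)
    _check_diameters(df, path)
    if df["time_days_from_diagnosis"].duplicated().any():
        raise MeasurementError(f"{path}: duplicated PT scan times")
    return df.sort_values("time_days_from_diagnosis").reset_index(drop=True)


def read_bm_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a brain-metastasis measurement CSV."""
    df = pd.read_csv(path)
    _check_schema(df, _BM_COLUMNS, path)
    _check_diameters(df, path)
    dup = df.duplicated(subset=["time_days_from_diagnosis", "lesion_id"])
    if dup.any():
        raise MeasurementError(
            f"{path}: duplicated (time, lesion_id) at row(s) {list(df.index[dup][:5])}"
        )
    return df.sort_values(["time_days_from_diagnosis", "lesion_id"]).reset_index(drop=True)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort frequency CSV (one row per diameter bin)."""
    df = pd.read_csv(path)
    _check_schema(df, _COHORT_COLUMNS, path)
    bad = df.index[df["d_min_mm"] >= df["d_max_mm"]]
    if len(bad):
        raise MeasurementError(f"{path}: d_min_mm >= d_max_mm at row(s) {list(bad[:5])}")
    bad = df.index[(df["n_with_bm"] < 0) | (df["n_with_bm"] > df["n_patients"])]
    if len(bad):
        raise MeasurementError(f"{path}: n_with_bm outside [0, n_patients] at row(s) {list(bad[:5])}")
    return df
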