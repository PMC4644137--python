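"""Tabular file formats: profile CSV, NCA CSV, weights CSV.

The profile dialect is a tidy comma-separated table, UTF-8, '.' decimal,
with a header row and columns ``subject_id, trial, time_h, conc_mg_per_l,
urine_cum_mg`` — one row per sampled time point.  Numeric columns are
written with 12 significant digits so that a write -> read round trip is
bit-exact at that precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "PROFILE_COLUMNS",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_nca_csv",
    "read_weights_csv",
]

PROFILE_COLUMNS = ["subject_id", "trial", "time_h", "conc_mg_per_l", "urine_cum_mg"]


def write_profiles_csv(profiles: pd.DataFrame, path) -> None:
    """Write a long-format profile table in the documented dialect."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ParseError(f"profile table lacks columns: {', '.join(missing)}")
    profiles[PROFILE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_profiles_csv(path) -> pd.DataFrame:
    """Read a profile CSV, validating the dialect.

    Raises :class:`ParseError` (naming the offending column or line) on
    an empty file, a missing column, or a non-numeric value.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    for col in ("time_h", "conc_mg_per_l", "urine_cum_mg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric value in {col!r} at line {line}")
        df[col] = coerced
    return df[PROFILE_COLUMNS]


def write_nca_csv(subjects: pd.DataFrame, path) -> None:
    """Write the per-subject NCA table."""
    subjects.to_csv(path, index=False, float_format="%.12g")


def read_weights_csv(path) -> dict[str, float]:
    """Read a two-column ``subject_id, weight_kg`` table."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    for col in ("subject_id", "weight_kg"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column(s): {col}")
    return dict(zip(df["subject_id"].astype(str), df["weight_kg"].astype(float)))
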