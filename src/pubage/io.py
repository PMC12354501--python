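"""Cohort CSV reading and writing.

The on-disk format is a plain CSV with header
``id,sex,age,phase_left,phase_right,session``; sex coded F/M, missing
phases as empty fields, ``session`` optional (defaults to 1). Malformed
rows are rejected with line-numbered messages and the dropped count is
logged — never silently.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .records import COLUMNS, N_STAGES, SEXES

logger = logging.getLogger("pubage")

REQUIRED = ["id", "sex", "age", "phase_left", "phase_right"]


def read_cohort(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Invalid rows (bad sex code, non-positive or non-numeric age, phase
    outside 1..6, both phases missing) are dropped with a line-numbered log
    message, or raise immediately when ``strict=True``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"id": str, "sex": str})
    except pd.errors.EmptyDataError:
        raise DomainError(f"{path}: empty input file") from None
    missing = [c for c in REQUIRED if c not in raw.columns]
    if missing:
        raise DomainError(f"{path}: missing required columns {missing}")
    if raw.empty:
        raise DomainError(f"{path}: no data rows")
    if "session" not in raw.columns:
        raw["session"] = 1

    problems: list[str] = []
    keep = np.ones(len(raw), dtype=bool)

    def _flag(mask: np.ndarray, msg: str) -> None:
        for i in np.flatnonzero(mask):
            problems.append(f"line {i + 2}: {msg}")  # +2: header + 1-based
        keep[mask] = False

    _flag(~raw["sex"].isin(SEXES).to_numpy(), f"sex must be one of {SEXES}")
    age = pd.to_numeric(raw["age"], errors="coerce")
    _flag((age.isna() | (age <= 0)).to_numpy() & keep, "age must be a positive number")
    for col in ("phase_left", "phase_right", "session"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.notna() & ((vals < 1) | (vals > (N_STAGES if col != "session" else np.inf)) | (vals % 1 != 0))
        _flag(bad.to_numpy() & keep, f"{col} must be an integer in range")
        raw[col] = vals
    both_missing = raw["phase_left"].isna() & raw["phase_right"].isna()
    _flag(both_missing.to_numpy() & keep, "both phases missing")
    _flag(raw["session"].isna().to_numpy() & keep, "session must be an integer >= 1")

    if problems:
        if strict:
            raise DomainError(f"{path}: {problems[0]} (+{len(problems) - 1} more)" if len(problems) > 1 else f"{path}: {problems[0]}")
        for p in problems:
            logger.warning("%s: dropped row, %s", path, p)
        logger.warning("%s: dropped %d malformed row(s)", path, len(problems))
    out = raw.loc[keep, COLUMNS].reset_index(drop=True)
    if out.empty:
        raise DomainError(f"{path}: no valid rows after validation")
    out["age"] = out["age"].astype(float)
    out["session"] = out["session"].astype(int)
    return out


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing phases become empty fields and phase
    columns round-trip as integers."""
    out = frame.copy()
    for col in ("phase_left", "phase_right"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)
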