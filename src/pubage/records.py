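"""Scored-individual records and their tabular representation.

A cohort is carried as a :class:`pandas.DataFrame` with columns
``id, sex, age, phase_left, phase_right, session``; :class:`PhaseRecord`
is the validated row-level view. Sex is coded ``F``/``M``; phases are
integers 1..6, missing sides are ``NaN``/``None``; ``session`` numbers
repeated rating attempts from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

COLUMNS = ["id", "sex", "age", "phase_left", "phase_right", "session"]

N_STAGES = 6

SEXES = ("F", "M")


@dataclass(frozen=True)
class PhaseRecord:
    """One scored individual (one rating session)."""

    id: str
    sex: str
    age_years: float
    phase_left: int | None
    phase_right: int | None
    session: int = 1

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not np.isfinite(self.age_years) or self.age_years <= 0:
            raise DomainError(f"age must be a positive number, got {self.age_years!r}")
        if self.phase_left is None and self.phase_right is None:
            raise DomainError("at least one of phase_left/phase_right must be present")
        for side, ph in (("left", self.phase_left), ("right", self.phase_right)):
            if ph is not None and not (1 <= int(ph) <= N_STAGES):
                raise DomainError(f"phase_{side} must be in 1..{N_STAGES}, got {ph!r}")
        if int(self.session) < 1:
            raise DomainError(f"session must be >= 1, got {self.session!r}")


def records_to_frame(records: list[PhaseRecord]) -> pd.DataFrame:
    """Pack records into the canonical cohort DataFrame."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex for r in records],
            "age": [float(r.age_years) for r in records],
            "phase_left": [np.nan if r.phase_left is None else int(r.phase_left) for r in records],
            "phase_right": [np.nan if r.phase_right is None else int(r.phase_right) for r in records],
            "session": [int(r.session) for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[PhaseRecord]:
    """Unpack a cohort DataFrame into validated records."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PhaseRecord(
                id=str(row.id),
                sex=str(row.sex),
                age_years=float(row.age),
                phase_left=None if pd.isna(row.phase_left) else int(row.phase_left),
                phase_right=None if pd.isna(row.phase_right) else int(row.phase_right),
                session=int(getattr(row, "session", 1)),
            )
        )
    return out


def extract_ages_phases(
    frame: pd.DataFrame,
    sex: str | None = None,
    side: str = "left",
    session: int | None = 1,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pull (ages, phases, n_dropped) for one sex and side from a cohort table.

    Records missing the requested side are dropped; the count of dropped rows
    is returned so callers can log it rather than losing them silently.
    """
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")
    df = frame
    if sex is not None:
        if sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {sex!r}")
        df = df[df["sex"] == sex]
    if session is not None and "session" in df.columns:
        df = df[df["session"] == session]
    col = f"phase_{side}"
    present = df[col].notna()
    dropped = int((~present).sum())
    sub = df[present]
    return sub["age"].to_numpy(float), sub[col].to_numpy(float).astype(int), dropped
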