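"""Validation statistics for phase-based age estimation.

Bias is the signed mean error of estimated vs recorded age in years,
``sum(A_est - A_rec)/n``; inaccuracy is the mean absolute error
``sum(|A_est - A_rec|)/n``. Classification accuracy checks whether each
individual's recorded age falls inside the unmodified age range of the
assigned phase. Bilateral concordance is the fraction of individuals whose
left and right faces received the same phase. Intra-observer agreement is
quantified by ICC(A,1) — single-rating, absolute-agreement, two-way — from
two-way ANOVA mean squares, with the conventional interpretation bands
(poor < 0.50, moderate 0.50–0.75, good 0.75–0.90, excellent > 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .exceptions import DomainError
from .records import N_STAGES


# ---------------------------------------------------------------------------
# bias / inaccuracy
# ---------------------------------------------------------------------------


def _paired(estimated, recorded) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float)
    rec = np.asarray(recorded, dtype=float)
    if est.size == 0 or est.shape != rec.shape:
        raise DomainError("estimated and recorded must be equal-length nonempty vectors")
    return est, rec


def bias(estimated, recorded) -> float:
    """Signed mean error (years): positive means over-estimation."""
    est, rec = _paired(estimated, recorded)
    return float(np.mean(est - rec))


def inaccuracy(estimated, recorded) -> float:
    """Mean absolute error (years); always >= |bias| on the same data."""
    est, rec = _paired(estimated, recorded)
    return float(np.mean(np.abs(est - rec)))


# ---------------------------------------------------------------------------
# classification against published phase age ranges
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseRangeTable:
    """Per-phase reference age ranges (and optionally means) in years.

    ``ranges[phase] = (lo, hi)``; ``means[phase]`` is the reference mean age
    used as the estimate ``A_est`` for bias/inaccuracy. Ranges may overlap
    across phases.
    """

    ranges: dict[int, tuple[float, float]]
    means: dict[int, float] | None = None

    def __post_init__(self) -> None:
        for ph, (lo, hi) in self.ranges.items():
            if not 1 <= int(ph) <= N_STAGES:
                raise DomainError(f"phase {ph} outside 1..{N_STAGES}")
            if lo > hi:
                raise DomainError(f"phase {ph}: range lo {lo} > hi {hi}")
            if self.means is not None and ph in self.means:
                m = self.means[ph]
                if not lo <= m <= hi:
                    raise DomainError(f"phase {ph}: mean {m} outside range [{lo}, {hi}]")


def classify(
    phases, ages, ranges: PhaseRangeTable
) -> pd.DataFrame:
    """Label each individual correct / above / below and tabulate per phase.

    'above' means the assigned phase over-estimates: the recorded age lies
    below the phase's range; 'below' is the converse. Returns a table with
    one row per phase plus a 'Total' row and columns n_correct, n_above,
    n_below, n, pct_correct.
    """
    phases = np.asarray(phases).astype(int)
    ages = np.asarray(ages, dtype=float)
    if phases.size == 0 or phases.shape != ages.shape:
        raise DomainError("phases and ages must be equal-length nonempty vectors")
    if np.any((phases < 1) | (phases > N_STAGES)):
        raise DomainError(f"phases must be in 1..{N_STAGES}")
    rows = []
    for ph in sorted(ranges.ranges):
        lo, hi = ranges.ranges[ph]
        sel = phases == ph
        a = ages[sel]
        n_above = int((a < lo).sum())   # assigned phase sits above the true age band
        n_below = int((a > hi).sum())
        n = int(sel.sum())
        rows.append(
            {
                "Phase": ph,
                "n_correct": n - n_above - n_below,
                "n_above": n_above,
                "n_below": n_below,
                "n": n,
            }
        )
    table = pd.DataFrame(rows)
    total = {
        "Phase": "Total",
        **{c: int(table[c].sum()) for c in ("n_correct", "n_above", "n_below", "n")},
    }
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    table["pct_correct"] = np.where(
        table["n"] > 0, 100.0 * table["n_correct"] / table["n"], np.nan
    )
    return table


def classification_accuracy(n_correct: int, n_total: int) -> float:
    """Percentage of correctly classified individuals."""
    if n_total <= 0 or n_correct < 0 or n_correct > n_total:
        raise DomainError("need 0 <= n_correct <= n_total with n_total > 0")
    return 100.0 * n_correct / n_total


# ---------------------------------------------------------------------------
# bilateral concordance
# ---------------------------------------------------------------------------


def bilateral_concordance(phase_left, phase_right) -> tuple[float, dict[int, int]]:
    """Fraction of complete left/right pairs that match, plus the histogram
    of (left - right) phase differences. Pairs with either side missing are
    excluded; no complete pairs is an error."""
    left = np.asarray(phase_left, dtype=float)
    right = np.asarray(phase_right, dtype=float)
    if left.shape != right.shape:
        raise DomainError("phase_left and phase_right must be equal-length")
    ok = ~(np.isnan(left) | np.isnan(right))
    if not ok.any():
        raise DomainError("no complete left/right pairs")
    diff = (left[ok] - right[ok]).astype(int)
    hist = {int(d): int((diff == d).sum()) for d in np.unique(diff)}
    return float(np.mean(diff == 0)), hist


# ---------------------------------------------------------------------------
# intraclass correlation, absolute agreement, single rating
# ---------------------------------------------------------------------------

ICC_BANDS = (
    (0.50, "poor"),        # < 0.50
    (0.75, "moderate"),    # 0.50 .. 0.75 (inclusive)
    (0.90, "good"),        # (0.75 .. 0.90]
    (np.inf, "excellent"), # > 0.90
)


def interpret_icc(value: float) -> str:
    """Interpretation band; 0.75 itself counts as 'moderate'."""
    if value < 0.50:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    value: float
    F: float
    df1: int
    df2: int
    ci95: tuple[float, float]
    band: str
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_absolute_agreement(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) from an n_subjects x k_sessions rating matrix.

    Two-way ANOVA decomposition (rows = subjects, columns = sessions):

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with the F test ``MS_R/MS_E`` on ``(n-1, (n-1)(k-1))`` degrees of freedom
    and the McGraw & Wong confidence-interval construction. Constant ratings
    across all cells leave the variance undefined and raise an error.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DomainError("ratings must be an (n>=2) x (k>=2) matrix")
    if np.any(~np.isfinite(X)):
        raise DomainError("ratings must not contain missing cells")
    n, k = X.shape
    gm = X.mean()
    if np.allclose(X, gm):
        raise DomainError("ratings are constant across all cells; ICC is undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ms_rows = k * np.sum((row_means - gm) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - gm) ** 2) / (k - 1)
    sse = np.sum((X - row_means[:, None] - col_means[None, :] + gm) ** 2)
    ms_error = sse / ((n - 1) * (k - 1))

    icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error + (k / n) * (ms_cols - ms_error))
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_error == 0:  # perfect agreement: F is unbounded, CI degenerate
        return ICCResult(
            value=float(icc), F=float("inf"), df1=df1, df2=df2,
            ci95=(float(icc), float(icc)), band=interpret_icc(float(icc)),
            ms_rows=float(ms_rows), ms_cols=float(ms_cols), ms_error=0.0,
        )
    F = ms_rows / ms_error

    # McGraw & Wong (1996) CI for ICC(A,1)
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v = (a * ms_cols + b * ms_error) ** 2 / (
        (a * ms_cols) ** 2 / (k - 1) + (b * ms_error) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (ms_rows - f1 * ms_error) / (
        f1 * (k * ms_cols + (k * n - k - n) * ms_error) + n * ms_rows
    )
    upper = n * (f2 * ms_rows - ms_error) / (
        k * ms_cols + (k * n - k - n) * ms_error + n * f2 * ms_rows
    )
    return ICCResult(
        value=float(icc),
        F=float(F),
        df1=df1,
        df2=df2,
        ci95=(float(lower), float(upper)),
        band=interpret_icc(float(icc)),
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_error),
    )


# ---------------------------------------------------------------------------
# bracketed reliability report
# ---------------------------------------------------------------------------


def reliability_report(
    estimated,
    recorded,
    brackets: tuple[tuple[float, float], ...] = (
        (17, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 84),
    ),
) -> pd.DataFrame:
    """Bias and inaccuracy per recorded-age bracket plus an overall row.

    Brackets are closed intervals in years on the recorded age; individuals
    outside every bracket are counted only in the overall row.
    """
    est, rec = _paired(estimated, recorded)
    rows = []
    for lo, hi in brackets:
        sel = (rec >= lo) & (rec <= hi)
        rows.append(
            {
                "bracket": f"{lo}-{hi}",
                "n": int(sel.sum()),
                "bias": bias(est[sel], rec[sel]) if sel.any() else np.nan,
                "inaccuracy": inaccuracy(est[sel], rec[sel]) if sel.any() else np.nan,
            }
        )
    rows.append(
        {"bracket": "Total", "n": est.size, "bias": bias(est, rec), "inaccuracy": inaccuracy(est, rec)}
    )
    return pd.DataFrame(rows)
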