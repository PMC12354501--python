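"""Bayesian inversion of the transition model to age-at-death posteriors.

Given a fitted transition model and an observed stage ``c_j``, the posterior
age-at-death density is

    Pr(a | c_j) = Pr(c_j | a) f(a) / integral Pr(c_j | x) f(x) dx

with ``f`` the age prior — here uniform on a truncated support (default
17–86 years), the conservative choice when population mortality data are
unavailable. The posterior is evaluated on a uniform age grid (default step
0.01 y) and normalized by trapezoidal quadrature. Point estimates are
posterior modes (for interior stages under the uniform prior the mode has
the closed form ``exp((t_{j-1} + t_j)/2)``); interval estimates are highest
posterior density (HPD) regions found by bisecting the density threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DomainError, EmptyPosteriorError
from .transition import TransitionAnalysis, TransitionModel, phase_probability

DEFAULT_GRID_STEP = 0.01
DEFAULT_COVERAGES = (0.5, 0.95)


@dataclass(frozen=True)
class UniformPrior:
    """Uniform age-at-death prior on a truncated support (years)."""

    support: tuple[float, float] = (17.0, 86.0)

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (0 < lo < hi):
            raise DomainError(f"prior support must satisfy 0 < lo < hi, got {self.support}")

    def density(self, ages: np.ndarray) -> np.ndarray:
        lo, hi = self.support
        return np.where((ages >= lo) & (ages <= hi), 1.0 / (hi - lo), 0.0)


@dataclass(frozen=True)
class PosteriorCurve:
    """Gridded age-at-death posterior for one stage.

    ``density`` integrates to 1 over the grid (trapezoid rule);
    ``normed_likelihood`` is the same curve rescaled to a maximum of 1.0,
    the form used for plotting.
    """

    phase: int
    grid: np.ndarray
    density: np.ndarray
    sex: str | None = None

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def normed_likelihood(self) -> np.ndarray:
        return self.density / self.density.max()

    def mass(self, mask: np.ndarray) -> float:
        """Trapezoidal mass of the region marked by a boolean mask."""
        return float(np.trapezoid(np.where(mask, self.density, 0.0), self.grid))


@dataclass(frozen=True)
class AgeEstimate:
    """Point estimate and HPD region set for one stage."""

    phase: int
    point_estimate: float
    hpd: dict[float, tuple[tuple[float, float], ...]]
    truncated_low: bool = False
    truncated_high: bool = False
    sex: str | None = None


def posterior_density(
    model: TransitionModel,
    phase: int,
    prior: UniformPrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PosteriorCurve:
    """Posterior age-at-death curve for one observed stage.

    The density is proportional to ``Pr(phase | a) * f(a)`` and normalized by
    trapezoidal integration over the prior support; it is zero outside it.
    """
    if not 1 <= int(phase) <= model.n_stages:
        raise DomainError(f"phase must be in 1..{model.n_stages}, got {phase}")
    prior = prior or UniformPrior(model.support)
    lo, hi = prior.support
    n = int(round((hi - lo) / grid_step)) + 1
    grid = lo + grid_step * np.arange(n)
    grid[-1] = hi
    lik = phase_probability(grid, model)[:, int(phase) - 1]
    unnorm = lik * prior.density(grid)
    z = np.trapezoid(unnorm, grid)
    if z <= 0 or not np.isfinite(z):
        raise EmptyPosteriorError(
            f"stage {phase} has zero likelihood everywhere on the prior support"
        )
    return PosteriorCurve(phase=int(phase), grid=grid, density=unnorm / z, sex=model.sex)


def point_estimate(curve: PosteriorCurve) -> float:
    """Posterior mode in years (smallest age on an exactly flat maximum)."""
    return float(curve.grid[int(np.argmax(curve.density))])


def normed_likelihood(
    model: TransitionModel,
    phase: int,
    prior: UniformPrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PosteriorCurve:
    """Posterior curve whose values are rescaled to a maximum of exactly 1.0
    (the presentation used in age-at-death distribution plots); the returned
    object also retains the normalized density."""
    return posterior_density(model, phase, prior, grid_step)


def hpd_interval(
    curve: PosteriorCurve, coverage: float
) -> tuple[tuple[tuple[float, float], ...], bool, bool]:
    """Highest posterior density region at the given coverage.

    Bisects the density threshold ``c`` so that the region
    ``{a : density(a) >= c}`` holds the requested mass; the region is the
    union of the contiguous grid runs above threshold. Returns
    ``(intervals, truncated_low, truncated_high)`` where the truncation
    flags mark intervals clipped at the support bounds.
    """
    if not 0 < coverage < 1:
        raise DomainError(f"coverage must be in (0, 1), got {coverage}")
    d = curve.density
    lo_c, hi_c = 0.0, float(d.max())
    for _ in range(60):
        mid = 0.5 * (lo_c + hi_c)
        if curve.mass(d >= mid) >= coverage:
            lo_c = mid
        else:
            hi_c = mid
    mask = d >= lo_c
    idx = np.flatnonzero(mask)
    intervals: list[tuple[float, float]] = []
    start = idx[0]
    for prev, cur in zip(idx[:-1], idx[1:]):
        if cur != prev + 1:
            intervals.append((float(curve.grid[start]), float(curve.grid[prev])))
            start = cur
    intervals.append((float(curve.grid[start]), float(curve.grid[idx[-1]])))
    truncated_low = idx[0] == 0
    truncated_high = idx[-1] == d.size - 1
    return tuple(intervals), bool(truncated_low), bool(truncated_high)


def estimate_for_phase(
    model: TransitionModel,
    phase: int,
    prior: UniformPrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    coverages: tuple[float, ...] = DEFAULT_COVERAGES,
) -> AgeEstimate:
    """Point estimate plus HPD regions at each coverage for one stage."""
    curve = posterior_density(model, phase, prior, grid_step)
    hpd: dict[float, tuple[tuple[float, float], ...]] = {}
    t_lo = t_hi = False
    for cov in coverages:
        intervals, lo_flag, hi_flag = hpd_interval(curve, cov)
        hpd[cov] = intervals
        t_lo = t_lo or lo_flag
        t_hi = t_hi or hi_flag
    return AgeEstimate(
        phase=int(phase),
        point_estimate=point_estimate(curve),
        hpd=hpd,
        truncated_low=t_lo,
        truncated_high=t_hi,
        sex=model.sex,
    )


def estimate_table(
    model: TransitionModel,
    prior: UniformPrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    coverages: tuple[float, ...] = DEFAULT_COVERAGES,
) -> pd.DataFrame:
    """Per-stage summary table: point estimate and the outermost interval of
    each HPD region, with truncation flags."""
    rows = []
    for phase in range(1, model.n_stages + 1):
        est = estimate_for_phase(model, phase, prior, grid_step, coverages)
        row: dict[str, object] = {"Phase": phase, "PointEst": est.point_estimate}
        for cov in coverages:
            pct = int(round(100 * cov))
            ivs = est.hpd[cov]
            row[f"HPD{pct}lo"] = ivs[0][0]
            row[f"HPD{pct}hi"] = ivs[-1][1]
        row["truncated_low"] = est.truncated_low
        row["truncated_high"] = est.truncated_high
        rows.append(row)
    return pd.DataFrame(rows)


class BayesianAgeEstimator(BaseEstimator):
    """Age-at-death estimation from ordinal stages, scikit-learn style.

    Either wraps an already-fitted :class:`TransitionModel` (``model=...``,
    call ``fit()`` with no data) or fits one from ``(ages, stages)`` training
    data. ``predict(phases)`` maps observed stages to posterior-mode ages;
    per-stage posteriors and HPD regions are exposed via :meth:`posterior`,
    :meth:`estimate` and :meth:`summary_table`.
    """

    def __init__(
        self,
        model: TransitionModel | None = None,
        prior_support: tuple[float, float] = (17.0, 86.0),
        grid_step: float = DEFAULT_GRID_STEP,
        coverages: tuple[float, ...] = DEFAULT_COVERAGES,
        random_state: int = 0,
    ):
        self.model = model
        self.prior_support = prior_support
        self.grid_step = grid_step
        self.coverages = coverages
        self.random_state = random_state

    def fit(self, X=None, y=None, sex: str | None = None):
        for cov in self.coverages:
            if not 0 < cov < 1:
                raise DomainError(f"coverages must lie in (0, 1), got {cov}")
        if self.model is not None:
            self.model_ = self.model.with_support(self.prior_support)
        else:
            if X is None or y is None:
                raise DomainError("either pass model=... or training data (X, y)")
            ta = TransitionAnalysis(
                support=self.prior_support, random_state=self.random_state
            ).fit(X, y, sex=sex)
            self.model_ = ta.model_
        self.prior_ = UniformPrior(self.prior_support)
        return self

    def posterior(self, phase: int) -> PosteriorCurve:
        self._check_fitted()
        return posterior_density(self.model_, phase, self.prior_, self.grid_step)

    def estimate(self, phase: int) -> AgeEstimate:
        self._check_fitted()
        return estimate_for_phase(
            self.model_, phase, self.prior_, self.grid_step, tuple(self.coverages)
        )

    def predict(self, phases) -> np.ndarray:
        """Posterior-mode age for each observed stage."""
        self._check_fitted()
        phases = np.asarray(phases).astype(int)
        modes = {p: self.estimate(p).point_estimate for p in np.unique(phases)}
        return np.array([modes[p] for p in phases])

    def summary_table(self) -> pd.DataFrame:
        self._check_fitted()
        return estimate_table(
            self.model_, self.prior_, self.grid_step, tuple(self.coverages)
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise DomainError("estimator is not fitted; call fit() first")
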