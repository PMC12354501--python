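"""Log-age cumulative probit transition analysis.

The model: an individual of age ``a`` is in ordinal stage ``j`` (of ``J``)
with probability

    Pr(stage = j | a) = Phi((t_j - ln a) / sigma) - Phi((t_{j-1} - ln a) / sigma)

with ``t_0 = -inf``, ``t_J = +inf`` and ``Phi`` the standard normal CDF.
Each threshold ``t_j`` is the mean log age at which the stage ``j -> j+1``
transition occurs, so the age-at-transition distributions are log-normal
with common log-scale SD ``sigma``; ``exp(t_j)`` is the maximum-likelihood
age-at-transition in years. Equivalently ``Pr(stage > j | a) =
Phi((ln a - t_j)/sigma)``, a cumulative probit in log age with common slope
``1/sigma`` and intercepts ``-t_j/sigma``.

Fitting maximizes the multinomial likelihood over the parameterization
``(t_1, log(t_2 - t_1), ..., log(t_{J-1} - t_{J-2}), log sigma)``, which keeps
the thresholds strictly ordered without constraints. Standard errors come
from the inverse observed information, differentiated directly in the
reported ``(t, sigma)`` coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceWarning,
    DegenerateDataError,
    DomainError,
    InvalidModelError,
)
from .records import N_STAGES

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def transition_labels(n_stages: int = N_STAGES) -> list[str]:
    """Labels 'I-II', 'II-III', ... for the stage boundaries."""
    return [f"{ROMAN[j]}-{ROMAN[j + 1]}" for j in range(n_stages - 1)]


@dataclass(frozen=True)
class TransitionModel:
    """Sex-specific fitted probit parameters.

    Parameters
    ----------
    thresholds : ndarray of shape (J-1,)
        Mean log ages-at-transition ``t_1 < ... < t_{J-1}`` (log-years).
    sigma : float
        Common log-scale SD (log-years), > 0.
    standard_errors : ndarray of shape (J-1,), optional
        SE of each threshold; NaN when the information matrix was singular.
    sigma_se : float, optional
        SE of ``sigma``.
    log_likelihood : float, optional
        Attained log-likelihood of the fit.
    support : (float, float)
        Age support in years used downstream for the uniform prior.
    """

    thresholds: np.ndarray
    sigma: float
    sex: str | None = None
    standard_errors: np.ndarray | None = None
    sigma_se: float | None = None
    log_likelihood: float | None = None
    converged: bool = True
    support: tuple[float, float] = (17.0, 86.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", t)
        if t.ndim != 1 or t.size < 1:
            raise InvalidModelError("thresholds must be a 1-D array with >= 1 entry")
        if not np.all(np.isfinite(t)):
            raise InvalidModelError("thresholds must be finite")
        if np.any(np.diff(t) <= 0):
            raise InvalidModelError(f"thresholds must be strictly increasing, got {t}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidModelError(f"sigma must be > 0, got {self.sigma}")
        lo, hi = self.support
        if not (0 < lo < hi):
            raise InvalidModelError(f"support must satisfy 0 < lo < hi, got {self.support}")

    @property
    def n_stages(self) -> int:
        return self.thresholds.size + 1

    def with_support(self, support: tuple[float, float]) -> "TransitionModel":
        return replace(self, support=tuple(support))


def phase_probability(age_years, model: TransitionModel) -> np.ndarray:
    """Probability vector over the J stages at the given age(s).

    Accepts a scalar age (returns shape ``(J,)``) or an array of ages
    (returns shape ``(n, J)``). Probabilities are nonnegative and sum to 1.
    """
    age = np.asarray(age_years, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    if np.any(~np.isfinite(age)) or np.any(age <= 0):
        raise DomainError("age must be positive and finite")
    z = (model.thresholds[None, :] - np.log(age)[:, None]) / model.sigma
    cum = np.concatenate(
        [np.zeros((age.size, 1)), norm.cdf(z), np.ones((age.size, 1))], axis=1
    )
    p = np.diff(cum, axis=1)
    p = np.clip(p, 0.0, 1.0)
    return p[0] if scalar else p


def stage_exceedance(age_years, model: TransitionModel, j: int) -> np.ndarray:
    """Pr(stage > j | age) = Phi((ln age - t_j) / sigma); nondecreasing in age."""
    if not 1 <= j <= model.n_stages - 1:
        raise DomainError(f"j must be in 1..{model.n_stages - 1}")
    age = np.asarray(age_years, dtype=float)
    if np.any(age <= 0):
        raise DomainError("age must be positive")
    return norm.cdf((np.log(age) - model.thresholds[j - 1]) / model.sigma)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, float]:
    """(t1, log d2.., log sigma) -> (ordered thresholds, sigma)."""
    t1 = theta[0]
    deltas = np.exp(theta[1:-1])
    sigma = float(np.exp(theta[-1]))
    return np.concatenate([[t1], t1 + np.cumsum(deltas)]), sigma


def _pack(thresholds: np.ndarray, sigma: float) -> np.ndarray:
    d = np.diff(thresholds)
    return np.concatenate([[thresholds[0]], np.log(d), [np.log(sigma)]])


def _nll(theta: np.ndarray, log_age: np.ndarray, phase: np.ndarray, n_stages: int) -> float:
    t, sigma = _unpack(theta)
    z = (t[None, :] - log_age[:, None]) / sigma
    cum = np.concatenate(
        [np.zeros((log_age.size, 1)), norm.cdf(z), np.ones((log_age.size, 1))], axis=1
    )
    p = cum[np.arange(phase.size), phase] - cum[np.arange(phase.size), phase - 1]
    return float(-np.sum(np.log(np.maximum(p, 1e-300))))


def _nll_natural(params: np.ndarray, log_age: np.ndarray, phase: np.ndarray, n_stages: int) -> float:
    """NLL in the reported (t_1..t_{J-1}, sigma) coordinates (for the Hessian)."""
    t, sigma = params[:-1], params[-1]
    if np.any(np.diff(t) <= 0) or sigma <= 0:
        return np.inf
    z = (t[None, :] - log_age[:, None]) / sigma
    cum = np.concatenate(
        [np.zeros((log_age.size, 1)), norm.cdf(z), np.ones((log_age.size, 1))], axis=1
    )
    p = cum[np.arange(phase.size), phase] - cum[np.arange(phase.size), phase - 1]
    return float(-np.sum(np.log(np.maximum(p, 1e-300))))


def _hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _initial_theta(log_age: np.ndarray, phase: np.ndarray, n_stages: int) -> np.ndarray:
    """Data-driven start: threshold j at the midpoint of mean log ages of
    adjacent observed phases, quantile fallback for unobserved phases;
    sigma at the pooled within-phase SD of log age."""
    means = np.full(n_stages, np.nan)
    for j in range(1, n_stages + 1):
        sel = phase == j
        if sel.any():
            means[j - 1] = log_age[sel].mean()
    t0 = np.empty(n_stages - 1)
    for j in range(n_stages - 1):
        lo, hi = means[j], means[j + 1]
        if np.isfinite(lo) and np.isfinite(hi) and hi > lo:
            t0[j] = 0.5 * (lo + hi)
        else:
            t0[j] = np.quantile(log_age, (j + 1) / n_stages)
    # enforce strict ordering on the start
    eps = 1e-3
    for j in range(1, n_stages - 1):
        t0[j] = max(t0[j], t0[j - 1] + eps)
    resid = []
    for j in range(1, n_stages + 1):
        sel = phase == j
        if sel.sum() >= 2:
            resid.append(log_age[sel] - log_age[sel].mean())
    sigma0 = float(np.std(np.concatenate(resid))) if resid else 0.3
    sigma0 = max(sigma0, 0.05)
    return _pack(t0, sigma0)


def fit_transition_model(
    ages: np.ndarray,
    phases: np.ndarray,
    sex: str | None = None,
    n_stages: int = N_STAGES,
    support: tuple[float, float] = (17.0, 86.0),
    n_starts: int = 3,
    tol: float = 1e-8,
    random_state: int = 0,
) -> TransitionModel:
    """Maximum-likelihood fit of the log-age cumulative probit model.

    Parameters
    ----------
    ages, phases : array-like
        Ages in years (> 0) and observed stages in 1..``n_stages``.
    n_starts : int
        Number of optimizer starts (1 data-driven + jittered copies).

    Raises
    ------
    DegenerateDataError
        If fewer than two distinct stages are observed (no transition is
        identifiable).
    """
    ages = np.asarray(ages, dtype=float)
    phases = np.asarray(phases).astype(int)
    if ages.size == 0 or ages.size != phases.size:
        raise DomainError("ages and phases must be equal-length and nonempty")
    if np.any(ages <= 0):
        raise DomainError("all ages must be positive")
    if np.any((phases < 1) | (phases > n_stages)):
        raise DomainError(f"phases must be in 1..{n_stages}")
    if np.unique(phases).size < 2:
        raise DegenerateDataError(
            "need at least 2 distinct observed phases to identify a transition"
        )

    log_age = np.log(ages)
    theta0 = _initial_theta(log_age, phases, n_stages)
    rng = np.random.default_rng(random_state)
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.1, size=theta0.size) for _ in range(n_starts - 1)
    ]

    best = None
    any_converged = False
    for s in starts:
        res = minimize(
            _nll, s, args=(log_age, phases, n_stages), method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn(
            "transition-model fit did not report convergence from any start",
            ConvergenceWarning,
            stacklevel=2,
        )

    t_hat, sigma_hat = _unpack(best.x)

    # observed information in the reported (t, sigma) coordinates
    se_t = np.full(n_stages - 1, np.nan)
    se_sigma = np.nan
    natural = np.concatenate([t_hat, [sigma_hat]])
    try:
        H = _hessian(lambda p: _nll_natural(p, log_age, phases, n_stages), natural)
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.all(np.isfinite(var)) and np.all(var > 0):
            se_t = np.sqrt(var[:-1])
            se_sigma = float(np.sqrt(var[-1]))
        else:
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information matrix is singular or indefinite; "
            "standard errors reported as NaN",
            ConvergenceWarning,
            stacklevel=2,
        )

    return TransitionModel(
        thresholds=t_hat,
        sigma=sigma_hat,
        sex=sex,
        standard_errors=se_t,
        sigma_se=se_sigma,
        log_likelihood=-float(best.fun),
        converged=any_converged,
        support=tuple(support),
    )


def age_at_transition_summary(model: TransitionModel) -> pd.DataFrame:
    """Per-transition summary table: Estimate (log-years), SE, expEst (years),
    plus a final 'SD' row holding the common log-scale SD."""
    labels = transition_labels(model.n_stages)
    se = (
        model.standard_errors
        if model.standard_errors is not None
        else np.full(model.n_stages - 1, np.nan)
    )
    rows = pd.DataFrame(
        {
            "Parameter": labels,
            "Estimate": model.thresholds,
            "SE": np.asarray(se, dtype=float),
            "expEst": np.exp(model.thresholds),
        }
    )
    sd_row = pd.DataFrame(
        {
            "Parameter": ["SD"],
            "Estimate": [model.sigma],
            "SE": [np.nan if model.sigma_se is None else model.sigma_se],
            "expEst": [np.nan],
        }
    )
    return pd.concat([rows, sd_row], ignore_index=True)


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


class TransitionAnalysis(BaseEstimator):
    """Ordinal cumulative-probit transition analysis, scikit-learn style.

    ``fit(X, y)`` takes ages (``X``, shape ``(n,)`` or ``(n, 1)``, years) and
    observed stages (``y``, integers 1..``n_stages``); ``predict_proba(X)``
    returns the stage probability matrix at the given ages.

    Attributes
    ----------
    thresholds_ : ndarray of shape (n_stages - 1,)
        Fitted mean log ages-at-transition.
    sigma_ : float
        Fitted common log-scale SD.
    standard_errors_, sigma_se_ : SEs from the observed information.
    log_likelihood_ : float
        Attained log-likelihood.
    model_ : TransitionModel
        The fitted model as an immutable value object.
    """

    def __init__(
        self,
        n_stages: int = N_STAGES,
        support: tuple[float, float] = (17.0, 86.0),
        n_starts: int = 3,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_stages = n_stages
        self.support = support
        self.n_starts = n_starts
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _as_ages(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DomainError("X must be a single column of ages")
            X = X[:, 0]
        return X

    def fit(self, X, y, sex: str | None = None):
        ages = self._as_ages(X)
        model = fit_transition_model(
            ages,
            np.asarray(y),
            sex=sex,
            n_stages=self.n_stages,
            support=self.support,
            n_starts=self.n_starts,
            tol=self.tol,
            random_state=self.random_state,
        )
        self.model_ = model
        self.thresholds_ = model.thresholds
        self.sigma_ = model.sigma
        self.standard_errors_ = model.standard_errors
        self.sigma_se_ = model.sigma_se
        self.log_likelihood_ = model.log_likelihood
        self.converged_ = model.converged
        self.classes_ = np.arange(1, self.n_stages + 1)
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return phase_probability(self._as_ages(X), self.model_)

    def predict(self, X) -> np.ndarray:
        """Most probable stage at each age."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        """Mean log-likelihood of the observed stages under the model."""
        self._check_fitted()
        p = self.predict_proba(X)
        y = np.asarray(y).astype(int)
        return float(np.mean(np.log(np.maximum(p[np.arange(y.size), y - 1], 1e-300))))

    def transition_summary(self) -> pd.DataFrame:
        self._check_fitted()
        return age_at_transition_summary(self.model_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise DomainError("estimator is not fitted; call fit(X, y) first")
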