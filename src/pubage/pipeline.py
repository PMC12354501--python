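"""End-to-end analysis pipeline: fit -> invert -> summarize -> validate.

``run_pipeline`` consumes a :class:`RunConfig` and writes, per sex present
in the input: the age-at-transition summary, the per-stage age-at-death
estimate table, optional gridded posterior curves, a bracketed
bias/inaccuracy report, a classification table against the reference phase
ranges, and a JSON summary (bilateral concordance, ICC when repeated
sessions exist). Every run also writes the config snapshot it used. Output
is deterministic given inputs and seed; rounding happens only at
serialization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, reliability
from .exceptions import ConfigError, PubageError
from .io import read_cohort
from .records import extract_ages_phases
from .reference import DEFAULT_BRACKETS, DEFAULT_SUPPORT, SUCHEY_BROOKS_RANGES
from .transition import TransitionAnalysis

logger = logging.getLogger("pubage")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input: str
    outdir: str
    sex_filter: str | None = None          # None = all sexes present
    side: str = "left"
    support: tuple[float, float] = DEFAULT_SUPPORT
    grid_step: float = 0.01
    coverages: tuple[float, ...] = (0.5, 0.95)
    phase_ranges: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(SUCHEY_BROOKS_RANGES)
    )
    reference_means: dict[int, float] | None = None
    brackets: tuple[tuple[float, float], ...] = DEFAULT_BRACKETS
    export_curves: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ConfigError(f"side must be 'left' or 'right', got {self.side!r}")
        lo, hi = self.support
        if not lo < hi:
            raise ConfigError(f"support must satisfy a_min < a_max, got {self.support}")
        for cov in self.coverages:
            if not 0 < cov < 1:
                raise ConfigError(f"coverages must lie in (0, 1), got {cov}")
        if self.sex_filter not in (None, "F", "M"):
            raise ConfigError(f"sex_filter must be None/'F'/'M', got {self.sex_filter!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "phase_ranges" in data:
            data["phase_ranges"] = {int(k): tuple(v) for k, v in data["phase_ranges"].items()}
        if data.get("reference_means"):
            data["reference_means"] = {int(k): float(v) for k, v in data["reference_means"].items()}
        for key in ("support", "coverages"):
            if key in data:
                data[key] = tuple(data[key])
        if "brackets" in data:
            data["brackets"] = tuple(tuple(b) for b in data["brackets"])
        return cls(**data)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["support"] = list(self.support)
        d["coverages"] = list(self.coverages)
        d["brackets"] = [list(b) for b in self.brackets]
        return d


def _stage(name: str):
    """Decorator re-raising package errors with the failing stage's name."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PubageError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("read")
def _read(config: RunConfig) -> pd.DataFrame:
    return read_cohort(config.input)


@_stage("fit")
def _fit(config: RunConfig, cohort: pd.DataFrame, sex: str) -> TransitionAnalysis:
    ages, phases, dropped = extract_ages_phases(cohort, sex=sex, side=config.side)
    if dropped:
        logger.info("sex %s: dropped %d record(s) missing %s phase", sex, dropped, config.side)
    ta = TransitionAnalysis(support=config.support, random_state=config.seed)
    return ta.fit(ages, phases, sex=sex)


@_stage("invert")
def _invert(config: RunConfig, ta: TransitionAnalysis) -> pd.DataFrame:
    est = bayes.BayesianAgeEstimator(
        model=ta.model_,
        prior_support=config.support,
        grid_step=config.grid_step,
        coverages=config.coverages,
    ).fit()
    return est.summary_table()


@_stage("validate")
def _validate(config: RunConfig, cohort: pd.DataFrame, sex: str) -> dict:
    ages, phases, _ = extract_ages_phases(cohort, sex=sex, side=config.side)
    ranges = reliability.PhaseRangeTable(config.phase_ranges, config.reference_means)
    out: dict[str, object] = {}
    out["classification"] = reliability.classify(phases, ages, ranges)
    if config.reference_means:
        a_est = np.array([config.reference_means[p] for p in phases])
        out["report"] = reliability.reliability_report(a_est, ages, config.brackets)
    sub = cohort[cohort["sex"] == sex]
    first = sub[sub["session"] == sub["session"].min()]
    both = first["phase_left"].notna() & first["phase_right"].notna()
    if both.any():
        frac, hist = reliability.bilateral_concordance(
            first["phase_left"], first["phase_right"]
        )
        out["concordance"] = frac
        out["lr_differences"] = hist
    sessions = sorted(sub["session"].unique())
    if len(sessions) >= 2:
        col = f"phase_{config.side}"
        mat = sub.pivot_table(index="id", columns="session", values=col).dropna()
        if len(mat) >= 2:
            icc = reliability.icc_absolute_agreement(mat.to_numpy())
            out["icc"] = icc
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write the artifact bundle to ``config.outdir``.

    Returns a dict mapping artifact names to file paths (and, under
    ``"results"``, the in-memory per-sex objects).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _read(config)
    sexes = [config.sex_filter] if config.sex_filter else sorted(cohort["sex"].unique())

    paths: dict[str, object] = {}
    results: dict[str, dict] = {}
    summary: dict[str, object] = {"seed": config.seed, "sexes": sexes}

    for sex in sexes:
        ta = _fit(config, cohort, sex)
        trans = ta.transition_summary()
        p = outdir / f"transitions_{sex}.csv"
        trans.round(4).to_csv(p, index=False)
        paths[f"transitions_{sex}"] = str(p)

        table5 = _invert(config, ta)
        p = outdir / f"age_estimates_{sex}.csv"
        table5.round(1).to_csv(p, index=False)
        paths[f"age_estimates_{sex}"] = str(p)

        if config.export_curves:
            est = bayes.BayesianAgeEstimator(
                model=ta.model_, prior_support=config.support, grid_step=config.grid_step
            ).fit()
            curves = []
            for phase in range(1, ta.model_.n_stages + 1):
                c = est.posterior(phase)
                curves.append(
                    pd.DataFrame(
                        {
                            "phase": phase,
                            "age": c.grid,
                            "density": c.density,
                            "normed_likelihood": c.normed_likelihood,
                        }
                    )
                )
            p = outdir / f"curves_{sex}.csv"
            pd.concat(curves, ignore_index=True).to_csv(p, index=False, float_format="%.6g")
            paths[f"curves_{sex}"] = str(p)

        val = _validate(config, cohort, sex)
        p = outdir / f"classification_{sex}.csv"
        val["classification"].round(1).to_csv(p, index=False)
        paths[f"classification_{sex}"] = str(p)
        if "report" in val:
            p = outdir / f"bias_inaccuracy_{sex}.csv"
            val["report"].round(1).to_csv(p, index=False)
            paths[f"bias_inaccuracy_{sex}"] = str(p)

        sex_summary: dict[str, object] = {
            "n": int((cohort["sex"] == sex).sum()),
            "log_likelihood": ta.log_likelihood_,
            "converged": bool(ta.converged_),
        }
        if "concordance" in val:
            sex_summary["bilateral_concordance"] = val["concordance"]
            sex_summary["lr_differences"] = {str(k): v for k, v in val["lr_differences"].items()}
        if "icc" in val:
            icc = val["icc"]
            sex_summary["icc"] = {
                "value": icc.value,
                "F": icc.F,
                "df": [icc.df1, icc.df2],
                "ci95": list(icc.ci95),
                "band": icc.band,
            }
        if "report" in val:
            total = val["report"].iloc[-1]
            sex_summary["bias"] = float(total["bias"])
            sex_summary["inaccuracy"] = float(total["inaccuracy"])
        total_row = val["classification"].iloc[-1]
        sex_summary["classification_pct_correct"] = float(total_row["pct_correct"])
        summary[sex] = sex_summary
        results[sex] = {"transition": ta, "table5": table5, "validation": val}

    p = outdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    paths["summary"] = str(p)

    p = outdir / "config.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(config.snapshot(), fh, sort_keys=True)
    paths["config"] = str(p)

    paths["results"] = results
    return paths
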