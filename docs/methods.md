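# Methods

## Model and assumptions

Stage assignment is modelled as a cumulative probit on log age with a
common scale parameter: the latent variable is ln(age-at-transition), each
boundary j → j+1 has mean `t_j` (log-years) and all boundaries share the
SD `σ` (log-years). Equivalent parameterizations exist in terms of probit
intercepts and a common slope (`t_j = α_j/β`, `σ = 1/β`); this package
works and reports in `(t, σ)` form because that is how population
standards tabulate age-at-transition (`exp(t_j)` in years). Assumptions
worth keeping in mind:

- a single common `σ` across boundaries (the classical homoscedastic
  form); stage-specific variances are deliberately out of scope;
- log-age scaling, which keeps age-at-transition distributions strictly
  positive and right-skewed in years;
- conditional independence of the observed stage given age — repeated
  ratings and left/right sides are treated by the reliability and
  simulation layers, not inside the likelihood.

## Fitting

The multinomial likelihood is maximized in the unconstrained
parameterization `(t_1, log Δ_2, …, log Δ_{J−1}, log σ)` with
`Δ_j = t_j − t_{j−1}`, which enforces strict threshold ordering by
construction. Optimization uses L-BFGS-B with numerically differenced
gradients, objective tolerance 1e−8, and three starts (one data-driven:
thresholds at midpoints of adjacent phases' mean log ages, `σ` at the
pooled within-phase SD of log age; two jittered copies, jitter drawn from
a fixed `random_state`) to guard against flat stretches of the likelihood.
Non-convergence from every start is surfaced as a `ConvergenceWarning` and
a `converged=False` flag, never silently.

Standard errors are square roots of the diagonal of the inverse observed
information, computed by central-difference Hessian directly in the
reported `(t, σ)` coordinates (equivalent to delta-method transformation
from the optimization coordinates, without the extra algebra). A singular
or indefinite Hessian yields NaN standard errors plus a warning rather
than fabricated values. Fewer than two observed stages is an error: no
transition is identifiable.

## Bayesian inversion

The posterior of age given stage is `Pr(c_j|a) f(a)` normalized by
trapezoidal quadrature on a uniform age grid over the prior support.
Numerical choices:

- **Prior.** Uniform on [17, 86] years by default. The prior abstraction
  admits only the uniform form; informative hazard-based priors
  (Gompertz-Makeham, Kaplan-Meier) require population mortality data and
  are a declared non-goal.
- **Grid.** Uniform in age (not log age), step 0.01 y. The age-scale
  choice is validated by a closed-form identity: for interior stages under
  a uniform-in-age prior the posterior mode is exactly
  `exp((t_{j−1}+t_j)/2)`, and the numerical mode matches within one grid
  step for every interior stage of both reference models.
- **Point estimate.** Grid argmax; ties on an exactly flat stretch break
  to the smallest age; boundary modes report the support bound.
- **HPD.** Bisection on the density threshold `c`: the region
  `{a : π(a) ≥ c}` is shrunk/grown until its trapezoidal mass hits the
  requested coverage (60 bisection steps). The region is a union of
  contiguous grid runs, so multi-interval output is supported even though
  all reference cases yield one interval; intervals touching the support
  bounds are flagged truncated. The mass error is at most one grid cell's
  mass and halving the step shrinks it (checked by test).
- Reported tables round to one decimal in years at serialization only.

### Known limitation: late-phase HPD bounds

Under the truncated uniform prior on [17, 86], the HPD bounds for phases
I–III (both sexes) and every truncated 17/86 endpoint are stable and
insensitive to algorithmic details. For phases IV–VI the posterior is
extremely flat near the upper truncation, so HPD endpoints there are
ill-conditioned: small differences in support handling or quadrature move
them by years. Published standards computed with other internals (e.g.
posteriors evaluated on a wider internal age range and clipped for
reporting, or sample-based HPD routines) can therefore differ for those
phases while agreeing exactly on all point estimates and early-phase
bounds. This package treats the stated prior support as authoritative and
documents the sensitivity rather than tuning to any particular published
rendering.

## Reliability metrics

- **Bias / inaccuracy**: signed and absolute mean error of estimated vs
  recorded age, in years; `A_est` is the reference mean age of the
  assigned phase, supplied via configuration (the classical standard's
  per-phase means are not bundled; synthetic workflows use the
  simulator's own phase means). Reported per closed integer age bracket
  (default 17–29, 30–39, 40–49, 50–59, 60–69, 70–84) plus overall.
- **Classification**: an individual is correct when the recorded age lies
  inside the unmodified S-B range of the assigned phase; otherwise the
  phase over-estimates ("above", recorded age below the range) or
  under-estimates ("below"). Counts are conserved across strata and the
  overall percentage is the n-weighted mean of per-phase percentages.
- **Bilateral concordance**: fraction of complete left/right pairs with
  identical phase, with the histogram of left-minus-right differences.
- **ICC(A,1)**: single-rating absolute-agreement two-way intraclass
  correlation from ANOVA mean squares,
  `(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, with
  `F = MS_R/MS_E` on `(n−1, (n−1)(k−1))` df and the McGraw-Wong 95% CI.
  Interpretation bands place 0.75 itself in "moderate": poor < 0.50,
  moderate 0.50–0.75, good (0.75–0.90], excellent > 0.90. Perfect
  agreement returns ICC 1 with an unbounded F and a degenerate CI;
  all-constant ratings are an error (undefined variance).
- Routine hypothesis tests around these metrics (Wilcoxon, Mann-Whitney,
  paired t) are delegated to scipy/statsmodels by users; they are not
  re-implemented here.

## Synthetic cohorts

`simulate_cohort` emulates the statistical observation process the
analysis assumes: ages from a truncated normal (female mean 43.7, SD 12.8;
male mean 50.9, SD 13.3; support 17–86 y — the reference cohort's moments)
or uniform distribution; the left-face stage drawn from the probit stage
probabilities at the drawn age; the right face equal to the left with
probability 1 − δ and otherwise off by exactly one stage (δ defaults to
0.315, the reference cohort's observed non-match rate, applied to both
sexes since no sex-specific breakdown is published); repeated sessions
perturb the previous rating by ±1 stage with probability ε per side,
clamped to 1..6 with no wraparound and to at most one stage of left/right
disagreement. ε defaults to 0.2 per session, chosen once as a realistic
re-rating perturbation rate for ordinal CT scoring that lands agreement in
the moderate-to-good ICC range typical of this instrument. Random streams
are spawned per component (ages, stages, asymmetry, sessions) from the
master seed, so toggling one feature leaves the others' draws unchanged.

What the generator does *not* emulate: true morphological variation
(stages are exactly probit-consistent, with no inter-individual scoring
style), age-heaping or record errors in recorded ages, missingness, and
any correlation between bilateral asymmetry and age. Passing tests
therefore demonstrate correctness of the statistical chain under its own
assumptions, not robustness of the S-B instrument on real skeletal
material.

`recovery_experiment` refits the model on replicate cohorts and reports
per-parameter bias, RMSE and Monte-Carlo SE, counting (never dropping)
non-convergent fits. Default experiment sizes used by the test suite and
the acceptance script (2000 individuals per cohort, 10–20 replicates; a
50k cohort for marginal-frequency checks) were chosen to keep Monte-Carlo
error well below the tolerances being asserted.

## Design notes

- Everything is sex-stratified; standards for females and males are fit
  and inverted separately throughout.
- The analysis chain is exposed both as scikit-learn-style estimators
  (`TransitionAnalysis`, `BayesianAgeEstimator`) and as plain functions;
  the estimators validate inputs, expose fitted attributes with trailing
  underscores, and compose with sklearn tooling.
- The pipeline (`run_pipeline` / `pubage report`) is deterministic given
  input and seed, writes the config snapshot beside its outputs, and
  prefixes stage names to propagated errors.
- Side selection defaults to the left symphyseal face; records missing the
  requested side are dropped with a logged count.
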