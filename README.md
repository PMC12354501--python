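# pubage

Transition analysis and Bayesian age-at-death estimation from
Suchey-Brooks pubic-symphysis phases.

Forensic anthropologists estimate adult age-at-death from the morphology of
the pubic symphyseal face, scored as one of six ordinal Suchey-Brooks (S-B)
phases. Classical phase-based standards inherit the age structure of their
reference sample ("age mimicry"); transition analysis plus Bayesian
inversion avoids this by modelling the ages at which individuals move
between phases and then conditioning on the observed phase. This package
implements that chain for population-specific standards — it ships the
parameters of a contemporary Indonesian reference cohort — together with
the validation statistics used to benchmark ageing methods and a synthetic
cohort generator so the entire pipeline is testable end to end.

## The model

Stage membership follows a log-age cumulative probit with common scale:

    Pr(stage = j | a) = Φ((t_j − ln a)/σ) − Φ((t_{j−1} − ln a)/σ),
    t_0 = −∞,  t_J = +∞,

so each age-at-transition j → j+1 is log-normal with mean log age `t_j` and
common log-scale SD `σ` (maximum-likelihood age-at-transition `exp(t_j)`
years). Fitting maximizes the multinomial likelihood over
`(t_1, log Δ_2, …, log Δ_{J−1}, log σ)`, which keeps thresholds ordered
without constraints; standard errors come from the inverse observed
information.

The fitted model is inverted with Bayes' theorem under a truncated uniform
age prior f(a) on [17, 86] years (the conservative choice when population
mortality data are unavailable):

    Pr(a | c_j) = Pr(c_j | a) f(a) / ∫ Pr(c_j | x) f(x) dx.

Per phase this yields a gridded posterior density of age-at-death, its mode
as point estimate (for interior phases the mode is exactly
`exp((t_{j−1}+t_j)/2)`), and 50%/95% highest-posterior-density (HPD)
regions found by bisecting the density threshold.

Validation statistics: bias `Σ(A_est − A_rec)/n` and inaccuracy
`Σ|A_est − A_rec|/n` (years), classification accuracy against the
unmodified S-B age ranges, bilateral left/right concordance, and
intra-observer ICC(A,1) (single-rating, absolute-agreement, two-way) with
the conventional interpretation bands.

## Worked example

Simulate a cohort at the female Indonesian reference truth, refit the
transition model, and invert the reference model to age-at-death estimates:

```python
import pubage as pa

cohort = pa.simulate_cohort(pa.preset("female-indonesia", n=213, seed=1))
m = pa.fit_transition_model(cohort["age"], cohort["phase_left"], sex="F")
print(pa.age_at_transition_summary(m).round(2).to_string(index=False))

est = pa.BayesianAgeEstimator(model=pa.INDONESIA_FEMALE).fit()
print(est.summary_table().round(1).to_string(index=False))
```

```
Parameter  Estimate   SE  expEst
     I-II      3.00 0.08   20.01
   II-III      3.32 0.05   27.66
   III-IV      3.62 0.03   37.39
     IV-V      3.91 0.03   49.91
     V-VI      4.31 0.06   74.76
       SD      0.33 0.03     NaN

 Phase  PointEst  HPD50lo  HPD50hi  HPD95lo  HPD95hi  truncated_low  truncated_high
     1      17.0     17.0     22.0     17.0     36.7           True           False
     2      23.4     18.5     29.7     17.0     50.7           True           False
     3      32.6     25.2     42.3     17.0     66.4           True           False
     4      44.7     35.1     57.0     24.5     81.6          False           False
     5      66.0     56.0     77.8     37.4     86.0          False            True
     6      86.0     73.7     86.0     50.0     86.0          False            True
```

The first table is the refit on the 213-individual simulated cohort: each
`Estimate` is a mean log age-at-transition recovered close to its
generating value, `expEst` the same transition in years. The second table
is the age-at-death standard derived from the reference parameters: a
female individual in phase IV has posterior-mode age 44.7 y, with 50%
probability of being 35.1–57.0 y and 95% probability of 24.5–81.6 y;
phases I and VI pile up against the prior support, so their point
estimates sit at the 17 y / 86 y truncation bounds.

The same chain is scriptable from the shell:

```sh
pubage simulate --preset female-indonesia --n 213 --seed 1 --out cohort.csv
pubage report --input cohort.csv --outdir results/
```

which writes the transition summary, per-phase age estimates,
classification and bias/inaccuracy tables, a JSON summary, and the config
snapshot used.

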