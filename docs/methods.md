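# Methods

## The index and its decision rules

`I_SIM = ES_THEO / ES_OBS` compares a point prediction with an observation on
the same scale. Three rules make the ratio usable as a verdict:

* **Opposite direction.** If the signs of prediction and observation
  disagree, the prediction has failed regardless of magnitude; `I_SIM` is
  recorded as 0. The raw signed ratio is retained in a diagnostic field so
  no information is destroyed. Two *negative* effects agree in direction and
  are treated like two positive ones (the ratio of differences is invariant
  to the order of the groups).
* **Zero observation.** `ES_OBS = 0` leaves the ratio undefined; such cases
  are counted separately, never silently dropped.
* **Zero prediction.** `ES_THEO = 0` is rejected as input. A point
  prediction of exactly no effect cannot be evaluated by a ratio, and an
  effect smaller than the standard measurement error is not a usable point
  prediction in the first place.

The similarity interval (SI) is applied as a *closed* interval
`[0.80, 1.20]`: a ratio exactly on a bound counts as a match. Nothing in the
index's definition forces this; we chose closed bounds for user-facing
classification because an observation that is exactly 25% off the prediction
should not fall between two categories. Under the continuous sampling models
used here the boundary carries zero probability, so the choice never affects
coverage percentages. Histogram binning, by contrast, follows the
conventional left-open/right-closed scheme of the ten reporting bins
(`<=0.6`, `(0.6,0.7]`, …, `>1.4`); opposite-direction repetitions (recorded
as 0) land in the lowest bin.

## Sampling model of the calibration engine

A study setting fixes the population control and treatment means, the
predicted mean, per-group sizes and a per-observation scale (defaults:
control mean 0, unit scale). Each repetition draws the two observed group
means independently as

    m̄_g = m_g,pop + pop_sd · T(df = n_g − 1) / √n_g

and computes `I_SIM = (m_theo − m̄0) / (m̄1 − m̄0)`. Two modelling points
deserve emphasis:

* **The sampled control mean enters the numerator.** The predicted *mean*
  is fixed, but the predicted mean *difference* is relative to the observed
  control group, so control-group noise perturbs numerator and denominator
  together (they are positively correlated). A model that fixes the
  numerator at `ES_THEO` and only samples the denominator produces visibly
  different coverage at small n.
* **t kernel with df = n − 1 per group.** Using df = 2n − 2 or a normal
  kernel changes coverages by well under 1 percentage point anywhere on the
  calibration grid (n ≥ 20); the `df_mode` switch (`t_nminus1`, `normal`,
  `raw_draws`) exposes the alternatives. `raw_draws` averages n individual
  t-distributed observations per group and is provided for checking the
  mean-draw shortcut, at ~n-fold cost.

With 10,000 repetitions per setting the Monte Carlo standard error of a
coverage percentage is at most 0.5 points. Per-setting RNG streams are
derived from the master seed by stable hashing of the setting's parameters,
so any grid row can be regenerated alone and grids are order-independent.

## Analytic coverage oracle

`analytic_coverage_oracle` computes P(I_SIM ∈ SI) without simulation.
Conditioning on the control mean m̄0, the numerator `m_theo − m̄0` is a
constant and the SI constraint becomes an interval condition on the observed
difference, whose probability is a difference of two kernel CDFs; the outer
integral over m̄0 is evaluated by adaptive quadrature in the CDF-transformed
variable (so heavy-tailed kernels at small df are integrated exactly over
their full support, with breakpoints at the numerator's sign change).
Quadrature results with an absolute-error estimate above 1e-4 raise rather
than return. The oracle is the independent check on the engine — every cell
of both calibration grids must agree with it within three binomial standard
errors — and the backend of the coverage-based sample-size planner.

The planner (`find_min_n`) brackets by doubling and then bisects. Matched
settings have coverage → 100% as n grows; a fixed prediction/truth ratio
outside the SI has coverage → 0%, and the planner returns an "unreachable"
sentinel (`None`) whenever the limiting coverage is below the target instead
of searching forever. A ratio exactly on an SI bound has limiting coverage
50%. Coverage is checked for monotonicity along the search path; the check
is skipped below n = 8, where df ≤ 3 kernels are genuinely non-monotone
(the n = 2 Cauchy-tailed means concentrate the ratio more than n = 4 does).

## Meta-analytic re-evaluation

The pipeline compares a predicted standardized difference `d_THEO` with each
study's observed `d` *individually* — deliberately no pooling and no
s-weighted averaging, since the index exists to keep the statistical element
s out of the theory appraisal. Standardization is implemented literally as
multiply-by-s then divide-by-s: a round trip to the raw mean difference that
makes the s = 1 comparison scale explicit (and is the identity up to
floating-point error, which a test verifies). Each study is annotated with
the matched-setting SI coverage expected at its per-group sample size: the
probability that a *correct* prediction would land inside the SI at that n,
i.e. how informative that study could possibly be. One-sample records (no
`n1`) use a two-group matched setting at n0 = n1 = n for this lookup; their
observed effect carries 1/√n-scale sampling error, which the two-group
lookup tracks to within about one percentage point at the relevant sizes.
Report percentages are rounded to whole percent.

`required_n_ttest` is the conventional companion: the smallest per-group n
whose exact noncentral-t power reaches the target, iterated over integer n
with no normal approximation (one-sample: df = n − 1, ncp = d√n;
two-sample: df = 2n − 2, ncp = d√(n/2)). For d = 0.20, α = 0.05 one-sided
and power 0.80 this gives 156 (one-sample) and 310 per group (two-sample),
and 272/542 under α = β = 0.05. Quoted figures of 101 and 201 for this
planning example circulate; they do not correspond to any standard one- or
two-sample noncentral-t computation, and this package implements the
standard computation rather than matching them.

## Synthetic study tables

The fixture generator emulates a meta-analytic table: `n_studies` studies of
one true standardized effect, each observing
`d_obs = true_d + T(n − 1)/√n` (one-sample default, matching the
within-subject scoring designs of the precognition literature this pipeline
was built to re-examine), or a two-group draw with √(2/n)-scale noise.
Per-group sizes are fixed or sampled uniformly from a list; a subset can be
flagged peer-reviewed to exercise quality filtering. All randomness flows
through a single generator seeded from the config, so a config reproduces
its table byte-for-byte.

What the generator does **not** emulate: publication bias, selective
reporting, heterogeneous true effects, or measurement-reliability
differences between studies. Passing calibration and recovery tests
therefore show that the machinery is correct under an ideal-world sampling
model, not that any real literature is that well behaved.

## Problem sizes and numerical choices

Calibration grids run at 10,000 repetitions per setting (the scale at which
the reference percentages are defined); the full 54-setting matched grid
plus the 24-setting mismatch grid complete in a few seconds on one CPU.
Unit tests use 2,000–10,000 repetitions. Grid exports round percentages to
two decimals; all internal values are unrounded. CSV outputs embed the
resolved configuration in `#`-comment lines, which the readers skip.

## Limitations

* The index evaluates one scalar prediction (a mean difference or a single
  correlation) at a time; it does not appraise multi-parameter models or
  whole correlation matrices.
* It offers no protection against predicting an effect after seeing it; a
  recycled observation trivially yields `I_SIM = 1`.
* The SI is a calibration convention, not a hypothesis test: no error rates
  are attached to an individual verdict, and statistical corroboration
  against chance remains a separate step.
* Meehl's Spielraum S is caller-supplied; the package does not estimate it.
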