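# Methods notes

## Model and procedure

The generator replicates a source time-to-event dataset in twelve
conceptual steps: validate and format the source; derive the administrative
censoring date (the last observed exit date) and the last observed exit
time; encode missing factor values as explicit levels; fit sequential
conditional covariate models; fit a flexible parametric survival model;
sample covariate profiles; rebuild the survival design for the synthetic
profiles; invert survival times; reconstruct diagnosis dates and vital
status; replicate administrative censoring; restore missing-data coding;
and emit a validated synthetic dataset.

### Covariate chain

The joint covariate law is factorised as p(x₁)·p(x₂|x₁)⋯p(x_M|x₁..x_{M−1}).
Default ordering is least-to-most distributional complexity — continuous
covariates first, then factors by ascending level count — because the
hardest distributions are then conditioned on the most information; an
explicit per-covariate order overrides this (the shipped colon
configuration uses age, year, stage, sex, subsite). Partial explicit
orderings are rejected rather than guessed.

Factor models are multinomial logistic regressions. Predictors are
reference-coded dummies for earlier factors, restricted cubic splines
(3 df default) for earlier continuous covariates, and — by default — the
products of the dummy blocks of the two most recently modelled factors, so
conditional structure beyond main effects is carried forward. A weak L2
penalty (`ridge`, default 1e-6) guards against separation in sparse level
combinations; intercept-only marginal models bypass the optimiser and use
the exact closed-form logits of the sample proportions. Sampling draws each
row's level from its conditional probability vector.

Continuous covariates use the inverse-normal-rank construction: with
tie-averaged ranks r, z = Φ⁻¹((r − ½)/n), and the observed covariate is
regressed (ordinary least squares) on a restricted cubic spline of z
(4 df default) plus the earlier covariates. Sampling pushes a fresh
z* ~ N(0,1) through the fitted spline and adds a normal residual with the
regression RMSE; without that residual, draws would collapse onto the
fitted curve and understate within-profile heterogeneity. Sampled values
are clipped to the observed source range and rounded to integers when the
source variable is integer-valued (both configurable). These choices keep
impossible values (e.g. ages outside the observed 18–99) out of the
synthetic data at the cost of tiny boundary point masses.

### Survival model

The survival model is a Royston–Parmar flexible parametric model on the
log cumulative-hazard scale: log H(t|x) = s₀(ln t; γ) + xᵀβ + Σ xⱼ sⱼ(ln t).
Restricted cubic splines use the plus-function basis with K knots and K−1
columns (linear beyond the boundary knots); a model with k df therefore has
k+1 knots, placed at the min/max of the *uncensored* log event times with
interior knots at equally spaced centiles (e.g. 20/40/60/80 for 5 df,
33.3/66.7 for the 3-df time-dependent splines). With 1 df the model is
exactly Weibull, which supplies both the warm start and a convenient
oracle for tests.

The censored log likelihood Σ dᵢ[ηᵢ + ln(∂ηᵢ/∂ln t) − ln tᵢ] − exp(ηᵢ) is
maximised by BFGS with the analytic gradient; design columns are centred
and scaled for the optimiser and estimates mapped back, so stored
coefficients are on the natural scale. Parameter vectors with non-positive
time-slope at an event time receive a large finite penalty (1e10 plus the
total violation) that steers the search back into the valid region.
Convergence is declared at gradient max-norm < 1e-4 (the optimiser's own
tolerance is 1e-6); a bounded L-BFGS-B polish runs if plain BFGS stalls.
Standard errors come from the observed information (analytic Hessian,
pseudo-inverted), used by the parameter-recovery tests and exposed for
diagnostics.

Continuous covariates enter through winsorized (2nd/98th percentile for
age) restricted cubic splines with 3 df — the non-linearity is wanted, the
exact df is a package choice exposed in `ModelSpec`. Two-way interactions
are products of main-effect column groups; time-dependent effects cross a
covariate's main-effect columns with a log-time spline. The design layout
fitted on the source (level order, spline knots, winsor bounds) is frozen
in the fit and reused verbatim when the design is rebuilt for synthetic
covariates, so fit-time and generation-time encodings cannot drift.

Times are modelled in years (days/365.24) so knots and coefficients live on
an interpretable scale; generated times are converted back to days and
rounded *up* to whole days (minimum 1 day, so exit always differs from
diagnosis).

### Inversion sampling and calendar reconstruction

S(t|x) = u is solved as η(ln t, x) = ln(−ln u). The scalar API brackets on
log time and refines with Brent's method; the bulk path runs a fully
vectorised bisection (80 halvings of an interval a few log-units wide,
giving residuals far below the 1e-8 contract). The initial bracket is the
baseline knot span ± 5 log-units, expanded as needed, with a hard cap at
1e4 × the largest observed time; capped draws are flagged with a warning
and are in practice censored far beyond the administrative date anyway.

Month and day of diagnosis are uniform over the sampled diagnosis year
(366 days in leap years). Vital status is pre-coded dead when the generated
time does not exceed the source's last observed exit time (inclusive
boundary), then administrative censoring overrides it: any exit beyond the
censoring date is clamped to that date and recoded alive, exactly the
clamp-then-recode order used on the source side. One uniform per individual
is consumed in row order from a single seeded stream, so a run is fully
reproducible from (configuration, seed).

## Appraisal conventions

* Proportion tables report counts, percentages and absolute differences per
  factor level, with missing values shown under their own label and age
  binned at <45 / 45–60 / 60–75 / >75 (left-inclusive boundaries). The
  headline fidelity summary (`max_factor_difference`) is the maximum over
  factor levels and vital status; binned-age rows are excluded because age
  is modelled continuously.
* Kaplan–Meier estimation delegates to lifelines; curve comparisons use the
  supremum distance over the union of event times, truncated where fewer
  than 10% of either sample remain at risk. Near the exhaustion of the risk
  set the product-limit estimator jumps by ~S/(at-risk), so untruncated
  suprema measure estimator noise rather than fidelity — two draws of the
  same law routinely differ by >0.05 there.
* Restricted mean survival time uses the exact step-function area for KM
  curves and a 2000-point trapezoid for model-based curves.
* The privacy match report interprets "within a 30-day range" as
  |Δ| ≤ 15 days (a 31-day inclusive window); for a uniform date in a fixed
  non-leap year the chance level is 31/365 ≈ 8.49%. Survival-time windows
  apply to ceiling-rounded day counts after censoring, since that is what a
  released dataset would contain.

## The fixture and what passing means

`generate_source_like_colon` emulates a population-based colon cancer
cohort: 9,064 patients, diagnosis years 1985–1994 (uniform), stage /
sex / subsite marginals matching the published teaching dataset, a
left-skewed integer age from the truncated mixture
0.35·N(58, 9²) + 0.65·N(74, 8²) on [18, 99], stage probabilities tilted by
age and calendar year, 14.45% of stage labels missing at random, and event
times from a Weibull proportional-hazards truth (shape 1.1, rate 0.111 per
year — calibrated so ~61% die before the 31 Dec 1995 censoring date) with
log hazard ratios ordered Localized < Regional < Distant. The ground truth
is written to a JSON sidecar so tests can compute oracle quantities.

The fixture deliberately omits features of real registry data: no
non-proportional true effects (the fitted time-dependent terms should
estimate near-zero), no seasonality in diagnoses, no informative censoring,
no measurement error, and missingness that is completely at random. Passing
tests therefore demonstrate that the machinery recovers a known joint
covariate-and-survival law at realistic scale — not that any particular
real dataset would be reproduced equally well.

## Numerical choices and degenerate inputs

* Rank-to-normal offset: (r − ½)/n with tie-averaged ranks.
* Spline knot placement refuses degenerate (tied) knots rather than
  silently merging them.
* Multinomial reference level is the first schema level; estimates are
  invariant to this choice. A factor level declared but never observed is
  an error instructing its removal.
* Single-level factors short-circuit to probability one; a single value
  maps to z = 0 under the rank transform.
* Inversion with u outside (0,1) is an error; a bracket-ceiling miss
  returns the capped horizon with a warning rather than failing a whole
  run.
* Datasets with zero events refuse to fit; empty datasets refuse censoring
  derivation; negative survival times and disagreeing exit dates are
  validation errors naming the offending row.

## Problem sizes used by the test-suite experiments

Full-pipeline fidelity checks run at the source scale of 9,064 records;
seed-stability re-runs the pipeline for 10 seeds; the uniform-date privacy
floor uses 10⁶ draws; matched-profile privacy checks in tests use 2×10⁴ to
10⁵ synthetic records (the CLI default is 10⁶); pattern-frequency audits in
tests use hundreds of replicate datasets. These sizes make the Monte-Carlo
error small relative to every tolerance asserted.

## Known limitations

* Sampling n records from exactly calibrated conditionals still leaves
  binomial noise: at n ≈ 9,000 individual level proportions fluctuate with
  sd ≈ 0.3–0.5 percentage points, so the maximum difference across ~20
  levels occasionally exceeds 1 point for an unlucky seed.
* The survival model requires a strictly increasing fitted log cumulative
  hazard; heavily non-monotone hazards with tiny event counts can trip the
  validity penalty.
* All-cause survival only; relative survival and life-table-based metrics
  need external expected-mortality rates and are out of scope.
* Continuous covariates are modelled marginally non-normal but
  conditionally homoscedastic normal around the spline fit; strongly
  heteroscedastic conditionals would be smoothed over.
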