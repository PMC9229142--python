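# survsynth

High-fidelity **synthetic time-to-event data** for registry-style survival
datasets. Given a source cohort with prognostic covariates, diagnosis dates
and administratively censored follow-up, `survsynth` fits a pair of models
to the source and generates a replica dataset that preserves the joint
covariate distribution, the conditional survival patterns and the censoring
structure — without copying any real record. The intended users are
biostatisticians and epidemiologists who want to publish a shareable
stand-in for individual-level patient data alongside methods or applied
papers.

## Method

Generation has two stages:

1. **Covariate synthesis.** The joint distribution of the M covariates is
   factorised into sequential conditionals: covariate m is regressed on
   covariates 1..m−1 and sampled in the same order (continuous variables
   first, then factors from least to most levels, or an explicit order).
   Factors use multinomial logistic regression; a continuous covariate x is
   handled through its *inverse-normal-rank transform*
   z = Φ⁻¹((rank(x) − ½)/n), with x regressed on a restricted cubic spline
   of z so that arbitrarily non-normal marginal shapes are reproduced when a
   fresh z* ~ N(0,1) is pushed back through the fit. Missing factor values
   are encoded as an explicit level so missingness patterns are themselves
   replicated.

2. **Survival synthesis.** An all-cause flexible parametric (Royston–Parmar)
   model is fitted on the log cumulative-hazard scale,

   log H(t | x) = s₀(ln t; γ) + xᵀβ + Σⱼ xⱼ sⱼ(ln t; δⱼ),

   with a restricted cubic spline baseline (5 df by default), winsorized age
   splines, two-way interactions and spline time-dependent effects (3 df)
   for selected covariates. For each synthetic profile x a uniform u is
   inverted through S(t | x) = exp(−exp(·)) = u by root finding on the
   log-time axis; times are rounded up to whole days. Diagnosis dates are
   drawn uniformly within the sampled diagnosis year, and the source's
   administrative censoring date and last observed exit time recode
   synthetic records as alive/dead exactly as in the source registry.

Appraisal utilities quantify fidelity (level-by-level proportion tables,
Kaplan–Meier overlays, restricted mean survival time, stability across
seeds) and disclosure risk (fraction of matched-profile synthetic records
within ±15 days of a probe's diagnosis date or survival time, and how often
rare covariate patterns appear at all across replicate datasets).

## Worked example

The package ships a colon-cancer-like fixture (9,064 patients, diagnoses
1985–1994, administrative censoring 31 Dec 1995, ~14% missing stage) with a
known Weibull ground truth:

```python
import numpy as np
import survsynth as sv

source = sv.generate_source_like_colon(sv.FixtureSpec(n=9064),
                                       np.random.default_rng(1))

model_spec = sv.ModelSpec(
    baseline_df=5,
    categorical_effects=("stage", "sex", "subsite"),
    continuous_effects={"age": 3},
    winsor={"age": (2.0, 98.0)},
    interactions=(("age", "stage"), ("age", "subsite"),
                  ("age", "sex"), ("stage", "sex")),
    tde={"age": 3, "stage": 3},
)
result = sv.run_pipeline(source, model_spec=model_spec, seed=2)

report = sv.compare_covariate_distributions(source, result.synthetic)
print(report[report.covariate == "stage"].round(2).to_string(index=False))
```

```
covariate     level  source_count  source_pct  synthetic_count  synthetic_pct  abs_diff_pct
    stage Localized          3695       40.77             3646          40.23          0.54
    stage  Regional          1151       12.70             1158          12.78          0.08
    stage   Distant          2917       32.18             2935          32.38          0.20
    stage   Missing          1301       14.35             1325          14.62          0.26
```

Every factor-level proportion is recovered to well under one percentage
point (`max_factor_difference` → 0.93 pp across stage, subsite, sex, year
and vital status), the survival curves overlap (Kaplan–Meier supremum
distance 0.013 over the supported follow-up) and the 10-year restricted
mean survival time matches (source 1674.1 vs synthetic 1673.6 days). A
privacy audit of the rarest source pattern against 100,000 matched-profile
synthetics finds 8.6% of diagnosis dates within ±15 days — the chance level
for a uniform date in a known year (31/365 ≈ 8.5%) — showing the synthetic
records carry no individual-level date information.

The same workflow is available from the shell:

```bash
survsynth fixture --n 9064 --seed 1 --out source.csv
survsynth fit --data source.csv --config config.yaml --out models/
survsynth generate --models models/ --n 9064 --seed 2 --out synthetic.csv
survsynth appraise --source source.csv --synthetic synthetic.csv \
                   --config config.yaml --out report/
survsynth privacy-audit --probes probes.csv --models models/ --n 1000000 \
                        --out privacy.csv
```

## Scope

The package fits all-cause survival only. Relative-survival appraisal and
conditional life-expectancy metrics need external population life tables
and are out of scope, as are competing-risks extensions, tree-based
(CART/synthpop-style) covariate models, and formal differential-privacy or
k-anonymity accounting.
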