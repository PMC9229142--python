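"""Colon-cancer-like source datasets with a known data-generating process.

Every stage of the replication pipeline is exercised in tests against a
registry-style dataset generated here: a cohort of colon cancer diagnoses
1985-1994 with stage, sex, anatomical subsite, calendar year, an integer age
at diagnosis from a left-skewed two-component normal mixture, stage labels
missing at random for a configurable fraction of records, and event times
from a Weibull proportional-hazards model with known log hazard ratios,
administratively censored at a fixed calendar date.  Because the true model
is known, oracle quantities (conditional survival curves, hazard ratios)
are available for parameter-recovery checks.

The default parameters reproduce the marginal covariate proportions of a
well-known population-based colon cancer teaching dataset of 9,064 patients
and a ~61% overall death fraction by the 1995-12-31 censoring date.  The
fixture is a synthetic test harness with a matching joint structure, not a
replica of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .data import CovariateSchema, CovariateSpec, TTEDataset, clamp_followup
from .fpm import TIME_UNIT_DAYS
from .generate import assign_diagnosis_dates

__all__ = [
    "FixtureSpec",
    "colon_schema",
    "generate_source_like_colon",
    "inject_missingness",
    "make_probe_records",
    "true_linear_predictor",
    "true_survival",
]

STAGE_LEVELS = ("Localized", "Regional", "Distant")
SEX_LEVELS = ("Male", "Female")
SUBSITE_LEVELS = (
    "Coecum and Ascending",
    "Transverse",
    "Sigmoid and Descending",
    "Other and NOS",
)


def colon_schema(years=(1985, 1994)) -> CovariateSchema:
    """Schema of the colon-like cohort, with the explicit modelling order
    continuous age first, then year, stage, sex and subsite."""
    year_levels = tuple(str(y) for y in range(years[0], years[1] + 1))
    return CovariateSchema((
        CovariateSpec("age", "continuous", model_order=1),
        CovariateSpec("year", "categorical", year_levels, model_order=2, is_year=True),
        CovariateSpec("stage", "categorical", STAGE_LEVELS, model_order=3),
        CovariateSpec("sex", "categorical", SEX_LEVELS, model_order=4),
        CovariateSpec("subsite", "categorical", SUBSITE_LEVELS, model_order=5),
    ))


@dataclass
class FixtureSpec:
    """Ground-truth parameters of the colon-like data-generating process."""

    n: int = 9064
    year_range: tuple = (1985, 1994)
    admin_censor_date: str = "1995-12-31"

    # observed marginal proportions: stage proportions are conditional on the
    # stage label being observed; a fraction stage_missing_rate is blanked
    stage_probs: tuple = (0.47821, 0.14775, 0.37404)
    stage_missing_rate: float = 0.1445
    sex_probs: tuple = (0.4182, 0.5818)
    subsite_probs: tuple = (0.3566, 0.1769, 0.4029, 0.0636)

    # age: two-component normal mixture, truncated and rounded to integers
    age_weights: tuple = (0.35, 0.65)
    age_means: tuple = (58.0, 74.0)
    age_sds: tuple = (9.0, 8.0)
    age_range: tuple = (18.0, 99.0)

    # dependence: additive shifts on the stage log-odds (vs Localized)
    stage_age_slope: dict = field(default_factory=lambda: {"Regional": 0.10, "Distant": 0.25})
    stage_year_slope: dict = field(default_factory=lambda: {"Distant": -0.02})

    # true hazard: Weibull baseline with proportional log hazard ratios
    weibull_shape: float = 1.1
    weibull_rate: float = 0.111  # per year; calibrated to a ~61% death fraction
    loghr_stage: dict = field(default_factory=lambda: {"Regional": 0.55, "Distant": 1.50})
    loghr_sex: dict = field(default_factory=lambda: {"Female": -0.10})
    loghr_subsite: dict = field(default_factory=lambda: {
        "Transverse": 0.08, "Sigmoid and Descending": -0.05, "Other and NOS": 0.20,
    })
    loghr_age_per_year: float = 0.035
    age_center: float = 68.4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for probs in (self.stage_probs, self.sex_probs, self.subsite_probs,
                      self.age_weights):
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError("probabilities must sum to 1")
        if self.weibull_shape <= 0 or self.weibull_rate <= 0:
            raise ValueError("Weibull shape and rate must be positive")
        if not (0.0 <= self.stage_missing_rate <= 1.0):
            raise ValueError("stage_missing_rate must be in [0, 1]")

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = list(v) if isinstance(v, tuple) else v
        return d


def true_linear_predictor(spec: FixtureSpec, stage, sex, subsite, age) -> np.ndarray:
    """True log hazard ratio of each record relative to the baseline profile."""
    stage = np.asarray(stage, dtype=object)
    sex = np.asarray(sex, dtype=object)
    subsite = np.asarray(subsite, dtype=object)
    age = np.asarray(age, dtype=float)
    lp = spec.loghr_age_per_year * (age - spec.age_center)
    for lev, b in spec.loghr_stage.items():
        lp = lp + b * (stage == lev)
    for lev, b in spec.loghr_sex.items():
        lp = lp + b * (sex == lev)
    for lev, b in spec.loghr_subsite.items():
        lp = lp + b * (subsite == lev)
    return lp


def true_survival(spec: FixtureSpec, lp, t_years) -> np.ndarray:
    """Analytic S(t) of the true Weibull proportional-hazards model."""
    t = np.asarray(t_years, dtype=float)
    return np.exp(-((spec.weibull_rate * t) ** spec.weibull_shape) * np.exp(lp))


def _truncated_mixture(spec: FixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    out = np.empty(n)
    todo = np.arange(n)
    comp = rng.choice(len(spec.age_weights), size=n, p=spec.age_weights)
    while todo.size:
        draw = rng.normal(np.asarray(spec.age_means)[comp[todo]],
                          np.asarray(spec.age_sds)[comp[todo]])
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out)


def _sample_stage(spec: FixtureSpec, age, years, rng) -> np.ndarray:
    base = np.log(np.asarray(spec.stage_probs) / spec.stage_probs[0])
    n = len(age)
    logits = np.tile(base, (n, 1))
    mid_year = 0.5 * (spec.year_range[0] + spec.year_range[1])
    for j, lev in enumerate(STAGE_LEVELS):
        shift = np.zeros(n)
        if lev in spec.stage_age_slope:
            shift += spec.stage_age_slope[lev] * (age - spec.age_center) / 10.0
        if lev in spec.stage_year_slope:
            shift += spec.stage_year_slope[lev] * (years - mid_year)
        logits[:, j] += shift
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray(STAGE_LEVELS, dtype=object)[np.minimum(idx, 2)]


def draw_event_times(spec: FixtureSpec, lp, rng: np.random.Generator) -> np.ndarray:
    """Uncensored event times (years) from the true Weibull model."""
    lp = np.asarray(lp, dtype=float)
    u = rng.uniform(size=lp.shape)
    return ((-np.log(u)) * np.exp(-lp)) ** (1.0 / spec.weibull_shape) / spec.weibull_rate


def generate_source_like_colon(spec: FixtureSpec | None = None,
                               rng: np.random.Generator | None = None) -> TTEDataset:
    """Draw a fully valid colon-like source dataset from the known model."""
    if spec is None:
        spec = FixtureSpec()
    if rng is None:
        rng = np.random.default_rng()
    n = spec.n
    schema = colon_schema(spec.year_range)

    age = _truncated_mixture(spec, n, rng)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)
    stage = _sample_stage(spec, age, years, rng)
    sex = np.asarray(SEX_LEVELS, dtype=object)[
        rng.choice(len(SEX_LEVELS), size=n, p=spec.sex_probs)
    ]
    subsite = np.asarray(SUBSITE_LEVELS, dtype=object)[
        rng.choice(len(SUBSITE_LEVELS), size=n, p=spec.subsite_probs)
    ]

    lp = true_linear_predictor(spec, stage, sex, subsite, age)
    t_years = draw_event_times(spec, lp, rng)
    days = np.maximum(np.ceil(t_years * TIME_UNIT_DAYS).astype(np.int64), 1)
    diagnosis = assign_diagnosis_dates(years, rng)

    df = pd.DataFrame({
        "age": age,
        "year": years.astype(str),
        "stage": stage,
        "sex": sex,
        "subsite": subsite,
        "diagnosis_date": diagnosis.to_numpy(),
        "survival_days": days,
        "vital_status": "dead",
    })
    ds = TTEDataset(df, schema)
    ds = clamp_followup(ds, spec.admin_censor_date)
    if spec.stage_missing_rate > 0:
        ds = inject_missingness(ds, "stage", spec.stage_missing_rate, rng)
    return ds


def inject_missingness(ds: TTEDataset, covariate: str, rate: float,
                       rng: np.random.Generator) -> TTEDataset:
    """Blank each record's value of a categorical covariate with probability rate."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    if ds.schema[covariate].kind != "categorical":
        raise ValueError("missingness injection applies to categorical covariates")
    df = ds.data.copy()
    blank = rng.uniform(size=len(df)) < rate
    df.loc[blank, covariate] = np.nan
    return TTEDataset(df, ds.schema)


def make_probe_records(ds: TTEDataset, k: int) -> pd.DataFrame:
    """The k records with the rarest full covariate patterns.

    Missing factor values count as their own pattern value; ties are broken
    by row order.  Suitable as probes for the privacy match report.
    """
    if k < 1 or k > len(ds):
        raise ValueError("k must lie in [1, n]")
    names = ds.schema.names
    key = ds.data[names].astype(str).agg("|".join, axis=1)
    freq = key.map(key.value_counts())
    order = np.lexsort((np.arange(len(ds)), freq.to_numpy()))
    out = ds.data.iloc[order[:k]].copy()
    out["pattern_frequency"] = freq.iloc[order[:k]].to_numpy()
    return out


def write_truth_sidecar(spec: FixtureSpec, path) -> None:
    """Machine-readable record of the fixture's ground-truth parameters."""
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1)
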