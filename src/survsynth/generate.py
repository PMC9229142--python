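"""Synthetic survival times, calendar dates and administrative censoring.

Survival times are drawn by inversion: for each synthetic covariate profile
x a uniform u ~ U(0,1) is transformed to the time t solving S(t | x) = u
under the fitted flexible parametric model.  On the log-cumulative-hazard
scale this is the root of eta(ln t, x) = ln(-ln u); eta is increasing in
ln t wherever the model is valid, so the root is found by bracketing on the
log-time axis (bisection for the vectorised bulk path, Brent refinement for
the scalar API).  Times are converted to days and rounded up to the nearest
full day (minimum one day).

Calendar structure is then reconstructed: the synthetic year of diagnosis
gets a uniformly distributed month/day within that year, vital status is
pre-coded dead when the generated time does not exceed the last observed
exit time of the source data, and administrative censoring is replicated by
clamping any exit date beyond the source's censoring date and recoding those
records as alive.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import pathlib
import warnings

import numpy as np
import pandas as pd

from .covariates import (
    CovariateModelSet,
    CovariateSettings,
    fit_covariate_sequence,
    sample_covariates,
)
from .data import (
    ALIVE,
    DEAD,
    CensoringInfo,
    CovariateSchema,
    TTEDataset,
    derive_censoring,
    encode_missing_as_level,
    restore_missing,
)
from .fpm import TIME_UNIT_DAYS, FPMFit, ModelSpec, build_design, fit_fpm

__all__ = [
    "invert_survival_time",
    "generate_times",
    "assign_diagnosis_dates",
    "code_vital_status",
    "apply_admin_censoring",
    "SyntheticCohort",
    "FitBundle",
    "PipelineResult",
    "default_model_spec",
    "run_pipeline",
]

_BRACKET_PAD = 5.0
_LO_FLOOR = 200.0           # never search below ln t_min - 200
_CAP_FACTOR = np.log(1e4)   # hard cap: 1e4 x the largest observed time


def _bracket_bounds(fit: FPMFit):
    lo = float(fit.baseline_knots[0]) - _BRACKET_PAD
    hi = float(fit.baseline_knots[-1]) + _BRACKET_PAD
    cap = float(fit.baseline_knots[-1]) + _CAP_FACTOR
    floor = float(fit.baseline_knots[0]) - _LO_FLOOR
    return lo, hi, cap, floor


def invert_survival_time(fit: FPMFit, profile, u: float) -> float:
    """Solve S(t | profile) = u for t (model time units) by Brent's method.

    Monotone: larger u gives smaller t.  If even the capped search horizon
    (1e4 x the largest observed time) cannot reach survival as low as u, the
    cap is returned with a warning.
    """
    from scipy.optimize import brentq

    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    X = fit.design_row(profile)
    target = float(np.log(-np.log(u)))

    def g(log_t: float) -> float:
        eta, _ = fit.linear_predictor(np.array([log_t]), X)
        return float(eta[0]) - target

    lo, hi, cap, floor = _bracket_bounds(fit)
    while g(lo) > 0 and lo > floor:
        lo -= 10.0
    while g(hi) < 0 and hi < cap:
        hi = min(hi + 2.0, cap)
    if g(hi) < 0:
        warnings.warn("inversion capped at the maximum search horizon", RuntimeWarning)
        return float(np.exp(cap))
    root = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(np.exp(root))


def _invert_vectorized(fit: FPMFit, X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Bisection solve of eta(ln t, x_i) = ln(-ln u_i) for every row."""
    n = len(u)
    target = np.log(-np.log(u))
    lo_0, hi_0, cap, floor = _bracket_bounds(fit)
    lo = np.full(n, lo_0)
    hi = np.full(n, hi_0)

    def eta_at(log_t):
        e, _ = fit.linear_predictor(log_t, X)
        return e

    g_lo = eta_at(lo) - target
    while True:
        mask = (g_lo > 0) & (lo > floor)
        if not mask.any():
            break
        lo[mask] -= 10.0
        idx = np.flatnonzero(mask)
        e, _ = fit.linear_predictor(lo[idx], X[idx])
        g_lo[idx] = e - target[idx]
    g_hi = eta_at(hi) - target
    while True:
        mask = (g_hi < 0) & (hi < cap)
        if not mask.any():
            break
        hi[mask] = np.minimum(hi[mask] + 2.0, cap)
        idx = np.flatnonzero(mask)
        e, _ = fit.linear_predictor(hi[idx], X[idx])
        g_hi[idx] = e - target[idx]
    capped = g_hi < 0
    if capped.any():
        warnings.warn(
            f"{int(capped.sum())} inversion(s) capped at the maximum search horizon",
            RuntimeWarning,
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        g_mid = eta_at(mid) - target
        take_hi = g_mid >= 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    t = np.exp(0.5 * (lo + hi))
    t[capped] = np.exp(cap)
    return t


def generate_times(fit: FPMFit, covariates: pd.DataFrame, rng: np.random.Generator,
                   *, return_details: bool = False):
    """Draw one survival time per covariate row; days, rounded up, >= 1."""
    X, _ = build_design(covariates, fit.spec, fit.layout)
    n = X.shape[0]
    u = rng.uniform(size=n)
    t_years = _invert_vectorized(fit, X, u)
    days = np.maximum(np.ceil(t_years * TIME_UNIT_DAYS).astype(np.int64), 1)
    if return_details:
        return days, u, t_years
    return days


def assign_diagnosis_dates(years, rng: np.random.Generator) -> pd.Series:
    """Uniform month/day of diagnosis within each record's calendar year."""
    years = np.asarray(years, dtype=int)
    start = pd.to_datetime(pd.DataFrame({"year": years, "month": 1, "day": 1}))
    is_leap = (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))
    ndays = np.where(is_leap, 366, 365)
    offsets = rng.integers(0, ndays)
    return pd.Series(start + pd.to_timedelta(offsets, unit="D"), name="diagnosis_date")


def code_vital_status(times_days, last_exit_days: int) -> np.ndarray:
    """Dead iff the generated time does not exceed the source's last exit time."""
    if last_exit_days <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(times_days)
    return np.where(t <= last_exit_days, DEAD, ALIVE).astype(object)


@dataclass
class SyntheticCohort:
    """Synthetic records plus the raw generation quantities.

    ``data`` holds the covariates, the uniform draw ``u``, the uncensored
    generated time ``raw_time_days``, calendar dates, vital status and the
    administratively censored ``recorded_time_days``.
    """

    data: pd.DataFrame
    censor: CensoringInfo | None = None


def apply_admin_censoring(cohort: SyntheticCohort, censor: CensoringInfo) -> SyntheticCohort:
    """Clamp exits beyond the administrative censoring date; recode as alive."""
    df = cohort.data.copy()
    censor_date = pd.Timestamp(censor.admin_censor_date)
    if (df["diagnosis_date"] > censor_date).any():
        raise ValueError("diagnosis date after the administrative censoring date")
    # work in day counts: extreme uncensored draws may overflow ns timestamps
    days_to_censor = (censor_date - df["diagnosis_date"]).dt.days.to_numpy()
    raw = df["raw_time_days"].to_numpy()
    over = raw > days_to_censor
    recorded = np.where(over, days_to_censor, raw)
    df["recorded_time_days"] = recorded
    df["exit_date"] = df["diagnosis_date"] + pd.to_timedelta(recorded, unit="D")
    df.loc[over, "vital_status"] = ALIVE
    return SyntheticCohort(data=df, censor=censor)


@dataclass
class FitBundle:
    """Everything fitted to a source dataset, enough to generate replicas."""

    schema: CovariateSchema
    covariate_models: CovariateModelSet
    fpm: FPMFit
    censor: CensoringInfo
    model_spec: ModelSpec
    missing_labels: dict  # covariate -> label used for the missing-data level

    def save(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.covariate_models.save(d / "covariate_models.json")
        with open(d / "survival_model.json", "w") as fh:
            json.dump(self.fpm.to_dict(), fh, indent=1)
        meta = {
            "schema": self.schema.to_dict(),
            "censor": self.censor.to_dict(),
            "model_spec": self.model_spec.to_dict(),
            "missing_labels": dict(self.missing_labels),
        }
        with open(d / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "FitBundle":
        d = pathlib.Path(directory)
        with open(d / "metadata.json") as fh:
            meta = json.load(fh)
        with open(d / "survival_model.json") as fh:
            fpm = FPMFit.from_dict(json.load(fh))
        return cls(
            schema=CovariateSchema.from_dict(meta["schema"]),
            covariate_models=CovariateModelSet.load(d / "covariate_models.json"),
            fpm=fpm,
            censor=CensoringInfo.from_dict(meta["censor"]),
            model_spec=ModelSpec.from_dict(meta["model_spec"]),
            missing_labels=dict(meta["missing_labels"]),
        )


@dataclass
class PipelineResult:
    synthetic: TTEDataset
    cohort: SyntheticCohort
    bundle: FitBundle


def default_model_spec(schema: CovariateSchema, *, baseline_df: int = 5,
                       continuous_df: int = 3, tde_df: int = 3,
                       include_year: bool = False) -> ModelSpec:
    """Survival-model structure used when none is supplied.

    Main effects for every covariate (the calendar-year covariate only on
    request), continuous covariates as winsorized (2nd/98th percentile)
    restricted cubic splines, interactions between each continuous covariate
    and every factor, and time-dependent effects for the continuous
    covariates plus the first factor covariate.
    """
    cats = [e.name for e in schema.entries
            if e.kind == "categorical" and (include_year or not e.is_year)]
    conts = schema.continuous
    interactions = tuple((c, f) for c in conts for f in cats)
    tde = {c: tde_df for c in conts}
    if cats:
        tde[cats[0]] = tde_df
    return ModelSpec(
        baseline_df=baseline_df,
        categorical_effects=tuple(cats),
        continuous_effects={c: continuous_df for c in conts},
        winsor={c: (2.0, 98.0) for c in conts},
        interactions=interactions,
        tde=tde,
    )


def run_pipeline(
    source: TTEDataset,
    *,
    model_spec: ModelSpec | None = None,
    cov_settings: CovariateSettings | None = None,
    n: int | None = None,
    seed: int = 0,
    missing_label: str = "Missing",
    restore_missing_levels: bool = True,
) -> PipelineResult:
    """Full source-to-replica pipeline.

    Derives censoring metadata, encodes missing factor levels, fits the
    conditional covariate chain and the survival model, then samples a
    synthetic cohort: covariates, inversion-sampled survival times, uniform
    dates within the sampled diagnosis year, vital-status coding and
    administrative censoring.  Fully reproducible from ``seed``.
    """
    if n is None:
        n = len(source)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    censor = derive_censoring(source)
    ds = source
    missing_labels: dict[str, str] = {}
    for name in ds.schema.categorical:
        if ds.data[name].isna().any():
            ds = encode_missing_as_level(ds, name, missing_label)
            missing_labels[name] = missing_label
    schema = ds.schema

    cov_models = fit_covariate_sequence(ds, schema, cov_settings)
    if model_spec is None:
        model_spec = default_model_spec(schema)
    fpm = fit_fpm(ds, model_spec)

    bundle = FitBundle(
        schema=schema, covariate_models=cov_models, fpm=fpm,
        censor=censor, model_spec=model_spec, missing_labels=missing_labels,
    )

    cohort = generate_cohort(bundle, n, rng)
    synthetic = cohort_to_dataset(cohort, bundle,
                                  restore_missing_levels=restore_missing_levels)
    return PipelineResult(synthetic=synthetic, cohort=cohort, bundle=bundle)


def generate_cohort(bundle: FitBundle, n: int, rng: np.random.Generator) -> SyntheticCohort:
    """Sample covariates, times and dates for n synthetic individuals."""
    covs = sample_covariates(bundle.covariate_models, n, rng)
    days, u, _ = generate_times(bundle.fpm, covs, rng, return_details=True)
    year_name = bundle.schema.year_name
    if year_name is not None:
        years = covs[year_name].astype(str).astype(int).to_numpy()
    else:
        years = np.full(n, pd.Timestamp(bundle.censor.admin_censor_date).year)
    dates = assign_diagnosis_dates(years, rng)
    df = covs.copy()
    df["u"] = u
    df["raw_time_days"] = days
    df["diagnosis_date"] = dates.to_numpy()
    df["vital_status"] = code_vital_status(days, bundle.censor.last_exit_time_days)
    cohort = SyntheticCohort(data=df)
    return apply_admin_censoring(cohort, bundle.censor)


def cohort_to_dataset(cohort: SyntheticCohort, bundle: FitBundle, *,
                      restore_missing_levels: bool = True) -> TTEDataset:
    """Assemble the synthetic cohort into a validated time-to-event dataset."""
    df = cohort.data
    out = df[bundle.schema.names].copy()
    for name in out.columns:
        if isinstance(out[name].dtype, pd.CategoricalDtype):
            out[name] = out[name].astype(object)
    out["diagnosis_date"] = df["diagnosis_date"]
    out["survival_days"] = df["recorded_time_days"].astype(np.int64)
    out["vital_status"] = df["vital_status"]
    out["patient_id"] = [f"S{i:06d}" for i in range(len(df))]
    ds = TTEDataset(out, bundle.schema)
    if restore_missing_levels:
        for name, label in bundle.missing_labels.items():
            ds = restore_missing(ds, name, label)
    return ds
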