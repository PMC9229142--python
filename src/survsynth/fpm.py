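"""Flexible parametric survival modelling on the log cumulative-hazard scale.

The model (Royston–Parmar family) writes the log cumulative hazard of a
subject with covariate vector x as

    log H(t | x) = eta(ln t, x)
                 = gamma0 + s0(ln t; gamma) + x'beta + sum_j x_j s_j(ln t; delta_j)

where s0 is a restricted cubic spline of log time with ``baseline_df`` basis
columns and the optional s_j terms give selected covariates time-dependent
(non-proportional) effects.  With one baseline degree of freedom the model
collapses to a Weibull: eta = gamma0 + gamma1 ln t, so gamma1 is the Weibull
shape.  Survival and hazard follow as

    S(t | x) = exp(-exp(eta)),     h(t | x) = exp(eta) * (d eta / d ln t) / t.

The censored log likelihood maximised here is

    sum_i d_i [eta_i + ln(d eta_i / d ln t) - ln t_i] - exp(eta_i)

which is the usual sum of d_i log h + log S contributions.  Validity of the
model requires the time-slope d eta / d ln t to be positive at event times;
parameter vectors violating that receive a large finite penalty so the
quasi-Newton search is steered back into the valid region.

Continuous covariates enter through restricted cubic splines (optionally
winsorized first), categorical covariates through reference-coded dummy
columns, and two-way interactions as products of the corresponding main
effect columns.  The design layout fitted on the source data is stored with
the fit so the identical encoding (same knots, same winsorizing bounds, same
dummy order) can be rebuilt for synthetic covariate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "rcs_basis",
    "spline_knots",
    "winsorize",
    "ModelSpec",
    "DesignLayout",
    "build_design",
    "fpm_loglik",
    "FPMFit",
    "fit_fpm",
    "fit_fpm_arrays",
    "predict_survival",
    "predict_hazard",
]

TIME_UNIT_DAYS = 365.24  # survival times are modelled in years

_PENALTY = 1e10
_SLOPE_EPS = 1e-10


# ---------------------------------------------------------------------------
# spline primitives
# ---------------------------------------------------------------------------

def rcs_basis(x, knots):
    """Restricted cubic spline basis and its derivative.

    For K strictly increasing knots the basis has K-1 columns: the first is
    x itself and column j+1 is

        v_j(x) = (x-k_j)^3_+ - lam_j (x-k_min)^3_+ - (1-lam_j)(x-k_max)^3_+

    with lam_j = (k_max-k_j)/(k_max-k_min), which makes every column linear
    beyond the boundary knots.  Returns ``(basis, derivative)`` with shapes
    ``x.shape + (K-1,)``.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be a strictly increasing vector of length >= 2")
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    span = kmax - kmin
    ncol = knots.size - 1
    B = np.empty(x.shape + (ncol,))
    D = np.empty_like(B)
    B[..., 0] = x
    D[..., 0] = 1.0
    p_min = np.maximum(x - kmin, 0.0)
    p_max = np.maximum(x - kmax, 0.0)
    for j, k in enumerate(knots[1:-1], start=1):
        lam = (kmax - k) / span
        p = np.maximum(x - k, 0.0)
        B[..., j] = p**3 - lam * p_min**3 - (1.0 - lam) * p_max**3
        D[..., j] = 3.0 * (p**2 - lam * p_min**2 - (1.0 - lam) * p_max**2)
    return B, D


def spline_knots(values, df: int) -> np.ndarray:
    """Knot vector for a restricted cubic spline with ``df`` basis columns.

    ``df`` columns need df+1 knots: boundary knots at the min/max of
    ``values`` and interior knots at equally spaced centiles 100*i/df.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to place knots")
    lo, hi = float(v.min()), float(v.max())
    if df == 1:
        knots = np.array([lo, hi])
    else:
        interior = np.percentile(v, 100.0 * np.arange(1, df) / df)
        knots = np.concatenate([[lo], interior, [hi]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate knot placement: values have too many ties")
    return knots


def winsorize(values, low_pct: float, high_pct: float) -> np.ndarray:
    """Clamp values below/above the given percentiles to those percentiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo = np.percentile(v, low_pct)
    hi = np.percentile(v, high_pct)
    return np.clip(v, lo, hi)


# ---------------------------------------------------------------------------
# model specification and covariate design
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Structure of the survival model's covariate part.

    Parameters
    ----------
    baseline_df:
        Degrees of freedom (basis columns) of the baseline log-time spline.
    categorical_effects:
        Factor covariates entering as reference-coded dummies.
    continuous_effects:
        Mapping covariate -> spline df (1 means a plain linear term).
    winsor:
        Mapping covariate -> (low, high) winsorizing percentiles applied
        before spline construction.
    interactions:
        Pairs of covariate names; all products of the two main-effect column
        groups are added.
    tde:
        Mapping covariate -> df of its time-dependent effect spline; each
        main-effect column of the covariate is crossed with that log-time
        spline.  Every tde covariate must also appear as a main effect.
    """

    baseline_df: int = 5
    categorical_effects: tuple = ()
    continuous_effects: dict = field(default_factory=dict)
    winsor: dict = field(default_factory=dict)
    interactions: tuple = ()
    tde: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_df < 1:
            raise ValueError("baseline_df must be >= 1")
        mains = set(self.categorical_effects) | set(self.continuous_effects)
        for name in self.tde:
            if name not in mains:
                raise ValueError(f"time-dependent term {name!r} must also be a main effect")
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(f"interaction ({a!r}, {b!r}) references a non-main-effect term")

    def to_dict(self) -> dict:
        return {
            "baseline_df": self.baseline_df,
            "categorical_effects": list(self.categorical_effects),
            "continuous_effects": dict(self.continuous_effects),
            "winsor": {k: list(v) for k, v in self.winsor.items()},
            "interactions": [list(p) for p in self.interactions],
            "tde": dict(self.tde),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            baseline_df=int(d.get("baseline_df", 5)),
            categorical_effects=tuple(d.get("categorical_effects", ())),
            continuous_effects={k: int(v) for k, v in d.get("continuous_effects", {}).items()},
            winsor={k: tuple(v) for k, v in d.get("winsor", {}).items()},
            interactions=tuple(tuple(p) for p in d.get("interactions", ())),
            tde={k: int(v) for k, v in d.get("tde", {}).items()},
        )


@dataclass
class DesignLayout:
    """Frozen covariate encoding so synthetic data reuse the source design."""

    columns: list = field(default_factory=list)
    levels: dict = field(default_factory=dict)        # categorical -> level order (ref first)
    knots: dict = field(default_factory=dict)         # continuous -> spline knots
    winsor_bounds: dict = field(default_factory=dict)  # continuous -> (lo, hi) values
    groups: dict = field(default_factory=dict)        # term -> column indices

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "levels": {k: list(v) for k, v in self.levels.items()},
            "knots": {k: list(map(float, v)) for k, v in self.knots.items()},
            "winsor_bounds": {k: [float(v[0]), float(v[1])] for k, v in self.winsor_bounds.items()},
            "groups": {k: list(map(int, v)) for k, v in self.groups.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignLayout":
        return cls(
            columns=list(d["columns"]),
            levels={k: list(v) for k, v in d["levels"].items()},
            knots={k: np.asarray(v, dtype=float) for k, v in d["knots"].items()},
            winsor_bounds={k: (float(v[0]), float(v[1])) for k, v in d["winsor_bounds"].items()},
            groups={k: list(v) for k, v in d["groups"].items()},
        )


def build_design(table: pd.DataFrame, spec: ModelSpec, layout: DesignLayout | None = None):
    """Build the covariate design matrix for a model specification.

    When ``layout`` is None a fresh layout is derived from the table
    (categorical level order, spline knots, winsorizing bounds) and returned
    with the matrix; passing a stored layout rebuilds the exact same columns
    for new data, raising on categorical levels unseen at fit time.
    """
    fresh = layout is None
    if fresh:
        layout = DesignLayout()
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}

    def add(name: str, col: np.ndarray, group: str) -> None:
        groups.setdefault(group, []).append(len(names))
        names.append(name)
        cols.append(np.asarray(col, dtype=float))

    for name in spec.categorical_effects:
        raw = table[name]
        if raw.isna().any():
            raise ValueError(
                f"covariate {name!r} has missing values; encode them as a level first"
            )
        vals = raw.astype(str).to_numpy()
        if fresh:
            if isinstance(raw.dtype, pd.CategoricalDtype):
                levels = [str(c) for c in raw.cat.categories]
            else:
                levels = sorted(set(vals))
            layout.levels[name] = levels
        else:
            levels = layout.levels[name]
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) for {name!r}: {sorted(unseen)}")
        for lev in levels[1:]:
            add(f"{name}[{lev}]", (vals == lev).astype(float), name)

    for name, df_ in spec.continuous_effects.items():
        x = pd.to_numeric(table[name]).to_numpy(dtype=float)
        if fresh:
            low, high = spec.winsor.get(name, (0.0, 100.0))
            lo = float(np.percentile(x, low))
            hi = float(np.percentile(x, high))
            layout.winsor_bounds[name] = (lo, hi)
        lo, hi = layout.winsor_bounds[name]
        xw = np.clip(x, lo, hi)
        if fresh:
            layout.knots[name] = spline_knots(xw, df_)
        B, _ = rcs_basis(xw, layout.knots[name])
        for j in range(B.shape[-1]):
            add(f"{name}_rcs{j + 1}", B[..., j], name)

    for a, b in spec.interactions:
        key = f"{a}:{b}"
        for ia in groups[a]:
            for ib in groups[b]:
                add(f"{names[ia]}:{names[ib]}", cols[ia] * cols[ib], key)

    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    if fresh:
        layout.columns = names
        layout.groups = groups
    else:
        if names != layout.columns:
            raise ValueError("rebuilt design does not match the stored layout")
    return X, layout


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def fpm_loglik(params, times, events, design, design_deriv) -> float:
    """Censored log likelihood of the log-cumulative-hazard model.

    ``design`` holds one row per subject of the full linear-predictor basis
    (intercept, baseline log-time spline at that subject's time, covariate
    columns, tde columns); ``design_deriv`` is its elementwise derivative
    with respect to ln t (zero for time-constant columns).  Returns a large
    negative penalty when the time-slope is non-positive at any event time.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    d = np.asarray(events, dtype=bool)
    theta = np.asarray(params, dtype=float)
    eta = design @ theta
    deta = design_deriv @ theta
    bad = d & (deta <= _SLOPE_EPS)
    if bad.any():
        return -_PENALTY * (1.0 + float(np.sum(_SLOPE_EPS - deta[bad])))
    ll = float(np.sum(eta[d] + np.log(deta[d]) - np.log(t[d])))
    ll -= float(np.sum(np.exp(np.minimum(eta, 300.0))))
    return ll


def _tde_blocks(log_t, X, layout: DesignLayout, tde_knots: dict):
    """Columns (and ln-t derivatives) of the time-dependent-effect terms."""
    blocks, dblocks = [], []
    for name, knots in tde_knots.items():
        Bt, Dt = rcs_basis(log_t, knots)
        Xg = X[:, layout.groups[name]]
        n, m = Xg.shape
        df_ = Bt.shape[-1]
        blocks.append((Xg[:, :, None] * Bt[:, None, :]).reshape(n, m * df_))
        dblocks.append((Xg[:, :, None] * Dt[:, None, :]).reshape(n, m * df_))
    return blocks, dblocks


def _assemble(log_t, X, layout, baseline_knots, tde_knots):
    """Full parameter basis C (eta = C theta) and its ln-t derivative E."""
    n = len(log_t)
    B0, D0 = rcs_basis(log_t, baseline_knots)
    blocks, dblocks = _tde_blocks(log_t, X, layout, tde_knots)
    C = np.column_stack([np.ones(n), B0, X, *blocks])
    E = np.column_stack([np.zeros(n), D0, np.zeros_like(X), *dblocks])
    return C, E


@dataclass
class FPMFit:
    """A fitted flexible parametric survival model."""

    spec: ModelSpec
    layout: DesignLayout
    baseline_knots: np.ndarray
    tde_knots: dict
    intercept: float
    gamma: np.ndarray      # baseline spline coefficients
    beta: np.ndarray       # one per layout column
    tde_coefs: dict        # name -> (n_group_cols, tde_df) array
    log_likelihood: float
    converged: bool
    n_iter: int
    param_names: list
    se: np.ndarray | None = None

    # -- parameter (un)packing ---------------------------------------------
    @property
    def params(self) -> np.ndarray:
        parts = [np.array([self.intercept]), self.gamma, self.beta]
        for name in self.tde_knots:
            parts.append(self.tde_coefs[name].ravel())
        return np.concatenate(parts)

    def linear_predictor(self, log_t, X):
        """eta and d eta/d ln t for aligned arrays of log-times and design rows."""
        log_t = np.asarray(log_t, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and log_t.ndim == 1 and log_t.size > 1:
            X = np.broadcast_to(X, (log_t.size, X.shape[1]))
        scalar = log_t.ndim == 0
        log_t = np.atleast_1d(log_t)
        B0, D0 = rcs_basis(log_t, self.baseline_knots)
        eta = self.intercept + B0 @ self.gamma
        deta = D0 @ self.gamma
        if X.shape[1]:
            eta = eta + X @ self.beta
        for name, knots in self.tde_knots.items():
            Bt, Dt = rcs_basis(log_t, knots)
            Xg = X[:, self.layout.groups[name]]
            coef = self.tde_coefs[name]
            eta = eta + np.sum(Xg * (Bt @ coef.T), axis=1)
            deta = deta + np.sum(Xg * (Dt @ coef.T), axis=1)
        if scalar:
            return float(eta[0]), float(deta[0])
        return eta, deta

    def design_row(self, profile) -> np.ndarray:
        """Encode a single covariate profile with the stored layout."""
        if isinstance(profile, pd.DataFrame):
            table = profile
        elif isinstance(profile, pd.Series):
            table = profile.to_frame().T
        else:
            table = pd.DataFrame([profile])
        X, _ = build_design(table, self.spec, self.layout)
        return X

    def survival(self, profile, t):
        X = self.design_row(profile)
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        eta, _ = self.linear_predictor(np.log(t), X)
        return np.exp(-np.exp(eta))

    def hazard(self, profile, t):
        X = self.design_row(profile)
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        eta, deta = self.linear_predictor(np.log(t), X)
        if np.any(np.asarray(deta) <= 0):
            raise ValueError("non-positive time-slope: hazard undefined at this time")
        return np.exp(eta) * deta / t

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "layout": self.layout.to_dict(),
            "baseline_knots": list(map(float, self.baseline_knots)),
            "tde_knots": {k: list(map(float, v)) for k, v in self.tde_knots.items()},
            "intercept": float(self.intercept),
            "gamma": list(map(float, self.gamma)),
            "beta": list(map(float, self.beta)),
            "tde_coefs": {k: np.asarray(v).tolist() for k, v in self.tde_coefs.items()},
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "param_names": list(self.param_names),
            "se": None if self.se is None else list(map(float, self.se)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPMFit":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            layout=DesignLayout.from_dict(d["layout"]),
            baseline_knots=np.asarray(d["baseline_knots"], dtype=float),
            tde_knots={k: np.asarray(v, dtype=float) for k, v in d["tde_knots"].items()},
            intercept=float(d["intercept"]),
            gamma=np.asarray(d["gamma"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            tde_coefs={k: np.asarray(v, dtype=float) for k, v in d["tde_coefs"].items()},
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            param_names=list(d["param_names"]),
            se=None if d.get("se") is None else np.asarray(d["se"], dtype=float),
        )


def _weibull_start(t, d):
    """Weibull (shape, log-scale) warm start: eta = g0 + g1 ln t."""
    try:
        from lifelines import WeibullFitter

        wf = WeibullFitter().fit(t, event_observed=d)
        rho = float(wf.rho_)
        lam = float(wf.lambda_)
        return -rho * np.log(lam), rho
    except Exception:
        # exponential moment start: H(t) = rate * t
        rate = max(d.sum(), 1) / t.sum()
        return float(np.log(rate)), 1.0


def fit_fpm_arrays(
    times_years,
    events,
    covariates: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    *,
    max_iter: int = 200,
    compute_se: bool = True,
) -> FPMFit:
    """Maximum-likelihood fit of the flexible parametric survival model.

    ``times_years`` must be positive; ``events`` flags deaths.  Baseline
    spline knots are placed on the log event times (boundary at min/max,
    interior at equally spaced centiles), as are the knots of each
    time-dependent-effect spline.
    """
    t = np.asarray(times_years, dtype=float)
    d = np.asarray(events, dtype=bool)
    if np.any(t <= 0):
        raise ValueError("all survival times must be positive")
    if not d.any():
        raise ValueError("cannot fit a survival model with no events")
    if spec is None:
        spec = ModelSpec(baseline_df=5) if covariates is not None else ModelSpec(
            baseline_df=1
        )
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(t)))
    X, layout = build_design(covariates, spec)

    log_t = np.log(t)
    log_te = log_t[d]
    baseline_knots = spline_knots(log_te, spec.baseline_df)
    tde_knots = {name: spline_knots(log_te, df_) for name, df_ in spec.tde.items()}

    C, E = _assemble(log_t, X, layout, baseline_knots, tde_knots)
    n, P = C.shape

    # centre and scale for optimizer stability; map estimates back afterwards
    mu = C.mean(axis=0)
    sd = C.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Cs = (C - mu) / sd
    Es = E / sd
    Cs_ev, Es_ev = Cs[d], Es[d]
    log_t_ev = log_t[d]

    def nll(theta):
        deta_ev = Es_ev @ theta
        viol = _SLOPE_EPS - deta_ev
        bad = viol > 0
        if bad.any():
            grad = _PENALTY * (-Es_ev[bad].sum(axis=0))
            return _PENALTY * (1.0 + float(viol[bad].sum())), grad
        eta = np.minimum(Cs @ theta, 300.0)
        H = np.exp(eta)
        eta_ev = Cs_ev @ theta
        ll = float(np.sum(eta_ev + np.log(deta_ev) - log_t_ev)) - float(H.sum())
        grad = Cs.T @ H - Cs_ev.sum(axis=0) - Es_ev.T @ (1.0 / deta_ev)
        return -ll, grad

    # warm start: Weibull submodel, all other coefficients zero
    g0, g1 = _weibull_start(t, d)
    theta0_orig = np.zeros(P)
    theta0_orig[0] = g0
    theta0_orig[1] = g1  # baseline linear-in-ln-t column
    theta0 = theta0_orig * sd
    theta0[0] = theta0_orig[0] + float(theta0_orig @ mu)

    res = minimize(nll, theta0, jac=True, method="BFGS",
                   options={"maxiter": max_iter, "gtol": 1e-6})
    gmax = float(np.max(np.abs(res.jac)))
    n_iter = int(res.nit)
    if not res.success and gmax > 1e-4:
        res2 = minimize(nll, res.x, jac=True, method="L-BFGS-B",
                        options={"maxiter": 5 * max_iter, "ftol": 1e-14, "gtol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
            gmax = float(np.max(np.abs(res.jac)))
            n_iter += int(res2.nit)
    converged = bool(res.success or gmax < 1e-4)

    theta_s = res.x
    theta = theta_s / sd
    theta[0] = theta_s[0] - float((theta_s[1:] * mu[1:] / sd[1:]).sum())

    ll = fpm_loglik(theta, t, d, C, E)

    names = ["intercept"] + [f"ln_t_rcs{j + 1}" for j in range(spec.baseline_df)]
    names += list(layout.columns)
    tde_coefs = {}
    pos = 1 + spec.baseline_df + X.shape[1]
    for name, knots in tde_knots.items():
        m = len(layout.groups[name])
        df_ = knots.size - 1
        tde_coefs[name] = theta[pos:pos + m * df_].reshape(m, df_)
        for ci in layout.groups[name]:
            for j in range(df_):
                names.append(f"{layout.columns[ci]}:ln_t_tde{j + 1}")
        pos += m * df_

    se = None
    if compute_se:
        eta = np.minimum(C @ theta, 300.0)
        H = np.exp(eta)
        deta_ev = E[d] @ theta
        hess = (C * H[:, None]).T @ C + (E[d] / deta_ev[:, None] ** 2 * 1.0).T @ E[d]
        try:
            cov = np.linalg.pinv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = None

    return FPMFit(
        spec=spec,
        layout=layout,
        baseline_knots=baseline_knots,
        tde_knots=tde_knots,
        intercept=float(theta[0]),
        gamma=theta[1:1 + spec.baseline_df].copy(),
        beta=theta[1 + spec.baseline_df:1 + spec.baseline_df + X.shape[1]].copy(),
        tde_coefs=tde_coefs,
        log_likelihood=ll,
        converged=converged,
        n_iter=n_iter,
        param_names=names,
        se=se,
    )


def fit_fpm(ds, spec: ModelSpec | None = None, covariates: pd.DataFrame | None = None,
            **kwargs) -> FPMFit:
    """Fit the model to a validated time-to-event dataset (times in years)."""
    if covariates is None:
        covariates = ds.covariates.copy()
        for e in ds.schema.entries:
            if e.kind == "categorical":
                covariates[e.name] = pd.Categorical(
                    covariates[e.name], categories=list(e.levels)
                )
    times = np.maximum(ds.times_days, 1) / TIME_UNIT_DAYS
    return fit_fpm_arrays(times, ds.events, covariates, spec, **kwargs)


def predict_survival(fit: FPMFit, profile, t):
    """S(t | profile) = exp(-exp(eta)); monotone non-increasing in t."""
    return fit.survival(profile, t)


def predict_hazard(fit: FPMFit, profile, t):
    """h(t | profile) = exp(eta) * (d eta/d ln t) / t."""
    return fit.hazard(profile, t)
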