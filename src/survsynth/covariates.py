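"""Sequential conditional modelling and sampling of covariate profiles.

The joint covariate distribution of the source data is factorised as a chain
of conditionals: M covariates are modelled one at a time, each regression
using all previously modelled covariates as predictors, so that sampling the
chain in fit order reproduces the joint distribution.  The default ordering
is least-to-most distributional complexity: continuous covariates first,
then factors by ascending level count, so the hardest distributions are
modelled with the most conditioning information.

Factor covariates use multinomial logistic regression; sampling draws each
row's level from its conditional probability vector.  Continuous covariates
use the inverse-normal-rank construction: the covariate's ranks are mapped
to standard-normal quantiles z, and the covariate is regressed on a
restricted cubic spline of z (plus prior covariates).  Sampling draws a
fresh z* ~ N(0,1), evaluates the spline prediction and adds a residual draw,
which reproduces arbitrarily non-normal marginal shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data import CovariateSchema, TTEDataset
from .fpm import rcs_basis, spline_knots

__all__ = [
    "CovariateSettings",
    "RankNormalMap",
    "MultinomialModel",
    "CovariateModelSet",
    "inverse_normal_rank",
    "order_covariates",
    "fit_covariate_sequence",
    "sample_covariates",
]


def inverse_normal_rank(values) -> np.ndarray:
    """Map values to standard-normal quantiles of their (tie-averaged) ranks.

    z_i = Phi^{-1}((r_i - 0.5) / n).  Order preserving; a single value maps
    to 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    r = rankdata(v)
    return norm.ppf((r - 0.5) / v.size)


def order_covariates(schema: CovariateSchema) -> list:
    """Modelling order: explicit ``model_order`` wins, else the heuristic.

    Heuristic: continuous covariates first (schema order), then categorical
    covariates by ascending level count (ties by schema order).  Explicit
    orders must be supplied for either all covariates or none.
    """
    explicit = [e for e in schema.entries if e.model_order is not None]
    if explicit:
        if len(explicit) != len(schema.entries):
            raise ValueError("model_order must be given for all covariates or none")
        return [e.name for e in sorted(explicit, key=lambda e: e.model_order)]
    cont = [e.name for e in schema.entries if e.kind == "continuous"]
    cats = sorted(
        (e for e in schema.entries if e.kind == "categorical"),
        key=lambda e: (len(e.levels), schema.names.index(e.name)),
    )
    return cont + [e.name for e in cats]


@dataclass
class CovariateSettings:
    """Tunables of the conditional covariate models.

    z_df: spline df for the inverse-normal-rank regression.
    predictor_df: spline df used when a continuous covariate appears as a
        predictor in later models.
    interactions: add products of the two most recently modelled categorical
        predictors in each factor model.
    ridge: L2 penalty on multinomial coefficients (separation safeguard).
    residual: add the regression-RMSE residual draw when sampling continuous
        covariates.
    round_integers: round sampled continuous values to integers when the
        source variable is integer-valued.
    clip_to_source: clamp sampled continuous values to the source range.
    """

    z_df: int = 4
    predictor_df: int = 3
    interactions: bool = True
    ridge: float = 1e-6
    residual: bool = True
    round_integers: bool = True
    clip_to_source: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSettings":
        return cls(**d)


@dataclass
class RankNormalMap:
    """Fitted inverse-normal-rank spline regression for one continuous covariate."""

    name: str
    knots_z: np.ndarray
    intercept: float
    prior_coefs: np.ndarray   # aligned with the predictor layout
    z_coefs: np.ndarray       # spline weights, len = len(knots_z) - 1
    residual_sd: float
    value_range: tuple
    round_to_int: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.knots_z) <= 0):
            raise ValueError("z-spline knots must be strictly increasing")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def predict(self, P: np.ndarray, z: np.ndarray) -> np.ndarray:
        Bz, _ = rcs_basis(z, self.knots_z)
        out = self.intercept + Bz @ self.z_coefs
        if P.shape[1]:
            out = out + P @ self.prior_coefs
        return out

    def to_dict(self) -> dict:
        return {
            "type": "rank_normal",
            "name": self.name,
            "knots_z": list(map(float, self.knots_z)),
            "intercept": float(self.intercept),
            "prior_coefs": list(map(float, self.prior_coefs)),
            "z_coefs": list(map(float, self.z_coefs)),
            "residual_sd": float(self.residual_sd),
            "value_range": [float(self.value_range[0]), float(self.value_range[1])],
            "round_to_int": bool(self.round_to_int),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RankNormalMap":
        return cls(
            name=d["name"],
            knots_z=np.asarray(d["knots_z"], dtype=float),
            intercept=float(d["intercept"]),
            prior_coefs=np.asarray(d["prior_coefs"], dtype=float),
            z_coefs=np.asarray(d["z_coefs"], dtype=float),
            residual_sd=float(d["residual_sd"]),
            value_range=tuple(d["value_range"]),
            round_to_int=bool(d["round_to_int"]),
        )


@dataclass
class MultinomialModel:
    """Reference-coded multinomial logistic model for one factor covariate."""

    name: str
    levels: list
    coef: np.ndarray  # (n_levels - 1, 1 + n_predictors); first column intercept

    def predict_proba(self, P: np.ndarray) -> np.ndarray:
        """Row-wise level probabilities; columns follow ``levels`` order."""
        n = P.shape[0]
        K = len(self.levels)
        logits = np.zeros((n, K))
        if K > 1:
            logits[:, 1:] = self.coef[:, 0] + P @ self.coef[:, 1:].T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def to_dict(self) -> dict:
        return {
            "type": "multinomial",
            "name": self.name,
            "levels": list(self.levels),
            "coef": np.asarray(self.coef).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultinomialModel":
        return cls(name=d["name"], levels=list(d["levels"]),
                   coef=np.asarray(d["coef"], dtype=float))


@dataclass
class PredictorEncoding:
    """Shared encoding of covariates when they act as predictors."""

    levels: dict = field(default_factory=dict)  # categorical -> level order
    knots: dict = field(default_factory=dict)   # continuous -> rcs knots

    def to_dict(self) -> dict:
        return {
            "levels": {k: list(v) for k, v in self.levels.items()},
            "knots": {k: list(map(float, v)) for k, v in self.knots.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorEncoding":
        return cls(
            levels={k: list(v) for k, v in d["levels"].items()},
            knots={k: np.asarray(v, dtype=float) for k, v in d["knots"].items()},
        )


@dataclass
class CovariateModelSet:
    """Ordered chain of fitted conditional covariate models."""

    fit_order: list
    kinds: dict                 # name -> "categorical" | "continuous"
    models: dict                # name -> RankNormalMap | MultinomialModel
    encoding: PredictorEncoding
    settings: CovariateSettings
    convergence: dict = field(default_factory=dict)  # name -> bool

    def to_dict(self) -> dict:
        return {
            "fit_order": list(self.fit_order),
            "kinds": dict(self.kinds),
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "encoding": self.encoding.to_dict(),
            "settings": self.settings.to_dict(),
            "convergence": {k: bool(v) for k, v in self.convergence.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateModelSet":
        models = {}
        for k, m in d["models"].items():
            if m["type"] == "multinomial":
                models[k] = MultinomialModel.from_dict(m)
            else:
                models[k] = RankNormalMap.from_dict(m)
        return cls(
            fit_order=list(d["fit_order"]),
            kinds=dict(d["kinds"]),
            models=models,
            encoding=PredictorEncoding.from_dict(d["encoding"]),
            settings=CovariateSettings.from_dict(d["settings"]),
            convergence=dict(d.get("convergence", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CovariateModelSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _predictor_matrix(columns: dict, prior_names: list, kinds: dict,
                      enc: PredictorEncoding, interactions: bool) -> np.ndarray:
    """Design matrix of prior covariates for model m (no intercept column).

    Categorical priors become reference-coded dummies, continuous priors a
    restricted cubic spline basis at the stored knots.  With ``interactions``
    the products of the dummy blocks of the two most recently modelled
    categorical priors are appended.
    """
    n = None
    blocks: list[np.ndarray] = []
    cat_blocks: dict[str, np.ndarray] = {}
    for name in prior_names:
        col = columns[name]
        n = len(col)
        if kinds[name] == "categorical":
            vals = np.asarray(col, dtype=object).astype(str)
            levels = enc.levels[name]
            block = np.column_stack([(vals == lev).astype(float) for lev in levels[1:]]) \
                if len(levels) > 1 else np.empty((n, 0))
            cat_blocks[name] = block
            blocks.append(block)
        else:
            x = np.asarray(col, dtype=float)
            B, _ = rcs_basis(x, enc.knots[name])
            blocks.append(B)
    if interactions:
        recent_cats = [nm for nm in prior_names if kinds[nm] == "categorical"][-2:]
        if len(recent_cats) == 2:
            A, B = cat_blocks[recent_cats[0]], cat_blocks[recent_cats[1]]
            if A.shape[1] and B.shape[1]:
                blocks.append((A[:, :, None] * B[:, None, :]).reshape(n, -1))
    if not blocks:
        return np.empty((len(next(iter(columns.values()))) if columns else 0, 0))
    return np.column_stack(blocks)


def _fit_multinomial(y_codes: np.ndarray, P: np.ndarray, K: int, ridge: float):
    """Reference-coded multinomial logistic coefficients.

    Intercept-only models use the closed form log(p_k / p_0); otherwise a
    weakly ridge-penalised fit (separation safeguard) via scikit-learn.
    Returns (coef, converged).
    """
    n = y_codes.size
    counts = np.bincount(y_codes, minlength=K).astype(float)
    if K == 1:
        return np.empty((0, 1 + P.shape[1])), True
    if P.shape[1] == 0:
        p = counts / n
        coef = np.column_stack([np.log(p[1:] / p[0])])
        return coef, True
    from sklearn.linear_model import LogisticRegression

    # standardise predictors for the optimizer; map estimates back afterwards
    mu = P.mean(axis=0)
    sd = P.std(axis=0)
    sd[sd == 0] = 1.0
    Ps = (P - mu) / sd

    C = 1.0 / max(ridge, 1e-12)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-9)
    clf.fit(Ps, y_codes)
    converged = bool(np.all(clf.n_iter_ < clf.max_iter))
    # sklearn's softmax parameterisation -> reference coding on level 0
    full = np.column_stack([clf.intercept_, clf.coef_])
    if K == 2 and full.shape[0] == 1:
        # binary fits return a single row already coded against class 0
        coef = full
    else:
        coef = full[1:] - full[0]
    slopes = coef[:, 1:] / sd
    intercepts = coef[:, 0] - slopes @ mu
    return np.column_stack([intercepts, slopes]), converged


def fit_covariate_sequence(
    ds: TTEDataset,
    schema: CovariateSchema | None = None,
    settings: CovariateSettings | None = None,
) -> CovariateModelSet:
    """Fit the ordered chain of conditional covariate models.

    Model m is fitted with covariates 1..m-1 as predictors; the first model
    is marginal.  Categorical covariates must be free of missing values
    (encode missingness as a level first) and every declared level must be
    observed at least once.
    """
    if schema is None:
        schema = ds.schema
    if settings is None:
        settings = CovariateSettings()
    order = order_covariates(schema)
    kinds = {e.name: e.kind for e in schema.entries}
    enc = PredictorEncoding()
    models: dict = {}
    convergence: dict = {}

    columns = {name: ds.data[name] for name in order}
    for m, name in enumerate(order):
        priors = order[:m]
        P = _predictor_matrix(columns, priors, kinds, enc, settings.interactions)
        if kinds[name] == "categorical":
            levels = list(schema[name].levels)
            vals = columns[name]
            if vals.isna().any():
                raise ValueError(
                    f"covariate {name!r} has missing values; encode them as a level first"
                )
            codes = np.asarray([levels.index(v) for v in vals.astype(str)])
            counts = np.bincount(codes, minlength=len(levels))
            if (counts == 0).any():
                empty = [levels[i] for i in np.flatnonzero(counts == 0)]
                raise ValueError(
                    f"level(s) {empty} of {name!r} observed zero times; "
                    "remove them from the schema before fitting"
                )
            coef, ok = _fit_multinomial(codes, P, len(levels), settings.ridge)
            if not ok:
                raise RuntimeError(f"multinomial model for {name!r} did not converge")
            if not np.all(np.isfinite(coef)):
                raise RuntimeError(f"non-finite coefficients for {name!r}")
            models[name] = MultinomialModel(name=name, levels=levels, coef=coef)
            convergence[name] = ok
            enc.levels[name] = levels
        else:
            y = pd.to_numeric(columns[name]).to_numpy(dtype=float)
            z = inverse_normal_rank(y)
            knots_z = spline_knots(z, settings.z_df)
            Bz, _ = rcs_basis(z, knots_z)
            D = np.column_stack([np.ones(len(y)), P, Bz])
            coefs, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coefs
            dof = max(len(y) - rank, 1)
            sd = float(np.sqrt(resid @ resid / dof))
            if not np.all(np.isfinite(coefs)):
                raise RuntimeError(f"non-finite coefficients for {name!r}")
            p = P.shape[1]
            models[name] = RankNormalMap(
                name=name,
                knots_z=knots_z,
                intercept=float(coefs[0]),
                prior_coefs=coefs[1:1 + p].copy(),
                z_coefs=coefs[1 + p:].copy(),
                residual_sd=sd if settings.residual else 0.0,
                value_range=(float(y.min()), float(y.max())),
                round_to_int=bool(
                    settings.round_integers and np.allclose(y, np.round(y))
                ),
            )
            convergence[name] = True
            enc.knots[name] = spline_knots(y, settings.predictor_df)
    return CovariateModelSet(
        fit_order=order, kinds=kinds, models=models, encoding=enc,
        settings=settings, convergence=convergence,
    )


def sample_covariates(models: CovariateModelSet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n synthetic covariate profiles from the fitted chain.

    Covariates are generated in fit order; each draw conditions on the values
    generated earlier in the row.  Categorical draws use the row-specific
    multinomial probabilities; continuous draws map z* ~ N(0,1) through the
    fitted z-spline and add the stored residual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, object] = {}
    settings = models.settings
    for name in models.fit_order:
        P = _predictor_matrix(out, [m for m in models.fit_order if m in out],
                              models.kinds, models.encoding, settings.interactions)
        if P.shape[0] == 0 and out:
            raise RuntimeError("internal error: empty predictor matrix")
        if P.shape[0] == 0:
            P = np.empty((n, 0))
        model = models.models[name]
        if isinstance(model, MultinomialModel):
            probs = model.predict_proba(P)
            u = rng.uniform(size=n)
            idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            idx = np.minimum(idx, len(model.levels) - 1)
            out[name] = pd.Categorical(
                np.asarray(model.levels, dtype=object)[idx], categories=model.levels
            )
        else:
            z = rng.standard_normal(n)
            y = model.predict(P, z)
            if model.residual_sd > 0 and settings.residual:
                y = y + rng.normal(0.0, model.residual_sd, size=n)
            if settings.clip_to_source:
                y = np.clip(y, *model.value_range)
            if model.round_to_int:
                y = np.round(y)
            out[name] = y
    return pd.DataFrame(out)
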