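"""Flexible parametric survival model: splines, likelihood, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import survsynth as sv


class TestRcsBasis:
    def test_vanishes_at_lower_boundary(self):
        knots = np.array([0.0, 0.7, 1.3, 2.0])
        B, _ = sv.rcs_basis(np.array([0.0]), knots)
        np.testing.assert_allclose(B[0, 1:], 0.0, atol=1e-15)
        assert B[0, 0] == 0.0

    def test_plus_function_arithmetic(self):
        # lam = 0.5 for the middle knot of (0, 1, 2):
        # v1(1.5) = 0.5^3 - 0.5 * 1.5^3 = -1.5625
        B, _ = sv.rcs_basis(np.array([1.5]), [0.0, 1.0, 2.0])
        assert B[0, 1] == pytest.approx(-1.5625, abs=1e-12)

    def test_linear_beyond_boundary(self):
        knots = np.array([-1.0, 0.0, 0.5, 2.0])
        x0 = 3.0  # beyond the upper boundary knot
        h = 1e-3
        B = lambda x: sv.rcs_basis(np.array([x]), knots)[0][0]
        second = (B(x0 + h) - 2 * B(x0) + B(x0 - h)) / h**2
        np.testing.assert_allclose(second, 0.0, atol=1e-6)

    def test_value_and_slope_continuous_at_knots(self):
        knots = np.array([-0.5, 0.2, 0.9, 1.7])
        eps = 1e-8
        for k in knots:
            Bl, Dl = sv.rcs_basis(np.array([k - eps]), knots)
            Br, Dr = sv.rcs_basis(np.array([k + eps]), knots)
            np.testing.assert_allclose(Bl, Br, atol=1e-6)
            np.testing.assert_allclose(Dl, Dr, atol=1e-6)

    def test_derivative_matches_finite_difference(self):
        knots = np.array([0.0, 0.5, 1.0, 2.0])
        x = np.array([0.3, 0.77, 1.5])
        h = 1e-6
        _, D = sv.rcs_basis(x, knots)
        Bp, _ = sv.rcs_basis(x + h, knots)
        Bm, _ = sv.rcs_basis(x - h, knots)
        np.testing.assert_allclose(D, (Bp - Bm) / (2 * h), atol=1e-6)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError):
            sv.rcs_basis(np.array([1.0]), [0.0, 0.0, 1.0])


class TestWinsorize:
    def test_full_range_unchanged(self):
        v = np.array([3.0, -1.0, 7.0])
        np.testing.assert_array_equal(sv.winsorize(v, 0, 100), v)

    def test_constant_vector_unchanged(self):
        v = np.full(10, 4.2)
        np.testing.assert_array_equal(sv.winsorize(v, 2, 98), v)

    def test_bounds_equal_percentiles(self):
        v = np.arange(1.0, 101.0)
        out = sv.winsorize(v, 2, 98)
        assert out.min() == pytest.approx(np.percentile(v, 2))
        assert out.max() == pytest.approx(np.percentile(v, 98))
        inner = (v > np.percentile(v, 2)) & (v < np.percentile(v, 98))
        np.testing.assert_array_equal(out[inner], v[inner])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sv.winsorize(np.array([]), 2, 98)


class TestBuildDesign:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            "age": rng.uniform(40, 90, size=n),
        })

    def test_reference_coding_column_count(self):
        spec = sv.ModelSpec(baseline_df=1, categorical_effects=("stage",))
        X, layout = sv.build_design(self._table(), spec)
        assert X.shape[1] == 3

    def test_spline_times_dummies_interaction_count(self):
        spec = sv.ModelSpec(
            baseline_df=1,
            categorical_effects=("stage",),
            continuous_effects={"age": 3},
            interactions=(("age", "stage"),),
        )
        X, layout = sv.build_design(self._table(), spec)
        assert len(layout.groups["age:stage"]) == 9

    def test_rebuild_is_layout_deterministic(self):
        spec = sv.ModelSpec(baseline_df=1, categorical_effects=("stage",),
                            continuous_effects={"age": 2}, winsor={"age": (2, 98)})
        table = self._table()
        X, layout = sv.build_design(table, spec)
        perm = np.random.default_rng(1).permutation(len(table))
        X2, _ = sv.build_design(table.iloc[perm], spec, layout)
        np.testing.assert_allclose(X2, X[perm])

    def test_unseen_level_rejected(self):
        spec = sv.ModelSpec(baseline_df=1, categorical_effects=("stage",))
        table = self._table()
        _, layout = sv.build_design(table, spec)
        bad = table.copy()
        bad.loc[0, "stage"] = "V"
        with pytest.raises(ValueError, match="unseen"):
            sv.build_design(bad, spec, layout)

    def test_winsor_bounds_reused_for_new_data(self):
        spec = sv.ModelSpec(baseline_df=1, continuous_effects={"age": 1},
                            winsor={"age": (10, 90)})
        table = self._table()
        _, layout = sv.build_design(table, spec)
        wide = pd.DataFrame({"age": [0.0, 200.0]})
        X, _ = sv.build_design(wide, spec, layout)
        lo, hi = layout.winsor_bounds["age"]
        np.testing.assert_allclose(X[:, 0], [lo, hi])


def _toy_design(log_t, gamma_knots):
    """Design for a covariate-free baseline-spline model."""
    B, D = sv.rcs_basis(log_t, gamma_knots)
    C = np.column_stack([np.ones(len(log_t)), B])
    E = np.column_stack([np.zeros(len(log_t)), D])
    return C, E


class TestLoglik:
    def test_exponential_event_contribution(self):
        # eta = ln t (unit exponential): density at t=1 is e^-1
        C, E = _toy_design(np.log([1.0]), np.array([-1.0, 1.0]))
        ll = sv.fpm_loglik([0.0, 1.0], [1.0], [True], C, E)
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_exponential_censored_contribution(self):
        C, E = _toy_design(np.log([2.0]), np.array([-1.0, 1.0]))
        ll = sv.fpm_loglik([0.0, 1.0], [2.0], [False], C, E)
        assert ll == pytest.approx(-2.0, abs=1e-12)

    def test_penalty_when_slope_non_positive(self):
        C, E = _toy_design(np.log([1.0, 2.0]), np.array([-1.0, 1.0]))
        ll = sv.fpm_loglik([0.0, -1.0], [1.0, 2.0], [True, False], C, E)
        assert ll < -1e9

    def test_non_positive_time_rejected(self):
        C, E = _toy_design(np.log([1.0]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            sv.fpm_loglik([0.0, 1.0], [0.0], [True], C, E)

    def test_matches_complex_step_oracle(self):
        """h(t)^d S(t) oracle: H from an independently coded spline basis,
        h via complex-step differentiation of H (machine precision)."""
        rng = np.random.default_rng(42)

        def oracle_H(t, knots, theta):
            # independent plus-function coding, complex-safe
            x = np.log(t)
            kmin, kmax = knots[0], knots[-1]
            cols = [np.ones_like(x), x]
            for k in knots[1:-1]:
                lam = (kmax - k) / (kmax - kmin)
                def plus3(v):
                    return np.where(v.real > 0, v**3, 0.0 * v)
                cols.append(plus3(x - k) - lam * plus3(x - kmin)
                            - (1 - lam) * plus3(x - kmax))
            eta = sum(c * w for c, w in zip(cols, theta))
            return np.exp(eta)

        for _ in range(100):
            n = 10
            t = rng.uniform(0.2, 5.0, n)
            d = rng.uniform(size=n) < 0.7
            df = rng.integers(1, 4)
            knots = np.sort(rng.uniform(np.log(0.1), np.log(6.0), df + 1))
            if np.min(np.diff(knots)) < 1e-3:
                continue
            theta = np.concatenate([rng.normal(0, 0.3, 1), [rng.uniform(0.5, 1.5)],
                                    rng.normal(0, 0.2, df - 1)])
            C, E = _toy_design(np.log(t), knots)
            ll = sv.fpm_loglik(theta, t, d, C, E)
            if ll < -1e9:
                continue  # invalid draw; the penalty branch is tested above
            h_step = 1e-200
            H = oracle_H(t, knots, theta).real
            h = oracle_H(t + 1j * h_step, knots, theta).imag / h_step
            ll_oracle = float(np.sum(d * np.log(h)) - np.sum(H))
            assert ll == pytest.approx(ll_oracle, abs=1e-10)


def _weibull_censored_mle(t, d):
    """Independent 2-parameter Weibull ML oracle (shape p, rate lam):
    S(t) = exp(-(lam t)^p)."""
    def nll(x):
        p, lam = np.exp(x)
        H = (lam * t) ** p
        logh = np.log(p) + p * np.log(lam) + (p - 1) * np.log(t)
        return -(np.sum(d * logh) - np.sum(H))
    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return np.exp(res.x)


class TestFitting:
    def test_exponential_parameter_recovery(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(1 / 0.2, 5000)
        fit = sv.fit_fpm_arrays(t, np.ones(5000, bool))
        se_g1 = fit.se[1]
        se_g0 = fit.se[0]
        assert abs(fit.gamma[0] - 1.0) < 3 * se_g1
        assert abs(fit.intercept - np.log(0.2)) < 3 * se_g0
        assert fit.converged

    def test_weibull_shape_recovery(self):
        rng = np.random.default_rng(11)
        t = rng.weibull(1.5, 5000)
        fit = sv.fit_fpm_arrays(t, np.ones(5000, bool))
        assert abs(fit.gamma[0] - 1.5) < 3 * fit.se[1]

    def test_matches_direct_weibull_mle_with_censoring(self):
        rng = np.random.default_rng(12)
        t_event = rng.weibull(1.3, 800) * 2.0
        cens = rng.uniform(0.5, 3.0, 800)
        t = np.minimum(t_event, cens)
        d = t_event <= cens
        fit = sv.fit_fpm_arrays(t, d)
        p_hat, lam_hat = _weibull_censored_mle(t, d)
        # eta = g0 + g1 ln t  <->  p = g1, lam = exp(g0 / g1)
        assert fit.gamma[0] == pytest.approx(p_hat, abs=1e-4)
        assert np.exp(fit.intercept / fit.gamma[0]) == pytest.approx(lam_hat, abs=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sv.fit_fpm_arrays(np.ones(10), np.zeros(10, bool))

    def test_row_permutation_invariance(self, small_source, small_spec):
        base = sv.encode_missing_as_level(small_source, "stage")
        perm = np.random.default_rng(3).permutation(len(base))
        shuffled = sv.TTEDataset(base.data.iloc[perm].reset_index(drop=True),
                                 base.schema)
        f1 = sv.fit_fpm(base, small_spec)
        f2 = sv.fit_fpm(shuffled, small_spec)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)


class TestPrediction:
    def test_closed_form_exponential_survival(self):
        rng = np.random.default_rng(13)
        fit = sv.fit_fpm_arrays(rng.exponential(1.0, 4000), np.ones(4000, bool))
        profile = pd.Series(dtype=float)
        # evaluate at the model's own median: S should be exactly 0.5
        t_med = sv.invert_survival_time(fit, profile, 0.5)
        assert sv.predict_survival(fit, profile, t_med) == pytest.approx(0.5, abs=1e-10)

    def test_survival_approaches_one_at_origin(self, pipeline_result):
        fit = pipeline_result.bundle.fpm
        profile = pipeline_result.cohort.data.iloc[0]
        assert float(fit.survival(profile, 1e-8)) == pytest.approx(1.0, abs=1e-4)

    def test_survival_monotone_on_grid(self, pipeline_result):
        fit = pipeline_result.bundle.fpm
        grid = np.linspace(0.01, 12.0, 1000)
        for i in [0, 50, 500]:
            profile = pipeline_result.cohort.data.iloc[i]
            s = np.asarray(fit.survival(profile, grid))
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s > 0) & (s <= 1))

    def test_hazard_matches_numerical_derivative(self, pipeline_result):
        fit = pipeline_result.bundle.fpm
        profile = pipeline_result.cohort.data.iloc[7]
        grid = np.linspace(0.5, 8.0, 25)
        h = np.asarray(fit.hazard(profile, grid))
        eps = 1e-5
        s_hi = np.asarray(fit.survival(profile, grid + eps))
        s_lo = np.asarray(fit.survival(profile, grid - eps))
        h_num = -(np.log(s_hi) - np.log(s_lo)) / (2 * eps)
        np.testing.assert_allclose(h, h_num, atol=1e-4, rtol=1e-4)

    def test_serialization_round_trip(self, small_pipeline, tmp_path):
        import json

        fit = small_pipeline.bundle.fpm
        back = sv.FPMFit.from_dict(json.loads(json.dumps(fit.to_dict())))
        profile = small_pipeline.cohort.data.iloc[3]
        grid = np.array([0.5, 2.0, 6.0])
        np.testing.assert_allclose(np.asarray(back.survival(profile, grid)),
                                   np.asarray(fit.survival(profile, grid)), atol=1e-12)
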