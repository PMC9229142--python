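"""Inversion sampling of survival times, calendar dates and censoring."""

import numpy as np
import pandas as pd
import pytest

import survsynth as sv
from survsynth.data import ALIVE, DEAD
from survsynth.fpm import DesignLayout


def _analytic_fit(gamma1: float, intercept: float) -> sv.FPMFit:
    """Covariate-free fit with eta = intercept + gamma1 ln t (Weibull)."""
    return sv.FPMFit(
        spec=sv.ModelSpec(baseline_df=1),
        layout=DesignLayout(columns=[], levels={}, knots={}, winsor_bounds={}, groups={}),
        baseline_knots=np.array([np.log(0.05), np.log(20.0)]),
        tde_knots={},
        intercept=intercept,
        gamma=np.array([gamma1]),
        beta=np.array([]),
        tde_coefs={},
        log_likelihood=0.0,
        converged=True,
        n_iter=0,
        param_names=["intercept", "ln_t_rcs1"],
    )


EXP1 = _analytic_fit(1.0, 0.0)  # unit exponential: S(t) = exp(-t)
EMPTY = pd.Series(dtype=float)


class TestInversion:
    def test_exponential_median_is_ln2(self):
        t = sv.invert_survival_time(EXP1, EMPTY, 0.5)
        assert t == pytest.approx(np.log(2.0), abs=1e-10)

    def test_monotone_in_u(self):
        assert sv.invert_survival_time(EXP1, EMPTY, 0.9) < sv.invert_survival_time(
            EXP1, EMPTY, 0.1
        )

    def test_u_outside_unit_interval_rejected(self):
        for u in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                sv.invert_survival_time(EXP1, EMPTY, u)

    def test_probability_integral_transform_exact(self):
        rng = np.random.default_rng(1)
        for u in rng.uniform(1e-5, 1 - 1e-5, 50):
            t = sv.invert_survival_time(EXP1, EMPTY, u)
            assert abs(np.exp(-t) - u) < 1e-8

    def test_weibull_draws_match_analytic_survival(self):
        # shape 1.5, rate 0.2: eta = 1.5 ln 0.2 + 1.5 ln t
        fit = _analytic_fit(1.5, 1.5 * np.log(0.2))
        rng = np.random.default_rng(2)
        table = pd.DataFrame(index=range(10_000))
        days = sv.generate_times(fit, table, rng)
        t_years = days / 365.24
        grid = np.linspace(0.1, 25.0, 200)
        emp = (t_years[:, None] > grid).mean(axis=0)
        ana = np.exp(-((0.2 * grid) ** 1.5))
        assert np.max(np.abs(emp - ana)) < 0.02


class TestGenerateTimes:
    def test_ceiling_rounding_to_full_days(self):
        # uniform draw chosen so t = 0.5 days -> rounds up to 1 day
        u_for_half_day = float(np.exp(-(0.5 / 365.24)))
        fit = EXP1

        class FixedRng:
            def uniform(self, size):
                return np.full(size, u_for_half_day)

        days = sv.generate_times(fit, pd.DataFrame(index=range(3)), FixedRng())
        assert (days == 1).all()

    def test_seed_reproducibility(self):
        fit = _analytic_fit(1.2, -0.5)
        a = sv.generate_times(fit, pd.DataFrame(index=range(500)), np.random.default_rng(3))
        b = sv.generate_times(fit, pd.DataFrame(index=range(500)), np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_scalar_and_vector_inversion_agree(self, small_pipeline):
        fit = small_pipeline.bundle.fpm
        covs = small_pipeline.cohort.data.iloc[:20]
        rng = np.random.default_rng(4)
        days, u, t_years = sv.generate_times(
            fit, covs[["stage", "sex", "subsite", "age"]], rng, return_details=True
        )
        for i in (0, 7, 19):
            t_scalar = sv.invert_survival_time(fit, covs.iloc[i], u[i])
            assert t_scalar == pytest.approx(t_years[i], rel=1e-6, abs=1e-9)


class TestDiagnosisDates:
    def test_dates_fall_inside_their_year(self):
        rng = np.random.default_rng(5)
        years = rng.integers(1985, 1995, size=2000)
        dates = sv.assign_diagnosis_dates(years, rng)
        assert (dates.dt.year.to_numpy() == years).all()

    def test_leap_day_reachable(self):
        rng = np.random.default_rng(6)
        dates = sv.assign_diagnosis_dates(np.full(20_000, 1992), rng)
        assert ((dates.dt.month == 2) & (dates.dt.day == 29)).any()

    def test_mean_day_of_year_is_mid_year(self):
        n = 100_000
        rng = np.random.default_rng(7)
        dates = sv.assign_diagnosis_dates(np.full(n, 1993), rng)
        doy = dates.dt.dayofyear.to_numpy()
        mc_se = np.sqrt((365**2 - 1) / 12 / n)  # discrete-uniform sd
        assert abs(doy.mean() - 183.0) < 3 * mc_se


class TestVitalStatus:
    @pytest.mark.parametrize("time,threshold,expected", [
        (10, 100, DEAD),
        (101, 100, ALIVE),
        (100, 100, DEAD),  # inclusive boundary
    ])
    def test_threshold_coding(self, time, threshold, expected):
        assert sv.code_vital_status([time], threshold)[0] == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            sv.code_vital_status([1], 0)


class TestAdminCensoring:
    def _cohort(self, diagnosis, raw_days, vital=DEAD):
        df = pd.DataFrame({
            "diagnosis_date": [pd.Timestamp(diagnosis)],
            "raw_time_days": [raw_days],
            "vital_status": [vital],
        })
        return sv.SyntheticCohort(data=df)

    def _censor(self, date):
        return sv.CensoringInfo(pd.Timestamp(date), 4000)

    def test_censored_record_clamped_and_alive(self):
        out = sv.apply_admin_censoring(self._cohort("1994-06-15", 800),
                                       self._censor("1995-12-31"))
        row = out.data.iloc[0]
        assert row["vital_status"] == ALIVE
        assert row["exit_date"] == pd.Timestamp("1995-12-31")
        assert row["recorded_time_days"] == 564

    def test_uncensored_record_untouched(self):
        out = sv.apply_admin_censoring(self._cohort("1990-01-01", 100),
                                       self._censor("1995-12-31"))
        row = out.data.iloc[0]
        assert row["vital_status"] == DEAD
        assert row["exit_date"] == pd.Timestamp("1990-04-11")
        assert row["recorded_time_days"] == 100

    def test_exit_exactly_on_censor_date_stays_dead(self):
        out = sv.apply_admin_censoring(self._cohort("1995-12-01", 30),
                                       self._censor("1995-12-31"))
        row = out.data.iloc[0]
        assert row["vital_status"] == DEAD
        assert row["exit_date"] == pd.Timestamp("1995-12-31")

    def test_diagnosis_after_censor_date_rejected(self):
        with pytest.raises(ValueError):
            sv.apply_admin_censoring(self._cohort("1996-01-05", 10),
                                     self._censor("1995-12-31"))


class TestPipeline:
    def test_zero_n_rejected(self, small_source):
        with pytest.raises(ValueError):
            sv.run_pipeline(small_source, n=0, seed=1)

    def test_same_seed_gives_identical_csv(self, small_source, small_spec, tmp_path):
        paths = []
        for i in (0, 1):
            res = sv.run_pipeline(small_source, model_spec=small_spec, n=400, seed=123)
            p = tmp_path / f"syn{i}.csv"
            sv.write_dataset(res.synthetic, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_cohort_invariants(self, pipeline_result):
        df = pipeline_result.cohort.data
        censor = pipeline_result.bundle.censor
        censor_date = pd.Timestamp(censor.admin_censor_date)
        days_to_censor = (censor_date - df["diagnosis_date"]).dt.days
        np.testing.assert_array_equal(
            df["recorded_time_days"].to_numpy(),
            np.minimum(df["raw_time_days"], days_to_censor),
        )
        assert (df["exit_date"] <= censor_date).all()
        dead = df["vital_status"] == DEAD
        assert (df.loc[dead, "raw_time_days"] <= censor.last_exit_time_days).all()
        assert (df.loc[dead, "exit_date"] <= censor_date).all()
        alive = ~dead
        beyond = (df["raw_time_days"] > days_to_censor) | (
            df["raw_time_days"] > censor.last_exit_time_days
        )
        assert alive.equals(beyond)

    def test_synthetic_dataset_contract(self, pipeline_result, colon_source):
        syn = pipeline_result.synthetic
        assert len(syn) == len(colon_source)
        # missing stage restored as truly missing
        assert syn.data["stage"].isna().any()
        assert "Missing" not in syn.schema["stage"].levels
        # uniforms recorded per record
        u = pipeline_result.cohort.data["u"].to_numpy()
        assert ((u > 0) & (u < 1)).all()

    def test_record_duplication_at_chance_level_only(self, pipeline_result, colon_source):
        cols = ["age", "stage", "sex", "subsite", "year"]
        src = colon_source.data[cols + ["diagnosis_date", "survival_days"]].astype(str)
        syn = pipeline_result.synthetic.data[cols + ["diagnosis_date", "survival_days"]].astype(str)
        full = len(syn.merge(src, how="inner"))
        # chance bound: pairs agreeing on the covariate pattern can further
        # agree on the uniform within-year diagnosis date w.p. ~1/365, and a
        # date-matching alive pair agrees on censored time automatically, so
        # E[full matches] <= covariate pairs / 365.  Poisson-style margin.
        pattern_pairs = len(syn[cols].merge(src[cols], how="inner"))
        expected = pattern_pairs / 365.0
        assert full <= expected + 4 * np.sqrt(expected) + 3, (full, expected)

    def test_bundle_round_trip_generates_identically(self, small_pipeline, tmp_path):
        bundle = small_pipeline.bundle
        bundle.save(tmp_path / "models")
        back = sv.FitBundle.load(tmp_path / "models")
        from survsynth.generate import generate_cohort

        a = generate_cohort(bundle, 150, np.random.default_rng(9)).data
        b = generate_cohort(back, 150, np.random.default_rng(9)).data
        pd.testing.assert_frame_equal(a, b)
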