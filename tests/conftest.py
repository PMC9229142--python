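import numpy as np
import pandas as pd
import pytest

import survsynth as sv


def colon_model_spec() -> sv.ModelSpec:
    """Survival-model structure used for the colon-like replication runs:
    5 df baseline, age as a winsorized 3-df spline, age x stage/subsite/sex
    and stage x sex interactions, 3-df time-dependent effects for age and
    stage."""
    return sv.ModelSpec(
        baseline_df=5,
        categorical_effects=("stage", "sex", "subsite"),
        continuous_effects={"age": 3},
        winsor={"age": (2.0, 98.0)},
        interactions=(("age", "stage"), ("age", "subsite"), ("age", "sex"), ("stage", "sex")),
        tde={"age": 3, "stage": 3},
    )


@pytest.fixture(scope="session")
def colon_source() -> sv.TTEDataset:
    """Full-size colon-like source cohort (n = 9,064)."""
    return sv.generate_source_like_colon(sv.FixtureSpec(), np.random.default_rng(1))


@pytest.fixture(scope="session")
def pipeline_result(colon_source) -> sv.PipelineResult:
    """One full fit-and-generate run at source size, fixed seed."""
    return sv.run_pipeline(colon_source, model_spec=colon_model_spec(), seed=2)


@pytest.fixture(scope="session")
def small_source() -> sv.TTEDataset:
    """Reduced cohort for fast pipeline-level unit tests."""
    return sv.generate_source_like_colon(sv.FixtureSpec(n=1200), np.random.default_rng(5))


@pytest.fixture(scope="session")
def small_spec() -> sv.ModelSpec:
    """Lightweight survival model for the reduced cohort."""
    return sv.ModelSpec(
        baseline_df=3,
        categorical_effects=("stage", "sex", "subsite"),
        continuous_effects={"age": 2},
        winsor={"age": (2.0, 98.0)},
        tde={"stage": 2},
    )


@pytest.fixture(scope="session")
def small_pipeline(small_source, small_spec) -> sv.PipelineResult:
    return sv.run_pipeline(small_source, model_spec=small_spec, seed=7)


def make_tte_frame(rows: list[dict]) -> pd.DataFrame:
    """Minimal hand-built record tables for contract tests."""
    return pd.DataFrame(rows)
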