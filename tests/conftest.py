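import numpy as np
import pandas as pd
import pytest

from ckbcvd import (
    OUTCOMES,
    PREDICTORS,
    CoefficientSet,
    ModelFamily,
    SimConfig,
    load_family,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def families():
    return {sex: load_family(sex) for sex in ("female", "male")}


@pytest.fixture(scope="session")
def small_female_cohort():
    """3-region female cohort with region-varying baseline hazards."""
    cfg = SimConfig(seed=101, n_per_region=3000, n_regions=3, female_fraction=1.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_male_cohort():
    cfg = SimConfig(seed=202, n_per_region=3000, n_regions=3, female_fraction=0.0)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_cohort():
    """Factory for minimal cohort tables with constant standard predictors."""

    def make(time, event, region, sex="female", **extra):
        n = len(time)
        df = pd.DataFrame({
            "id": np.arange(1, n + 1),
            "region": region if np.ndim(region) else [region] * n,
            "sex": sex,
            "age": 55.0,
            "sbp": 120.0,
            "dbp": 80.0,
            "bp_treatment": 0,
            "daily_smoker": 0,
            "diabetes": 0,
            "waist": 80.0,
            "time": np.asarray(time, dtype=float),
            "event": list(event),
        })
        for key, value in extra.items():
            df[key] = value
        return df

    return make


def flat_family(sex="female", s0=(0.900, 0.910, 0.986)):
    """A model family with every coefficient zero (constant hazards)."""
    submodels = {
        o: CoefficientSet(
            outcome=o, sex=sex,
            beta_main={p: 0.0 for p in PREDICTORS},
            beta_age_interaction={p: 0.0 for p in PREDICTORS if p != "age"},
            s0_10=s,
        )
        for o, s in zip(OUTCOMES, s0)
    }
    return ModelFamily(sex=sex, submodels=submodels,
                       metadata={"version": "flat", "provenance": "test"})
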