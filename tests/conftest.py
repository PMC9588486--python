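import numpy as np
import pytest

from erkin.models import ExperimentDesign, FullParams
from erkin.synthdata import (
    DEFAULT_TRUE_PARAMS,
    VariantScenario,
    default_scenario,
    generate_timecourse,
)


@pytest.fixture(scope="session")
def wt_design() -> ExperimentDesign:
    return ExperimentDesign((0.5, 2.0, 3.25, 3.75, 5.0, 10.0, 20.0), 11)


@pytest.fixture(scope="session")
def paper_regime_full_params() -> FullParams:
    """Rate constants matching the measured regime k_Mi = 25 uM with
    order-one catalytic and unbinding rates."""
    return FullParams(kf1=0.08, kr1=1.0, kc1=1.0, kf2=0.08, kr2=1.0, kc2=1.0)


@pytest.fixture(scope="session")
def wt_linear_data(wt_design):
    """One seeded noisy wild-type data set from the default Linear truth."""
    scenario = default_scenario("wild-type")
    return generate_timecourse(scenario, model="linear", seed=3)


@pytest.fixture(scope="session")
def noise_free_linear_data(wt_design):
    scenario = VariantScenario(
        "wt", wt_design, DEFAULT_TRUE_PARAMS, sigma=0.0
    )
    return generate_timecourse(scenario, model="linear", seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
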