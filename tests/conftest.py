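import numpy as np
import pytest

from periyield.sequence_features import (
    ALPHABET,
    FeatureRegistry,
    PropertyPredictorSuite,
)
from periyield.synthetic_data import SimulationConfig, simulate_dataset
from periyield.two_stage_model import ModelConfig

#: Thinned grids (exponent step 4) used throughout the tests to stay inside
#: the CPU budget; the default spec grids remain the package default.
SMALL_SVC_GRID = tuple(
    {"C": 2.0**c, "gamma": 2.0**g} for c in (-5, -1, 3, 7, 11, 15) for g in (-15, -11, -7, -3, 1)
)
SMALL_SVR_GRID = tuple(
    {"C": 2.0**c, "gamma": 2.0**g, "epsilon": eps}
    for c in (-5, -1, 3, 7, 11, 15)
    for g in (-15, -11, -7, -3, 1)
    for eps in (0.01, 0.1, 1.0)
)
ONE_POINT_SVC = ({"C": 8.0, "gamma": 0.125},)
ONE_POINT_SVR = ({"C": 8.0, "gamma": 0.125, "epsilon": 0.1},)

PLANTED3 = (("dp_QD", 1.0), ("dp_VT", 1.0), ("dp_ER", 1.0))
ALL_TASKS = ("classification", "reg_high", "reg_medium", "reg_low")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def registry():
    return FeatureRegistry()


@pytest.fixture(scope="session")
def suite():
    return PropertyPredictorSuite.default()


@pytest.fixture()
def stub_suite():
    return PropertyPredictorSuite.constant(1.0)


@pytest.fixture(scope="session")
def sim_dataset(registry, suite):
    """A 98-instance planted-signal dataset shared by heavier tests."""
    config = SimulationConfig(
        n=98,
        planted=PLANTED3,
        noise_sd=0.1,
        seed=11,
        planted_boost=3,
        planted_boost_shared=3,
        length_range=(150, 250),
    )
    return simulate_dataset(config, registry, suite)


@pytest.fixture(scope="session")
def sim_matrix(sim_dataset, registry, suite):
    from periyield.sequence_features import extract_matrix

    return extract_matrix([r for r, _ in sim_dataset.records], registry, suite)


def fixed_config(features=("dp_QD", "dp_VT", "dp_ER"), **kwargs) -> ModelConfig:
    """A fast deterministic model config with pinned features."""
    defaults = dict(
        feature_mode="fixed",
        fixed_features={t: list(features) for t in ALL_TASKS},
        svc_grid=ONE_POINT_SVC,
        svr_grid=ONE_POINT_SVR,
        log_targets=True,
        seed=0,
    )
    defaults.update(kwargs)
    return ModelConfig(**defaults)
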