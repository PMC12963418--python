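import numpy as np
import pytest

from zfmf.model import ModelParams
from zfmf.stimulus import BatteryConfig, behavior_battery, imaging_set


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def battery():
    return behavior_battery(BatteryConfig(seed=0))


@pytest.fixture(scope="session")
def imaging():
    return imaging_set()


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort over the default battery, shared across
    tests that only read it."""
    from zfmf.synth import CohortSpec, generate_cohort

    entries = behavior_battery(BatteryConfig(seed=0))
    return generate_cohort(
        CohortSpec(n_fish=6, trials_per_stim=3, seed=1234), entries)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
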