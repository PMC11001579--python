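import numpy as np
import pytest

from neuroforage.foraging_agents import MVTAgentParams, run_mvt_agent
from neuroforage.synthetic_data import DatasetConfig, EncodingSpec, generate_dataset
from neuroforage.task_model import VISchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mvt_session():
    """A moderately long mixed-schedule MVT session reused across tests."""
    sched = VISchedule.from_pairs([(20, 40), (40, 20), (15, 25), (25, 15)],
                                  n_rewards=34)
    return run_mvt_agent(MVTAgentParams(), sched, np.random.default_rng(42))


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small full bundle (behavior + locomotion + 12 units) for unit tests."""
    cfg = DatasetConfig(
        schedule_pairs=((20.0, 40.0), (40.0, 20.0)),
        n_rewards_per_block=15,
        encoding=EncodingSpec(n_units=12),
    )
    return generate_dataset(cfg, 7)
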