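"""Shared fixtures: a desk-scale synthetic cohort reused across tests."""

import numpy as np
import pytest

from runsurf.layout import SensorCombination
from runsurf.model import ModelConfig
from runsurf.preprocessing import assemble_tensor, select_channels
from runsurf.segmentation import segment_trials
from runsurf.synthetic import (
    DEFAULT_SURFACES,
    GeneratorConfig,
    make_population,
    simulate_dataset,
)

#: Desk-scale study: 8 runners x 10 trials per surface (~1,000 gait cycles).
DESK_SEED = 42
DESK_SUBJECTS = 8
DESK_TRIALS_PER_SURFACE = 10


@pytest.fixture(scope="session")
def generator_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def desk_trials(generator_config):
    population = make_population(DESK_SUBJECTS, generator_config, seed=DESK_SEED)
    return simulate_dataset(
        population,
        DEFAULT_SURFACES,
        DESK_TRIALS_PER_SURFACE,
        generator_config,
        seed=DESK_SEED,
    )


@pytest.fixture(scope="session")
def feet_tensor(desk_trials):
    """Gait-cycle tensor of foot acceleration channels."""
    segments, _ = segment_trials(desk_trials, mode="cycles")
    feet = select_channels(segments, SensorCombination("feet", "acceleration"))
    return assemble_tensor(feet)


@pytest.fixture(scope="session")
def fast_model_config():
    """A small, quick-training config inside the tuning grid."""
    return ModelConfig(
        filters=(32, 32), batch_size=100, max_epochs=45, patience=18
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
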