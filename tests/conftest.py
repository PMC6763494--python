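import numpy as np
import pytest

from pixelpeck import (
    PixelGrid,
    SimulationConfig,
    classify_pixels,
    simulate_experiment,
    transcribe_training_pair,
)
from pixelpeck.stats import mean_scores


@pytest.fixture(scope="session")
def pair_a():
    return transcribe_training_pair("A")


@pytest.fixture(scope="session")
def class_map(pair_a):
    return classify_pixels(pair_a)


@pytest.fixture(scope="session")
def experiment():
    """Default synthetic experiment, master seed 1."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def scores(experiment):
    return mean_scores(experiment.records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, p=0.4):
    return PixelGrid(rng.random((7, 5)) < p)
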