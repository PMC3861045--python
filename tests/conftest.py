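import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from navinfer import Maze, harness, sensemodel, train_on_environment
from navinfer.sensemodel import HDBasis, PlaceBasis

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_maze():
    return harness.make_fixtures("mini-maze")


@pytest.fixture(scope="session")
def default_maze():
    return Maze.default()


@pytest.fixture(scope="session")
def mini_model(mini_maze):
    return harness.make_fixtures("trained-mini-model")


@pytest.fixture(scope="session")
def toy_lds():
    return harness.make_fixtures("toy-lds", seed=0)


@pytest.fixture(scope="session")
def arena_model(default_maze):
    """Full-size model of the default arena (10x10 place, 32 HD, P=20)."""
    return train_on_environment(default_maze)


@pytest.fixture(scope="session")
def arena_model_swapped(default_maze):
    from navinfer.envsim import swap_border_colours

    return train_on_environment(swap_border_colours(default_maze))


@pytest.fixture(scope="session")
def arena_model_speed(default_maze):
    return train_on_environment(default_maze, include_speed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
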