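import numpy as np
import pytest

from valuedyn.syndata import TaskConfig, sample_population, generate_session
from valuedyn.prep import bin_session


@pytest.fixture(scope="session")
def task():
    return TaskConfig(trials_per_condition=20)


@pytest.fixture(scope="session")
def mixed_session(task):
    """Small planted mixture: 6 stable, 6 sequential, 6 untuned units."""
    specs = sample_population(
        {"stable_linear": 6, "sequential": 6, "untuned": 6}, seed=11, task=task
    )
    return generate_session(specs, task, seed=12)


@pytest.fixture(scope="session")
def rm_encoding(mixed_session):
    """Encoding grid (100 ms bins every 25 ms)."""
    return bin_session(mixed_session)


@pytest.fixture(scope="session")
def rm_coarse(mixed_session):
    """Coarse search grid (non-overlapping 200 ms bins)."""
    return bin_session(mixed_session, bin_width=0.2, step=0.2)


@pytest.fixture(scope="session")
def strong_stable_rm(task):
    """Stable-only population with gains well above noise."""
    specs = sample_population(
        {"stable_linear": 16}, seed=21, task=task,
        param_ranges={"stable_linear": {"value_gain": (3.5, 5.0)}},
    )
    ses = generate_session(specs, task, seed=22)
    return bin_session(ses, bin_width=0.2, step=0.2)


@pytest.fixture(scope="session")
def sequential_rm(task):
    """Sequential-only population with reliable, value-modulated bumps."""
    specs = sample_population(
        {"sequential": 30}, seed=31, task=task,
        param_ranges={"sequential": {"bump_amp": (12.0, 18.0),
                                     "value_gain": (5.0, 8.0),
                                     "bump_sd": (0.12, 0.2)}},
    )
    ses = generate_session(specs, task, seed=32)
    return bin_session(ses, bin_width=0.2, step=0.2)


@pytest.fixture(scope="session")
def untuned_rm(task):
    specs = sample_population({"untuned": 12}, seed=41, task=task)
    ses = generate_session(specs, task, seed=42)
    return bin_session(ses, bin_width=0.2, step=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
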