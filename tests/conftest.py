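import numpy as np
import pytest

from laminakit import stimuli


@pytest.fixture(scope="session")
def arena_cal():
    return stimuli.Calibration.led_arena()


@pytest.fixture(scope="session")
def on_edges():
    """Small mirrored ON-edge protocol (behavioral conditions)."""
    return stimuli.build_edge_protocol("ON", n_trials=2, seed=11)


@pytest.fixture(scope="session")
def staircase():
    return stimuli.build_staircase(n_repeats=2)


@pytest.fixture(scope="session")
def flashes():
    return stimuli.build_random_flashes(total_duration=150.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
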