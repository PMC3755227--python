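"""Shared fixtures: default morphology, controller settings and cached
steady-walking traces (session-scoped, so expensive simulations run once)."""

import numpy as np
import pytest

import hexawalk as hw
from hexawalk.config import ControllerConfig, MorphologyConfig
from hexawalk.geometry import LegID


@pytest.fixture(scope="session")
def morph():
    return MorphologyConfig()


@pytest.fixture(scope="session")
def ctrl():
    return ControllerConfig()


@pytest.fixture
def left_middle_geom(morph):
    return morph.leg_geometry(LegID("L", 2))


@pytest.fixture
def right_front_geom(morph):
    return morph.leg_geometry(LegID("R", 1))


@pytest.fixture(scope="session")
def steady_trace():
    """A 30 s default forward walk (tetrapod regime), shared by tests that
    only need some steady walking to analyse."""
    return hw.simulate(hw.default_config(duration=30.0, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
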