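"""Shared fixtures: small synthetic objects built fresh per test session."""

from __future__ import annotations

import numpy as np
import pytest

from mesostate import synth
from mesostate.types import AlignedRun, ObservationMatrix, TransitionMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_config():
    return synth.SimConfig(n_sessions=4, process_noise_sd=0.01, seed=0)


@pytest.fixture(scope="session")
def small_dataset(sim_config):
    return synth.make_two_class_dataset(sim_config)


@pytest.fixture()
def random_observation(rng):
    from mesostate.synth import _random_initial_state

    return _random_initial_state(rng, shrink=0.4)


@pytest.fixture()
def random_transition(rng):
    """A well-conditioned random transition with bounded spectral radius."""
    blocks = {}
    for name, shape in TransitionMatrix.SHAPES.items():
        b = 0.6 * np.eye(*shape) + 0.1 * rng.standard_normal(shape)
        blocks[name] = b
    return TransitionMatrix(**blocks)


def make_aligned_run(rng, n_samples=2000, condition="resting", fs=250.0):
    data = rng.standard_normal((7, n_samples))
    return AlignedRun(data=data, sampling_rate=fs, condition=condition)


@pytest.fixture()
def aligned_run(rng):
    return make_aligned_run(rng)
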