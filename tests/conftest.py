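import dataclasses

import numpy as np
import pytest

from valveseg.phantom import PhantomSpec, generate_phantom, phantom_fixture_suite


@pytest.fixture(scope="session")
def presets():
    return dict(phantom_fixture_suite())


@pytest.fixture(scope="session")
def small_spec():
    """A fast-to-process phantom for pipeline-level unit tests."""
    return PhantomSpec(
        height=48,
        width=48,
        n_frames=16,
        valve_length=14,
        valve_thickness=3,
        hinge_position=(10, 24),
        swing_period=8,
        noise_sigma=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def easy_phantom(presets):
    return generate_phantom(presets["easy"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_lowrank(s, t, rank, rng, scale=1.0):
    """Exact nonnegative rank-``rank`` matrix with entries O(scale)."""
    W = rng.random((s, rank))
    H = rng.random((rank, t))
    M = W @ H
    return scale * M / M.max(), W, H


@pytest.fixture(scope="session")
def tiny_spec(small_spec):
    return dataclasses.replace(small_spec, n_frames=10)
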