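"""Shared fixtures: synthetic scenes and colour models are expensive enough
to build once per session and reuse read-only across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from thermomesh.colormap import ColormapSpec, full_ramp_table, train_inverse_model
from thermomesh.synthetic import make_scene


@pytest.fixture(scope="session")
def scene_noiseless():
    """Default 7-view scene with zero sensor noise (ground-truth renders)."""
    return make_scene(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def scene_noisy():
    """Default scene with sensor noise at the camera's NETD."""
    return make_scene(seed=0)


@pytest.fixture(scope="session")
def colormap_spec():
    return ColormapSpec()


@pytest.fixture(scope="session")
def ramp_model(colormap_spec):
    """Inverse colour model trained on the full synthetic temperature ramp."""
    return train_inverse_model(full_ramp_table(colormap_spec), split_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
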