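"""Shared fixtures.

The expensive fixtures — a trained simple-cell layer and the jittered
training sequences — are session-scoped and shared by the complex-layer
and acceptance tests.  Everything is generated from fixed seeds, so the
suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from v1complex import lgn_simple, retina, stimuli
from v1complex.config import ExperimentConfig, make_training_sequences

DESK_SEED = 0
SEQUENCE_SEED = 100


@pytest.fixture(scope="session")
def desk_config() -> ExperimentConfig:
    return ExperimentConfig.preset("desk", seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_images(desk_config):
    return [stimuli.make_synthetic_naturalistic(
                desk_config.image_size, seed=i, kind="gabor")
            for i in range(desk_config.n_images)]


@pytest.fixture(scope="session")
def desk_simple_layer(desk_config, desk_images):
    """Simple-cell layer trained with the desk protocol (cached per session)."""
    conn, log = lgn_simple.train_simple_layer(
        desk_images, desk_config.simple_train_config(), seed=DESK_SEED)
    assert conn.check_bounds()
    return conn


@pytest.fixture(scope="session")
def desk_sequences(desk_config, desk_images):
    rng = np.random.default_rng(SEQUENCE_SEED)
    return make_training_sequences(desk_config, desk_images, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
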