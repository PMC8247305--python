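"""Shared fixtures: one trained detector and seeded fixture sets per session."""

from __future__ import annotations

import numpy as np
import pytest

from wrinklefind import pipeline_fit, synthetic_data

TRAIN_SEED = 11
TEST_SEED = 101


@pytest.fixture(scope="session")
def train_fixtures() -> list[synthetic_data.Fixture]:
    return synthetic_data.generate_dataset(20, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def test_fixtures() -> list[synthetic_data.Fixture]:
    return synthetic_data.generate_dataset(20, seed=TEST_SEED)


@pytest.fixture(scope="session")
def detector(train_fixtures) -> pipeline_fit.DetectorModels:
    pairs = [(fx.image, fx.landmarks) for fx in train_fixtures]
    return pipeline_fit.train_detector(pairs)


@pytest.fixture()
def clean_fixture() -> synthetic_data.Fixture:
    """A single noise-free, evenly lit fixture with the default wrinkle."""
    spec = synthetic_data.FixtureSpec(noise_std=0.0, illumination_gradient=0.0)
    return synthetic_data.generate_fixture(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
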