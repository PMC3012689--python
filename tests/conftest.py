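"""Shared fixtures: small synthetic datasets and model configurations.

All fixtures use reduced grids (few channels, 100-ms epochs) so the whole
suite runs on one CPU in minutes; the generator itself is exercised at the
full study scale in dedicated tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import erpdecode as ed

REDUCED_NOISE = dict(
    background_sd=8.0, temporal_ar_coefficient=0.5, spatial_mixing_neighbors=0
)


@pytest.fixture(scope="session")
def small_spec() -> ed.ModelSpec:
    """Model spec matching the reduced 100-ms epoch grid."""
    return ed.ModelSpec(interval=(-20.0, 80.0))


@pytest.fixture(scope="session")
def null_dataset() -> ed.EpochedDataset:
    """80 trials, 6 channels, 50 samples, no class-dependent signal."""
    cfg = ed.SimulationConfig(
        n_channels=6,
        sampling_rate=500.0,
        epoch_window=(-20.0, 80.0),
        n_trials_per_exemplar=20,
        exemplars=ed.default_exemplars(2),
        noise=ed.NoiseSpec(**REDUCED_NOISE),
        seed=101,
    )
    return ed.generate_dataset(cfg)


@pytest.fixture(scope="session")
def signal_dataset() -> ed.EpochedDataset:
    """Strongly separable two-category dataset (large category effect)."""
    cfg = ed.SimulationConfig(
        n_channels=6,
        sampling_rate=500.0,
        epoch_window=(-20.0, 80.0),
        n_trials_per_exemplar=20,
        exemplars=ed.default_exemplars(2),
        category_effect=[
            ed.EffectSpec(channels=(1, 2), time_window=(10.0, 70.0), amplitude=18.0)
        ],
        noise=ed.NoiseSpec(**REDUCED_NOISE),
        seed=202,
    )
    return ed.generate_dataset(cfg)


@pytest.fixture
def toy_features() -> ed.FeatureMatrix:
    """40-trial, 3-feature logistic toy problem with known coefficients."""
    rng = np.random.default_rng(7)
    n, p = 40, 3
    X = rng.standard_normal((n, p))
    beta = np.array([2.0, -1.0, 0.0])
    prob = 1.0 / (1.0 + np.exp(-(X @ beta + 0.3)))
    y = (rng.random(n) < prob).astype(int)
    index = ed.FeatureIndex(np.arange(p), np.array([0.0]))
    return ed.FeatureMatrix(X=X, y=y, feature_index=index)
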