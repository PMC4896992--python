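"""Shared fixtures: small simulated experiments reused across the suite.

Simulated recordings are moderately expensive (band-limited noise synthesis
at ~1.5 kHz), so the canonical training/test pair is session-scoped. All
fixtures are fully seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

import cortstate as cs


@pytest.fixture(scope="session")
def train_experiment():
    """A 400 s, 4-channel labelled recording used for model training."""
    cfg = cs.SimConfig(duration_s=400.0, n_channels=4, rng_seed=100)
    rec, truth = cs.simulate_lfp(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def trained_model(train_experiment):
    _, rec, truth = train_experiment
    return cs.train_classifier(rec, truth)


@pytest.fixture(scope="session")
def test_experiment():
    """An independent 400 s labelled recording for classification tests."""
    cfg = cs.SimConfig(duration_s=400.0, n_channels=4, rng_seed=3)
    rec, truth = cs.simulate_lfp(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def test_segmentation(test_experiment, trained_model):
    _, rec, _ = test_experiment
    return cs.classify_recording(rec, trained_model)


@pytest.fixture(scope="session")
def unbalanced_experiments():
    """Three recordings spending ~80% of the time synchronised."""
    out = []
    for seed in (1, 2, 3):
        cfg = cs.SimConfig(
            duration_s=400.0,
            n_channels=4,
            rng_seed=seed,
            dwell_mean_s={cs.SYNCHRONISED: 200.0, cs.DESYNCHRONISED: 45.0},
            initial_state=cs.SYNCHRONISED,
        )
        out.append((cfg, *cs.simulate_lfp(cfg)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
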