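"""Shared fixtures: synthetic recordings and trained models.

Heavy artifacts (multi-seed sweeps, trained fold models) are session-scoped
so the decoding-quality, null-calibration and importance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from fusdecode.fcnn import TrainConfig, cross_validate
from fusdecode.pipeline import default_config, simulate_animal
from fusdecode.preprocess import build_balanced_dataset, make_feature_dataset
from fusdecode.synthetic import (
    SLEEP_STATES,
    SimConfig,
    simulate_recording,
    simulate_state_sequence,
    sleep_signal_map,
)

# training recipe used across the suite: minibatch SGD, harmonic LR decay,
# LR candidates selected on validation data, restarts against stuck optima
TRAIN_CFG = TrainConfig(
    minibatch=8, max_epochs=300, restarts=10, alpha_grid=(0.5, 0.05)
)


def sleep_config(seed: int, n_rois: int = 22) -> dict:
    cfg = default_config("sleep")
    cfg["sim"]["n_rois"] = n_rois
    cfg["seed"] = seed
    return cfg


def sleep_dataset(seed: int, n_rois: int = 22):
    """Ground-truth-labeled, balanced ROI dataset (22 ROIs, 3 informative)."""
    cfg = sleep_config(seed, n_rois)
    _, rec, states, _ = simulate_animal(cfg)
    ds = make_feature_dataset(rec, states.labels, mode="roi")
    return build_balanced_dataset(ds, seed=seed), rec, states


@pytest.fixture(scope="session")
def sleep_sweep():
    """Five seeds x stratified 5-fold CV on the 4-state ROI task."""
    out = []
    for seed in range(5):
        bal, rec, states = sleep_dataset(seed)
        folds = cross_validate(bal, k=5, cfg=TRAIN_CFG, seed=seed)
        out.append({"seed": seed, "dataset": bal, "folds": folds})
    return out


@pytest.fixture(scope="session")
def tiny_recording():
    """A small, fast 4-state recording for unit tests."""
    cfg = SimConfig(
        n_states=4,
        state_names=SLEEP_STATES,
        duration_s=300.0,
        frame_rate_hz=1.0,
        grid_shape=(20, 24),
        n_rois=6,
        roi_signal_map=sleep_signal_map(6),
        hemo_tau_s=1.5,
        dwell_mean_s=30.0,
        noise_sigma=0.02,
        roi_noise_sigma=0.01,
        initial_state="QW",
        initial_hold_s=60.0,
        seed=7,
    )
    states = simulate_state_sequence(cfg)
    rec = simulate_recording(states, cfg)
    return cfg, states, rec
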