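"""Shared fixtures: small synthetic sessions and stores built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trialwise import (
    GroundTruth,
    TrialStore,
    build_store,
    detect_artifacts,
    simulate_session,
)
from trialwise.montage import N2_ROI, P3B_ROI, standard_layout
from trialwise.preprocessing import PreprocessConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

DESK_CHANNELS = list(N2_ROI) + list(P3B_ROI) + ["F3", "F4", "O1", "O2"]


@pytest.fixture(scope="session")
def layout():
    return standard_layout()


@pytest.fixture(scope="session")
def desk_gt() -> GroundTruth:
    """Small simulation profile used throughout the unit tests."""
    return GroundTruth(
        n_participants=6,
        n_trials=64,
        n_blocks=2,
        n_items=4,
        sampling_rate=100.0,
        noise_sd=1.0,
        artifact_rate=0.05,
    )


@pytest.fixture(scope="session")
def desk_store(desk_gt, layout) -> TrialStore:
    """Simulated session assembled into a trial store with validity flags."""
    sess = simulate_session(desk_gt, seed=42, layout=layout, channels=DESK_CHANNELS)
    cfg = PreprocessConfig()
    store = build_store(sess.epochs, sess.behavior)
    store.meta["eeg_valid"] = np.concatenate(
        [detect_artifacts(ep, cfg) for ep in sess.epochs]
    )
    return store


def tiny_store(
    n_trials: int = 10,
    n_channels: int = 3,
    n_samples: int = 8,
    amplitudes: np.ndarray | None = None,
    **meta_cols,
) -> TrialStore:
    """Hand-built store for arithmetic-level tests."""
    if amplitudes is None:
        amplitudes = np.zeros((n_channels, n_samples, n_trials))
    meta = pd.DataFrame(
        {
            "participant_id": meta_cols.pop(
                "participant_id", ["P1"] * n_trials
            ),
            "trial_index": meta_cols.pop(
                "trial_index", np.arange(1, n_trials + 1)
            ),
            "eeg_valid": meta_cols.pop("eeg_valid", [True] * n_trials),
            **meta_cols,
        }
    )
    return TrialStore(
        amplitudes=amplitudes,
        time_ms=np.arange(n_samples, dtype=float),
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        meta=meta,
    )
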