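"""Shared fixtures: a small synthetic cohort and a trained pipeline.

The "micro" scale (a few minutes of video per organ, 64x64 frames) keeps
training fixtures fast while preserving every structural property of the
full-scale conditions (ordered segments, debris, variable frame rate).
"""

from __future__ import annotations

import pytest

import wcelocate as w
from wcelocate.model import TrainConfig, build_frame_dataset, train_cnn, train_lstm


@pytest.fixture(scope="session")
def micro_cohort():
    cfg = w.SyntheticConfig(
        n_videos=6,
        organ_durations_min=(2.5, 7.0, 2.0),
        debris_rate=0.2,
        incomplete_fraction=0.0,
        seed=42,
    )
    return w.generate_cohort(cfg)


@pytest.fixture(scope="session")
def micro_videos(micro_cohort):
    return micro_cohort.videos


@pytest.fixture(scope="session")
def micro_datasets(micro_videos):
    train_ds = build_frame_dataset(micro_videos[:3], stride=5)
    val_ds = build_frame_dataset(micro_videos[3:4], stride=5)
    return train_ds, val_ds


@pytest.fixture(scope="session")
def trained(micro_datasets):
    """A small but genuinely trained two-stage model on debris-laden data."""
    train_ds, val_ds = micro_datasets
    config = TrainConfig(max_epochs=5, seed=0, cnn_lr=3e-3, adam_lr=1e-3)
    backbone, cnn_history = train_cnn(train_ds, val_ds, config)
    snapshot = backbone.snapshot()
    head, lstm_history = train_lstm(train_ds, val_ds, backbone, config)
    return {
        "backbone": backbone,
        "head": head,
        "cnn_history": cnn_history,
        "lstm_history": lstm_history,
        "backbone_snapshot_before_lstm": snapshot,
        "config": config,
    }
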