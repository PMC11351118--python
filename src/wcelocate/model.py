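"""Two-stage sequence-aware organ classifier.

Stage 1 trains a convolutional backbone + frame-wise softmax head with
cross-entropy (SAM optimizer, batch 32, Mix-up and color augmentation);
each frame i_j is compressed to a feature x_j = GAP(backbone(i_j)).
Stage 2 freezes the backbone and trains a 5-layer, 64-unit LSTM over
32-frame feature sequences (Adam, batch 1) whose loss is the *sum* of the
per-frame cross-entropies within the window; the LSTM's hidden state at
step j sees only frames 1..j, so prediction is strictly causal and can run
on a live stream.

Desk-scale work uses the "tiny" backbone (32-dim features at 64x64 input);
the "standard" backbone honors the 1280-dim GAP-feature contract of an
EfficientNet-B0-class extractor at 512x512.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .calibration import ProbabilityTrace
from .preprocessing import (
    AugmentConfig,
    augment,
    center_crop,
    downsample_frames,
)

__all__ = [
    "BackboneParams",
    "SequenceHeadParams",
    "TrainConfig",
    "FrameDataset",
    "build_backbone",
    "build_frame_dataset",
    "normalize_frames",
    "extract_features",
    "classify_frames",
    "cnn_loss",
    "lstm_forward",
    "lstm_loss",
    "train_cnn",
    "train_lstm",
    "predict_video",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-12

#: Fixed input normalization: uint8 -> (x/255 - 0.5) / 0.25.
_NORM_MEAN, _NORM_STD = 0.5, 0.25

_ARCHITECTURES = {
    # name -> (conv specs (c_in, c_out, k, stride, pad), feature_dim)
    "tiny": ([(3, 8, 3, 2, 1), (8, 16, 3, 2, 1), (16, 32, 3, 2, 1)], 32),
    "standard": (
        [
            (3, 16, 3, 2, 1),
            (16, 32, 3, 2, 1),
            (32, 64, 3, 2, 1),
            (64, 128, 3, 2, 1),
            (128, 1280, 1, 1, 0),
        ],
        1280,
    ),
}


@dataclass
class BackboneParams:
    """A convolutional feature extractor ending in global average pooling."""

    architecture_name: str
    feature_dim: int
    net: nn.Sequential
    frame_head: nn.Linear  # the stage-1 classifier (removed for stage 2)

    def param_items(self) -> list[tuple[nn.Layer, str]]:
        return self.net.param_items()

    def snapshot(self) -> list[np.ndarray]:
        return nn.clone_params(self.param_items())


@dataclass
class SequenceHeadParams:
    """Stacked LSTM + 3-class projection operating on frame features."""

    feature_dim: int
    hidden_units: int
    lstm_layers: int
    lstm: nn.LSTMStack
    proj: nn.Linear

    def param_items(self) -> list[tuple[nn.Layer, str]]:
        return self.lstm.param_items() + [(self.proj, k) for k in self.proj.params]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for the two training stages."""

    max_epochs: int = 20
    early_stopping_patience: int = 3
    cnn_batch: int = 32
    lstm_batch: int = 1
    sam_rho: float = 0.05
    sgd_momentum: float = 0.9
    cnn_lr: float = 1e-3
    adam_lr: float = 1e-4
    sequence_length: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.cnn_batch < 1 or self.lstm_batch < 1:
            raise ValueError("epochs and batch sizes must be >= 1")
        if self.sam_rho <= 0 or self.cnn_lr <= 0 or self.adam_lr <= 0:
            raise ValueError("sam_rho and learning rates must be positive")


def build_backbone(
    architecture_name: str = "tiny", rng: np.random.Generator | None = None
) -> BackboneParams:
    if architecture_name not in _ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture_name!r}; "
            f"choose from {sorted(_ARCHITECTURES)}"
        )
    rng = rng or np.random.default_rng(0)
    specs, feature_dim = _ARCHITECTURES[architecture_name]
    layers: list[nn.Layer] = []
    for c_in, c_out, k, s, p in specs:
        layers.append(nn.Conv2d(c_in, c_out, k, stride=s, pad=p, rng=rng))
        layers.append(nn.ReLU())
    layers.append(nn.GlobalAvgPool())
    return BackboneParams(
        architecture_name=architecture_name,
        feature_dim=feature_dim,
        net=nn.Sequential(layers),
        frame_head=nn.Linear(feature_dim, 3, rng=rng),
    )


def build_sequence_head(
    feature_dim: int,
    hidden_units: int = 64,
    lstm_layers: int = 5,
    rng: np.random.Generator | None = None,
) -> SequenceHeadParams:
    rng = rng or np.random.default_rng(0)
    return SequenceHeadParams(
        feature_dim=feature_dim,
        hidden_units=hidden_units,
        lstm_layers=lstm_layers,
        lstm=nn.LSTMStack(feature_dim, hidden=hidden_units, n_layers=lstm_layers, rng=rng),
        proj=nn.Linear(hidden_units, 3, rng=rng),
    )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def normalize_frames(images: np.ndarray) -> np.ndarray:
    """uint8 [N, H, W, 3] -> float32 [N, 3, H, W], standardized."""
    x = images.astype(np.float32) / 255.0
    x = (x - _NORM_MEAN) / _NORM_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def extract_features(
    frames: np.ndarray, backbone: BackboneParams, chunk: int = 64
) -> np.ndarray:
    """Map [N, 3, H, W] (float) or [N, H, W, 3] (uint8) frames to
    [N, feature_dim] GAP features.  Deterministic in evaluation mode."""
    if frames.ndim != 4:
        raise ValueError("frames must be a 4-D array")
    if frames.dtype == np.uint8:
        frames = normalize_frames(frames)
    if frames.shape[1] != 3:
        raise ValueError("frames must be channel-first [N, 3, H, W]")
    outs = []
    for s in range(0, frames.shape[0], chunk):
        outs.append(backbone.net.forward(frames[s : s + chunk], train=False))
    feats = np.concatenate(outs, axis=0)
    if feats.shape[1] != backbone.feature_dim:
        raise RuntimeError("backbone produced unexpected feature width")
    return feats


def classify_frames(features: np.ndarray, head: nn.Linear) -> np.ndarray:
    """Frame-wise softmax probabilities [N, 3] from features."""
    if features.shape[-1] != head.params["W"].shape[0]:
        raise ValueError(
            f"feature width {features.shape[-1]} does not match head "
            f"input {head.params['W'].shape[0]}"
        )
    return nn.softmax(features @ head.params["W"] + head.params["b"], axis=-1)


def cnn_loss(predicted: np.ndarray, label: int) -> float:
    """Frame cross-entropy: -log p(true class), with an epsilon clamp so a
    (numerically) zero probability yields a large finite loss."""
    p = float(np.clip(predicted[int(label)], _EPS, 1.0))
    return -float(np.log(p))


def lstm_forward(
    feature_sequence: np.ndarray,
    head: SequenceHeadParams,
    h0: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Run the LSTM over [T, feature_dim] features; returns ([T, 3]
    probabilities, final per-layer (h, c) states).  Output at step j
    depends only on inputs 1..j."""
    feature_sequence = np.asarray(feature_sequence, dtype=np.float32)
    if feature_sequence.ndim != 2 or feature_sequence.shape[1] != head.feature_dim:
        raise ValueError(
            f"expected [T, {head.feature_dim}] features, got {feature_sequence.shape}"
        )
    hidden, finals = head.lstm.forward(feature_sequence, h0=h0, train=False)
    probs = nn.softmax(hidden @ head.proj.params["W"] + head.proj.params["b"], axis=-1)
    return probs, finals


def lstm_loss(outputs: np.ndarray, labels: Sequence[int]) -> float:
    """Sequence cross-entropy: the sum over the window of the per-frame
    cross-entropies (identical to summing :func:`cnn_loss` row by row)."""
    outputs = np.asarray(outputs)
    labels = np.asarray(labels, dtype=np.int64)
    if outputs.shape[0] != labels.shape[0]:
        raise ValueError("outputs and labels length mismatch")
    p = np.clip(outputs[np.arange(len(labels)), labels], _EPS, 1.0)
    return -float(np.log(p).sum())


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class FrameDataset:
    """Downsampled, preprocessed frames pooled over videos, with per-video
    extents retained so sequence windows never cross video boundaries."""

    images: np.ndarray  # uint8 [N, H, W, 3]
    labels: np.ndarray  # int64 [N]
    timestamps: np.ndarray  # float64 [N]
    video_slices: list[tuple[str, slice]]
    debris: np.ndarray | None = None  # bool [N] when known (synthetic data)

    def __len__(self) -> int:
        return len(self.labels)


def build_frame_dataset(
    videos: Sequence,
    stride: int = 5,
    crop: int | None = None,
    chunk: int = 256,
) -> FrameDataset:
    """Render/load every video's 1-in-``stride`` frames into one array.

    Works for both synthetic videos (rendered on the fly; debris flags
    retained) and on-disk videos (PNG frames loaded; debris unknown).
    """
    images, labels, times, slices, debris_parts = [], [], [], [], []
    have_debris = True
    pos = 0
    for video in videos:
        mani = downsample_frames(video.manifest, stride) if stride > 1 else video.manifest
        if mani.labels is None:
            raise ValueError(f"video {video.video_id} has unlabeled frames")
        idx = mani.frame_indices
        for part, imgs in video.iter_chunks(idx, chunk=chunk):
            if crop is not None:
                imgs = np.stack([center_crop(im, crop) for im in imgs])
            images.append(imgs)
        labels.append(mani.labels)
        times.append(mani.timestamps)
        slices.append((video.video_id, slice(pos, pos + len(mani))))
        pos += len(mani)
        vdebris = getattr(video, "debris", None)
        if vdebris is None:
            have_debris = False
        else:
            debris_parts.append(np.asarray(vdebris)[idx])
    return FrameDataset(
        images=np.concatenate(images, axis=0),
        labels=np.concatenate(labels),
        timestamps=np.concatenate(times),
        video_slices=slices,
        debris=np.concatenate(debris_parts) if have_debris else None,
    )


# ---------------------------------------------------------------------------
# stage 1: CNN training (SAM)
# ---------------------------------------------------------------------------


def _cnn_forward_backward(
    backbone: BackboneParams, x: np.ndarray, y_soft: np.ndarray
) -> float:
    """One forward/backward pass; gradients accumulate into the layers."""
    feats = backbone.net.forward(x, train=True)
    logits = backbone.frame_head.forward(feats, train=True)
    p = nn.softmax(logits, axis=-1)
    n = x.shape[0]
    loss = -float(np.mean(np.sum(y_soft * np.log(np.clip(p, _EPS, 1.0)), axis=1)))
    dlogits = ((p - y_soft) / n).astype(np.float32)
    dfeats = backbone.frame_head.backward(dlogits)
    backbone.net.backward(dfeats)
    return loss


def _cnn_evaluate(
    backbone: BackboneParams, ds: FrameDataset, batch: int = 256
) -> tuple[float, float]:
    losses, correct = [], 0
    for s in range(0, len(ds), batch):
        x = normalize_frames(ds.images[s : s + batch])
        y = ds.labels[s : s + batch]
        p = classify_frames(backbone.net.forward(x, train=False), backbone.frame_head)
        losses.append(-np.log(np.clip(p[np.arange(len(y)), y], _EPS, 1.0)))
        correct += int((p.argmax(axis=1) == y).sum())
    loss = float(np.concatenate(losses).mean())
    return loss, correct / len(ds)


def train_cnn(
    train_ds: FrameDataset,
    val_ds: FrameDataset | None,
    config: TrainConfig,
    architecture_name: str = "tiny",
    augment_config: AugmentConfig | None = None,
) -> tuple[BackboneParams, pd.DataFrame]:
    """Stage-1 supervised training of the backbone + frame head.

    SGD-momentum wrapped in Sharpness-Aware Minimization (two passes per
    batch), Mix-up with soft labels, early stopping on validation loss with
    the best-validation checkpoint restored.  Fully deterministic under
    ``config.seed``.
    """
    if len(train_ds) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    aug = augment_config or AugmentConfig()
    backbone = build_backbone(architecture_name, rng=rng)
    items = backbone.param_items() + [
        (backbone.frame_head, k) for k in backbone.frame_head.params
    ]
    opt = nn.SGDMomentum(lr=config.cnn_lr, momentum=config.sgd_momentum)

    def zero():
        backbone.net.zero_grad()
        backbone.frame_head.zero_grad()

    history = []
    best = {"loss": np.inf, "snap": None, "epoch": -1}
    bad_epochs = 0
    n = len(train_ds)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for s in range(0, n, config.cnn_batch):
            sel = perm[s : s + config.cnn_batch]
            if sel.size < 2:
                continue
            imgs = [
                augment(train_ds.images[i], int(train_ds.labels[i]), aug, rng)[0]
                for i in sel
            ]
            xs = np.stack(imgs)
            pair = rng.permutation(sel.size)
            lam = rng.beta(aug.mixup_alpha, aug.mixup_alpha, size=sel.size)
            xf = xs.astype(np.float32) / 255.0
            mixed = lam[:, None, None, None] * xf + (1 - lam[:, None, None, None]) * xf[pair]
            y1 = np.eye(3)[train_ds.labels[sel]]
            y_soft = lam[:, None] * y1 + (1 - lam[:, None]) * y1[pair]
            x = np.ascontiguousarray(
                ((mixed - _NORM_MEAN) / _NORM_STD).transpose(0, 3, 1, 2)
            ).astype(np.float32)
            # SAM: gradient at w, ascend to w + e, gradient there, step from w
            zero()
            loss = _cnn_forward_backward(backbone, x, y_soft)
            eps = nn.sam_perturb(items, config.sam_rho)
            zero()
            _cnn_forward_backward(backbone, x, y_soft)
            nn.sam_restore(items, eps)
            opt.step(items)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        if val_ds is not None and len(val_ds) > 0:
            val_loss, val_acc = _cnn_evaluate(backbone, val_ds)
        else:
            val_loss, val_acc = train_loss, np.nan
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best["loss"]:
            best = {
                "loss": val_loss,
                "snap": nn.clone_params(items),
                "epoch": epoch,
            }
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stopping_patience:
                break
    if best["snap"] is not None:
        nn.restore_params(items, best["snap"])
    return backbone, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# stage 2: LSTM training (Adam, frozen backbone)
# ---------------------------------------------------------------------------


def _feature_windows(
    ds: FrameDataset, backbone: BackboneParams, L: int, drop_partial: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract features once, then cut per-video consecutive L-frame windows."""
    feats = extract_features(ds.images, backbone)
    windows = []
    for _, sl in ds.video_slices:
        f = feats[sl]
        y = ds.labels[sl]
        for s in range(0, len(y), L):
            e = min(s + L, len(y))
            if drop_partial and e - s < L:
                continue
            windows.append((f[s:e], y[s:e]))
    return windows


def train_lstm(
    train_ds: FrameDataset,
    val_ds: FrameDataset | None,
    backbone: BackboneParams,
    config: TrainConfig,
    hidden_units: int = 64,
    lstm_layers: int = 5,
) -> tuple[SequenceHeadParams, pd.DataFrame]:
    """Stage-2 training of the sequence head on frozen backbone features.

    The backbone is only run in evaluation mode and its parameters are never
    updated (bit-identical before/after).  Each optimization step consumes
    one 32-frame window (batch 1, Adam) with the summed per-frame
    cross-entropy as the objective; checkpoint selection is best validation
    loss with early stopping.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.sequence_length
    train_windows = _feature_windows(train_ds, backbone, L, drop_partial=True)
    if not train_windows:
        raise ValueError("training split has no full sequence window")
    val_windows = (
        _feature_windows(val_ds, backbone, L, drop_partial=True)
        if val_ds is not None and len(val_ds) > 0
        else []
    )
    head = build_sequence_head(
        backbone.feature_dim, hidden_units=hidden_units, lstm_layers=lstm_layers, rng=rng
    )
    items = head.param_items()
    opt = nn.Adam(lr=config.adam_lr)

    def eval_loss(windows) -> tuple[float, float]:
        total, correct, count = 0.0, 0, 0
        for f, y in windows:
            p, _ = lstm_forward(f, head)
            total += lstm_loss(p, y)
            correct += int((p.argmax(axis=1) == y).sum())
            count += len(y)
        return total / len(windows), correct / count

    history = []
    best = {"loss": np.inf, "snap": None, "epoch": -1}
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_windows))
        epoch_losses = []
        for wi in order:
            f, y = train_windows[wi]
            head.lstm.zero_grad()
            head.proj.zero_grad()
            hidden, _ = head.lstm.forward(f, train=True)
            logits = head.proj.forward(hidden, train=True)
            p = nn.softmax(logits, axis=-1)
            loss = lstm_loss(p, y)
            dlogits = (p - np.eye(3)[y]).astype(np.float32)  # d(sum CE)/dlogits
            dh = head.proj.backward(dlogits)
            head.lstm.backward(dh)
            opt.step(items)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        if val_windows:
            val_loss, val_acc = eval_loss(val_windows)
        else:
            val_loss, val_acc = train_loss, np.nan
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "snap": nn.clone_params(items), "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stopping_patience:
                break
    if best["snap"] is not None:
        nn.restore_params(items, best["snap"])
    return head, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# streaming prediction
# ---------------------------------------------------------------------------


def predict_video(
    video,
    backbone: BackboneParams,
    head: SequenceHeadParams | None = None,
    stride: int = 5,
    crop: int | None = None,
    sequence_length: int = 32,
    carry_state: bool = False,
    chunk: int = 256,
) -> ProbabilityTrace:
    """Predict one probability vector per downsampled frame, in time order.

    With ``head=None`` the frame-wise CNN probabilities are returned (the
    sequence-unaware baseline); otherwise the LSTM runs over consecutive
    32-frame windows (hidden state reset per window unless ``carry_state``).
    Streaming contract: the prediction for frame t never uses frames after
    t, so truncating the video leaves earlier predictions unchanged.
    """
    mani = downsample_frames(video.manifest, stride) if stride > 1 else video.manifest
    if len(mani) == 0:
        raise ValueError("empty video")
    idx = mani.frame_indices
    feats = []
    for part, imgs in video.iter_chunks(idx, chunk=chunk):
        if crop is not None:
            imgs = np.stack([center_crop(im, crop) for im in imgs])
        feats.append(extract_features(imgs, backbone))
    features = np.concatenate(feats, axis=0)
    if head is None:
        probs = classify_frames(features, backbone.frame_head)
    else:
        parts = []
        state = None
        for s in range(0, features.shape[0], sequence_length):
            p, finals = lstm_forward(features[s : s + sequence_length], head, h0=state)
            parts.append(p)
            if carry_state:
                state = finals
        probs = np.concatenate(parts, axis=0)
    return ProbabilityTrace(
        video_id=video.video_id,
        timestamps=mani.timestamps,
        probs=probs,
        frame_indices=idx,
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    backbone: BackboneParams,
    head: SequenceHeadParams | None = None,
    extra: dict | None = None,
) -> None:
    """Serialize parameters + architecture echo to a single ``.npz`` file."""
    arrays: dict[str, np.ndarray] = {}
    for i, (layer, k) in enumerate(backbone.param_items()):
        arrays[f"backbone.{i}.{k}"] = layer.params[k]
    for k in backbone.frame_head.params:
        arrays[f"frame_head.{k}"] = backbone.frame_head.params[k]
    meta = {
        "architecture_name": backbone.architecture_name,
        "feature_dim": backbone.feature_dim,
        "has_head": head is not None,
    }
    if head is not None:
        for k in head.lstm.params:
            arrays[f"lstm.{k}"] = head.lstm.params[k]
        for k in head.proj.params:
            arrays[f"proj.{k}"] = head.proj.params[k]
        meta.update(
            {"hidden_units": head.hidden_units, "lstm_layers": head.lstm_layers}
        )
    if extra:
        meta["extra"] = extra
    import json

    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[BackboneParams, SequenceHeadParams | None, dict]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        backbone = build_backbone(meta["architecture_name"])
        for i, (layer, k) in enumerate(backbone.param_items()):
            layer.params[k] = data[f"backbone.{i}.{k}"].copy()
        for k in backbone.frame_head.params:
            backbone.frame_head.params[k] = data[f"frame_head.{k}"].copy()
        head = None
        if meta["has_head"]:
            head = build_sequence_head(
                meta["feature_dim"],
                hidden_units=meta["hidden_units"],
                lstm_layers=meta["lstm_layers"],
            )
            for k in head.lstm.params:
                head.lstm.params[k] = data[f"lstm.{k}"].copy()
            for k in head.proj.params:
                head.proj.params[k] = data[f"proj.{k}"].copy()
    return backbone, head, meta.get("extra", {})
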