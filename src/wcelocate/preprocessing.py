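"""Manifest I/O and frame preprocessing.

Covers the standard conditioning applied to capsule video before modeling:
center-cropping the recorder's 576x576 export to 512x512 (the border
carries burned-in device text), 1-in-5 temporal downsampling, slicing a
video into 32-frame sequence windows, and the training-time augmentations
(color jitter, grayscale, horizontal flip, right-angle rotation, Mix-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

__all__ = [
    "FrameRecord",
    "VideoManifest",
    "SequenceWindow",
    "AugmentConfig",
    "read_manifest",
    "center_crop",
    "downsample_frames",
    "make_sequences",
    "augment",
    "mixup",
    "DiskVideo",
    "load_dataset",
]


@dataclass(frozen=True)
class FrameRecord:
    """One frame of a capsule video."""

    frame_index: int
    timestamp_s: float
    image_path: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be non-negative")


@dataclass
class VideoManifest:
    """Ordered per-frame records for one capsule video."""

    video_id: str
    frames: list[FrameRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("manifest must contain at least one frame")
        ts = [f.timestamp_s for f in self.frames]
        for i in range(1, len(ts)):
            if ts[i] < ts[i - 1]:
                raise ValueError(
                    f"timestamps not sorted: row {i} "
                    f"({ts[i]:.6g} s after {ts[i-1]:.6g} s)"
                )
        idx = [f.frame_index for f in self.frames]
        if len(set(idx)) != len(idx):
            raise ValueError("frame_index values must be unique within a video")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames], dtype=np.float64)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=np.int64)

    @property
    def labels(self) -> np.ndarray | None:
        """Per-frame organ labels, or None if any frame is unlabeled."""
        vals = [f.label for f in self.frames]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_indices,
                "timestamp_s": self.timestamps,
                "label": [f.label for f in self.frames],
                "path": [f.image_path for f in self.frames],
            }
        )


REQUIRED_COLUMNS = ("frame_index", "timestamp_s", "label", "path")


def read_manifest(path: str | Path, video_id: str | None = None) -> VideoManifest:
    """Read a per-video ``manifest.csv``.

    The label column may be empty (prediction mode); timestamps must be
    sorted.  Raises ``ValueError`` naming the offending column or row.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.csv"
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required column(s): {missing}")
    frames = []
    for _, row in df.iterrows():
        label = row["label"]
        label = None if pd.isna(label) else int(label)
        frames.append(
            FrameRecord(
                frame_index=int(row["frame_index"]),
                timestamp_s=float(row["timestamp_s"]),
                image_path=None if pd.isna(row["path"]) else str(row["path"]),
                label=label,
            )
        )
    vid = video_id if video_id is not None else path.parent.name
    return VideoManifest(video_id=vid, frames=frames)


def center_crop(image: np.ndarray, target: int = 512) -> np.ndarray:
    """Crop the centered ``target x target`` region (floor-split margins).

    The recorder's native 576x576 export carries device text near the
    border; the centered 512x512 region is the clean field of view.
    """
    h, w = image.shape[:2]
    if h < target or w < target:
        raise ValueError(f"image {h}x{w} smaller than crop target {target}")
    top = (h - target) // 2
    left = (w - target) // 2
    return image[top : top + target, left : left + target]


def downsample_frames(manifest: VideoManifest, stride: int = 5) -> VideoManifest:
    """Keep frames at positions 0, stride, 2*stride, ... of the original
    order (the 1-in-5 temporal downsample); timestamps are preserved."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kept = manifest.frames[::stride]
    meta = dict(manifest.metadata)
    meta["downsample_stride"] = stride * meta.get("downsample_stride", 1)
    return VideoManifest(video_id=manifest.video_id, frames=kept, metadata=meta)


@dataclass
class SequenceWindow:
    """A consecutive run of frames fed to the sequence model.

    ``images`` is filled lazily ([L, C, H, W]); ``partial`` marks a final
    window shorter than the nominal length.
    """

    frame_indices: np.ndarray
    labels: np.ndarray | None
    timestamps: np.ndarray
    partial: bool = False
    images: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frame_indices)


def make_sequences(
    manifest: VideoManifest, L: int = 32, drop_partial: bool = False
) -> list[SequenceWindow]:
    """Slice a video into consecutive non-overlapping windows of length L.

    The windows partition the manifest in order; the final shorter window
    is flagged ``partial`` and kept unless ``drop_partial`` (inference needs
    every frame predicted; fixed-length training batches do not).
    """
    if L < 1:
        raise ValueError("sequence length L must be >= 1")
    n = len(manifest)
    idx = manifest.frame_indices
    ts = manifest.timestamps
    labels = manifest.labels
    windows = []
    for s in range(0, n, L):
        e = min(s + L, n)
        partial = (e - s) < L
        if partial and drop_partial:
            continue
        windows.append(
            SequenceWindow(
                frame_indices=idx[s:e],
                labels=None if labels is None else labels[s:e],
                timestamps=ts[s:e],
                partial=partial,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation policy.

    Color jitter is applied with probability 0.8, grayscale and horizontal
    flip with 0.5 each, and rotation angle is drawn uniformly from the
    right-angle set.  Jitter magnitudes are mild defaults (+-0.2 relative;
    hue +-0.05) since only the probabilities are pinned down by the
    protocol this emulates.
    """

    color_jitter_prob: float = 0.8
    grayscale_prob: float = 0.5
    hflip_prob: float = 0.5
    rotation_angles: tuple[int, ...] = (0, 90, 180, 270)
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    mixup_alpha: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("color_jitter_prob", "grayscale_prob", "hflip_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(a % 90 != 0 for a in self.rotation_angles):
            raise ValueError("rotation_angles must be multiples of 90 degrees")
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive")


def _color_jitter(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter on a float image in [0, 1]."""
    b = rng.uniform(1.0 - cfg.brightness, 1.0 + cfg.brightness)
    c = rng.uniform(1.0 - cfg.contrast, 1.0 + cfg.contrast)
    s = rng.uniform(1.0 - cfg.saturation, 1.0 + cfg.saturation)
    h = rng.uniform(-cfg.hue, cfg.hue)
    img = img * b
    img = img.mean() + c * (img - img.mean())
    gray = img @ np.array([0.299, 0.587, 0.114])
    img = gray[..., None] + s * (img - gray[..., None])
    img = np.clip(img, 0.0, 1.0)
    if cfg.hue > 0:
        hsv = rgb_to_hsv(img)
        hsv[..., 0] = (hsv[..., 0] + h) % 1.0
        img = hsv_to_rgb(hsv)
    return np.clip(img, 0.0, 1.0)


def augment(
    image: np.ndarray,
    label: int | None,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int | None]:
    """Apply the stochastic augmentation pipeline to one H x W x 3 image.

    The label is never changed; each transform fires independently with its
    configured probability.  Accepts uint8 (returned as uint8) or float in
    [0, 1].
    """
    was_uint8 = image.dtype == np.uint8
    img = image.astype(np.float64) / 255.0 if was_uint8 else image.astype(np.float64)
    if rng.random() < config.color_jitter_prob:
        img = _color_jitter(img, config, rng)
    if rng.random() < config.grayscale_prob:
        gray = img @ np.array([0.299, 0.587, 0.114])
        img = np.repeat(gray[..., None], 3, axis=-1)
    if rng.random() < config.hflip_prob:
        img = img[:, ::-1]
    angle = int(rng.choice(np.asarray(config.rotation_angles)))
    if angle % 360:
        img = np.rot90(img, k=(angle // 90) % 4)
    img = np.ascontiguousarray(img)
    if was_uint8:
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img, label


def _onehot(label: int | np.ndarray, n_classes: int = 3) -> np.ndarray:
    if np.isscalar(label) or np.ndim(label) == 0:
        v = np.zeros(n_classes)
        v[int(label)] = 1.0
        return v
    return np.asarray(label, dtype=np.float64)


def mixup(
    image_a: np.ndarray,
    image_b: np.ndarray,
    label_a: int | np.ndarray,
    label_b: int | np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Convex-combine two images and their (one-hot) labels with a
    Beta(alpha, alpha) coefficient; returns (image, soft label, lambda)."""
    if image_a.shape != image_b.shape:
        raise ValueError(f"shape mismatch: {image_a.shape} vs {image_b.shape}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    a = image_a.astype(np.float64)
    b = image_b.astype(np.float64)
    mixed = lam * a + (1.0 - lam) * b
    soft = lam * _onehot(label_a) + (1.0 - lam) * _onehot(label_b)
    return mixed, soft, lam


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------


@dataclass
class DiskVideo:
    """A video stored as PNG frames + manifest, loadable frame-by-frame."""

    video_id: str
    manifest: VideoManifest
    root: Path
    ground_truth: "object | None" = None  # GroundTruth when present

    def render(self, frame_indices: Sequence[int] | np.ndarray) -> np.ndarray:
        by_index = {f.frame_index: f for f in self.manifest.frames}
        images = []
        for i in np.asarray(frame_indices, dtype=np.int64):
            rec = by_index[int(i)]
            with Image.open(self.root / rec.image_path) as im:
                images.append(np.asarray(im.convert("RGB"), dtype=np.uint8))
        return np.stack(images)

    def iter_chunks(self, frame_indices, chunk: int = 256):
        idx = np.asarray(frame_indices, dtype=np.int64)
        for s in range(0, idx.size, chunk):
            part = idx[s : s + chunk]
            yield part, self.render(part)


def load_dataset(directory: str | Path) -> tuple[list[DiskVideo], dict[str, str]]:
    """Load a written dataset directory; returns (videos, splits).

    ``splits`` is empty when no ``splits.json`` is present.
    """
    import json as _json

    from .synthetic import GroundTruth

    directory = Path(directory)
    videos = []
    for vdir in sorted(p for p in directory.iterdir() if p.is_dir()):
        if not (vdir / "manifest.csv").exists():
            continue
        manifest = read_manifest(vdir)
        gt = None
        gt_path = vdir / "ground_truth.json"
        if gt_path.exists():
            raw = _json.loads(gt_path.read_text())
            gt = GroundTruth(
                si_entry_s=raw["si_entry_s"], colon_entry_s=raw.get("colon_entry_s")
            )
        videos.append(
            DiskVideo(video_id=vdir.name, manifest=manifest, root=vdir, ground_truth=gt)
        )
    if not videos:
        raise ValueError(f"no videos found under {directory}")
    splits_path = directory / "splits.json"
    splits = _json.loads(splits_path.read_text()) if splits_path.exists() else {}
    return videos, splits
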