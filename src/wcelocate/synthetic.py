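"""Synthetic wireless-capsule-endoscopy video generator.

Real capsule studies are 8-13 h recordings at an adaptive 2-6 frames/s in
which the capsule traverses stomach -> small intestine -> colon, with the
small intestine contributing 70-80% of all frames.  Patient video cannot be
redistributed, so this module fabricates videos with the same structure:
three ordered organ segments with organ-specific color/texture, a variable
frame rate, ground-truth transition timestamps, debris frames whose color is
drawn from the *wrong* organ (defeating any color-only classifier while
temporal context still disambiguates), and a configurable fraction of
incomplete studies in which the recording ends before the colon.

Everything is deterministic given ``SyntheticConfig.seed``: the same config
produces bit-identical pixels, manifests and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

from .preprocessing import FrameRecord, VideoManifest

__all__ = [
    "OrganLabel",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticVideo",
    "Cohort",
    "ORGAN_BASE_RGB",
    "COLOR_BAND_RADIUS",
    "generate_frame",
    "generate_video",
    "generate_cohort",
    "write_dataset",
    "nearest_mean_color_label",
]


class OrganLabel(IntEnum):
    """Integer organ codes; the plotting convention is 0/1/2."""

    STOMACH = 0
    SMALL_INTESTINE = 1
    COLON = 2


#: Mean RGB appearance per organ: stomach smooth pink-red, small intestine
#: yellow-orange speckle, colon darker brown-green with debris-like blobs.
ORGAN_BASE_RGB: dict[int, tuple[float, float, float]] = {
    int(OrganLabel.STOMACH): (185.0, 95.0, 115.0),
    int(OrganLabel.SMALL_INTESTINE): (205.0, 155.0, 65.0),
    int(OrganLabel.COLON): (115.0, 120.0, 60.0),
}

#: Radius (per-channel, 8-bit counts) of the color band around each organ's
#: base color within which a clean frame's channel means are guaranteed to
#: fall.  Used by the nearest-mean-color oracle in the test-suite.
COLOR_BAND_RADIUS = 35.0

#: Reference distribution of main pathologic findings used to stratify the
#: cohort (normal, bleeding, inflammatory, vascular, polypoid).
PATHOLOGY_STRATA: tuple[tuple[str, int], ...] = (
    ("normal", 46),
    ("bleeding", 20),
    ("inflammatory", 30),
    ("vascular", 15),
    ("polypoid", 15),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic capsule cohort.

    Parameters
    ----------
    organ_durations_min
        Nominal (stomach, small-intestine, colon) dwell times in minutes.
        The default (16, 60, 8) puts the small-intestine frame share at
        ~71%, inside the 70-80% band typical of real capsule studies, and
        yields ~3,000 frames per video after 1-in-5 downsampling.
    fps_range
        Adaptive frame-rate band in frames/second; must lie inside [2, 6].
    debris_rate
        Per-frame probability that appearance is drawn from a *different*
        organ's distribution (bubbles/food debris making color misleading).
    resolution
        Square frame edge in pixels.  64 is the desk-scale default; the
        full-scale 576 (recorder native) is supported.
    seed
        Master seed; identical configs are bit-identical.
    n_videos
        Cohort size.
    incomplete_fraction
        Probability that a video ends inside the small intestine (battery
        exhausted before cecal entry), i.e. an incomplete study.
    duration_jitter
        Per-video, per-organ multiplicative jitter (uniform in
        ``[1-j, 1+j]``) so transition times vary across the cohort.
    """

    organ_durations_min: tuple[float, float, float] = (16.0, 60.0, 8.0)
    fps_range: tuple[float, float] = (2.0, 6.0)
    debris_rate: float = 0.2
    resolution: int = 64
    seed: int = 0
    n_videos: int = 12
    incomplete_fraction: float = 0.2
    duration_jitter: float = 0.15

    def __post_init__(self) -> None:
        if len(self.organ_durations_min) != 3 or any(
            d <= 0 for d in self.organ_durations_min
        ):
            raise ValueError("organ_durations_min must be three positive durations")
        lo, hi = self.fps_range
        if not (2.0 <= lo <= hi <= 6.0):
            raise ValueError("fps_range must satisfy 2 <= lo <= hi <= 6")
        for name in ("debris_rate", "incomplete_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16 pixels")
        if self.n_videos < 1:
            raise ValueError("n_videos must be positive")
        if not 0.0 <= self.duration_jitter < 1.0:
            raise ValueError("duration_jitter must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """True organ-transition timestamps for one video (seconds)."""

    si_entry_s: float
    colon_entry_s: float | None  # None = incomplete study

    def __post_init__(self) -> None:
        if self.si_entry_s <= 0:
            raise ValueError("si_entry_s must be positive")
        if self.colon_entry_s is not None and self.colon_entry_s <= self.si_entry_s:
            raise ValueError("colon_entry_s must exceed si_entry_s")

    @property
    def complete(self) -> bool:
        return self.colon_entry_s is not None

    def to_dict(self) -> dict:
        return {
            "si_entry_s": self.si_entry_s,
            "colon_entry_s": self.colon_entry_s,
            "complete": self.complete,
        }


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _render(appearance: int, resolution: int, rng: np.random.Generator) -> np.ndarray:
    """Render one frame with the given organ's appearance model.

    Appearance = per-organ base color (+ small per-frame jitter) + organ
    texture + i.i.d. pixel noise; channel means stay within
    ``COLOR_BAND_RADIUS`` of the base color.
    """
    r = resolution
    base = np.asarray(ORGAN_BASE_RGB[appearance], dtype=np.float64)
    mean = base + rng.normal(0.0, 4.0, size=3)
    img = np.broadcast_to(mean, (r, r, 3)).astype(np.float64).copy()

    if appearance == OrganLabel.STOMACH:
        # smooth mucosa: low-frequency shading only
        coarse = rng.normal(0.0, 1.0, size=(4, 4))
        rep = -(-r // 4)  # ceil division
        shade = np.repeat(np.repeat(coarse, rep, axis=0), rep, axis=1)[:r, :r]
        img += shade[..., None] * np.array([12.0, 8.0, 8.0])
    elif appearance == OrganLabel.SMALL_INTESTINE:
        # villi: high-frequency zero-mean speckle, strongest in red/green
        speckle = rng.normal(0.0, 22.0, size=(r, r))
        img += speckle[..., None] * np.array([1.0, 0.8, 0.4])
    else:
        # colon: mild shading plus dark debris-like blobs
        coarse = rng.normal(0.0, 1.0, size=(4, 4))
        rep = -(-r // 4)
        shade = np.repeat(np.repeat(coarse, rep, axis=0), rep, axis=1)[:r, :r]
        img += shade[..., None] * np.array([8.0, 8.0, 6.0])
        yy, xx = np.mgrid[0:r, 0:r]
        for _ in range(int(rng.integers(3, 9))):
            cy, cx = rng.uniform(0, r, size=2)
            rad = rng.uniform(r / 16.0, r / 8.0)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < rad * rad
            img[mask] *= 0.45

    img += rng.normal(0.0, 10.0, size=(r, r, 3))
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def generate_frame(
    organ: OrganLabel | int,
    debris: bool = False,
    resolution: int = 64,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one synthetic frame as a ``(resolution, resolution, 3)`` uint8 array.

    With ``debris=True`` the appearance is drawn from one of the two *other*
    organs, so a color-only classifier is led astray while the true label is
    unchanged.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16 pixels")
    if rng is None:
        rng = np.random.default_rng(0)
    organ = int(organ)
    if debris:
        others = [o for o in (0, 1, 2) if o != organ]
        appearance = int(rng.choice(others))
    else:
        appearance = organ
    return _render(appearance, resolution, rng)


def nearest_mean_color_label(image: np.ndarray) -> int:
    """Color-only oracle: assign the organ whose base color is nearest (L2)
    to the image's channel means.  Used to certify that clean frames are
    color-separable while debris frames are not."""
    mean = np.asarray(image, dtype=np.float64).reshape(-1, 3).mean(axis=0)
    dists = {
        organ: float(np.linalg.norm(mean - np.asarray(rgb)))
        for organ, rgb in ORGAN_BASE_RGB.items()
    }
    return min(dists, key=dists.get)


# ---------------------------------------------------------------------------
# video and cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticVideo:
    """One generated capsule video: manifest + ground truth + render state.

    Pixels are *not* stored; each frame is re-rendered deterministically
    from ``(render_seed, frame_index)`` on demand, so arbitrarily long
    videos cost no memory until rendered.
    """

    video_id: str
    manifest: VideoManifest
    ground_truth: GroundTruth
    debris: np.ndarray  # bool per frame (raw indexing)
    appearance: np.ndarray  # organ code actually rendered per frame
    render_seed: int
    resolution: int
    stratum: str = "normal"

    def render(self, frame_indices: Sequence[int] | np.ndarray) -> np.ndarray:
        """Render the given raw frame indices to a ``[n, H, W, 3]`` uint8 stack."""
        idx = np.asarray(frame_indices, dtype=np.int64)
        out = np.empty((idx.size, self.resolution, self.resolution, 3), dtype=np.uint8)
        for k, i in enumerate(idx):
            rng = np.random.default_rng([self.render_seed, int(i)])
            out[k] = _render(int(self.appearance[i]), self.resolution, rng)
        return out

    def iter_chunks(
        self, frame_indices: Sequence[int] | np.ndarray, chunk: int = 256
    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        idx = np.asarray(frame_indices, dtype=np.int64)
        for s in range(0, idx.size, chunk):
            part = idx[s : s + chunk]
            yield part, self.render(part)


def generate_video(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    video_id: str = "video_000",
    stratum: str = "normal",
) -> SyntheticVideo:
    """Generate one video: ordered organ segments, variable frame rate,
    debris flags, and exact ground-truth transition timestamps.

    Returns a :class:`SyntheticVideo`; its manifest covers the *raw* (not
    yet downsampled) frames, every frame labeled by its organ segment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    j = config.duration_jitter
    durations = np.asarray(config.organ_durations_min, dtype=np.float64)
    if j > 0:
        durations = durations * rng.uniform(1.0 - j, 1.0 + j, size=3)
    si_entry = durations[0] * 60.0
    colon_entry = (durations[0] + durations[1]) * 60.0
    end = float(durations.sum() * 60.0)

    incomplete = rng.random() < config.incomplete_fraction
    if incomplete:
        # battery dies in the distal small intestine: no colon frames
        end = float(rng.uniform(si_entry + 0.5 * (colon_entry - si_entry), colon_entry))
        gt = GroundTruth(si_entry_s=float(si_entry), colon_entry_s=None)
    else:
        gt = GroundTruth(si_entry_s=float(si_entry), colon_entry_s=float(colon_entry))

    lo, hi = config.fps_range
    n_est = int(end * hi) + 8
    intervals = rng.uniform(1.0 / hi, 1.0 / lo, size=n_est)
    ts = np.concatenate(([0.0], np.cumsum(intervals)))
    ts = ts[ts < end]

    labels = np.full(ts.size, int(OrganLabel.SMALL_INTESTINE), dtype=np.int64)
    labels[ts < si_entry] = int(OrganLabel.STOMACH)
    if not incomplete:
        labels[ts >= colon_entry] = int(OrganLabel.COLON)

    debris = rng.random(ts.size) < config.debris_rate
    offset = rng.integers(1, 3, size=ts.size)
    appearance = np.where(debris, (labels + offset) % 3, labels)

    render_seed = int(rng.integers(0, 2**31 - 1))

    frames = [
        FrameRecord(
            frame_index=i,
            timestamp_s=float(ts[i]),
            image_path=f"frame_{i:06d}.png",
            label=int(labels[i]),
        )
        for i in range(ts.size)
    ]
    manifest = VideoManifest(
        video_id=video_id,
        frames=frames,
        metadata={"stratum": stratum, "complete": not incomplete},
    )
    return SyntheticVideo(
        video_id=video_id,
        manifest=manifest,
        ground_truth=gt,
        debris=debris,
        appearance=appearance.astype(np.int64),
        render_seed=render_seed,
        resolution=config.resolution,
        stratum=stratum,
    )


@dataclass
class Cohort:
    """A cohort of synthetic videos with pathology strata and data splits."""

    videos: list[SyntheticVideo]
    splits: dict[str, str]  # video_id -> train | val | test
    config: SyntheticConfig

    def split(self, name: str) -> list[SyntheticVideo]:
        return [v for v in self.videos if self.splits[v.video_id] == name]

    def __iter__(self) -> Iterator[SyntheticVideo]:
        return iter(self.videos)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _allocate_strata(n: int) -> list[str]:
    """Largest-remainder allocation of n videos over the pathology strata."""
    weights = np.array([w for _, w in PATHOLOGY_STRATA], dtype=np.float64)
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for (name, _), c in zip(PATHOLOGY_STRATA, counts):
        out.extend([name] * int(c))
    return out


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate ``config.n_videos`` videos, stratify them by pathology-like
    category, and split each stratum train+validation : test 2:3 (1:1 for
    the "normal" stratum); train : validation within the development pool is
    roughly 4:1.  Videos never appear in two splits."""
    if config.n_videos < 5:
        raise ValueError(
            "n_videos must be >= 5 so that the per-stratum 2:3 "
            "(1:1 for normal) development:test ratios can be honored"
        )
    root = np.random.SeedSequence(config.seed)
    split_rng = np.random.default_rng(root.spawn(1)[0])
    video_seeds = root.spawn(config.n_videos)

    strata = _allocate_strata(config.n_videos)
    videos: list[SyntheticVideo] = []
    for i, (stratum, seq) in enumerate(zip(strata, video_seeds)):
        vid = generate_video(
            config,
            rng=np.random.default_rng(seq),
            video_id=f"video_{i:03d}",
            stratum=stratum,
        )
        videos.append(vid)

    splits: dict[str, str] = {}
    for stratum_name in {s for s in strata}:
        members = [v.video_id for v in videos if v.stratum == stratum_name]
        order = split_rng.permutation(len(members))
        members = [members[k] for k in order]
        dev_frac = 0.5 if stratum_name == "normal" else 0.4
        n_dev = _round_half_up(len(members) * dev_frac)
        dev, test = members[:n_dev], members[n_dev:]
        n_val = max(1, _round_half_up(len(dev) / 5.0)) if len(dev) >= 2 else 0
        for vid_id in dev[: len(dev) - n_val]:
            splits[vid_id] = "train"
        for vid_id in dev[len(dev) - n_val :]:
            splits[vid_id] = "val"
        for vid_id in test:
            splits[vid_id] = "test"
    return Cohort(videos=videos, splits=splits, config=config)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_dataset(
    data: Cohort | Sequence[SyntheticVideo],
    directory: str | Path,
    chunk: int = 256,
) -> Path:
    """Write videos to ``<dir>/<video_id>/frame_<n>.png`` plus per-video
    ``manifest.csv`` (header ``frame_index,timestamp_s,label,path``) and
    ``ground_truth.json``; for a cohort also ``splits.json`` at the root.

    Round-trips losslessly through :func:`wcelocate.preprocessing.read_manifest`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    videos = data.videos if isinstance(data, Cohort) else list(data)
    for video in videos:
        vdir = directory / video.video_id
        vdir.mkdir(parents=True, exist_ok=True)
        indices = np.arange(len(video.manifest.frames))
        for part, images in video.iter_chunks(indices, chunk=chunk):
            for i, img in zip(part, images):
                Image.fromarray(img).save(vdir / f"frame_{i:06d}.png")
        with open(vdir / "manifest.csv", "w") as fh:
            fh.write("frame_index,timestamp_s,label,path\n")
            for rec in video.manifest.frames:
                fh.write(
                    f"{rec.frame_index},{rec.timestamp_s!r},{rec.label},"
                    f"frame_{rec.frame_index:06d}.png\n"
                )
        with open(vdir / "ground_truth.json", "w") as fh:
            json.dump(video.ground_truth.to_dict(), fh, indent=1)
    if isinstance(data, Cohort):
        with open(directory / "splits.json", "w") as fh:
            json.dump(data.splits, fh, indent=1, sort_keys=True)
    return directory
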