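"""High-level model interface: fit a localizer on a cohort, get results.

``CapsuleLocalizer`` bundles the study conditions (splits, backbone,
training and calibration settings); ``fit()`` runs the two training stages
and returns a ``LocalizerResults`` carrying the trained parameters,
training histories and everything needed to predict, locate boundaries and
evaluate new videos.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as _model
from .calibration import (
    BoundarySet,
    CalibConfig,
    CalibratedTrace,
    ProbabilityTrace,
    compute_transit_times,
    detect_boundaries,
    smooth_trace,
)
from .evaluation import (
    MetricsReport,
    completeness_confusion,
    confusion_matrix,
    metrics_report,
    transit_error_summary,
)
from .model import (
    BackboneParams,
    FrameDataset,
    SequenceHeadParams,
    TrainConfig,
    build_frame_dataset,
    predict_video,
    train_cnn,
    train_lstm,
)
from .preprocessing import AugmentConfig

__all__ = ["CapsuleLocalizer", "LocalizerResults"]


class CapsuleLocalizer:
    """Sequence-aware organ-localization model over a capsule-video cohort.

    Parameters
    ----------
    train_videos, val_videos
        Labeled videos (synthetic or on-disk) for the two training stages.
    architecture_name
        Backbone: "tiny" (32-dim features, desk scale) or "standard"
        (1280-dim, full scale).
    train_config, augment_config, calib_config
        Stage hyper-parameters; defaults follow the documented protocol
        (20 epochs max, SAM batch 32 / Adam batch 1, jitter probabilities
        0.8/0.5, Gaussian window 128, 512-frame skip).
    stride, crop
        1-in-``stride`` temporal downsampling and optional center crop
        applied before the model sees any frame.
    """

    def __init__(
        self,
        train_videos: Sequence,
        val_videos: Sequence = (),
        architecture_name: str = "tiny",
        train_config: TrainConfig | None = None,
        augment_config: AugmentConfig | None = None,
        calib_config: CalibConfig | None = None,
        stride: int = 5,
        crop: int | None = None,
    ) -> None:
        if not train_videos:
            raise ValueError("need at least one training video")
        self.train_videos = list(train_videos)
        self.val_videos = list(val_videos)
        self.architecture_name = architecture_name
        self.train_config = train_config or TrainConfig()
        self.augment_config = augment_config or AugmentConfig()
        self.calib_config = calib_config or CalibConfig()
        self.stride = stride
        self.crop = crop
        self._train_ds: FrameDataset | None = None
        self._val_ds: FrameDataset | None = None

    def _datasets(self) -> tuple[FrameDataset, FrameDataset | None]:
        if self._train_ds is None:
            self._train_ds = build_frame_dataset(
                self.train_videos, stride=self.stride, crop=self.crop
            )
            self._val_ds = (
                build_frame_dataset(self.val_videos, stride=self.stride, crop=self.crop)
                if self.val_videos
                else None
            )
        return self._train_ds, self._val_ds

    def fit(self, stages: str = "both") -> "LocalizerResults":
        """Run the training stages ("cnn", "lstm" requires a prior cnn via
        ``fit_lstm``, or "both") and return the results object."""
        if stages not in ("cnn", "both"):
            raise ValueError("stages must be 'cnn' or 'both'")
        train_ds, val_ds = self._datasets()
        backbone, cnn_history = train_cnn(
            train_ds,
            val_ds,
            self.train_config,
            architecture_name=self.architecture_name,
            augment_config=self.augment_config,
        )
        head, lstm_history = (None, None)
        if stages == "both":
            head, lstm_history = train_lstm(
                train_ds, val_ds, backbone, self.train_config
            )
        return LocalizerResults(
            model=self,
            backbone=backbone,
            head=head,
            cnn_history=cnn_history,
            lstm_history=lstm_history,
        )

    def fit_lstm(self, backbone: BackboneParams) -> "LocalizerResults":
        """Train only the sequence stage on an existing backbone."""
        train_ds, val_ds = self._datasets()
        head, lstm_history = train_lstm(train_ds, val_ds, backbone, self.train_config)
        return LocalizerResults(
            model=self,
            backbone=backbone,
            head=head,
            cnn_history=None,
            lstm_history=lstm_history,
        )


@dataclass
class LocalizerResults:
    """Trained localizer: parameters, training curves, prediction/evaluation."""

    model: CapsuleLocalizer
    backbone: BackboneParams
    head: SequenceHeadParams | None
    cnn_history: pd.DataFrame | None
    lstm_history: pd.DataFrame | None

    # -- prediction ---------------------------------------------------------

    def predict(self, video, baseline: bool = False) -> ProbabilityTrace:
        """Per-frame probability trace; ``baseline=True`` bypasses the LSTM
        (frame-wise CNN probabilities)."""
        head = None if baseline else self.head
        return predict_video(
            video,
            self.backbone,
            head=head,
            stride=self.model.stride,
            crop=self.model.crop,
            sequence_length=self.model.train_config.sequence_length,
        )

    def locate(
        self, video, baseline: bool = False, calib_config: CalibConfig | None = None
    ) -> tuple[CalibratedTrace, BoundarySet, "object"]:
        """Predict, calibrate, detect boundaries and derive transit times."""
        cfg = calib_config or self.model.calib_config
        trace = self.predict(video, baseline=baseline)
        calibrated = smooth_trace(trace, cfg)
        boundaries = detect_boundaries(calibrated, cfg)
        transit = compute_transit_times(boundaries)
        return calibrated, boundaries, transit

    # -- evaluation ---------------------------------------------------------

    def evaluate_frames(
        self, videos: Sequence, baseline: bool = False
    ) -> MetricsReport:
        """Frame-level metrics of the raw (uncalibrated) argmax path."""
        true, pred = [], []
        for video in videos:
            trace = self.predict(video, baseline=baseline)
            mani = video.manifest
            from .preprocessing import downsample_frames

            labels = downsample_frames(mani, self.model.stride).labels
            if labels is None:
                raise ValueError(f"video {video.video_id} is unlabeled")
            true.append(labels)
            pred.append(trace.path)
        cm = confusion_matrix(np.concatenate(true), np.concatenate(pred))
        return metrics_report(cm)

    def evaluate_transit(
        self, videos: Sequence, baseline: bool = False
    ) -> dict:
        """Boundary/transit agreement against each video's ground truth."""
        pred_si, true_si = {}, {}
        pred_colon, true_colon = {}, {}
        pred_complete, true_complete = {}, {}
        for video in videos:
            gt = video.ground_truth
            _, boundaries, _ = self.locate(video, baseline=baseline)
            vid = video.video_id
            true_si[vid] = gt.si_entry_s
            pred_si[vid] = boundaries.si_entry[1] if boundaries.si_entry else None
            true_colon[vid] = gt.colon_entry_s
            pred_colon[vid] = (
                boundaries.colon_entry[1] if boundaries.colon_entry else None
            )
            pred_complete[vid] = boundaries.complete
            true_complete[vid] = gt.complete
        si_summary, si_table = transit_error_summary(pred_si, true_si)
        out = {
            "si_entry": si_summary,
            "si_table": si_table,
            "completeness": completeness_confusion(pred_complete, true_complete),
        }
        if any(v is not None for v in true_colon.values()):
            colon_summary, colon_table = transit_error_summary(pred_colon, true_colon)
            out["colon_entry"] = colon_summary
            out["colon_table"] = colon_table
        return out

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        tc = self.model.train_config
        lines = [
            "      Capsule Organ Localization — fit summary",
            "=" * 56,
            f"backbone: {self.backbone.architecture_name} "
            f"(feature_dim={self.backbone.feature_dim})",
            f"sequence head: "
            + (
                f"{self.head.lstm_layers} LSTM layers x {self.head.hidden_units} units"
                if self.head
                else "none (frame-wise baseline)"
            ),
            f"train videos: {len(self.model.train_videos)}   "
            f"val videos: {len(self.model.val_videos)}   "
            f"stride: {self.model.stride}",
            f"optimizer: SAM(rho={tc.sam_rho}, SGD lr={tc.cnn_lr}) / "
            f"Adam(lr={tc.adam_lr})   max epochs: {tc.max_epochs}",
        ]
        for name, hist in (("CNN", self.cnn_history), ("LSTM", self.lstm_history)):
            if hist is not None and len(hist):
                best = hist.loc[hist["val_loss"].idxmin()]
                lines.append(
                    f"{name}: {len(hist)} epoch(s), best val loss "
                    f"{best['val_loss']:.4f} (epoch {int(best['epoch'])}, "
                    f"val acc {best['val_accuracy']:.3f})"
                )
        lines.append(
            f"calibration: window={self.model.calib_config.window} "
            f"sigma={self.model.calib_config.effective_sigma:.1f} "
            f"skip={self.model.calib_config.skip_frames} "
            f"mode={self.model.calib_config.mode}"
        )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        _model.save_checkpoint(
            path,
            self.backbone,
            self.head,
            extra={"stride": self.model.stride, "crop": self.model.crop},
        )
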