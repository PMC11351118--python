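"""Two-stage classifier: feature contracts, losses, causality, training."""

import copy

import numpy as np
import pytest

import wcelocate as w
from wcelocate import nn
from wcelocate.model import (
    TrainConfig,
    build_backbone,
    build_frame_dataset,
    build_sequence_head,
    classify_frames,
    cnn_loss,
    extract_features,
    load_checkpoint,
    lstm_forward,
    lstm_loss,
    predict_video,
    save_checkpoint,
    train_cnn,
)
from wcelocate.preprocessing import downsample_frames
from wcelocate.synthetic import SyntheticVideo


class TestFeatures:
    def test_tiny_shape_contract(self):
        backbone = build_backbone("tiny", np.random.default_rng(0))
        x = np.random.default_rng(1).integers(0, 255, (8, 64, 64, 3), dtype=np.uint8)
        feats = extract_features(x, backbone)
        assert feats.shape == (8, 32)

    def test_standard_backbone_1280_features(self):
        backbone = build_backbone("standard", np.random.default_rng(0))
        x = np.random.default_rng(1).integers(0, 255, (2, 512, 512, 3), dtype=np.uint8)
        feats = extract_features(x, backbone)
        assert feats.shape == (2, 1280)

    def test_identical_frames_identical_features(self):
        backbone = build_backbone("tiny", np.random.default_rng(0))
        frame = np.random.default_rng(2).integers(0, 255, (1, 64, 64, 3), dtype=np.uint8)
        x = np.repeat(frame, 2, axis=0)
        feats = extract_features(x, backbone)
        assert np.array_equal(feats[0], feats[1])

    def test_bad_input_rejected(self):
        backbone = build_backbone("tiny", np.random.default_rng(0))
        with pytest.raises(ValueError):
            extract_features(np.zeros((3, 64, 64)), backbone)
        with pytest.raises(ValueError):
            build_backbone("resnet-zzz")


class TestClassifyAndLosses:
    def test_rows_on_simplex(self):
        head = nn.Linear(8, 3, np.random.default_rng(0))
        p = classify_frames(np.random.default_rng(1).normal(size=(10, 8)).astype(np.float32), head)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_logits_uniform(self):
        head = nn.Linear(4, 3)
        head.params["W"][:] = 0
        head.params["b"][:] = 0
        p = classify_frames(np.ones((2, 4), dtype=np.float32), head)
        assert np.allclose(p, 1 / 3)

    def test_softmax_shift_invariance(self):
        z = np.random.default_rng(0).normal(size=(5, 3))
        assert np.allclose(nn.softmax(z), nn.softmax(z + 100.0))

    def test_width_mismatch(self):
        head = nn.Linear(8, 3)
        with pytest.raises(ValueError):
            classify_frames(np.zeros((2, 5)), head)

    def test_cnn_loss_closed_forms(self):
        assert cnn_loss(np.array([0.0, 1.0, 0.0]), 1) == pytest.approx(0.0)
        assert cnn_loss(np.full(3, 1 / 3), 0) == pytest.approx(np.log(3))
        # monotone decreasing in the true-class probability
        losses = [cnn_loss(np.array([p, 1 - p, 0.0]), 0) for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_cnn_loss_zero_probability_clamped(self):
        val = cnn_loss(np.array([0.0, 1.0, 0.0]), 0)
        assert np.isfinite(val) and val > 20

    def test_lstm_loss_is_sum_of_frame_losses(self):
        rng = np.random.default_rng(3)
        outputs = nn.softmax(rng.normal(size=(32, 3)))
        labels = rng.integers(0, 3, 32)
        total = sum(cnn_loss(outputs[j], labels[j]) for j in range(32))
        assert lstm_loss(outputs, labels) == pytest.approx(total, abs=1e-10)

    def test_lstm_loss_uniform_closed_form(self):
        assert lstm_loss(np.full((2, 3), 1 / 3), [0, 2]) == pytest.approx(2 * np.log(3))

    def test_lstm_loss_length_mismatch(self):
        with pytest.raises(ValueError):
            lstm_loss(np.full((3, 3), 1 / 3), [0, 1])


class TestLSTMForward:
    def _head(self, d=6):
        return build_sequence_head(d, hidden_units=8, lstm_layers=2, rng=np.random.default_rng(0))

    def test_strict_causality(self):
        head = self._head()
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 6)).astype(np.float32)
        base, _ = lstm_forward(x, head)
        for t in (9, 5):
            pert = x.copy()
            pert[t] += 1.0
            out, _ = lstm_forward(pert, head)
            assert np.allclose(out[:t], base[:t])
            assert not np.allclose(out[t], base[t])

    def test_single_step(self):
        head = self._head()
        x = np.ones((1, 6), dtype=np.float32)
        out, finals = lstm_forward(x, head)
        assert out.shape == (1, 3)
        assert len(finals) == head.lstm_layers

    def test_deterministic_replay(self):
        head = self._head()
        x = np.random.default_rng(2).normal(size=(7, 6)).astype(np.float32)
        a, _ = lstm_forward(x, head)
        b, _ = lstm_forward(x, head)
        assert np.array_equal(a, b)

    def test_rows_on_simplex(self):
        head = self._head()
        out, _ = lstm_forward(np.zeros((4, 6), dtype=np.float32), head)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_width_mismatch(self):
        head = self._head()
        with pytest.raises(ValueError):
            lstm_forward(np.zeros((4, 5), dtype=np.float32), head)


class TestTraining:
    def test_clean_data_beats_color_oracle_bound(self):
        """On debris-free data the CNN reaches >95% validation accuracy
        within 5 epochs (the nearest-mean-color oracle bound)."""
        cfg = w.SyntheticConfig(
            n_videos=5,
            organ_durations_min=(3.0, 9.0, 2.0),
            debris_rate=0.0,
            incomplete_fraction=0.0,
            seed=7,
        )
        cohort = w.generate_cohort(cfg)
        train_ds = build_frame_dataset(cohort.videos[:3], stride=5)
        val_ds = build_frame_dataset(cohort.videos[3:4], stride=5)
        backbone, hist = train_cnn(
            train_ds, val_ds, TrainConfig(max_epochs=5, seed=0, cnn_lr=3e-3)
        )
        assert hist["val_accuracy"].max() > 0.95

    def test_debris_harder_than_clean_for_cnn(self, trained, micro_videos):
        res_true, res_pred, res_deb = [], [], []
        for video in micro_videos[4:]:
            trace = predict_video(video, trained["backbone"], None, stride=5)
            mani = downsample_frames(video.manifest, 5)
            res_true.append(mani.labels)
            res_pred.append(trace.path)
            res_deb.append(np.asarray(video.debris)[mani.frame_indices])
        t = np.concatenate(res_true)
        p = np.concatenate(res_pred)
        d = np.concatenate(res_deb)
        assert (p == t)[d].mean() < (p == t)[~d].mean()

    def test_seeded_determinism(self, micro_datasets):
        train_ds, val_ds = micro_datasets
        cfg = TrainConfig(max_epochs=1, seed=5)
        _, h1 = train_cnn(train_ds, val_ds, cfg)
        _, h2 = train_cnn(train_ds, val_ds, cfg)
        assert h1["val_loss"].iloc[-1] == h2["val_loss"].iloc[-1]

    def test_backbone_frozen_during_lstm(self, trained):
        before = trained["backbone_snapshot_before_lstm"]
        after = trained["backbone"].snapshot()
        assert nn.params_equal(before, after)

    def test_lstm_checkpoint_no_worse_than_first_epoch(self, trained):
        hist = trained["lstm_history"]
        assert hist["val_loss"].min() <= hist["val_loss"].iloc[0]

    def test_sequence_model_beats_cnn_on_debris(self, trained, micro_videos):
        """Temporal context recovers debris frames that fool the
        frame-wise classifier — the pipeline's central claim."""
        accs = {}
        for name, head in (("cnn", None), ("lstm", trained["head"])):
            correct = total = 0
            for video in micro_videos[4:]:
                trace = predict_video(video, trained["backbone"], head, stride=5)
                mani = downsample_frames(video.manifest, 5)
                deb = np.asarray(video.debris)[mani.frame_indices]
                correct += int((trace.path == mani.labels)[deb].sum())
                total += int(deb.sum())
            accs[name] = correct / total
        assert accs["lstm"] > accs["cnn"]


class TestPredictVideo:
    def test_trace_shape_and_simplex(self, trained, micro_videos):
        video = micro_videos[-1]
        trace = predict_video(video, trained["backbone"], trained["head"], stride=5)
        mani = downsample_frames(video.manifest, 5)
        assert len(trace) == len(mani)
        assert np.allclose(trace.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_streaming_prefix_invariance(self, trained, micro_videos):
        """Truncating the video leaves all earlier predictions unchanged."""
        video = micro_videos[-1]
        full = predict_video(video, trained["backbone"], trained["head"], stride=5)
        k_raw = video.manifest.frames[len(video.manifest) // 2].frame_index
        truncated = SyntheticVideo(
            video_id=video.video_id,
            manifest=w.VideoManifest(
                video_id=video.video_id,
                frames=[f for f in video.manifest.frames if f.frame_index <= k_raw],
            ),
            ground_truth=video.ground_truth,
            debris=video.debris,
            appearance=video.appearance,
            render_seed=video.render_seed,
            resolution=video.resolution,
        )
        part = predict_video(truncated, trained["backbone"], trained["head"], stride=5)
        assert np.allclose(part.probs, full.probs[: len(part)], atol=1e-6)

    def test_checkpoint_roundtrip(self, trained, micro_videos, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, trained["backbone"], trained["head"], extra={"k": 1})
        backbone, head, extra = load_checkpoint(path)
        assert extra == {"k": 1}
        video = micro_videos[0]
        a = predict_video(video, trained["backbone"], trained["head"], stride=5)
        b = predict_video(video, backbone, head, stride=5)
        assert np.allclose(a.probs, b.probs)
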