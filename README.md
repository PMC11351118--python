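# wcelocate

Sequence-aware organ localization and transit-time estimation for
wireless capsule endoscopy (WCE).

A capsule endoscope records 8–13 hours of video at 2–6 frames/s on its way
through the stomach, small intestine and colon. Clinicians need to know —
in real time — when the capsule leaves the stomach (gastric retention
beyond one hour calls for intervention) and whether it ever reaches the
colon (20–30% of studies are incomplete). Frame-wise classifiers lean on
color and break down on food debris; this package implements a pipeline
that is robust to that failure mode:

1. **CNN features** — each frame `i_j` is compressed to
   `x_j = GAP(f_backbone(i_j))` and classified with a softmax head trained
   by cross-entropy (SAM optimizer, batch 32, Mix-up + color jitter).
2. **LSTM sequence head** — with the backbone frozen, a 5-layer, 64-unit
   LSTM consumes 32-frame feature windows; its loss is
   `L = Σ_j −log o_j[y_j]`, the summed per-frame cross-entropy (Adam,
   batch 1). The output at step *j* sees only frames 1..j, so inference
   is strictly causal (streaming-safe).
3. **Probability calibration** — per-class probabilities are smoothed with
   a causal half-Gaussian kernel `w_i ∝ exp(−i²/2σ²)` (window 128), the
   first 512 frames are excluded from the boundary search, and a monotone
   stomach → SI → colon state machine commits transitions from the
   smoothed argmax path.
4. **Transit times** — gastric time (start → SI entry), small-bowel time
   (SI entry → colon entry), the one-hour gastric-retention alarm, and an
   incomplete-study flag when no colon entry is seen.

Because patient video is private, the package ships a synthetic capsule
video generator (`wcelocate.synthetic`) with organ-specific color/texture,
a 2–6 fps adaptive frame rate, exact ground-truth transition timestamps,
incomplete studies, and *debris frames* whose color is drawn from the
wrong organ — a color-only classifier fails on them by construction while
temporal context recovers them. Every stage of the pipeline is tested
against this generator. The CNN/LSTM engine is implemented natively in
NumPy; there is no deep-learning-framework dependency.

## Worked example

```python
import wcelocate as w
from wcelocate.model import TrainConfig

cohort = w.generate_cohort(w.SyntheticConfig(seed=1))   # 12 videos, 64x64
loc = w.CapsuleLocalizer(
    cohort.split("train"), cohort.split("val"),
    train_config=TrainConfig(max_epochs=5, seed=1),
)
res = loc.fit()                      # stage 1 (CNN) then stage 2 (LSTM)
print(res.summary())

video = cohort.split("test")[0]
calibrated, boundaries, transit = res.locate(video)
print(boundaries.to_dict())
print(f"gastric {transit.gastric_min:.1f} min, "
      f"small bowel {transit.small_bowel_min:.1f} min, "
      f"truth SI entry {video.ground_truth.si_entry_s:.0f} s")
```

Output from this exact script:

```
      Capsule Organ Localization — fit summary
========================================================
backbone: tiny (feature_dim=32)
sequence head: 5 LSTM layers x 64 units
train videos: 4   val videos: 1   stride: 5
optimizer: SAM(rho=0.05, SGD lr=0.001) / Adam(lr=0.0001)   max epochs: 5
CNN: 5 epoch(s), best val loss 0.5260 (epoch 4, val acc 0.777)
LSTM: 5 epoch(s), best val loss 6.9346 (epoch 4, val acc 0.942)
calibration: window=128 sigma=32.0 skip=512 mode=half_gaussian
{'si_entry': {'index': 597, 'timestamp_s': 1009.7172368176708},
 'colon_entry': {'index': 2810, 'timestamp_s': 4717.712398524547},
 'complete': True}
gastric 16.8 min, small bowel 61.8 min, truth SI entry 953 s
```

The CNN alone scores ~0.36 on debris frames (color misleads it); the
sequence-aware model scores ~0.95 on the same frames, and the calibrated
SI-entry estimate lands within about a minute of the true transition —
mostly the intrinsic lag of the causal smoothing kernel.

The `wce-locate` CLI wraps the same stages for on-disk datasets:
`wce-locate simulate|train|predict|evaluate --config config.yaml`.

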