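"""Half-Gaussian smoothing, boundary detection and transit times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wcelocate.calibration import (
    BoundarySet,
    CalibConfig,
    ProbabilityTrace,
    compute_transit_times,
    detect_boundaries,
    half_gaussian_kernel,
    smooth_trace,
    sweep_calibration,
)
from wcelocate.synthetic import GroundTruth


def _trace(path, video_id="v", dt=1.0, soft=0.0):
    """One-hot (or softened) trace following an argmax path."""
    path = np.asarray(path)
    probs = np.full((len(path), 3), soft / 2)
    probs[np.arange(len(path)), path] = 1.0 - soft
    return ProbabilityTrace(
        video_id=video_id,
        timestamps=np.arange(len(path)) * dt,
        probs=probs,
    )


def _segments(*lengths):
    return np.concatenate([np.full(n, i) for i, n in enumerate(lengths)])


class TestKernel:
    def test_window_one(self):
        assert np.array_equal(half_gaussian_kernel(1, 2.0), [1.0])

    def test_large_sigma_uniform_limit(self):
        k = half_gaussian_kernel(16, 1e9)
        assert np.allclose(k, 1 / 16)

    @settings(deadline=None, max_examples=40)
    @given(window=st.integers(1, 256), sigma=st.floats(0.1, 500.0))
    def test_normalized_and_monotone(self, window, sigma):
        k = half_gaussian_kernel(window, sigma)
        assert k.sum() == pytest.approx(1.0)
        assert np.all(np.diff(k) <= 1e-15)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            half_gaussian_kernel(0, 1.0)
        with pytest.raises(ValueError):
            half_gaussian_kernel(8, 0.0)


class TestSmoothing:
    def test_constant_trace_identity(self):
        trace = _trace(np.ones(300, dtype=int), soft=0.3)
        out = smooth_trace(trace, CalibConfig(window=64))
        assert np.allclose(out.probs, trace.probs, atol=1e-12)

    def test_rows_stay_on_simplex(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=500)
        trace = ProbabilityTrace("v", np.arange(500.0), probs)
        out = smooth_trace(trace, CalibConfig(window=128))
        assert np.allclose(out.probs.sum(axis=1), 1.0)
        assert np.all(out.probs >= 0)

    def test_causality_future_perturbation(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(3), size=400)
        a = ProbabilityTrace("v", np.arange(400.0), probs.copy())
        probs2 = probs.copy()
        probs2[200:] = rng.dirichlet(np.ones(3), size=200)
        b = ProbabilityTrace("v", np.arange(400.0), probs2)
        cfg = CalibConfig(window=64)
        sa = smooth_trace(a, cfg)
        sb = smooth_trace(b, cfg)
        assert np.allclose(sa.probs[:200], sb.probs[:200])
        assert not np.allclose(sa.probs[200:], sb.probs[200:])

    def test_isolated_flip_removed_matches_convolution_oracle(self):
        """A one-frame label flip inside a long run does not move the
        smoothed argmax anywhere (window 128); the smoothed values equal a
        direct convolution computed independently."""
        path = _segments(500, 500)
        path[250] = 2  # isolated wrong frame
        trace = _trace(path)
        cfg = CalibConfig(window=128)
        out = smooth_trace(trace, cfg)
        clean_smoothed = smooth_trace(_trace(_segments(500, 500)), cfg)
        assert np.array_equal(out.path, clean_smoothed.path)
        # independent direct-sum oracle
        k = np.exp(-0.5 * (np.arange(128) / 32.0) ** 2)
        k /= k.sum()
        for t in (0, 64, 250, 251, 700, 999):
            num = np.zeros(3)
            den = 0.0
            for lag in range(min(t + 1, 128)):
                num += k[lag] * trace.probs[t - lag]
                den += k[lag]
            assert np.allclose(out.probs[t], num / den, atol=1e-12)

    def test_full_gaussian_mode_runs(self):
        trace = _trace(_segments(50, 50))
        out = smooth_trace(trace, CalibConfig(window=16, mode="full_gaussian"))
        assert np.allclose(out.probs.sum(axis=1), 1.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityTrace("v", np.zeros(0), np.zeros((0, 3)))


class TestBoundaries:
    def test_exact_on_clean_trace(self):
        trace = _trace(_segments(100, 100, 100))
        cfg = CalibConfig(window=1, skip_frames=0)
        bs = detect_boundaries(trace, cfg)
        assert bs.si_entry == (100, 100.0)
        assert bs.colon_entry == (200, 200.0)
        assert bs.complete

    def test_skip_rule_first_admissible_frame(self):
        trace = _trace(_segments(100, 100, 100))
        bs = detect_boundaries(trace, CalibConfig(window=1, skip_frames=150))
        assert bs.si_entry == (150, 150.0)
        assert bs.colon_entry == (200, 200.0)

    def test_incomplete_study(self):
        trace = _trace(_segments(100, 200))
        bs = detect_boundaries(trace, CalibConfig(window=1, skip_frames=0))
        assert bs.si_entry == (100, 100.0)
        assert bs.colon_entry is None
        assert not bs.complete

    def test_trace_shorter_than_skip(self):
        trace = _trace(_segments(10, 10))
        bs = detect_boundaries(trace, CalibConfig(window=1, skip_frames=100))
        assert bs.si_entry is None and bs.colon_entry is None

    def test_monotone_no_backward_transition(self):
        # colon -> SI flicker after colon entry must not move boundaries
        path = np.concatenate([_segments(50, 50, 30), np.full(5, 1), np.full(20, 2)])
        bs = detect_boundaries(_trace(path), CalibConfig(window=1, skip_frames=0))
        assert bs.si_entry[0] == 50
        assert bs.colon_entry[0] == 100

    def test_persistence_requires_sustained_run(self):
        path = _segments(50, 50).copy()
        path[20] = 1  # single-frame excursion
        bs = detect_boundaries(_trace(path), CalibConfig(window=1, skip_frames=0, persistence=3))
        assert bs.si_entry[0] == 50

    def test_order_invariant(self):
        bs = detect_boundaries(
            _trace(_segments(30, 40, 30)), CalibConfig(window=1, skip_frames=0)
        )
        assert bs.si_entry[0] < bs.colon_entry[0]

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000), rate=st.floats(0.01, 0.2))
    def test_smoothing_reduces_changepoints(self, seed, rate):
        """With i.i.d. label flips at rate <= 0.2, the number of argmax
        change points never increases after window-128 smoothing."""
        rng = np.random.default_rng(seed)
        path = _segments(400, 800, 300)
        flip = rng.random(path.size) < rate
        noisy = path.copy()
        noisy[flip] = (noisy[flip] + rng.integers(1, 3, int(flip.sum()))) % 3
        trace = _trace(noisy)
        before = int(np.count_nonzero(np.diff(trace.path)))
        after = int(np.count_nonzero(np.diff(smooth_trace(trace, CalibConfig(window=128)).path)))
        assert after <= before


class TestTransitTimes:
    def test_arithmetic(self):
        bs = BoundarySet(si_entry=(10, 600.0), colon_entry=(250, 15000.0))
        tt = compute_transit_times(bs, 0.0)
        assert tt.gastric_min == pytest.approx(10.0)
        assert tt.small_bowel_min == pytest.approx(240.0)
        assert not tt.gastric_alarm

    def test_one_hour_retention_alarm(self):
        tt = compute_transit_times(BoundarySet(si_entry=(5, 3660.0), colon_entry=None))
        assert tt.gastric_min == pytest.approx(61.0)
        assert tt.gastric_alarm

    def test_incomplete_study_no_small_bowel_time(self):
        tt = compute_transit_times(BoundarySet(si_entry=(5, 600.0), colon_entry=None))
        assert tt.small_bowel_min is None

    def test_missing_si_entry_status(self):
        tt = compute_transit_times(BoundarySet(si_entry=None, colon_entry=None))
        assert tt.status == "no_si_entry"
        assert tt.gastric_min is None


class TestSweep:
    def _val_data(self, n=3):
        traces, gts = [], []
        for i in range(n):
            path = _segments(80 + i, 200, 60)
            traces.append(_trace(path))
            gts.append(
                GroundTruth(si_entry_s=float(80 + i), colon_entry_s=float(280 + i))
            )
        return traces, gts

    _base = CalibConfig(window=1, skip_frames=0)

    def test_singleton_grid(self):
        traces, gts = self._val_data()
        best, table = sweep_calibration(traces, gts, [1], base_config=self._base)
        assert best.window == 1
        assert len(table) == 1

    def test_noiseless_small_window_wins(self):
        traces, gts = self._val_data()
        best, table = sweep_calibration(traces, gts, [16, 4, 1], base_config=self._base)
        assert best.window == 1
        assert table.loc[table["window"] == 1, "mean_abs_error_min"].iloc[0] == 0.0

    def test_tie_breaks_to_smaller_window(self):
        # both windows give zero error on a hard step trace
        traces, gts = self._val_data()
        best, _ = sweep_calibration(traces, gts, [2, 1], base_config=self._base)
        assert best.window == 1

    def test_empty_grid_rejected(self):
        traces, gts = self._val_data()
        with pytest.raises(ValueError):
            sweep_calibration(traces, gts, [], base_config=self._base)
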