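"""Trace processing: extraction, percentile detrend, baseline, 4-sigma detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinesync import synthgen, traces
from spinesync.errors import EstimationFailedError, InvalidConfigError, InvalidRoiError
from spinesync.roi import Roi
from spinesync.traces import (
    BaselineEstimate,
    DetrendParams,
    FluorescenceTrace,
    detect_transients,
    detrend,
    estimate_baseline,
    event_frequency,
    extract_trace,
    to_dff,
)


def _brute_force_detrend(v, frame_interval_s, params=DetrendParams()):
    w = int(round(params.half_window_s / frame_interval_s))
    return np.array(
        [
            v[t] - np.percentile(v[max(0, t - w) : min(len(v), t + w + 1)], params.percentile)
            for t in range(len(v))
        ]
    )


class TestTraceType:
    def test_rejects_nonfinite_and_bad_interval(self):
        with pytest.raises(InvalidConfigError):
            FluorescenceTrace(np.array([1.0, np.nan]), 0.242)
        with pytest.raises(InvalidConfigError):
            FluorescenceTrace(np.array([1.0]), 0.0)

    def test_times_are_frame_centers(self):
        tr = FluorescenceTrace(np.zeros(4), 0.5)
        assert np.allclose(tr.times_s, [0.25, 0.75, 1.25, 1.75])


class TestExtractTrace:
    def test_background_subtraction_arithmetic(self):
        stack = np.zeros((5, 4, 4))
        stack[:, :2, :] = 100.0
        stack[:, 2:, :] = 40.0
        roi = Roi.from_pixels("r", "soma", [(0, 0), (0, 1), (1, 0)])
        bg = Roi.from_pixels("b", "background", [(3, 0), (3, 1)])
        tr = extract_trace(stack, roi, bg)
        assert np.allclose(tr.values, 60.0)
        assert tr.state == "background_subtracted"

    def test_identical_roi_values_cancel(self):
        stack = np.tile(np.arange(6.0)[:, None, None], (1, 3, 3))
        roi = Roi.from_pixels("r", "soma", [(0, 0)])
        bg = Roi.from_pixels("b", "background", [(2, 2)])
        assert np.allclose(extract_trace(stack, roi, bg).values, 0.0)

    def test_overlapping_masks_rejected(self):
        stack = np.zeros((5, 3, 3))
        roi = Roi.from_pixels("r", "soma", [(0, 0), (1, 1)])
        bg = Roi.from_pixels("b", "background", [(1, 1)])
        with pytest.raises(InvalidRoiError):
            extract_trace(stack, roi, bg)

    def test_recovers_generator_signal(self):
        cfg = synthgen.SimulationConfig(
            seed=8, n_frames=400, noise_sd=0.0, drift_amplitude=0.0, rate_local_hz=0.05
        )
        spine, _, _ = synthgen.simulate_spine_recording(cfg)
        stack, masks, _ = synthgen.render_cell_stack(
            [spine], np.array([[50.0, 50.0]]), 100.0, fov_px=32, pixel_noise_sd=0.01, seed=1
        )
        roi = Roi.from_mask("r", "spine", masks[0])
        bg = Roi.from_mask("b", "background", ~masks[0])
        tr = extract_trace(stack, roi, bg, cfg.frame_interval_s)
        assert np.corrcoef(tr.values, spine.values)[0, 1] > 0.99


class TestDetrend:
    def test_constant_trace_maps_to_zero(self):
        tr = FluorescenceTrace(np.full(500, 7.3), 0.242)
        assert np.allclose(detrend(tr).values, 0.0)

    def test_matches_brute_force_exactly(self, rng):
        """The windowed implementation equals naive per-frame recomputation."""
        for _ in range(5):
            v = rng.normal(0, 1, 700) + np.sin(np.linspace(0, 5, 700))
            tr = FluorescenceTrace(v, 0.242)
            assert np.array_equal(detrend(tr).values, _brute_force_detrend(v, 0.242))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(5, 400),
        dt=st.sampled_from([0.1, 0.242, 0.39, 2.0, 40.0]),
    )
    def test_brute_force_equivalence_property(self, seed, n, dt):
        """Exact oracle equivalence across lengths, including short traces."""
        v = np.random.default_rng(seed).normal(0, 1, n)
        tr = FluorescenceTrace(v, dt)
        assert np.array_equal(detrend(tr).values, _brute_force_detrend(v, dt))

    def test_removes_ramp_preserves_spike(self):
        n, dt = 1000, 0.242
        v = np.linspace(0, 2.0, n).copy()
        v[500] += 1.0
        out = detrend(FluorescenceTrace(v, dt)).values
        spike = out[500] - np.median(out[480:499])
        assert abs(spike - 1.0) < 0.05
        # away from the spike, the ramp reduces to the constant window offset
        body = out[100:400]
        assert np.ptp(body) < 0.01

    def test_idempotent_on_flat_baseline_events(self):
        v = np.zeros(800)
        v[100] = v[400] = 1.0
        tr = FluorescenceTrace(v, 0.242)
        once = detrend(tr)
        twice = detrend(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-9


class TestBaseline:
    def test_gaussian_noise_sigma_recovered(self, rng):
        v = rng.normal(5.0, 1.0, 3000)
        est = estimate_baseline(FluorescenceTrace(v, 0.242, state="detrended"))
        assert 0.9 <= est.sigma <= 1.1
        assert abs(est.mu - 5.0) < 0.1

    def test_zero_noise_flat_trace_with_events(self):
        v = np.zeros(100)
        v[10:13] = 1.0
        est = estimate_baseline(FluorescenceTrace(v, 0.242))
        assert est.sigma == 0.0
        ev = detect_transients(FluorescenceTrace(v, 0.242), est)
        assert len(ev) == 1 and ev[0].onset_frame == 10 and ev[0].offset_frame == 12

    def test_one_long_transient_fails(self):
        v = np.linspace(0, 50, 100) ** 2  # monotone explosion, no quiet region
        with pytest.raises(EstimationFailedError):
            estimate_baseline(FluorescenceTrace(v, 0.242), clip_k=0.1, max_iter=50)


class TestDetect:
    def test_flat_trace_no_events(self):
        tr = FluorescenceTrace(np.zeros(50), 0.242)
        base = BaselineEstimate(0.0, 1.0, np.ones(50, bool))
        assert detect_transients(tr, base) == []

    def test_rectangular_pulse_bounds(self):
        v = np.zeros(30)
        v[10:15] = 6.0
        tr = FluorescenceTrace(v, 0.242)
        base = BaselineEstimate(0.0, 1.0, np.ones(30, bool))
        (ev,) = detect_transients(tr, base)
        assert (ev.onset_frame, ev.peak_frame, ev.offset_frame) == (10, 10, 14)
        assert ev.peak_value == 6.0

    def test_merge_gap_joins_nearby_runs(self):
        v = np.zeros(30)
        v[5:8] = 6.0
        v[9:12] = 5.0
        tr = FluorescenceTrace(v, 0.242)
        base = BaselineEstimate(0.0, 1.0, np.ones(30, bool))
        assert len(detect_transients(tr, base, merge_gap=1)) == 2
        (ev,) = detect_transients(tr, base, merge_gap=2)
        assert (ev.onset_frame, ev.offset_frame) == (5, 11)

    def test_raising_threshold_shrinks_detections(self, rng):
        """Higher k_sigma flags a subset of frames; events nest inside
        lower-threshold events (a run may split, but never grow)."""
        v = rng.normal(0, 1, 2000)
        v[200:205] += 8
        v[900:903] += 5
        tr = FluorescenceTrace(v, 0.242)
        base = estimate_baseline(tr)

        def frames(k):
            out = set()
            for e in detect_transients(tr, base, k_sigma=k):
                out |= set(range(e.onset_frame, e.offset_frame + 1))
            return out

        prev = frames(2)
        for k in (3, 4, 5, 6):
            cur = frames(k)
            assert cur <= prev
            prev = cur

    def test_noise_exceedance_matches_gaussian_tail(self, rng):
        """Per-frame 4-sigma exceedance rate on pure noise ~ normal tail mass."""
        n = 200_000
        v = rng.normal(0.0, 1.0, n)
        tr = FluorescenceTrace(v, 0.242)
        base = estimate_baseline(tr)
        thr = base.mu + 4 * base.sigma
        count = int((v > thr).sum())
        from scipy.stats import norm

        p = norm.sf(4.0)
        assert abs(count - n * p) <= 5 * np.sqrt(n * p)


class TestDffAndFrequency:
    def test_dff_normalization(self):
        tr = FluorescenceTrace(np.array([10.0, 20.0, 10.0]), 0.242, state="detrended")
        base = BaselineEstimate(10.0, 0.5, np.ones(3, bool))
        out = to_dff(tr, base)
        assert np.allclose(out.values, [0.0, 1.0, 0.0])
        assert out.state == "dff"

    def test_dff_nonpositive_baseline_warns_and_passes_through(self):
        tr = FluorescenceTrace(np.array([1.0, 2.0]), 0.242, state="detrended")
        base = BaselineEstimate(0.0, 0.5, np.ones(2, bool))
        with pytest.warns(RuntimeWarning):
            out = to_dff(tr, base)
        assert np.array_equal(out.values, tr.values)

    def test_event_frequency(self):
        assert event_frequency([], 100.0) == 0.0
        assert event_frequency(list(range(12)), 600.0) == pytest.approx(0.020)
        with pytest.raises(InvalidConfigError):
            event_frequency([], 0.0)
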