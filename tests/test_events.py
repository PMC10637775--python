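"""Trace conditioning and event calling: smoothing, support line, detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from casyn.events import (
    EventDetectionParams,
    detect_events,
    detrend,
    fit_support_line,
    smooth_trace,
)
from oracles import support_line_bruteforce

FP = 0.328


def _poly(coeffs, n):
    return np.polynomial.polynomial.polyval(np.arange(n, dtype=float), coeffs)


class TestSmoothTrace:
    def test_dc_preserved(self):
        out = smooth_trace(np.full(200, 7.5), cutoff_hz=0.5, frame_period_s=FP)
        assert np.allclose(out, 7.5)

    def test_fast_sinusoid_attenuated(self):
        # component at 2x the cutoff should lose >= 90 % amplitude
        t = np.arange(2000) * FP
        x = np.sin(2 * np.pi * 1.0 * t)
        out = smooth_trace(x, cutoff_hz=0.5, frame_period_s=FP)
        assert np.max(np.abs(out[100:-100])) < 0.35 * np.max(np.abs(x))

    def test_slow_ramp_unchanged(self):
        x = np.linspace(0.0, 10.0, 3000)
        out = smooth_trace(x, cutoff_hz=0.5, frame_period_s=FP)
        core = slice(100, -100)
        assert np.allclose(out[core], x[core], rtol=0.01, atol=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(100), cutoff_hz=2.0, frame_period_s=FP)


class TestSupportLine:
    def test_constant_series_self_envelope(self):
        sl = fit_support_line(np.full(50, 3.0))
        assert np.allclose(sl.values, 3.0, atol=1e-7)
        assert sl.objective == pytest.approx(0.0, abs=1e-6)

    def test_exact_cubic_recovered(self):
        coeffs = np.array([5.0, 0.01, -1e-4, 1e-7])
        y = _poly(coeffs, 60)
        sl = fit_support_line(y)
        assert np.allclose(sl.values, y, atol=1e-6)
        assert np.allclose(sl.coeffs, coeffs, atol=1e-6)

    def test_bump_on_line_ignored(self):
        # positive bump on a line: the envelope is the line itself
        n = 60
        y = 2.0 + 0.05 * np.arange(n)
        y[25:30] += 4.0
        sl = fit_support_line(y)
        expect = 2.0 + 0.05 * np.arange(n)
        assert np.allclose(sl.values, expect, atol=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            y = rng.normal(0, 1, n) + rng.normal(0, 0.5) * np.linspace(0, 1, n)
            sl = fit_support_line(y)
            obj_bf, _ = support_line_bruteforce(y)
            assert sl.objective == pytest.approx(obj_bf, abs=1e-6)
            assert np.all(sl.values <= y + 1e-9)

    def test_exclusion_window_not_constrained(self):
        # a huge terminal transient must not push the envelope up
        y = np.zeros(100)
        y[80:] = 50.0
        sl = fit_support_line(y, exclude=(80, 100))
        assert np.all(np.abs(sl.values[:80]) < 1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_support_line(np.zeros(7))

    @given(st.integers(0, 2**31 - 1))
    def test_cubic_equivariance(self, seed):
        # fit(y + q) == fit(y) + q for any cubic q
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 50))
        y = r.normal(0, 1, n)
        q = r.normal(0, 1, 4) / (n ** np.arange(4))
        sl0 = fit_support_line(y)
        sl1 = fit_support_line(y + _poly(q, n))
        assert np.allclose(sl1.coeffs, sl0.coeffs + q, atol=1e-8)


class TestDetrend:
    def test_detrend_of_support_line_is_zero(self):
        y = _poly([1.0, 0.02, 0.0, 0.0], 50)
        sl = fit_support_line(y)
        dt = detrend(y, sl, FP)
        assert np.allclose(dt.filtered, 0.0, atol=1e-7)
        assert dt.baseline_level == pytest.approx(0.0, abs=1e-7)

    def test_envelope_property(self, rng):
        y = rng.normal(0, 1, 80)
        sl = fit_support_line(y)
        dt = detrend(y, sl, FP)
        assert np.all(dt.filtered >= -1e-9)

    def test_baseline_sd_positive_for_noisy_trace(self, rng):
        y = rng.normal(10, 2, 300)
        dt = detrend(y, fit_support_line(y), FP)
        assert dt.baseline_sd > 0


def _transient(n, peak_frame, amp_sd, sd=1.0, width=2):
    y = np.zeros(n)
    y[peak_frame - width + 1 : peak_frame + 1] = amp_sd * sd * np.linspace(0.4, 1.0, width)
    y[peak_frame + 1 : peak_frame + width + 1] = amp_sd * sd * np.linspace(0.8, 0.2, width)
    return y


class TestDetectEvents:
    def _detrended(self, y, exclude=None):
        return detrend(y, fit_support_line(y, exclude=exclude), FP, kcl_window=exclude)

    def test_single_transient_detected_with_amplitude(self, rng):
        y = rng.normal(0, 1.0, 400)
        dt0 = self._detrended(y)
        y2 = y + _transient(400, 200, 5.0, dt0.baseline_sd)
        dt = self._detrended(y2)
        events = detect_events(dt)
        assert len(events) == 1
        assert abs(events[0].peak - 200) <= 1  # noise can shift the argmax
        assert events[0].amplitude_sd == pytest.approx(5.0, abs=1.5)

    def test_subthreshold_transient_ignored(self, rng):
        y = rng.normal(0, 1.0, 400) * 0.001  # near-silent baseline
        dt0 = self._detrended(y)
        y2 = y + _transient(400, 200, 2.0, dt0.baseline_sd)
        events = detect_events(self._detrended(y2), EventDetectionParams(threshold_sd=3.0))
        assert events == []

    def test_event_fields_consistent(self, rng):
        y = rng.normal(0, 1.0, 500)
        y += _transient(500, 100, 8.0) + _transient(500, 300, 6.0)
        events = detect_events(self._detrended(y))
        for ev in events:
            assert ev.onset <= ev.peak <= ev.offset
            assert ev.amplitude_sd >= 3.0
            assert ev.duration_s == pytest.approx((ev.offset - ev.onset + 1) * FP)

    def test_kcl_window_excluded_from_calling(self, rng):
        y = rng.normal(0, 1.0, 500)
        y[450:] += 30.0
        dt = self._detrended(y, exclude=(450, 500))
        events = detect_events(dt)
        assert all(ev.peak < 450 for ev in events)

    def test_all_nan_rejected(self):
        from casyn.events import DetrendedTrace

        dt = DetrendedTrace(filtered=np.full(50, np.nan), baseline_sd=1.0, frame_period_s=FP)
        with pytest.raises(ValueError):
            detect_events(dt)

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        # raising k never increases the event count
        r = np.random.default_rng(seed)
        y = r.normal(0, 1, 300)
        y[r.integers(20, 280, size=5)] += 8.0
        dt = self._detrended(y)
        counts = [
            len(detect_events(dt, EventDetectionParams(threshold_sd=k)))
            for k in (2.0, 3.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_cubic_drift_does_not_move_peaks(self, rng, peak_matcher):
        n = 600
        y = rng.normal(0, 1.0, n)
        for f in (100, 250, 400, 500):
            y += _transient(n, f, 7.0)
        drift = _poly([3.0, 0.05, -1e-4, 8e-8], n)
        ev0 = detect_events(self._detrended(y))
        ev1 = detect_events(self._detrended(y + drift))
        p0 = [e.peak for e in ev0]
        p1 = [e.peak for e in ev1]
        assert peak_matcher(p1, p0, tol=1) == len(p0)
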