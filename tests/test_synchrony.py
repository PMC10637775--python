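"""Population PCA, SE detection, participation windows, bursts, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from casyn.synchrony import (
    EventRaster,
    SynchronyParams,
    classify_async,
    detect_bursts,
    detect_ses,
    participation,
    population_pca,
    select_se_component,
    summarize_movie,
)
from oracles import participation_bruteforce, sync_async_bruteforce

FP = 0.328


def _raster(matrix):
    return EventRaster(np.asarray(matrix, dtype=bool), FP)


class TestPopulationPca:
    def test_shared_transient_dominates(self, rng):
        tc = np.zeros(200)
        tc[50:60] = 10.0
        x = np.tile(tc, (20, 1)) + rng.normal(0, 0.01, (20, 200))
        pc = population_pca(x)
        assert pc.variance_fractions[0] > 0.99

    def test_loadings_orthonormal(self, rng):
        x = rng.normal(0, 1, (15, 100))
        pc = population_pca(x)
        gram = pc.loadings.T @ pc.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_sign_convention_under_negation(self, rng):
        x = rng.normal(0, 1, (10, 80)) + 5.0 * (rng.random((10, 80)) < 0.02)
        a = population_pca(x)
        b = population_pca(-x)
        assert np.allclose(a.time_courses[:3], b.time_courses[:3], atol=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            population_pca(np.ones((5, 50)))


class TestSelectSeComponent:
    def test_single_candidate(self, rng):
        x = rng.normal(0, 1, (8, 60))
        pc = population_pca(x)
        raster = _raster(rng.random((8, 60)) < 0.05)
        idx, conf, low = select_se_component(pc, raster, n_candidates=1)
        assert idx == 0

    def test_global_ses_found_with_high_confidence(self, rng):
        n_cells, n_frames = 40, 800
        m = np.zeros((n_cells, n_frames), dtype=bool)
        x = rng.normal(0, 1.0, (n_cells, n_frames))
        transient = np.array([3.0, 8.0, 6.0, 3.5, 1.5])  # fast rise, ~1 s decay
        for f in range(80, 800, 90):
            part = rng.choice(n_cells, 28, replace=False)
            m[part, f] = True
            x[part, f - 1 : f + 4] += transient
        pc = population_pca(x)
        idx, conf, low = select_se_component(pc, _raster(m), n_candidates=3)
        assert idx in (0, 1)
        assert conf > 0.8
        assert not low

    def test_pure_async_low_confidence(self, rng):
        n_cells, n_frames = 100, 800
        x = rng.normal(0, 1.0, (n_cells, n_frames))
        m = np.zeros((n_cells, n_frames), dtype=bool)
        for c in range(n_cells):
            for f in rng.integers(5, n_frames - 5, size=5):
                x[c, f] += 8.0
                m[c, f] = True
        pc = population_pca(x)
        _, conf, low = select_se_component(pc, _raster(m), n_candidates=3)
        assert low
        assert conf < 0.2


class TestDetectSes:
    def test_constructed_three_peaks(self, rng):
        n = 300
        trace = rng.normal(0, 0.5, n) * 0.1
        m = np.zeros((10, n), dtype=bool)
        for f in (50, 150, 250):
            trace[f] = 10.0
            trace[f - 1] = 5.0
            trace[f + 1] = 5.0
            m[:, f] = True
        ses = detect_ses(trace, EventRaster(m, FP))
        assert [s.peak_frame for s in ses] == [50, 150, 250]

    def test_flat_trace_no_ses(self):
        m = np.zeros((5, 100), dtype=bool)
        assert detect_ses(np.zeros(100), EventRaster(m, FP)) == []

    def test_low_participation_peak_rejected(self, rng):
        n = 200
        trace = rng.normal(0, 0.1, n) * 0.1
        trace[100] = 10.0
        m = np.zeros((20, n), dtype=bool)
        m[0, 100] = True  # only 5 % of cells participate
        assert detect_ses(trace, EventRaster(m, FP)) == []


class TestParticipation:
    def test_window_is_three_frames_at_default_period(self):
        assert SynchronyParams().window_frames(0.328) == 3

    def test_all_cells_at_peak(self):
        m = np.zeros((6, 50), dtype=bool)
        m[:, 25] = True
        part, frac = participation(_raster(m), 25)
        assert frac == 1.0
        assert np.array_equal(part, np.arange(6))

    def test_matches_bruteforce_scan(self, rng):
        m = rng.random((5, 60)) < 0.08
        raster = _raster(m)
        for peak in (5, 30, 55):
            part, _ = participation(raster, peak)
            expect = participation_bruteforce(m, peak, 3)
            assert np.array_equal(part, expect)

    @given(st.integers(0, 2**31 - 1))
    def test_window_monotonicity(self, seed):
        # widening the window never loses participants
        r = np.random.default_rng(seed)
        m = r.random((8, 80)) < 0.1
        raster = _raster(m)
        sizes = []
        for w_s in (0.328, 0.984, 1.968):
            part, _ = participation(raster, 40, SynchronyParams(participation_window_s=w_s))
            sizes.append(part.size)
        assert sizes == sorted(sizes)


class TestClassifyAsync:
    def test_event_at_se_peak_is_sync(self):
        from casyn.synchrony import SyncEvent

        se = SyncEvent(peak_frame=40, participants=np.array([0]), fraction=0.1, pc_amplitude=5.0)
        assert classify_async(np.array([40]), [se], FP) == (1, 0)

    def test_far_event_is_async(self):
        from casyn.synchrony import SyncEvent

        se = SyncEvent(peak_frame=40, participants=np.array([0]), fraction=0.1, pc_amplitude=5.0)
        assert classify_async(np.array([50]), [se], FP) == (0, 1)

    @given(st.integers(0, 2**31 - 1))
    def test_partition_matches_bruteforce_and_conserves(self, seed):
        from casyn.synchrony import SyncEvent

        r = np.random.default_rng(seed)
        peaks = r.integers(0, 200, size=30)
        se_peaks = r.integers(0, 200, size=4)
        ses = [
            SyncEvent(peak_frame=int(f), participants=np.array([]), fraction=0.5, pc_amplitude=4.0)
            for f in se_peaks
        ]
        n_sync, n_async = classify_async(peaks, ses, FP)
        assert (n_sync, n_async) == sync_async_bruteforce(peaks, se_peaks, 3)
        assert n_sync + n_async == 30


def _se(frame):
    from casyn.synchrony import SyncEvent

    return SyncEvent(peak_frame=frame, participants=np.arange(5), fraction=0.5, pc_amplitude=5.0)


def _peaky_trace(n, peaks, valley_floor=0.0):
    t = np.zeros(n)
    for p in peaks:
        t[p - 2 : p + 3] = [3.0, 6.0, 10.0, 6.0, 3.0]
    return t


class TestDetectBursts:
    def test_separated_peaks_no_burst(self):
        trace = _peaky_trace(300, [50, 250])
        bursts, pct = detect_bursts(trace, [_se(50), _se(250)])
        assert bursts == []
        assert pct == 0.0

    def test_merged_pair_one_burst(self):
        trace = _peaky_trace(300, [100, 120])
        trace[100:121] = np.maximum(trace[100:121], 5.0)  # valley stays high
        bursts, pct = detect_bursts(trace, [_se(100), _se(120)])
        assert len(bursts) == 1
        assert bursts[0].members == (0, 1)
        assert pct == 100.0

    def test_five_ses_one_merged_pair_gives_40pct(self):
        peaks = [40, 100, 160, 220, 280]
        trace = _peaky_trace(400, peaks)
        trace[220:281] = np.maximum(trace[220:281], 5.0)  # chain SEs 3 and 4
        ses = [_se(p) for p in peaks]
        bursts, pct = detect_bursts(trace, ses)
        assert len(bursts) == 1
        assert bursts[0].members == (3, 4)
        assert pct == pytest.approx(40.0)

    def test_fewer_than_two_ses(self):
        bursts, pct = detect_bursts(np.zeros(100), [_se(50)])
        assert bursts == [] and pct == 0.0


class TestSummarizeMovie:
    def test_rate_arithmetic(self):
        m = np.zeros((4, 100), dtype=bool)
        ses = [_se(f) for f in (10, 20, 30, 40, 50, 60)]
        s = summarize_movie(_raster(m), ses, [], duration_s=180.0)
        assert s.n_se == 6
        assert s.se_per_min == pytest.approx(2.0)

    def test_silent_movie_all_zero(self):
        m = np.zeros((4, 100), dtype=bool)
        s = summarize_movie(_raster(m), [], [], duration_s=60.0)
        assert s.total_events == 0
        assert s.pct_active_cells == 0.0
        assert s.pct_cells_per_se == 0.0
        assert s.pct_se_in_bursts == 0.0

    def test_sync_async_conservation(self, rng):
        m = rng.random((10, 200)) < 0.05
        raster = _raster(m)
        ses = [_se(f) for f in (50, 120)]
        s = summarize_movie(raster, ses, [], duration_s=60.0)
        assert s.n_sync_events + s.n_async_events == s.total_events

    def test_shift_invariance(self, rng):
        # shifting every event and SE peak by a constant leaves summaries alone
        m = np.zeros((8, 300), dtype=bool)
        base = rng.random((8, 200)) < 0.05
        m[:, 20:220] = base
        ses = [_se(60), _se(140)]
        s1 = summarize_movie(_raster(m), ses, [], duration_s=98.4)
        shift = 40
        m2 = np.zeros_like(m)
        m2[:, 20 + shift : 220 + shift] = base
        ses2 = [_se(60 + shift), _se(140 + shift)]
        s2 = summarize_movie(_raster(m2), ses2, [], duration_s=98.4)
        assert s1 == s2

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            summarize_movie(_raster(np.zeros((2, 10), dtype=bool)), [], [], duration_s=0.0)
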