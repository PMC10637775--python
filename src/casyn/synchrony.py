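"""Population synchrony: synchronous events, bursts and per-movie summaries.

The immature hippocampal network fires in population-wide synchronous events
(SEs).  Because SEs are strongly correlated across cells they dominate the
leading principal components of the detrended population activity: SEs are
detected as supra-threshold local maxima of the selected PC time course, each
cell's participation is scored by whether it has an event peak within +/-984 ms
of the SE peak, and runs of SEs between which the PC trace does not return to
baseline are grouped into bursts (the dominant firing mode at P5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from casyn.events import CalciumEvent

__all__ = [
    "SynchronyParams",
    "EventRaster",
    "PopulationComponents",
    "SyncEvent",
    "Burst",
    "MovieSummary",
    "population_pca",
    "select_se_component",
    "detect_ses",
    "participation",
    "classify_async",
    "detect_bursts",
    "summarize_movie",
]


@dataclass(frozen=True)
class SynchronyParams:
    """Windows and thresholds for SE/burst detection.

    ``participation_window_s`` is the half-window around an SE peak within
    which a cell's event counts as participating (984 ms = exactly 3 frames at
    the 0.328 s frame period).  ``se_threshold_sd`` thresholds PC-trace local
    maxima in robust SDs; a supra-threshold peak only counts as an SE if at
    least ``min_se_participation`` of the viable cells have events in its
    window (the automated analogue of corroborating PC peaks against the
    raster).  ``burst_baseline_eps_sd`` sets how far above the PC baseline
    (10th percentile) the inter-SE valley must stay for two SEs to belong to
    one burst.
    """

    participation_window_s: float = 0.984
    n_pc_candidates: int = 3
    se_threshold_sd: float = 3.0
    min_se_participation: float = 0.2
    burst_baseline_eps_sd: float = 0.5
    low_confidence_corr: float = 0.2

    def __post_init__(self) -> None:
        if self.participation_window_s <= 0:
            raise ValueError("participation window must be positive")

    def window_frames(self, frame_period_s: float) -> int:
        return int(round(self.participation_window_s / frame_period_s))


@dataclass
class EventRaster:
    """Boolean cells x frames matrix with True at event peak frames.

    Rows are restricted to retained (viable, non-glia) cells; ``cell_ids``
    keeps the original indexing for bookkeeping.
    """

    matrix: np.ndarray
    frame_period_s: float
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=bool))
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.matrix.shape[0])
        self.cell_ids = np.asarray(self.cell_ids)

    @classmethod
    def from_events(
        cls,
        events_per_cell: list[list[CalciumEvent]],
        n_frames: int,
        frame_period_s: float,
        cell_ids: np.ndarray | None = None,
    ) -> "EventRaster":
        m = np.zeros((len(events_per_cell), n_frames), dtype=bool)
        for i, events in enumerate(events_per_cell):
            for ev in events:
                m[i, ev.peak] = True
        return cls(m, frame_period_s, cell_ids)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def event_counts(self) -> np.ndarray:
        """Number of event peaks per frame across the population."""
        return self.matrix.sum(axis=0)


@dataclass(frozen=True)
class PopulationComponents:
    """PCA of population activity: orthonormal loadings, oriented time courses."""

    loadings: np.ndarray  # cells x k, columns orthonormal
    time_courses: np.ndarray  # k x frames
    variance_fractions: np.ndarray  # (k,)


@dataclass(frozen=True)
class SyncEvent:
    peak_frame: int
    participants: np.ndarray  # row indices into the raster
    fraction: float  # |participants| / |viable|
    pc_amplitude: float


@dataclass(frozen=True)
class Burst:
    members: tuple[int, ...]  # indices into the SE list, consecutive
    start_frame: int
    end_frame: int


@dataclass(frozen=True)
class MovieSummary:
    """Per-movie network-activity metrics (the Fig-style readouts)."""

    n_se: int
    se_per_min: float
    total_events: int
    pct_cells_per_se: float
    pct_active_cells: float
    pct_se_in_bursts: float
    n_sync_events: int
    n_async_events: int


def population_pca(detrended: np.ndarray) -> PopulationComponents:
    """PCA of the cell-mean-centered detrended matrix (cells x frames).

    Loadings are orthonormal over cells; each time course carries the
    component amplitude and is sign-flipped so its skewness is non-negative
    (calcium transients are positive-going).
    """
    x = np.atleast_2d(np.asarray(detrended, dtype=float))
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 cells and >= 2 frames")
    xc = x - x.mean(axis=1, keepdims=True)
    total_var = float(np.sum(xc**2))
    if total_var <= 1e-12:
        raise ValueError("zero-variance population matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tc = s[:, None] * vt
    centered = tc - tc.mean(axis=1, keepdims=True)
    skew = np.mean(centered**3, axis=1)
    flip = skew < 0
    tc[flip] *= -1.0
    u[:, flip] *= -1.0
    return PopulationComponents(
        loadings=u, time_courses=tc, variance_fractions=s**2 / (s**2).sum()
    )


def select_se_component(
    pc: PopulationComponents,
    raster: EventRaster,
    n_candidates: int = 3,
    params: SynchronyParams | None = None,
) -> tuple[int, float, bool]:
    """Pick the SE-carrying component among the leading PCs.

    Returns (index, confidence, low_confidence): the candidate whose time
    course best correlates with the per-frame population event count (the
    automated stand-in for matching rasters to PC traces by eye).  Because the
    PC time course is itself a sum of calcium transients, the counts are first
    convolved with a causal calcium-shaped kernel (1 s decay) — a matched
    filter that removes the width mismatch between single-frame event peaks
    and multi-frame transients.  Confidence below ``low_confidence_corr``
    flags a movie without clear synchrony.
    """
    if params is None:
        params = SynchronyParams()
    k = pc.time_courses.shape[0]
    n_candidates = min(n_candidates, k)
    counts = raster.event_counts().astype(float)
    decay_frames = max(1.0, 1.0 / raster.frame_period_s)
    kern = np.exp(-np.arange(int(4 * decay_frames) + 1) / decay_frames)
    counts = np.convolve(counts, kern)[: counts.size]
    n = min(counts.size, pc.time_courses.shape[1])
    counts = counts[:n]
    best_i, best_r = 0, -np.inf
    for i in range(n_candidates):
        tc = pc.time_courses[i][:n]
        if np.std(tc) == 0 or np.std(counts) == 0:
            r = 0.0
        else:
            r = float(pearsonr(tc, counts)[0])
        if r > best_r:
            best_i, best_r = i, r
    if not np.isfinite(best_r):
        best_r = 0.0
    return best_i, best_r, best_r < params.low_confidence_corr


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    sd = 1.4826 * float(np.median(np.abs(x - med)))
    return sd if sd > 0 else float(np.std(x))


def detect_ses(
    pc_trace: np.ndarray, raster: EventRaster, params: SynchronyParams | None = None
) -> list[SyncEvent]:
    """SEs = local maxima of the PC trace >= threshold x its robust SD.

    Peaks closer than one participation window are merged (highest wins) so a
    jittered SE is not double-counted, and peaks in whose window fewer than
    ``min_se_participation`` of the viable cells have events are rejected
    (coincident asynchronous activity, not a population event).  Each SE's
    participants and fraction come from :func:`participation`.
    """
    if params is None:
        params = SynchronyParams()
    trace = np.asarray(pc_trace, dtype=float)
    sd = _robust_sd(trace)
    if sd <= 0:
        return []
    height = params.se_threshold_sd * sd
    w = params.window_frames(raster.frame_period_s)
    peaks, _ = find_peaks(trace, height=height, distance=max(1, w))
    ses = []
    for pk in peaks:
        part, frac = participation(raster, int(pk), params)
        if frac < params.min_se_participation:
            continue
        ses.append(
            SyncEvent(
                peak_frame=int(pk),
                participants=part,
                fraction=frac,
                pc_amplitude=float(trace[pk] / sd),
            )
        )
    return ses


def participation(
    raster: EventRaster, se_peak: int, params: SynchronyParams | None = None
) -> tuple[np.ndarray, float]:
    """Cells with an event peak within the +/-984 ms window around an SE peak.

    The fraction uses the viable-cell denominator (all raster rows).
    """
    if params is None:
        params = SynchronyParams()
    if not 0 <= se_peak < raster.n_frames:
        raise ValueError("SE peak outside movie")
    w = params.window_frames(raster.frame_period_s)
    lo = max(0, se_peak - w)
    hi = min(raster.n_frames, se_peak + w + 1)
    rows = np.flatnonzero(raster.matrix[:, lo:hi].any(axis=1))
    return rows, float(rows.size / raster.n_cells)


def classify_async(
    event_peaks: np.ndarray,
    ses: list[SyncEvent],
    frame_period_s: float,
    params: SynchronyParams | None = None,
) -> tuple[int, int]:
    """Partition event peaks into synchronous and asynchronous counts.

    An event is synchronous iff its peak falls within the participation window
    of at least one SE; asynchronous events are all the rest, so the two
    counts always sum to the total.
    """
    if params is None:
        params = SynchronyParams()
    peaks = np.asarray(event_peaks, dtype=int)
    if peaks.size == 0:
        return 0, 0
    w = params.window_frames(frame_period_s)
    sync = np.zeros(peaks.size, dtype=bool)
    for se in ses:
        sync |= np.abs(peaks - se.peak_frame) <= w
    n_sync = int(sync.sum())
    return n_sync, int(peaks.size - n_sync)


def detect_bursts(
    pc_trace: np.ndarray, ses: list[SyncEvent], params: SynchronyParams | None = None
) -> tuple[list[Burst], float]:
    """Group SEs whose inter-peak PC trace never returns to baseline.

    Baseline is the 10th percentile of the PC trace; consecutive SEs are
    chained iff the valley between their peaks stays above baseline +
    ``burst_baseline_eps_sd`` robust SDs.  Bursts are maximal chains of >= 2
    SEs; also returns the percentage of all SEs occurring within bursts.
    """
    if params is None:
        params = SynchronyParams()
    if len(ses) < 2:
        return [], 0.0
    trace = np.asarray(pc_trace, dtype=float)
    baseline = float(np.percentile(trace, 10.0))
    floor = baseline + params.burst_baseline_eps_sd * _robust_sd(trace)
    order = np.argsort([se.peak_frame for se in ses])
    chained = []
    for a, b in zip(order[:-1], order[1:]):
        lo, hi = ses[a].peak_frame, ses[b].peak_frame
        valley = float(trace[lo : hi + 1].min())
        chained.append(valley > floor)
    bursts: list[Burst] = []
    i = 0
    while i < len(order):
        j = i
        while j < len(chained) and chained[j]:
            j += 1
        if j > i:
            members = tuple(int(k) for k in order[i : j + 1])
            bursts.append(
                Burst(
                    members=members,
                    start_frame=ses[members[0]].peak_frame,
                    end_frame=ses[members[-1]].peak_frame,
                )
            )
        i = j + 1
    n_in = sum(len(b.members) for b in bursts)
    return bursts, 100.0 * n_in / len(ses)


def summarize_movie(
    raster: EventRaster,
    ses: list[SyncEvent],
    bursts: list[Burst],
    duration_s: float,
    params: SynchronyParams | None = None,
) -> MovieSummary:
    """Per-movie readouts: SE count/rate, total events, participation, activity.

    ``total_events`` counts all event peaks of retained cells;
    ``pct_cells_per_se`` is the mean SE participation in percent of viable
    cells; ``pct_active_cells`` the percentage of viable cells with at least
    one event.  Sync/async counts (conserving the total) are included because
    conventions for "total events" differ.
    """
    if duration_s <= 0:
        raise ValueError("movie duration must be positive")
    total = int(raster.matrix.sum())
    peaks = np.flatnonzero(raster.matrix.any(axis=0))
    all_peaks = [f for row in raster.matrix for f in np.flatnonzero(row)]
    n_sync, n_async = classify_async(
        np.asarray(all_peaks, dtype=int), ses, raster.frame_period_s, params
    )
    n_in_bursts = sum(len(b.members) for b in bursts)
    return MovieSummary(
        n_se=len(ses),
        se_per_min=len(ses) / (duration_s / 60.0),
        total_events=total,
        pct_cells_per_se=100.0 * float(np.mean([se.fraction for se in ses])) if ses else 0.0,
        pct_active_cells=100.0 * float(raster.matrix.any(axis=1).mean()) if raster.n_cells else 0.0,
        pct_se_in_bursts=100.0 * n_in_bursts / len(ses) if ses else 0.0,
        n_sync_events=n_sync,
        n_async_events=n_async,
    )
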