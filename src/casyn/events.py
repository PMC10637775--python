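"""Per-cell trace conditioning and calcium-event detection.

Fluorescence traces from developing-slice movies ride on a slowly decaying
photobleaching baseline.  The pipeline here removes that drift by fitting a
cubic *support line* — the cubic curve lying entirely beneath the smoothed
trace whose total distance to it is minimal — and then calls calcium events as
excursions of the detrended trace above a multiple of the baseline noise SD
(the SD of resting fluorescence F0).  A terminal KCl depolarization window,
used only to certify cell viability, is excluded from both the support-line
fit and event calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.signal import butter, filtfilt

__all__ = [
    "EventDetectionParams",
    "SupportLine",
    "DetrendedTrace",
    "CalciumEvent",
    "smooth_trace",
    "fit_support_line",
    "detrend",
    "detect_events",
]

#: degree of the support-line polynomial (cubic)
_SL_DEGREE = 3


@dataclass(frozen=True)
class EventDetectionParams:
    """Parameters for trace smoothing and SD-threshold event calling.

    Attributes
    ----------
    smoothing_cutoff_hz : float
        High-frequency cutoff of the zero-phase low-pass applied before the
        support-line fit.  Must be below Nyquist.
    threshold_sd : float
        Event threshold ``k`` in multiples of the baseline-fluorescence SD
        (default 3, i.e. events are excursions >= 3 x SD of F0).
    kcl_window : tuple[int, int] | None
        Half-open frame range ``[start, stop)`` of the terminal KCl
        depolarization; excluded from the support-line fit, the baseline-SD
        estimate and event calling.
    """

    smoothing_cutoff_hz: float = 0.5
    threshold_sd: float = 3.0
    kcl_window: tuple[int, int] | None = None
    merge_gap_frames: int = 1

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")
        if self.smoothing_cutoff_hz <= 0:
            raise ValueError("smoothing_cutoff_hz must be > 0")


@dataclass(frozen=True)
class SupportLine:
    """Cubic lower envelope of a smoothed trace.

    ``coeffs`` are ascending-power cubic coefficients over the *frame index*
    ``t`` (so ``p(t) = c0 + c1 t + c2 t^2 + c3 t^3``); ``values`` are ``p(t)``
    evaluated at every frame; ``excluded`` is the half-open frame range left
    out of the fit (the KCl window), or None.
    """

    coeffs: np.ndarray
    values: np.ndarray
    excluded: tuple[int, int] | None = None
    objective: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), self.coeffs)


@dataclass(frozen=True)
class DetrendedTrace:
    """Trace minus its support line, with the baseline level and noise scale.

    The support line is a *lower* envelope, so the detrended series rides a
    small positive offset: ``baseline_level`` (its median outside the KCl
    window) estimates the resting fluorescence F0 on the detrended scale, and
    ``baseline_sd`` is a robust estimate (1.4826 x MAD) of the SD of F0.
    Event thresholds are measured from ``baseline_level`` in units of
    ``baseline_sd``.
    """

    filtered: np.ndarray
    baseline_sd: float
    frame_period_s: float
    baseline_level: float = 0.0
    kcl_window: tuple[int, int] | None = None


@dataclass(frozen=True)
class CalciumEvent:
    """One detected calcium transient.

    Frames are inclusive indices with ``onset <= peak <= offset``; amplitude is
    the peak detrended fluorescence in multiples of ``baseline_sd``; duration
    counts frames at or above threshold.
    """

    cell_id: int
    onset: int
    peak: int
    offset: int
    amplitude_sd: float
    duration_s: float


def _included_mask(n: int, exclude: tuple[int, int] | None) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    if exclude is not None:
        lo, hi = exclude
        if not (0 <= lo <= hi <= n):
            raise ValueError(f"exclusion window {exclude} outside trace of length {n}")
        mask[lo:hi] = False
    return mask


def smooth_trace(trace: np.ndarray, cutoff_hz: float, frame_period_s: float) -> np.ndarray:
    """Zero-phase low-pass the trace (2nd-order Butterworth, unit DC gain).

    Removes high-frequency oscillations before the support-line fit while
    keeping DC, so the envelope fit sees the slow baseline.
    """
    trace = np.asarray(trace, dtype=float)
    nyquist = 0.5 / frame_period_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(2, cutoff_hz / nyquist)
    # filtfilt needs a minimum length; short traces pass through unchanged
    padlen = 3 * max(len(a), len(b))
    if trace.size <= padlen:
        return trace.copy()
    return filtfilt(b, a, trace)


def fit_support_line(
    smoothed: np.ndarray, exclude: tuple[int, int] | None = None
) -> SupportLine:
    """Fit the cubic support line beneath a smoothed trace.

    Solves the linear program: minimize the L1 sum of gaps
    ``sum_t (y(t) - p(t))`` over included frames subject to ``p(t) <= y(t)``
    for every included frame.  The fit is done in a normalized time basis
    ``x = t/(n-1)`` for conditioning and the coefficients converted back to
    the frame-index basis.

    Parameters
    ----------
    smoothed : array
        The low-passed trace.
    exclude : (int, int), optional
        Half-open frame range (the KCl window) left out of the fit.
    """
    y = np.asarray(smoothed, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    included = _included_mask(n, exclude)
    n_inc = int(included.sum())
    if n_inc < 8:
        raise ValueError(f"need >= 8 included frames, got {n_inc}")

    scale = float(n - 1)
    x = np.arange(n, dtype=float) / scale
    vand = np.vander(x, _SL_DEGREE + 1, increasing=True)
    v_inc = vand[included]
    y_inc = y[included]

    # maximize sum p(t)  <=>  minimize -(sum_t V[t]) . c
    res = linprog(
        c=-v_inc.sum(axis=0),
        A_ub=v_inc,
        b_ub=y_inc,
        bounds=[(None, None)] * (_SL_DEGREE + 1),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"support-line LP failed: {res.message}")
    c_norm = res.x
    values = vand @ c_norm
    coeffs = c_norm / scale ** np.arange(_SL_DEGREE + 1)
    objective = float(np.sum(y_inc - v_inc @ c_norm))
    return SupportLine(coeffs=coeffs, values=values, excluded=exclude, objective=objective)


def _robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation — SD of F0 insensitive to transients."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detrend(
    trace: np.ndarray,
    sl: SupportLine,
    frame_period_s: float,
    kcl_window: tuple[int, int] | None = None,
) -> DetrendedTrace:
    """Subtract the support line and estimate the baseline noise SD.

    The baseline SD is the robust (MAD-based) SD of the detrended series with
    the KCl window excluded.  If the MAD degenerates to zero on a non-constant
    trace (more than half the samples identical), the ordinary SD is used.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size != sl.values.size:
        raise ValueError("trace and support line lengths differ")
    filtered = trace - sl.values
    window = kcl_window if kcl_window is not None else sl.excluded
    included = _included_mask(trace.size, window)
    base = filtered[included]
    sd = _robust_sd(base)
    if sd == 0.0:
        sd = float(np.std(base))
    return DetrendedTrace(
        filtered=filtered, baseline_sd=sd, frame_period_s=frame_period_s,
        baseline_level=float(np.median(base)), kcl_window=window,
    )


def detect_events(
    dt: DetrendedTrace, params: EventDetectionParams | None = None, cell_id: int = 0
) -> list[CalciumEvent]:
    """Call calcium events as maximal supra-threshold runs of the detrended trace.

    An event is a maximal run of frames with
    ``filtered - baseline_level >= k * baseline_sd`` (k = ``params.threshold_sd``,
    default 3), i.e. excursions of >= k SDs above the resting-F0 level of the
    detrended trace.  The event peak is the argmax of the run (earliest frame
    on ties); frames inside the KCl window never start or extend an event.
    """
    if params is None:
        params = EventDetectionParams()
    filtered = np.asarray(dt.filtered, dtype=float) - dt.baseline_level
    if np.all(np.isnan(filtered)):
        raise ValueError("trace is all-NaN")
    if dt.baseline_sd <= 0:
        raise ValueError("baseline_sd must be > 0 for event detection")
    window = params.kcl_window if params.kcl_window is not None else dt.kcl_window
    thr = params.threshold_sd * dt.baseline_sd
    above = filtered >= thr
    above &= _included_mask(filtered.size, window)
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(np.int8)))
    starts, stops = list(edges[::2]), list(edges[1::2])
    # one transient can dip briefly below threshold on noise: merge runs
    # separated by <= merge_gap_frames sub-threshold frames
    merged_starts, merged_stops = [starts[0]], [stops[0]]
    for on, stop in zip(starts[1:], stops[1:]):
        if on - merged_stops[-1] <= params.merge_gap_frames:
            merged_stops[-1] = stop
        else:
            merged_starts.append(on)
            merged_stops.append(stop)
    events = []
    for on, stop in zip(merged_starts, merged_stops):
        seg = filtered[on:stop]
        peak = on + int(np.argmax(seg))  # argmax takes the earliest tie
        events.append(
            CalciumEvent(
                cell_id=cell_id,
                onset=int(on),
                peak=peak,
                offset=int(stop - 1),
                amplitude_sd=float(filtered[peak] / dt.baseline_sd),
                duration_s=float((stop - on) * dt.frame_period_s),
            )
        )
    return events
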