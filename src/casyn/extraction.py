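"""Cell identification in calcium movies and cell-level inclusion filters.

Cells are found by spatiotemporal PCA/ICA: the movie is reduced by PCA, and
independent components are obtained by skewness maximization on a mu-weighted
concatenation of the spatial and temporal principal components (mu = 0.5 weighs
both equally).  Each independent component's spatial filter is thresholded and
split into connected components to yield ROIs; traces are weighted ROI means.

Two physiology-motivated filters follow: cells must respond to the terminal
KCl depolarization (viability), and cells whose calcium events are very slow
(> 5 s) are excluded as putative glia.  Movies are assumed motion-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import ndimage

from casyn.events import (
    CalciumEvent,
    DetrendedTrace,
    EventDetectionParams,
    detrend,
    fit_support_line,
    smooth_trace,
)

__all__ = [
    "FluorescenceMovie",
    "ROI",
    "CellTraces",
    "ExtractionParams",
    "pca_ica_segment",
    "extract_roi_traces",
    "filter_viable",
    "filter_glia",
]


@dataclass(frozen=True)
class FluorescenceMovie:
    """A motion-corrected fluorescence movie: frames x height x width."""

    data: np.ndarray
    frame_period_s: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("movie must be (frames, h, w) with >= 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass(frozen=True)
class ROI:
    """A weighted set of pixels; weights are non-negative and sum to 1."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if self.pixels.shape[0] == 0:
            raise ValueError("ROI must be non-empty")
        if np.any(self.weights < 0):
            raise ValueError("ROI weights must be non-negative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0):
            object.__setattr__(self, "weights", self.weights / total)

    def mask(self, h: int, w: int) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    def iou(self, other: "ROI") -> float:
        a = {tuple(p) for p in self.pixels}
        b = {tuple(p) for p in other.pixels}
        return len(a & b) / len(a | b)


@dataclass
class CellTraces:
    """Cell x frame fluorescence matrix with acquisition frame period."""

    data: np.ndarray
    frame_period_s: float
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("traces contain non-finite values")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.data.shape[0])
        self.cell_ids = np.asarray(self.cell_ids)
        if self.cell_ids.size != self.data.shape[0]:
            raise ValueError("cell_ids length must match number of rows")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def subset(self, mask: np.ndarray) -> "CellTraces":
        return CellTraces(self.data[mask], self.frame_period_s, self.cell_ids[mask])


@dataclass(frozen=True)
class ExtractionParams:
    """Knobs for PCA/ICA segmentation and the cell filters.

    ``n_principal_components`` defaults to 1.5 x ``expected_n_cells`` (mildly
    over-complete reduction).  ``ica_mu`` in [0, 1] weighs spatial vs temporal
    information in the ICA (0.5 = equal).  Spatial filters are thresholded at
    ``spatial_threshold_sd`` SDs and connected components below
    ``min_roi_pixels`` are discarded.  ``kcl_response_threshold_sd`` is the
    detrended-amplitude threshold (in baseline SDs) a cell must exceed inside
    the KCl window to count as viable; ``glia_max_event_duration_s`` is the
    longest event duration a neuron may show (strictly longer events mark the
    cell as glia).
    """

    n_principal_components: int | None = None
    expected_n_cells: int = 20
    ica_mu: float = 0.5
    spatial_threshold_sd: float = 2.5
    min_roi_pixels: int = 5
    kcl_response_threshold_sd: float = 5.0
    glia_max_event_duration_s: float = 5.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ica_mu <= 1.0:
            raise ValueError("ica_mu must be in [0, 1]")
        if self.spatial_threshold_sd <= 0 or self.kcl_response_threshold_sd <= 0:
            raise ValueError("thresholds must be > 0")

    def n_components(self) -> int:
        if self.n_principal_components is not None:
            return self.n_principal_components
        return ceil(1.5 * self.expected_n_cells)


def _skew_ica(y: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float) -> np.ndarray:
    """Skewness-maximizing ICA rotation for whitened rows of ``y`` (k x m).

    Fixed-point iteration with symmetric decorrelation; returns the unmixing
    matrix W (k x k) with orthonormal rows.
    """
    k, m = y.shape
    w = rng.standard_normal((k, k))
    w = _sym_orth(w)
    for _ in range(max_iter):
        proj = w @ y  # (k, m)
        w_new = (proj**2) @ y.T / m  # gradient of third-moment contrast
        w_new = _sym_orth(w_new)
        delta = 1.0 - np.abs(np.einsum("ij,ij->i", w_new, w)).min()
        w = w_new
        if delta < tol:
            break
    return w


def _sym_orth(w: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(w, full_matrices=False)
    return u @ vt


def pca_ica_segment(
    movie: FluorescenceMovie, params: ExtractionParams | None = None
) -> tuple[list[ROI], CellTraces]:
    """Identify cell ROIs by spatiotemporal PCA/ICA and extract their traces.

    Returns a (possibly empty) ROI list and the matching traces; a movie with
    no structure (zero variance, or no filter pixels above threshold) yields
    zero ROIs rather than an error.
    """
    if params is None:
        params = ExtractionParams()
    t, h, w = movie.data.shape
    x = movie.data.reshape(t, h * w).astype(float)
    mean_px = x.mean(axis=0)
    xc = x - mean_px
    total_var = float(np.sum(xc**2))
    if total_var <= 1e-12:
        return [], CellTraces(np.empty((0, t)), movie.frame_period_s, np.empty(0, dtype=int))

    k = min(params.n_components(), t - 1, h * w)
    # economy SVD on the smaller Gram side
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    keep = s > 1e-10 * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    k = s.size

    # mu-weighted concatenation of spatial (vt) and temporal (u.T) PCs;
    # rows are orthonormal per block so the joint rows are uncorrelated
    mu = params.ica_mu
    y = np.concatenate([mu * vt, (1.0 - mu) * u.T], axis=1)
    rng = np.random.default_rng(params.seed)
    w_unmix = _skew_ica(y, rng, params.max_iter, params.tol)

    filters = w_unmix @ vt  # (k, pixels)
    # orient each filter to positive skewness so cells are bright
    skew = np.mean(filters**3, axis=1)
    filters[skew < 0] *= -1.0

    rois: list[ROI] = []
    for f in filters:
        z = (f - f.mean()) / (f.std() or 1.0)
        above = (z > params.spatial_threshold_sd).reshape(h, w)
        labels, n_lab = ndimage.label(above)
        for lab in range(1, n_lab + 1):
            rr, cc = np.nonzero(labels == lab)
            if rr.size < params.min_roi_pixels:
                continue
            wts = np.clip(f.reshape(h, w)[rr, cc], 0.0, None)
            if wts.sum() <= 0:
                continue
            rois.append(ROI(pixels=np.column_stack([rr, cc]), weights=wts / wts.sum()))

    # de-duplicate: the same cell can surface in several components
    deduped: list[ROI] = []
    for roi in sorted(rois, key=lambda r: -r.pixels.shape[0]):
        if all(roi.iou(kept) <= 0.5 for kept in deduped):
            deduped.append(roi)
    if not deduped:
        return [], CellTraces(np.empty((0, t)), movie.frame_period_s, np.empty(0, dtype=int))
    traces = extract_roi_traces(movie, deduped)
    return deduped, traces


def extract_roi_traces(movie: FluorescenceMovie, rois: list[ROI]) -> CellTraces:
    """Weighted ROI-mean fluorescence as a function of time, one row per ROI."""
    if not rois:
        raise ValueError("no ROIs given")
    t, h, w = movie.data.shape
    flat = movie.data.reshape(t, h * w)
    out = np.empty((len(rois), t))
    for i, roi in enumerate(rois):
        if np.any(roi.pixels[:, 0] >= h) or np.any(roi.pixels[:, 1] >= w):
            raise ValueError("ROI outside movie bounds")
        idx = roi.pixels[:, 0] * w + roi.pixels[:, 1]
        out[i] = flat[:, idx] @ roi.weights
    return CellTraces(out, movie.frame_period_s)


def detrend_cell(
    trace: np.ndarray,
    frame_period_s: float,
    kcl_window: tuple[int, int] | None = None,
    smoothing_cutoff_hz: float = 0.5,
) -> DetrendedTrace:
    """Smooth, fit the support line (KCl excluded) and detrend one trace."""
    sm = smooth_trace(trace, smoothing_cutoff_hz, frame_period_s)
    sl = fit_support_line(sm, exclude=kcl_window)
    return detrend(trace, sl, frame_period_s, kcl_window=kcl_window)


def filter_viable(
    traces: CellTraces,
    kcl_window: tuple[int, int],
    params: ExtractionParams | None = None,
    detrended: list[DetrendedTrace] | None = None,
) -> np.ndarray:
    """Keep cells that respond to the terminal KCl depolarization.

    A cell is viable iff its detrended trace exceeds
    ``kcl_response_threshold_sd x baseline_sd`` somewhere inside the KCl
    window.  Pass precomputed ``detrended`` traces to avoid refitting.
    """
    if params is None:
        params = ExtractionParams()
    lo, hi = kcl_window
    if not (0 <= lo < hi <= traces.n_frames):
        raise ValueError("empty or out-of-bounds KCl window")
    mask = np.zeros(traces.n_cells, dtype=bool)
    for i in range(traces.n_cells):
        dt = (
            detrended[i]
            if detrended is not None
            else detrend_cell(traces.data[i], traces.frame_period_s, kcl_window)
        )
        if dt.baseline_sd <= 0:
            continue
        mask[i] = bool(
            np.max(dt.filtered[lo:hi]) - dt.baseline_level
            >= params.kcl_response_threshold_sd * dt.baseline_sd
        )
    return mask


def filter_glia(
    events_per_cell: list[list[CalciumEvent]], max_duration_s: float = 5.0
) -> np.ndarray:
    """Keep cells with no very slow calcium responses.

    A cell is excluded (mask False) iff any of its events lasts strictly
    longer than ``max_duration_s`` — such cells are most likely glia.  An
    event of exactly the threshold duration is kept.
    """
    mask = np.ones(len(events_per_cell), dtype=bool)
    for i, events in enumerate(events_per_cell):
        if any(ev.duration_s > max_duration_s for ev in events):
            mask[i] = False
    return mask
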