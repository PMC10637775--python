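"""End-to-end per-movie analysis: traces in, MovieSummary out.

Chains the stages in the order the physiology demands: per-cell smoothing and
support-line detrending, SD-threshold event calling, KCl viability and glia
filtering (masks compose — population statistics only ever see retained
cells), population PCA, SE/burst detection and the movie summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from casyn.events import (
    CalciumEvent,
    DetrendedTrace,
    EventDetectionParams,
    detect_events,
    detrend,
    fit_support_line,
    smooth_trace,
)
from casyn.extraction import CellTraces, ExtractionParams, filter_glia, filter_viable
from casyn.synchrony import (
    Burst,
    EventRaster,
    MovieSummary,
    PopulationComponents,
    SyncEvent,
    SynchronyParams,
    detect_bursts,
    detect_ses,
    population_pca,
    select_se_component,
    summarize_movie,
)

__all__ = ["MovieAnalysis", "analyze_traces"]


@dataclass
class MovieAnalysis:
    """Everything the per-movie pipeline produced, masks included."""

    detrended: list[DetrendedTrace]
    events_per_cell: list[list[CalciumEvent]]
    viable_mask: np.ndarray
    glia_keep_mask: np.ndarray
    retained_mask: np.ndarray
    raster: EventRaster
    components: PopulationComponents | None
    se_component: int
    se_confidence: float
    low_confidence: bool
    ses: list[SyncEvent]
    bursts: list[Burst]
    summary: MovieSummary


def analyze_traces(
    traces: CellTraces,
    kcl_window: tuple[int, int] | None = None,
    event_params: EventDetectionParams | None = None,
    extraction_params: ExtractionParams | None = None,
    synchrony_params: SynchronyParams | None = None,
) -> MovieAnalysis:
    """Run the full trace-level pipeline on one movie.

    When ``kcl_window`` is None the viability filter is skipped (all cells
    viable), matching recordings without a terminal KCl challenge.
    """
    if event_params is None:
        event_params = EventDetectionParams(kcl_window=kcl_window)
    elif event_params.kcl_window is None and kcl_window is not None:
        event_params = EventDetectionParams(
            smoothing_cutoff_hz=event_params.smoothing_cutoff_hz,
            threshold_sd=event_params.threshold_sd,
            kcl_window=kcl_window,
        )
    if extraction_params is None:
        extraction_params = ExtractionParams()
    if synchrony_params is None:
        synchrony_params = SynchronyParams()

    fp = traces.frame_period_s
    detrended: list[DetrendedTrace] = []
    events_per_cell: list[list[CalciumEvent]] = []
    for i in range(traces.n_cells):
        sm = smooth_trace(traces.data[i], event_params.smoothing_cutoff_hz, fp)
        sl = fit_support_line(sm, exclude=kcl_window)
        dt = detrend(traces.data[i], sl, fp, kcl_window=kcl_window)
        detrended.append(dt)
        if dt.baseline_sd > 0:
            events_per_cell.append(detect_events(dt, event_params, cell_id=i))
        else:
            events_per_cell.append([])

    if kcl_window is not None:
        viable = filter_viable(traces, kcl_window, extraction_params, detrended=detrended)
    else:
        viable = np.ones(traces.n_cells, dtype=bool)
    glia_keep = filter_glia(events_per_cell, extraction_params.glia_max_event_duration_s)
    retained = viable & glia_keep

    idx = np.flatnonzero(retained)
    raster = EventRaster.from_events(
        [events_per_cell[i] for i in idx], traces.n_frames, fp, cell_ids=traces.cell_ids[idx]
    )

    components: PopulationComponents | None = None
    se_idx, confidence, low_conf = 0, 0.0, True
    ses: list[SyncEvent] = []
    bursts: list[Burst] = []
    # population analysis runs on the pre-KCl segment only: the shared KCl
    # transient would otherwise dominate the leading component
    stop = kcl_window[0] if kcl_window is not None else traces.n_frames
    if idx.size >= 2:
        mat = np.vstack([detrended[i].filtered[:stop] for i in idx])
        try:
            components = population_pca(mat)
        except ValueError:
            components = None
        if components is not None:
            pre_raster = EventRaster(
                raster.matrix[:, :stop], fp, cell_ids=raster.cell_ids
            )
            se_idx, confidence, low_conf = select_se_component(
                components, pre_raster, synchrony_params.n_pc_candidates, synchrony_params
            )
            pc_trace = components.time_courses[se_idx]
            ses = detect_ses(pc_trace, raster, synchrony_params)
            bursts, _ = detect_bursts(pc_trace, ses, synchrony_params)

    duration_s = traces.n_frames * fp
    if kcl_window is not None:
        duration_s = kcl_window[0] * fp  # analysis period ends at KCl
    summary = summarize_movie(raster, ses, bursts, duration_s, synchrony_params)
    return MovieAnalysis(
        detrended=detrended,
        events_per_cell=events_per_cell,
        viable_mask=viable,
        glia_keep_mask=glia_keep,
        retained_mask=retained,
        raster=raster,
        components=components,
        se_component=se_idx,
        se_confidence=confidence,
        low_confidence=low_conf,
        ses=ses,
        bursts=bursts,
        summary=summary,
    )
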