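"""Readers and writers for the pipeline's on-disk formats.

Traces travel as HDF5 (datasets ``traces``, attr ``frame_period_s``, optional
``truth`` group) or delimited text; movies as multi-page unsigned-16-bit TIFF;
EEG as two-column delimited text (time_s, microvolts) or HDF5; event tables
and movie summaries as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from casyn.eeg import EEGSignal
from casyn.events import CalciumEvent
from casyn.extraction import CellTraces, FluorescenceMovie, ROI
from casyn.simulate import GroundTruth

__all__ = [
    "save_traces_h5", "load_traces_h5",
    "save_traces_csv", "load_traces_csv",
    "save_movie_tiff", "load_movie_tiff",
    "save_roi_labels_tiff",
    "save_eeg_txt", "load_eeg_txt",
    "events_to_frame", "save_events_csv",
]


def save_traces_h5(path: str | Path, traces: CellTraces, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=traces.data)
        d.attrs["frame_period_s"] = traces.frame_period_s
        f.create_dataset("cell_ids", data=np.asarray(traces.cell_ids))
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("se_frames", data=truth.se_frames)
            g.create_dataset("burst_membership", data=truth.burst_membership)
            g.create_dataset("bleach_poly", data=truth.bleach_poly)
            g.create_dataset("viable_mask", data=truth.viable_mask)
            g.create_dataset("glia_mask", data=truth.glia_mask)
            if truth.kcl_window is not None:
                g.attrs["kcl_window"] = truth.kcl_window
            sp = g.create_group("spike_frames")
            for i, s in enumerate(truth.spike_frames):
                sp.create_dataset(str(i), data=np.asarray(s, dtype=int))
            pp = g.create_group("se_participants")
            for i, s in enumerate(truth.se_participants):
                pp.create_dataset(str(i), data=np.asarray(s, dtype=int))


def load_traces_h5(path: str | Path) -> tuple[CellTraces, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        d = f["traces"]
        traces = CellTraces(d[...], float(d.attrs["frame_period_s"]), f["cell_ids"][...])
        truth = None
        if "truth" in f:
            g = f["truth"]
            n = traces.n_cells
            truth = GroundTruth(
                spike_frames=[g["spike_frames"][str(i)][...] for i in range(n)],
                se_frames=g["se_frames"][...],
                se_participants=[
                    g["se_participants"][str(i)][...] for i in range(len(g["se_participants"]))
                ],
                burst_membership=g["burst_membership"][...],
                bleach_poly=g["bleach_poly"][...],
                viable_mask=g["viable_mask"][...].astype(bool),
                glia_mask=g["glia_mask"][...].astype(bool),
                kcl_window=tuple(g.attrs["kcl_window"]) if "kcl_window" in g.attrs else None,
            )
    return traces, truth


def save_traces_csv(path: str | Path, traces: CellTraces) -> None:
    """Wide delimited text: one row per cell; frame period in a comment line."""
    with open(path, "w") as f:
        f.write(f"# frame_period_s={traces.frame_period_s}\n")
        pd.DataFrame(traces.data, index=pd.Index(traces.cell_ids, name="cell_id")).to_csv(f)


def load_traces_csv(path: str | Path) -> CellTraces:
    with open(path) as f:
        first = f.readline()
        if not first.startswith("# frame_period_s="):
            raise ValueError("missing frame_period_s header comment")
        fp = float(first.split("=", 1)[1])
        df = pd.read_csv(f, index_col=0)
    return CellTraces(df.to_numpy(float), fp, df.index.to_numpy())


def save_movie_tiff(path: str | Path, movie: FluorescenceMovie) -> None:
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"frame_period_s": movie.frame_period_s})


def load_movie_tiff(path: str | Path, frame_period_s: float | None = None) -> FluorescenceMovie:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        if frame_period_s is None:
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta and isinstance(meta, (list, tuple)):
                meta = meta[0]
            if not meta or "frame_period_s" not in meta:
                raise ValueError("frame_period_s not stored in TIFF; pass it explicitly")
            frame_period_s = float(meta["frame_period_s"])
    return FluorescenceMovie(data, frame_period_s)


def save_roi_labels_tiff(path: str | Path, rois: list[ROI], h: int, w: int) -> None:
    """Labelled ROI map: pixel value = ROI index + 1, 0 = background."""
    labels = np.zeros((h, w), dtype=np.uint16)
    for i, roi in enumerate(rois, start=1):
        labels[roi.pixels[:, 0], roi.pixels[:, 1]] = i
    tifffile.imwrite(path, labels)


def save_eeg_txt(path: str | Path, sig: EEGSignal) -> None:
    t = np.arange(sig.samples.size) / sig.fs_hz
    header = f"injection_time_s={sig.injection_time_s} fs_hz={sig.fs_hz}\ntime_s\tuV"
    np.savetxt(path, np.column_stack([t, sig.samples]), header=header, delimiter="\t")


def load_eeg_txt(path: str | Path, injection_time_s: float | None = None) -> EEGSignal:
    inj = injection_time_s
    with open(path) as f:
        first = f.readline()
    if first.startswith("#") and "injection_time_s=" in first and inj is None:
        inj = float(first.split("injection_time_s=")[1].split()[0])
    arr = np.loadtxt(path, delimiter="\t")
    t, x = arr[:, 0], arr[:, 1]
    fs = 1.0 / np.median(np.diff(t))
    return EEGSignal(samples=x, fs_hz=float(round(fs, 6)), injection_time_s=inj or 0.0)


def events_to_frame(events_per_cell: list[list[CalciumEvent]]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": ev.cell_id,
            "onset": ev.onset,
            "peak": ev.peak,
            "offset": ev.offset,
            "amplitude_sd": ev.amplitude_sd,
            "duration_s": ev.duration_s,
        }
        for events in events_per_cell
        for ev in events
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "onset", "peak", "offset", "amplitude_sd", "duration_s"]
    )


def save_events_csv(path: str | Path, events_per_cell: list[list[CalciumEvent]]) -> None:
    events_to_frame(events_per_cell).to_csv(path, index=False)
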