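"""EEG spectral analysis for the kainic-acid seizure paradigm.

The recording is cut into consecutive 10-s epochs from the injection time;
each epoch is Fourier transformed (Hann-windowed periodogram) and its power
integrated over conventional frequency bands (delta/theta/alpha/sigma/beta/
gamma).  Cumulative per-band power over the 90-min post-injection period and
an automated, EEG-only seizure onset/duration call (twofold jump in both
amplitude and dominant frequency over baseline) complete the readouts.

Seizure calls here implement only the electrographic half of the published
criterion — behavioral video confirmation is not modelled — and are labelled
``eeg_only`` in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

__all__ = [
    "EEGSignal",
    "BandDef",
    "DEFAULT_BANDS",
    "Epoch",
    "SeizureCall",
    "epoch_signal",
    "band_power",
    "epoch_power_table",
    "cumulative_power",
    "detect_onset",
]


@dataclass(frozen=True)
class EEGSignal:
    """Single-channel EEG: samples in microvolts at a fixed sampling rate."""

    samples: np.ndarray
    fs_hz: float
    injection_time_s: float = 0.0
    artifact_mask: np.ndarray | None = None  # True = contaminated sample

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.artifact_mask is not None and len(self.artifact_mask) != len(self.samples):
            raise ValueError("artifact mask length must match samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class BandDef:
    """A half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"bad band {self.name}: [{self.f_lo}, {self.f_hi})")


#: conventional rodent EEG bands; edges are config, not measurement
DEFAULT_BANDS = (
    BandDef("delta", 0.5, 4.0),
    BandDef("theta", 4.0, 8.0),
    BandDef("alpha", 8.0, 12.0),
    BandDef("sigma", 12.0, 16.0),
    BandDef("beta", 16.0, 24.0),
    BandDef("gamma", 24.0, 80.0),
)


@dataclass(frozen=True)
class Epoch:
    index: int
    start_s: float
    samples: np.ndarray
    included: bool = True
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class SeizureCall:
    """EEG-only seizure onset/offset, in seconds after injection."""

    onset_s: float
    offset_s: float
    baseline_rms: float
    trigger_rms: float
    eeg_only: bool = True
    offset_criterion: str = "rms < 1.5 x baseline for >= 30 s (invented for duration reporting)"

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def epoch_signal(sig: EEGSignal, epoch_s: float = 10.0) -> list[Epoch]:
    """Cut the record into consecutive epochs starting at the injection time.

    The trailing partial epoch is dropped; epochs overlapping the artifact
    mask (movement/grooming) are flagged excluded rather than removed, so
    bookkeeping stays aligned.
    """
    start = int(round(sig.injection_time_s * sig.fs_hz))
    per = int(round(epoch_s * sig.fs_hz))
    if per <= 0:
        raise ValueError("epoch_s must be positive")
    n_epochs = (sig.samples.size - start) // per
    if n_epochs < 1:
        raise ValueError("record shorter than one epoch")
    epochs = []
    for i in range(n_epochs):
        a, b = start + i * per, start + (i + 1) * per
        contaminated = (
            sig.artifact_mask is not None and bool(np.any(sig.artifact_mask[a:b]))
        )
        epochs.append(
            Epoch(
                index=i,
                start_s=i * epoch_s,
                samples=sig.samples[a:b],
                included=not contaminated,
                exclusion_reason="artifact" if contaminated else None,
            )
        )
    return epochs


def band_power(
    samples: np.ndarray, fs_hz: float, bands: tuple[BandDef, ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Integrated periodogram power (uV^2) per half-open band.

    Hann-windowed one-sided periodogram; band powers are exact partitions of
    the power in the union range because bins are assigned half-open.
    """
    nyq = fs_hz / 2.0
    for b in bands:
        if b.f_hi > nyq + 1e-9:
            raise ValueError(f"band {b.name} exceeds Nyquist {nyq} Hz")
    f, psd = periodogram(np.asarray(samples, dtype=float), fs=fs_hz, window="hann")
    df = f[1] - f[0]
    return {b.name: float(psd[(f >= b.f_lo) & (f < b.f_hi)].sum() * df) for b in bands}


def epoch_power_table(
    epochs: list[Epoch], fs_hz: float, bands: tuple[BandDef, ...] = DEFAULT_BANDS
) -> pd.DataFrame:
    """Per-epoch band powers plus totals, one row per epoch.

    ``total`` is the power over the union of the band ranges; ``total_all`` is
    the full-spectrum power and ``total_24_80`` the 24-80 Hz power — both are
    emitted because published "total power" conventions differ.
    """
    lo = min(b.f_lo for b in bands)
    hi = max(b.f_hi for b in bands)
    rows = []
    for ep in epochs:
        powers = band_power(ep.samples, fs_hz, bands)
        f, psd = periodogram(ep.samples, fs=fs_hz, window="hann")
        df = f[1] - f[0]
        rows.append(
            {
                "epoch": ep.index,
                "start_s": ep.start_s,
                **powers,
                "total": float(psd[(f >= lo) & (f < hi)].sum() * df),
                "total_all": float(psd.sum() * df),
                "total_24_80": float(psd[(f >= 24.0) & (f < 80.0)].sum() * df),
                "included": ep.included,
                "exclusion_reason": ep.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def cumulative_power(
    table: pd.DataFrame, period_s: float = 5400.0, bands: tuple[BandDef, ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Sum of included-epoch band powers over the post-injection period.

    Default period is the 90-min observation window after kainic-acid
    injection.
    """
    sel = table[(table["included"]) & (table["start_s"] < period_s)]
    cols = [b.name for b in bands] + [c for c in ("total", "total_all", "total_24_80") if c in table]
    return {c: float(sel[c].sum()) for c in cols}


def _window_features(x: np.ndarray, fs_hz: float, f_max: float = 80.0) -> tuple[float, float]:
    """RMS and median (spectral-edge-50) frequency of one analysis window."""
    rms = float(np.sqrt(np.mean(x**2)))
    f, psd = periodogram(x, fs=fs_hz, window="hann")
    sel = (f >= 1.0) & (f < min(f_max, fs_hz / 2.0))
    p = psd[sel]
    if p.sum() <= 0:
        return rms, 0.0
    cum = np.cumsum(p) / p.sum()
    sef = float(f[sel][np.searchsorted(cum, 0.5)])
    return rms, sef


def detect_onset(
    sig: EEGSignal,
    baseline_window_s: tuple[float, float] = (0.0, 60.0),
    factor: float = 2.0,
    min_hold_s: float = 10.0,
    window_s: float = 10.0,
    step_s: float = 1.0,
    offset_factor: float = 1.5,
    offset_hold_s: float = 30.0,
) -> SeizureCall | None:
    """Automated EEG-only seizure call by the twofold amplitude + frequency rule.

    Onset is the start of the first sliding window run (length >= min_hold_s)
    in which RMS >= factor x baseline RMS AND the median frequency >= factor x
    baseline median frequency.  The baseline window must be artifact-free and
    precede any candidate seizure.  Offset is the first subsequent window with
    RMS < offset_factor x baseline sustained offset_hold_s (end of record if
    never reached).  Returns None when no window qualifies.

    The criterion is ratio-based, so the call is invariant to a global
    amplitude rescaling of the recording.
    """
    fs = sig.fs_hz
    b0, b1 = (int(round(s * fs)) for s in baseline_window_s)
    if b1 <= b0:
        raise ValueError("empty baseline window")
    base_rms, base_sef = _window_features(sig.samples[b0:b1], fs)
    if base_rms <= 0:
        raise ValueError("flat baseline")

    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(b1, sig.samples.size - win + 1, step)
    if starts.size == 0:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(sig.samples, win)[starts]
    rms_arr = np.sqrt(np.mean(windows**2, axis=1))
    f, psd = periodogram(windows, fs=fs, window="hann", axis=1)
    sel = (f >= 1.0) & (f < min(80.0, fs / 2.0))
    p = psd[:, sel]
    tot = p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1) / np.where(tot > 0, tot, 1.0)
    sef_arr = f[sel][np.argmax(cum >= 0.5, axis=1)]
    sef_arr[tot[:, 0] <= 0] = 0.0
    hot = (rms_arr >= factor * base_rms) & (
        (base_sef <= 0) | (sef_arr >= factor * base_sef)
    )

    need = max(1, int(round(min_hold_s / step_s)))
    onset_i = None
    run = 0
    for i, h in enumerate(hot):
        run = run + 1 if h else 0
        if run >= need:
            onset_i = i - need + 1
            break
    if onset_i is None:
        return None
    onset_s = float(starts[onset_i] / fs - sig.injection_time_s)

    quiet_need = max(1, int(round(offset_hold_s / step_s)))
    quiet = rms_arr < offset_factor * base_rms
    offset_s = float(sig.duration_s - sig.injection_time_s)
    run = 0
    for i in range(onset_i + need, starts.size):
        run = run + 1 if quiet[i] else 0
        if run >= quiet_need:
            offset_s = float(starts[i - quiet_need + 1] / fs - sig.injection_time_s)
            break
    trigger_rms = float(rms_arr[onset_i])
    return SeizureCall(
        onset_s=onset_s, offset_s=offset_s, baseline_rms=base_rms, trigger_rms=trigger_rms
    )
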