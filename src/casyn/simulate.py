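"""Ground-truth simulators for calcium traces, movies and EEG.

The trace generator emulates Fluo-4 movies of the developing CA3 network:
Poisson-timed synchronous events (SEs) in which a fraction of the viable
neurons fire near-coincidently, optional bursts of closely spaced SEs,
asynchronous per-cell events, a cubic photobleaching baseline, i.i.d. Gaussian
noise, a terminal KCl depolarization of viable cells, and contaminant
populations (non-viable cells without activity, glia with only very slow
transients).  The EEG generator produces 1/f background plus band-limited
oscillations, with an optional gain-switched seizure segment carrying a sharp
spike train.  Everything is reproducible bit-for-bit under a fixed seed and
returns the ground truth needed to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from casyn.extraction import CellTraces, FluorescenceMovie, ROI
from casyn.eeg import EEGSignal

__all__ = [
    "TraceSimParams",
    "GroundTruth",
    "EEGSimParams",
    "generate_traces",
    "render_movie",
    "generate_eeg",
]


@dataclass(frozen=True)
class TraceSimParams:
    """World description for the calcium-trace simulator.

    Defaults describe a 5-minute movie of 100 cells at the acquisition frame
    period of 0.328 s, SEs at 2/min with 60 % mean participation, 6-SD event
    amplitudes, and a terminal KCl challenge.  Amplitudes (``amp_mean_sd_units``,
    ``kcl_amp_sd_units``) are in multiples of ``noise_sd`` so detection
    thresholds in SD units are meaningful by construction.
    """

    n_cells: int = 100
    n_frames: int = 915
    frame_period_s: float = 0.328
    se_rate_per_min: float = 2.0
    participation_mean: float = 0.6
    participation_sd: float = 0.1
    burst_prob: float = 0.0
    burst_size_mean: float = 3.0
    intra_burst_interval_s: float = 1.5
    async_rate_per_cell_per_min: float = 1.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 1.0
    amp_mean_sd_units: float = 6.0
    bleach_cubic_coeffs: tuple[float, float, float, float] | None = None
    noise_sd: float = 1.0
    kcl_enabled: bool = True
    kcl_onset_frame: int | None = None
    kcl_amp_sd_units: float = 20.0
    frac_nonviable: float = 0.05
    frac_glia: float = 0.05
    glia_event_duration_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("participation_mean", "participation_sd", "burst_prob",
                     "frac_nonviable", "frac_glia"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("se_rate_per_min", "async_rate_per_cell_per_min", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.se_rate_per_min > 0 and self.n_frames * self.frame_period_s < 60.0:
            raise ValueError("movies with SEs must be >= 60 s long")
        if self.kcl_onset_frame is not None and not (0 <= self.kcl_onset_frame < self.n_frames):
            raise ValueError("kcl_onset_frame must fall inside the movie")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def kcl_onset(self) -> int | None:
        """KCl onset frame; defaults to 20 s before the end of the movie."""
        if not self.kcl_enabled:
            return None
        if self.kcl_onset_frame is not None:
            return self.kcl_onset_frame
        return self.n_frames - int(round(20.0 / self.frame_period_s))

    def kcl_window(self) -> tuple[int, int] | None:
        onset = self.kcl_onset()
        return None if onset is None else (onset, self.n_frames)


@dataclass
class GroundTruth:
    """Generator-side truth against which every analysis stage is scored."""

    spike_frames: list[np.ndarray]
    se_frames: np.ndarray
    se_participants: list[np.ndarray]
    burst_membership: np.ndarray  # burst id per SE, -1 = not in a burst
    bleach_poly: np.ndarray  # (n_cells, 4) ascending coefficients over frame index
    viable_mask: np.ndarray
    glia_mask: np.ndarray
    kcl_window: tuple[int, int] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.spike_frames)

    def participation_fractions(self) -> np.ndarray:
        denom = int(np.sum(self.viable_mask))
        return np.array([len(p) / denom for p in self.se_participants])


def _calcium_kernel(
    rise_s: float, decay_s: float, frame_period_s: float
) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials kernel, peak-normalized to 1.

    Returns the kernel and its peak index; events are placed so the kernel
    *peak* falls on the stated event frame, because every downstream stage
    timestamps events by their peaks.
    """
    length = int(np.ceil(6.0 * decay_s / frame_period_s)) + 1
    t = np.arange(length) * frame_period_s
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel degenerate; need rise < decay")
    return k / peak, int(np.argmax(k))


def _add_kernel(
    signal: np.ndarray, frame: int, amp: float, kernel: np.ndarray, peak_idx: int = 0
) -> None:
    start = frame - peak_idx
    lo = max(0, start)
    stop = min(signal.size, start + kernel.size)
    if stop > lo:
        signal[lo:stop] += amp * kernel[lo - start : stop - start]


def generate_traces(params: TraceSimParams) -> tuple[CellTraces, GroundTruth]:
    """Simulate a cell x frame trace matrix and its ground truth.

    Trace model per cell: cubic bleach polynomial + sum of kernel-shaped
    events + Gaussian noise.  Viable cells carry the terminal KCl transient;
    glia carry only slow events (kernel decay = ``glia_event_duration_s``,
    amplitude 3e x noise so the supra-3SD duration matches that parameter);
    non-viable cells carry no activity at all.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n, t = p.n_cells, p.n_frames
    fp = p.frame_period_s
    duration_min = p.duration_s / 60.0
    noise_unit = p.noise_sd if p.noise_sd > 0 else 1.0

    order = rng.permutation(n)
    n_glia = int(round(p.frac_glia * n))
    n_nonviable = int(round(p.frac_nonviable * n))
    glia_mask = np.zeros(n, dtype=bool)
    glia_mask[order[:n_glia]] = True
    viable_mask = np.ones(n, dtype=bool)
    viable_mask[order[n_glia : n_glia + n_nonviable]] = False
    neuron_ids = np.flatnonzero(viable_mask & ~glia_mask)

    kcl_onset = p.kcl_onset()
    margin = max(1, int(round(5.0 / fp)))
    last_ok = (kcl_onset if kcl_onset is not None else t) - margin

    # SE times: Poisson count at the movie-level rate, placed uniformly in the
    # usable window (clear of edges and the KCl tail)
    se_frames: list[int] = []
    burst_membership: list[int] = []
    n_seeds = rng.poisson(p.se_rate_per_min * duration_min)
    seed_frames = np.sort(rng.integers(margin, max(margin + 1, last_ok), size=n_seeds))
    burst_id = 0
    step = max(1, int(round(p.intra_burst_interval_s / fp)))
    for f in seed_frames:
        if p.burst_prob > 0 and rng.random() < p.burst_prob:
            size = max(2, int(rng.geometric(1.0 / p.burst_size_mean)))
            members = [int(f + j * step) for j in range(size)]
            members = [m for m in members if m < last_ok]
            if len(members) >= 2:
                se_frames.extend(members)
                burst_membership.extend([burst_id] * len(members))
                burst_id += 1
                continue
        se_frames.append(int(f))
        burst_membership.append(-1)
    se_order = np.argsort(se_frames, kind="stable")
    se_arr = np.asarray(se_frames, dtype=int)[se_order]
    burst_arr = np.asarray(burst_membership, dtype=int)[se_order]

    spike_frames: list[list[int]] = [[] for _ in range(n)]
    se_participants: list[np.ndarray] = []
    for f in se_arr:
        frac = float(np.clip(rng.normal(p.participation_mean, p.participation_sd), 0.0, 1.0))
        n_part = int(round(frac * neuron_ids.size))
        part = rng.choice(neuron_ids, size=n_part, replace=False)
        se_participants.append(np.sort(part))
        jitter = rng.integers(-1, 2, size=n_part)
        for c, j in zip(part, jitter):
            spike_frames[c].append(int(np.clip(f + j, 0, t - 1)))

    for c in neuron_ids:
        n_async = rng.poisson(p.async_rate_per_cell_per_min * duration_min)
        if n_async:
            frames = rng.integers(margin, max(margin + 1, last_ok), size=n_async)
            spike_frames[c].extend(int(f) for f in frames)

    glia_ids = np.flatnonzero(glia_mask)
    for c in glia_ids:
        n_ev = max(1, rng.poisson(p.async_rate_per_cell_per_min * duration_min))
        frames = rng.integers(margin, max(margin + 1, last_ok), size=n_ev)
        spike_frames[c] = [int(f) for f in frames]

    # bleach polynomial per cell: default ~100 units of baseline decaying ~10 %
    # over the movie with mild per-cell variation
    bleach = np.zeros((n, 4))
    if p.bleach_cubic_coeffs is not None:
        bleach[:] = np.asarray(p.bleach_cubic_coeffs, dtype=float)
    else:
        scale = float(max(t - 1, 1))
        for c in range(n):
            f0 = 100.0 * (1.0 + 0.1 * rng.random())
            drop = f0 * (0.08 + 0.04 * rng.random())
            curv = 0.3 * drop * (rng.random() - 0.5)
            # coefficients over x = t/scale, converted to frame index below
            cn = np.array([f0, -drop + curv, -curv, 0.2 * curv])
            bleach[c] = cn / scale ** np.arange(4)

    kernel, kpk = _calcium_kernel(p.kernel_rise_s, p.kernel_decay_s, fp)
    glia_kernel, gpk = _calcium_kernel(p.kernel_rise_s, p.glia_event_duration_s, fp)
    kcl_kernel, _ = _calcium_kernel(0.5, 10.0, fp)
    amp = p.amp_mean_sd_units * noise_unit
    glia_amp = 3.0 * np.e * noise_unit
    kcl_amp = p.kcl_amp_sd_units * noise_unit

    frames_idx = np.arange(t, dtype=float)
    data = np.empty((n, t))
    for c in range(n):
        sig = np.polynomial.polynomial.polyval(frames_idx, bleach[c]).astype(float)
        k, pk = (glia_kernel, gpk) if glia_mask[c] else (kernel, kpk)
        a = glia_amp if glia_mask[c] else amp
        for f in sorted(spike_frames[c]):
            _add_kernel(sig, f, a, k, pk)
        if kcl_onset is not None and viable_mask[c]:
            _add_kernel(sig, kcl_onset, kcl_amp, kcl_kernel)
        data[c] = sig
    if p.noise_sd > 0:
        data += rng.normal(0.0, p.noise_sd, size=data.shape)

    truth = GroundTruth(
        spike_frames=[np.array(sorted(set(s)), dtype=int) for s in spike_frames],
        se_frames=se_arr,
        se_participants=se_participants,
        burst_membership=burst_arr,
        bleach_poly=bleach,
        viable_mask=viable_mask,
        glia_mask=glia_mask,
        kcl_window=p.kcl_window(),
    )
    return CellTraces(data, fp), truth


def render_movie(
    traces: CellTraces,
    h: int,
    w: int,
    roi_radius: int = 3,
    background: float = 10.0,
    pixel_noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[FluorescenceMovie, list[ROI]]:
    """Paint traces into disc ROIs on a quiet background.

    Cells are placed on a jittered grid of non-overlapping discs of
    ``roi_radius`` (radius 0 = single pixel); every disc pixel carries the
    cell's trace value plus i.i.d. pixel noise, all other pixels the constant
    background plus noise.  Returns the movie and the true uniform-weight ROIs.
    """
    rng = np.random.default_rng(seed)
    n, t = traces.n_cells, traces.n_frames
    pitch = 2 * roi_radius + 3
    rows = np.arange(roi_radius + 1, h - roi_radius - 1, pitch)
    cols = np.arange(roi_radius + 1, w - roi_radius - 1, pitch)
    centers = [(int(r), int(c)) for r in rows for c in cols]
    if len(centers) < n:
        raise ValueError(f"cannot place {n} disjoint ROIs of radius {roi_radius} in {h}x{w}")
    centers = [centers[i] for i in rng.permutation(len(centers))[:n]]

    yy, xx = np.mgrid[0:h, 0:w]
    movie = np.full((t, h, w), background, dtype=float)
    rois: list[ROI] = []
    for i, (r, c) in enumerate(centers):
        disc = (yy - r) ** 2 + (xx - c) ** 2 <= roi_radius**2
        rr, cc = np.nonzero(disc)
        movie[:, rr, cc] = traces.data[i][:, None]
        rois.append(ROI(pixels=np.column_stack([rr, cc]),
                        weights=np.full(rr.size, 1.0 / rr.size)))
    if pixel_noise_sd > 0:
        movie += rng.normal(0.0, pixel_noise_sd, size=movie.shape)
    movie = np.clip(movie, 0.0, None)
    return FluorescenceMovie(movie, traces.frame_period_s), rois


@dataclass(frozen=True)
class EEGSimParams:
    """World description for the single-channel EEG simulator.

    Background is 1/f^exponent Gaussian noise of RMS ``noise_rms`` plus pure
    sinusoidal ``band_components`` (center Hz, amplitude uV).  If a seizure
    window is given, samples inside it are multiplied by ``seizure_gain`` and
    a sharp spike train at ``seizure_spike_rate_hz`` is added, emulating the
    amplitude-and-frequency jump of a kainic-acid seizure.
    """

    fs_hz: float = 500.0
    duration_s: float = 1200.0
    band_components: tuple[tuple[float, float], ...] = ((6.0, 20.0),)
    noise_exponent: float = 1.0
    noise_rms: float = 20.0
    seizure_onset_s: float | None = None
    seizure_offset_s: float | None = None
    seizure_gain: float = 3.0
    seizure_spike_rate_hz: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_components:
            fmax = max(f for f, _ in self.band_components)
            if self.fs_hz < 2.0 * fmax:
                raise ValueError(f"fs {self.fs_hz} Hz aliases a {fmax} Hz component")
        if self.seizure_onset_s is not None:
            if self.seizure_offset_s is None:
                raise ValueError("seizure onset without offset")
            if not (0 <= self.seizure_onset_s < self.seizure_offset_s <= self.duration_s):
                raise ValueError("need onset < offset <= duration")
        if self.seizure_gain < 1.0:
            raise ValueError("seizure_gain must be >= 1")


def _one_over_f_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shaping = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def generate_eeg(params: EEGSimParams) -> tuple[EEGSignal, dict]:
    """Simulate an EEG recording; returns the signal and the truth dict.

    Truth carries ``onset_s``/``offset_s`` (None when no seizure was
    generated).  Injection time is 0 s: the record starts at injection.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.fs_hz * p.duration_s))
    t = np.arange(n) / p.fs_hz
    x = np.zeros(n)
    for f0, a in p.band_components:
        x += a * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    if p.noise_rms > 0:
        x += _one_over_f_noise(n, p.noise_exponent, p.noise_rms, rng)

    truth = {"onset_s": None, "offset_s": None}
    if p.seizure_onset_s is not None:
        i0 = int(round(p.seizure_onset_s * p.fs_hz))
        i1 = int(round(p.seizure_offset_s * p.fs_hz))
        baseline_rms = float(np.sqrt(np.mean(x[:i0] ** 2))) if i0 > 0 else float(x.std())
        x[i0:i1] *= p.seizure_gain
        if p.seizure_spike_rate_hz > 0:
            # biphasic epileptiform spikes (~50 ms support, derivative of a
            # Gaussian), several-fold larger than the ongoing background
            width = 0.008
            tw = np.arange(-3 * width, 3 * width, 1.0 / p.fs_hz)
            wavelet = -tw / width * np.exp(0.5 - (tw / (np.sqrt(2) * width)) ** 2)
            spike_amp = 5.0 * p.seizure_gain * baseline_rms
            period = int(round(p.fs_hz / p.seizure_spike_rate_hz))
            for s in range(i0, i1 - wavelet.size, period):
                jit = int(rng.integers(0, max(1, period // 4)))
                stop = min(n, s + jit + wavelet.size)
                x[s + jit : stop] += spike_amp * wavelet[: stop - s - jit]
        truth = {"onset_s": float(p.seizure_onset_s), "offset_s": float(p.seizure_offset_s)}
    sig = EEGSignal(samples=x, fs_hz=p.fs_hz, injection_time_s=0.0)
    return sig, truth
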