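# Methods

This note documents the models, defaults and numerical choices behind
`casyn`, and what the synthetic-data generator does and does not emulate.

## Trace conditioning and event detection

**Smoothing.** The "band-pass" conditioning step is implemented as a
zero-phase low-pass (2nd-order Butterworth, `filtfilt`, default cutoff
0.5 Hz at the 0.328 s frame period). Only removal of high-frequency
oscillation is required before the envelope fit, and DC must survive for the
support line to track the bleaching baseline, so no high-pass edge is applied.
Filter family, order and cutoff are exposed.

**Support line.** Photobleaching is removed by the cubic *lower envelope* of
the smoothed trace: the cubic p minimizing Σ(smoothed(t) − p(t)) over included
frames subject to p(t) ≤ smoothed(t). The L1 objective keeps the problem a
linear program in the four coefficients (solved with HiGHS); at the optimum at
least one constraint is active. The LP is solved in the normalized basis
x = t/(n−1) for conditioning and the coefficients converted back exactly. The
terminal KCl window is excluded from the fit (and from everything downstream
except the viability check). The fit is equivariant under addition of any
cubic, which is what makes event detection drift-invariant.

**Baseline level and SD.** Because the support line is a *lower* envelope,
the detrended trace rides a small positive offset. The resting-F0 level is
estimated as the median of the detrended series (KCl window excluded) and its
SD robustly as 1.4826 × MAD — insensitive to the very transients being
detected. Events are maximal runs with detrended − level ≥ k·SD, k = 3 by
default (the paper-style "≥ 3-fold SD of F0" rule with the manual per-movie
threshold replaced by this deterministic estimate). Runs separated by a single
sub-threshold frame are merged (one transient dipping on noise), the event
peak is the run argmax (earliest tie), and event timestamps are peak frames
throughout the package.

## Population synchrony

PCA is computed on the cell-mean-centered detrended traces (not the binary
raster) so the PC trace has an amplitude baseline for the burst rule; each
time course is sign-oriented to non-negative skewness (calcium transients are
positive). With a KCl window present, population analysis uses only the
pre-KCl segment: the shared depolarization otherwise dominates the leading
component.

**SE component selection.** The manual matching of raster plots to PC traces
is automated: among the first 3 components, select the one whose time course
best correlates (Pearson) with the per-frame population event count. Counts
are first convolved with a causal calcium-shaped kernel (1 s decay) — the PC
trace is itself a sum of transients, so this matched filter removes the width
mismatch between single-frame peaks and multi-frame transients; without it the
correlation ceiling is ~0.73 even for perfect recordings. Correlation < 0.2
flags a movie without clear synchrony.

**SE detection.** SEs are local maxima of the PC trace ≥ 3 × its robust SD,
with peaks closer than one participation window merged. A supra-threshold
peak only counts if ≥ 20 % of viable cells have an event peak in its window:
the paper determines SE counts by *comparing* the raster with the PC trace,
and this floor is the programmatic form of that corroboration (in simulation,
true SEs have ≥ 36 % participation and coincidence artifacts ≤ 16 %, so the
default sits in a wide margin between the two populations).

**Participation and windows.** A cell participates in an SE if it has an
event peak within w = round(0.984 s / frame period) frames of the SE peak —
exactly ±3 frames at 0.328 s, matching the printed 984 ms = 3 × 328 ms. The
participation denominator is always the viable (KCl-responsive, non-glia)
cell count. Every event is synchronous (peak inside some SE window) or
asynchronous; the two counts always sum to the total.

**Bursts.** "The PC trace does not return to baseline between SEs" is
operationalized as: valley between consecutive SE peaks > 10th percentile of
the PC trace + 0.5 robust SD. Bursts are maximal chains of ≥ 2 SEs. The
threshold is exposed and validated against constructed positives/negatives.

**Summaries.** `total_events` counts all events of retained cells (sync and
async counts are emitted separately, since published "total events" labels
are ambiguous on this point). `pct_active_cells` uses the viable-cell
denominator.

## Cell extraction from movies

Movies (assumed motion-corrected) are segmented by spatiotemporal PCA/ICA:
SVD reduction to ~1.5 × the expected cell count, then ICA by skewness
maximization (fixed-point iteration, symmetric decorrelation, seeded random
init, 500-iteration cap, tol 1e-6) on the µ-weighted concatenation of spatial
and temporal principal components (µ = 0.5). Each IC's spatial filter is
z-scored, thresholded at 2.5 SD, split into connected components of ≥ 5
pixels, and de-duplicated at IoU > 0.5 (the programmatic replacement for
manual verification). Traces are weight-normalized ROI means, which makes
extraction linear in the movie.

Viability: a cell is kept iff its detrended trace exceeds 5 × baseline SD
inside the KCl window. Glia: a cell is excluded iff any event lasts strictly
more than 5 s (an event of exactly 5.0 s is kept). Masks compose before any
population statistic.

## Group statistics

**ROUT (one-sample adaptation).** Center = median; robust SD (RSDR) = 68.27th
percentile of |residuals| × n/(n−1); two-sided p per point from the t
distribution (n−1 df); sort p ascending and flag the leading block with
p(i) ≤ Q·i/n, stopping at the first failure (step-down). This is the
normative definition the tests check. On clean Gaussian data the any-flag
rate is ≈ 1 % at Q = 1 % (bounded by ~Q), and flagging is affine-equivariant.

**Mixed model.** value ~ group + (1 | animal), REML (statsmodels MixedLM).
Contrasts of each group vs control use the residual-based df
(n − groups − animals + 1); Satterthwaite df are not exposed by the backend,
and with movie-level replication the two are close. Dunnett adjustment is
Monte-Carlo: draw from the fitted contrast correlation (seeded, 100k draws by
default), t-scale with the same df, and take p = P(max|T| ≥ |t|), clamped to
be ≥ the unadjusted p so monotonicity is exact under MC noise. Degenerate
random effects (one observation per animal, singular fits) are surfaced via a
`singular` flag, never hidden. In a 2-group simulation (δ = 1, animal SD 0.5,
residual SD 0.5, 10 animals × 4 movies) the 95 % CI covers δ in ≥ 93/100
replicates with < 5 % bias.

## EEG

Epochs are consecutive 10 s windows from the injection time (trailing partial
dropped; artifact-masked epochs flagged excluded, not deleted). Power is the
Hann-windowed one-sided periodogram integrated over half-open bands
δ 0.5–4, θ 4–8, α 8–12, σ 12–16, β 16–24, γ 24–80 Hz — band edges are a
convention, not a measurement, and are fully overridable. Half-open bin
assignment makes the band powers an exact partition of the union-range power.
Because "total power" conventions differ, three totals are emitted: union of
bands, full spectrum, and 24–80 Hz. Cumulative power sums included epochs over
the 90-min default period.

Onset calls are EEG-only (no behavioral video confirmation) and labelled as
such: onset = start of the first sliding 10 s window run (≥ 10 s) with RMS ≥
2 × baseline RMS *and* median (SEF50, 1–80 Hz) frequency ≥ 2 × baseline,
offset = first subsequent window with RMS < 1.5 × baseline sustained 30 s.
The offset criterion is invented for duration reporting and flagged in the
output metadata. All criteria are ratios, so calls are invariant to global
amplitude rescaling.

## The synthetic world

`generate_traces` emulates: Poisson-timed SEs (movie-level rate, default
2/min) with normally distributed participation (mean 0.6, SD 0.1) among
viable non-glia neurons and ±1 frame jitter; optional bursts (geometric size,
1.5 s intra-burst spacing); per-cell asynchronous events (1/min); a
difference-of-exponentials calcium kernel (0.05 s rise, 1 s decay) placed so
the kernel *peak* lands on the stated event frame; per-cell cubic bleaching
(~100 fluorescence units decaying ~10 % per movie); i.i.d. Gaussian noise
(event amplitudes are specified in units of the noise SD, default 6); a
terminal KCl transient (20 SD) in viable cells; and contaminants — 5 %
non-viable cells (no activity, no KCl response) and 5 % glia whose events use
a slow kernel (amplitude 3e × noise so the supra-3SD duration matches the 6 s
default). `render_movie` paints traces into non-overlapping uniform discs on
a constant background with i.i.d. pixel noise. `generate_eeg` produces
1/f^α Gaussian background (default RMS 20 µV, α = 1) plus sinusoidal band
components (default 6 Hz, 20 µV), and optionally a seizure segment: samples
scaled by the gain (default 3) plus a train of sharp biphasic spikes (~50 ms,
5 × gain × baseline RMS, default 8/s) — sharp enough that the median
frequency genuinely doubles, as real electrographic seizures do against a 1/f
background.

Not emulated: cell-shape heterogeneity and overlapping ROIs, motion,
indicator nonlinearity and saturation, correlated (shared) noise, traveling
waves, wake/sleep EEG state changes, EKG contamination, movement artifacts
(beyond the mask mechanism). A green test therefore establishes algorithmic
correctness on the stated statistical structure, not robustness to every
failure mode of real recordings.

Defaults were chosen once to be realistic for the preparation (5-min movies
of ~100 CA3 cells at 0.328 s/frame; SE rates of a few per minute) and for
testability where the source material gives no number (e.g. control SE rates
are not printed); they were not tuned against test outcomes.

## Known limitations

- The LP support line can be degenerate when the smoothed series is exactly a
  cubic on the active set; any optimal vertex is accepted (objective is
  unique, coefficients may not be).
- Event amplitudes are reported in baseline-SD units, not ΔF/F; no
  deconvolution or spike inference is attempted.
- `select_se_component` assumes one dominant synchrony component; movies with
  two independent co-active populations will yield a low-confidence flag
  rather than two SE sets.
- The mixed model fits a single random intercept; random slopes and
  crossed designs are out of scope.
- Dunnett p-values are Monte-Carlo estimates (SE ≈ 0.0015 at 100k draws).
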