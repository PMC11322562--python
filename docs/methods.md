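# Methods

This note documents the models implemented in `petss`, the defaults and
why they were chosen, what the synthetic phantom does and does not
emulate, and the package's numerical conventions and known limitations.

## Problem setting

A dynamic PET acquisition records coincidence events from injection
onward. Unlisted into low-resolution sinograms at a working rate of
2 Hz (500 ms frames, chosen high enough to resolve breathing at
0.1–0.4 Hz while aliasing cardiac motion away from the band of
interest), the data form a five-axis array
`(radial, angle, plane, tof, time)`. Respiratory motion appears as a
coherent, quasi-periodic modulation of many bins at once —
low-dimensional structure that dimensionality reduction can find. The
difficulty specific to dynamic data is the tracer's first pass and
uptake: at early times the kinetic variance dominates the respiratory
variance by orders of magnitude, and its sharp transients even carry
spectral energy into the respiratory band.

## Preprocessing

Counts are Poisson; PCA implicitly assumes additive homoscedastic
noise. The chain, applied in order:

1. **Temporal rebinning** to the working rate by summing whole frames
   (count-conserving; non-integer frame ratios are rejected).
2. **Freeman–Tukey transform** `X ↦ √(X+1) + √X`, which stabilises the
   variance of Poisson counts to ≈ 1 (within [0.9, 1.1] for means
   5–100; this is asserted in the tests).
3. **Yeo–Johnson power transform** with a single λ for the whole array.
   λ is fitted by grid search over [−2, 2] in steps of 0.05, minimising
   the KL divergence from the empirical distribution of transformed
   values (Freedman–Diaconis histogram, capped at 512 bins) to the
   Gaussian with matched mean and variance. The divergence direction
   (empirical ‖ Gaussian) is a package choice — it is stable for heavy
   tails because empty histogram bins contribute nothing. Inputs larger
   than 200 000 values are subsampled deterministically. Both branches
   of the transform are computed via `expm1`/`log1p`, which is exact
   for the printed formulas and stays stable as λ → 0 or λ → 2.
4. **Static mask** removing the lowest 5 % of bins. The percentile is
   taken of the *time-mean* sinogram so that one mask serves every
   frame; bins strictly above the threshold are retained. Two edge
   cases are defined explicitly: percentile 0 keeps everything, and if
   the strict comparison would empty the mask (all values tied) every
   bin is retained.
5. **Gaussian smoothing** over (radial, angle, plane) with reflect
   boundaries — σ = (1.0, 0.5, 2.0) bins for PCA-based methods and
   (1.0, 3.0, 1.0) for the spectral-mask methods — followed by
   **linear-interpolation downsampling** (default: halve the radial and
   plane axes, matching the post-smoothing bandwidth). Interpolation is
   endpoint-aligned and therefore exact on constants.

The whole chain is monotone element-wise, so it preserves the ranking
of bin values. Order of operations (transforms → mask → smoothing) is
a package decision; the mask is computed on transformed data so the
percentile acts on the same scale the extraction sees.

## Extraction methods

All methods produce the trace `W_t = Σ_bins PC ⊙ S_t`. The global sign
of any trace is arbitrary; every consumer compares by |r| or aligns
signs explicitly via the full-record correlation.

**PCA.** Frames are flattened over bins, per-bin time means removed,
and the (time × bins) matrix decomposed by SVD. Components are the top
right-singular vectors — orthonormal over bins — with a deterministic
sign convention (largest-magnitude weight positive). Zero-variance bins
are excluded from the decomposition and re-inserted with weight zero.
Components beyond the numerical rank are dropped with a warning.

**Conventional selection.** Each of the top `n_components` (default
10; the number is a package choice) is scored by the mean magnitude of
the FFT of its trace inside the fixed respiratory band [0.1, 0.4) Hz,
and the best trace returned. Note this score is amplitude-*dependent*:
a huge kinetic component with modest in-band leakage can outscore a
clean but small respiratory component. That failure mode is exactly
what is observed on dynamic data.

**Spectral signed mask (SAM).** A bin joins the mask when the mean
spectral magnitude of its own time-activity curve inside the
respiratory band exceeds α (default 2) times its mean magnitude
elsewhere (DC excluded). Signs resolve breathing phase: bins are
visited in decreasing band strength, each taking the sign of its
correlation with the running mean of already-included signed curves,
seeded by the strongest bin. Weights are in {−1, 0, +1}.

**Moving window.** Window lengths are indexed by start frame;
successive windows overlap by half. Defaults: 60 s windows before the
late-time cutoff, growing linearly to 120 s at the end of the record —
short windows where kinetics are most severe, long windows late for
noise averaging. (The window-length schedule is a package default; a
schedule learned from reference traces would replace it where such
traces exist.) Each window contributes its first principal component's
trace (or the SAM trace), NaN-padded; a window's sign is flipped when
its overlap with the previous window correlates negatively; the final
window is re-anchored to the record end; the output is the NaN-ignoring
mean. Windows with degenerate content are skipped with a warning. Raw
(not z-normalised) window traces are averaged — a package choice,
configurable by normalising inside a custom engine.

**Late-time interval.** PCA over frames from `cutoff_fraction`
(default 0.62, ≈ 520 s into a 14 min record) to the end; the
best-scoring late component is applied to all frames. The rationale:
breathing is roughly stationary across the scan, so a component that
captures it late captures it early too, while the late fit window
contains no bolus to contaminate the weights.

**Score–Select–Combine (SSC).** Pipeline: late-time initial trace →
adaptive respiratory window → full-record PCA → score/select →
greedy combination → apply. The adaptive band centre is the
power-weighted mean frequency (spectral centroid) of the initial
trace's magnitude spectrum and the half-width is half the
power-weighted standard deviation, so a full standard deviation
separates the bounds; the band is clipped inside (0, Nyquist), with
kinetic = everything below and noise = everything above. (The phrase
"frequency at the mean of the PSD" admits a second reading — the
frequency where power equals the mean power; the centroid reading was
chosen as the stable one.) The frequency score is the product of the
respiratory/kinetic and respiratory/noise mean-magnitude ratios —
scale-invariant, +∞ for idealised signals with empty comparison bands.
Components scoring at or below the threshold (0 for the frequency
scorer, 0.5 for [0, 1] scorers) are dropped; the rest are sorted
descending, stably. Combination starts from the best component; each
further component is added to and subtracted from the score-weighted
running best (raw scores as weights, not re-normalised), and a
candidate is kept only when it strictly improves the score, sum branch
preferred. The ± branches make the search invariant to every input
component's sign.

**Pluggable scorer.** The interface accepts any callable trace →
[0, 1]. The shipped `FeatureScorer` is a transparent logistic function
of the log band-ratio features, mapping flat spectra to 0.5. It stands
in for learned scorers trained on clinician labels, whose weights are
not distributable; any such model can be plugged in unchanged.

## Post-processing

Order fixed: compression → outlier repair → bandpass → Savitzky–Golay.

* **Parallel compression** (two-channel): channel B is the trace
  divided by its running amplitude envelope (smoothed moving maximum of
  |x| over `envelope_window_s`, default 8 s ≈ two breathing cycles)
  raised toward unity with ratio R (gain `(e_ref/e)^(1−1/R)`, reference
  = median envelope; default R = 4), then mixed 50/50 with the
  untouched channel A. Sustained loudness differences (kinetic
  transients, drift) shrink while breath-to-breath detail survives. The
  compressor law and parameters are package decisions. Like any
  envelope follower with a centred window, it has a release transient
  of about half a window after a loud-to-quiet step.
* **Outlier repair**: samples outside the Tukey fences
  [Q1 − k·IQR, Q3 + k·IQR] (k = 1.5, a package default) are replaced by
  linear interpolation from the nearest inliers; boundary outliers take
  the nearest inlier's value. Repair is stable (idempotent) on
  realistic traces — smooth signals with sparse spikes; adversarial
  discrete inputs can shift the quartiles on repair and expose new
  outliers. A defensive guard refuses signals in which more than half
  the samples lie outside the fences (with Tukey fences this cannot
  occur; the guard protects custom fence multipliers).
* **Bandpass**: truncated sinc kernel
  `h(t) = 2B_H sinc(2B_H t) − 2B_L sinc(2B_L t)` with band
  [0.1, 0.4] Hz, sampled at the trace rate and scaled by the sampling
  interval, truncated at ±8/B_L s with a Hann taper (≤ 1 % passband
  ripple for the default band), applied by zero-phase convolution with
  reflect edges. The kernel centre value is exactly `2B_H − 2B_L`.
* **Savitzky–Golay**: order 3, window 5; reproduces cubic polynomials
  exactly.

The full chain preserves respiratory phase: zero-crossing times of a
clean in-band sinusoid shift by less than one sample end to end.

## The phantom

The simulator produces the study conditions every test runs under:
1680 frames × 500 ms (14 min) on a 64×64×16 voxel grid, forward
projected to 24 radial bins × 16 angles × 8 planes (TOF bins optional,
default 1), injection 20 s after scan start so the first ~20 s hold no
counts, and 10⁵ expected total counts in the peak-activity frame.

* **Respiration**: quasi-periodic displacement — each cycle draws its
  own period (base 0.25 Hz, 5 % jitter) and amplitude (0.5 voxels,
  5 % jitter), joined continuously at zero crossings; optional baseline
  drift and breath holds (the trace freezes at hold onset and the phase
  clock pauses). Motion is rigid axial translation of all structures,
  with sub-voxel shifts by linear interpolation.
* **Kinetics**: three tissue regions (body, liver, myocardium) with
  slow monoexponential uptake carry the respiratory signal, while a
  chain of 24 small, axially elongated "vessel" ellipsoids carries a
  sharp dispersed first-pass bolus: peak times 3 → 10 s post-injection
  along the chain (first-pass transit is genuinely seconds-sharp),
  amplitudes ~20× the tissue plateau decaying along the path. The
  axial elongation keeps the vessels' plane-direction projection
  gradients weak, so the chain contributes the dominant *kinetic*
  variance but little *respiratory* variance. This reproduces the
  regime dynamic acquisitions are in: early kinetic variance dominates,
  kinetic spectral leakage reaches into the fixed respiratory band, and
  whole-record PCA selection fails while late-time and adaptive-band
  methods do not.
* **Projector**: nearest-neighbour ray summation via a precomputed
  sparse matrix; TOF bins split counts along the ray with a Gaussian
  profile normalised across bins. Counts are Poisson draws around the
  scaled projections; a noise-free mode returns the means.

Ground truth (`PhantomTruth`) carries the injected breathing trace
exactly, the per-region activity curves, and the time of first counts.
Fixed seeds give bit-identical output.

What the phantom does **not** emulate: attenuation, scatter, randoms,
detector geometry and normalisation, non-rigid deformation, hysteresis,
cardiac motion, and spatially continuous kinetic heterogeneity beyond
the discrete region set. Passing tests therefore demonstrate the
algorithmic behaviour of the methods under controlled conditions — the
failure of amplitude-based selection under kinetic dominance, the value
of late-window fitting and adaptive bands — not clinical performance on
patient data.

## The standard bank and evaluation

The evaluation harness mirrors how such methods are assessed against an
external tracking device: Pearson correlation over the usable record
(20–840 s), over the first usable 120 s (20–140 s), and in contiguous
20 s bins, with the trace's global sign aligned to the reference using
the full-record correlation before any interval is reported (the
alignment rule is a package choice; correlations are computed on the
post-processed traces by default, configurable). The standard bank is
five phantoms with base breathing rates spread over 0.24–0.30 Hz and
distinct seeds; on it the methods reproduce the expected hierarchy —
conventional PCA near zero early, moving-window intermediate, late-time
and SSC high from the first usable frames, with the [0, 1]-scorer SSC
variant marginally ahead of the frequency-scored one.

## Numerical conventions and degenerate inputs

* Frequency bands are half-open `[lo, hi)`; adjacent windows are
  disjoint by construction.
* Spectra are one-sided magnitude spectra (|FFT| of the mean-removed
  trace); NaN padding is dropped before the FFT.
* The adaptive band falls back to the fixed defaults, with a warning,
  when the spectrum is degenerate (no power, or a collapsed band).
* Constant series, all-zero masks, empty selections, too-short late
  windows, and non-integer rebinning ratios raise typed errors
  (`DegenerateInputError`, `NoCandidateError`, `ParameterError`).
* Ties: component selection keeps original order on equal scores; the
  combination prefers the sum branch on equal improvement.
* All randomness flows from explicit integer seeds; the full pipeline
  is bit-deterministic for a fixed configuration.

## Known limitations

* The frequency score measures band-energy ratios, not fidelity to any
  reference: when respiratory energy is split across components with
  strongly different temporal envelopes, a combination step guided by
  the score alone can prefer a mixture that a reference-based measure
  would rank lower. The adaptive band mitigates but does not remove
  this.
* The moving-window sign chain has no global anchor: one degenerate
  window can flip the alignment of everything after it. The average
  across overlapping windows limits, but does not eliminate, the
  damage.
* Slow breathers near or below the kinetic band remain ambiguous for
  any band-ratio score; with the fixed band they are misclassified as
  kinetics, and with the adaptive band a noisy initial estimate widens
  the window into kinetic territory.
* `remove_outliers` idempotence holds for sparse-outlier signals, not
  for adversarial discrete inputs (see above).
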