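# petss — respiratory surrogate signals from dynamic PET

Respiratory motion blurs PET images and distorts quantification, so
reconstruction pipelines gate or correct the data using a 1-D
**surrogate signal (SS)** that tracks the breathing cycle. On *static*
acquisitions the signal can be extracted directly from the data:
principal component analysis (PCA) of a time series of low-resolution
sinograms finds motion as the dominant coherent variation. On *dynamic*
acquisitions — tracer injected after the scan starts — this breaks
down, because the rapid redistribution of activity through the
circulation creates kinetic variance that dwarfs the respiratory
variance at early times.

`petss` implements a family of extraction methods that remain usable on
dynamic data, together with everything needed to exercise them without
patient data: a phantom simulator with known ground truth, the
Gaussianising preprocessing chain, trace post-processing, and a
correlation-based evaluation harness.

## Methods

Every method builds on the same primitive. Given a component `PC` (a
weight map over sinogram bins) and the sinogram series `S`, the
candidate trace is

```
W_t = Σ_bins  PC ⊙ S_t
```

* **Conventional PCA** (`ConventionalPCAExtractor`) — SVD of the whole
  record; keeps the component whose trace maximises the mean spectral
  magnitude inside the respiratory band (0.1–0.4 Hz). Fails on dynamic
  data when a kinetic component's sheer amplitude wins the selection.
* **Moving window** (`MovingWindowExtractor`) — PCA (or the spectral
  signed-mask method, SAM) inside half-overlapping windows; window signs
  are chained by correlating overlaps and the NaN-padded traces
  averaged.
* **Late-time interval** (`LateTimeExtractor`) — PCA only on the frames
  after a cutoff (default 62 % of the scan) where kinetics have
  settled; the winning component is applied to *all* frames.
* **Score–Select–Combine** (`ScoreSelectCombineExtractor`) — scores all
  components of a full-record PCA with the kinetics-aware ratio score

  ```
  score = (resp / kinetic) × (resp / noise)      (mean band magnitudes)
  ```

  inside a respiratory band estimated adaptively (spectral centroid ±
  half a spectral standard deviation of a late-time initial trace),
  drops weak components, and greedily sums/subtracts score-weighted
  components while the score strictly improves. A pluggable scorer
  interface accepts any callable mapping a trace to [0, 1]; a
  transparent logistic stand-in is provided.

Preprocessing (`SinogramPreprocessor`) rebins to 2 Hz, applies the
Freeman–Tukey transform `X ↦ √(X+1) + √X` and a Yeo–Johnson power
transform with λ fitted by KL-divergence grid search, masks the lowest
5 % of bins, and smooths/downsamples spatially. Post-processing
(`TracePostprocessor`) applies parallel compression, quartile outlier
repair, a truncated-sinc bandpass `h(t) = 2B_H sinc(2B_H t) −
2B_L sinc(2B_L t)`, and Savitzky–Golay smoothing (order 3, window 5).

## Worked example

```python
import warnings
from petss import (PhantomConfig, generate_phantom, preprocess,
                   conventional_extract, late_time_extract, ssc_extract,
                   postprocess, align_and_correlate)

config = PhantomConfig(seed=42)          # 14 min dynamic scan, injection at 20 s
series, truth = generate_phantom(config)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    processed = preprocess(series)
    for name, extract in [("conventional PCA", conventional_extract),
                          ("late-time PC", late_time_extract),
                          ("score-select-combine", ssc_extract)]:
        trace = postprocess(extract(processed))
        r_early = align_and_correlate(trace, truth.resp_trace, 20, 140)
        r_full = align_and_correlate(trace, truth.resp_trace, 20, 840)
        print(f"{name:22s} |r| 20-140 s: {abs(r_early):.3f}   "
              f"|r| 20-840 s: {abs(r_full):.3f}")
```

prints

```
conventional PCA       |r| 20-140 s: 0.141   |r| 20-840 s: 0.057
late-time PC           |r| 20-140 s: 0.885   |r| 20-840 s: 0.976
score-select-combine   |r| 20-140 s: 0.872   |r| 20-840 s: 0.974
```

The numbers are Pearson correlations (after sign alignment — an
extracted trace's polarity is arbitrary) between each cleaned trace and
the phantom's ground-truth breathing, over the first usable 120 s and
over the whole usable record. Conventional PCA selects a
kinetics-dominated component and fails; the late-time and
score-select-combine methods recover the breathing trace from the first
frames with counts.

A command-line interface mirrors the library:

```bash
petss simulate --seed 1 --out sino.h5 --truth-out truth.csv
petss preprocess sino.h5 proc.h5
petss extract --method ssc_freq proc.h5 trace.csv
petss postprocess trace.csv clean.csv
petss evaluate clean.csv truth.csv --out report.json
petss run-all --seed 1 --outdir results/
```

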