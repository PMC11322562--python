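"""Surrogate-signal extraction from preprocessed sinogram time series.

Four families of methods are implemented, all built on the same
primitive: a component (a principal-component weight map, or a signed
spectral mask) is multiplied element-wise with every sinogram frame and
summed, ``W_t = sum_bins(PC * S_t)``, yielding a 1-D candidate trace.

* **Conventional PCA** decomposes the whole series at once and keeps the
  component whose trace has the largest mean spectral magnitude inside
  the respiratory frequency band. On dynamic data this fails early in
  the scan, where tracer-kinetic variance dominates.
* **Moving window** runs PCA (or the spectral-analysis signed mask)
  inside half-overlapping windows, chains window signs by correlating
  overlaps, and averages the NaN-padded window traces.
* **Late-time interval** decomposes only the frames after a cutoff
  (default 62% of the scan), where kinetics have settled, and applies
  the winning late component to *all* frames.
* **Score-Select-Combine (SSC)** scores every component of a full-series
  decomposition with a kinetics-aware respiratory score, drops weak
  ones, and greedily sums/subtracts score-weighted components while the
  score keeps improving. The respiratory band is estimated adaptively
  from a late-time initial trace (spectral centroid +/- half a spectral
  standard deviation).

Every trace has an arbitrary global sign; downstream consumers compare
by |r| or align signs explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    Component,
    DegenerateInputError,
    FrequencyWindows,
    ParameterError,
    SinogramSeries,
    SurrogateSignal,
)

logger = logging.getLogger(__name__)

DEFAULT_RESP_WINDOW = (0.1, 0.4)


class NoCandidateError(ValueError):
    """No component survives scoring/selection."""


# --------------------------------------------------------------------------
# spectra and scores
# --------------------------------------------------------------------------

@dataclass
class PSD:
    """One-sided magnitude spectrum on [0, Nyquist]."""

    freqs: np.ndarray
    power: np.ndarray

    def band_mean(self, lo: float, hi: float) -> float:
        """Mean magnitude over the half-open band [lo, hi)."""
        sel = (self.freqs >= lo) & (self.freqs < hi)
        if not sel.any():
            raise ParameterError(f"band [{lo}, {hi}) contains no frequency bin")
        return float(self.power[sel].mean())


def compute_psd(signal: SurrogateSignal) -> PSD:
    """Magnitude of the FFT of the mean-removed trace (one-sided).

    NaN samples (moving-window padding) are dropped before the FFT.
    """
    x = signal.values[np.isfinite(signal.values)]
    if x.size < 8:
        raise ParameterError("need at least 8 finite samples for a PSD")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / signal.sampling_hz)
    return PSD(freqs=freqs, power=power)


def conventional_score(
    signal: SurrogateSignal, window: tuple[float, float] = DEFAULT_RESP_WINDOW
) -> float:
    """Mean spectral magnitude inside the respiratory band."""
    lo, hi = window
    if not (0 <= lo < hi <= signal.sampling_hz / 2 + 1e-12):
        raise ParameterError("respiratory window outside [0, Nyquist]")
    return compute_psd(signal).band_mean(lo, hi)


def frequency_score(signal: SurrogateSignal, windows: FrequencyWindows) -> float:
    """(resp / kinetic) * (resp / noise) mean-magnitude ratio product.

    Amplitude-invariant by construction; returns +inf when the kinetic
    or noise band is exactly empty of power (an idealised signal).
    """
    psd = compute_psd(signal)
    kin = psd.band_mean(*windows.kinetic)
    resp = psd.band_mean(*windows.respiratory)
    noi = psd.band_mean(*windows.noise)
    if kin == 0.0 or noi == 0.0:
        return float("inf")
    return (resp / kin) * (resp / noi)


class FeatureScorer:
    """Transparent stand-in for a learned [0, 1] signal scorer.

    A logistic function of the log band-magnitude ratios (the same
    features the frequency score multiplies): flat spectra map to 0.5,
    respiratory-dominated spectra toward 1, kinetic- or noise-dominated
    spectra toward 0. Any callable mapping a trace to [0, 1] can be
    plugged in instead.
    """

    def __init__(self, windows: FrequencyWindows, gain: float = 0.5):
        self.windows = windows
        self.gain = gain

    def __call__(self, signal: SurrogateSignal) -> float:
        score = frequency_score(signal, self.windows)
        if score == 0.0:
            return 0.0
        if not np.isfinite(score):
            return 1.0
        return float(1.0 / (1.0 + np.exp(-self.gain * np.log(score))))


def estimate_resp_window(
    initial: SurrogateSignal,
    fallback: FrequencyWindows | None = None,
) -> FrequencyWindows:
    """Adaptive respiratory band from an initial trace estimate.

    The band centre is the power-weighted mean frequency (spectral
    centroid) of the trace's PSD; the half-width is half the
    power-weighted standard deviation, so a full standard deviation
    separates the bounds. The kinetic band is everything below, the
    noise band everything above, up to Nyquist.
    """
    fallback = fallback or FrequencyWindows()
    if len(initial) < 64:
        raise ParameterError("need >= 64 samples to estimate the band")
    psd = compute_psd(initial)
    total = psd.power.sum()
    nyq = signal_nyquist = initial.sampling_hz / 2.0
    df = psd.freqs[1] if len(psd.freqs) > 1 else 0.0
    if total <= 0 or df == 0.0:
        warnings.warn("degenerate spectrum; falling back to default windows")
        return fallback
    centre = float((psd.freqs * psd.power).sum() / total)
    std = float(np.sqrt(((psd.freqs - centre) ** 2 * psd.power).sum() / total))
    hw = 0.5 * std
    lo = max(centre - hw, df)
    hi = min(centre + hw, nyq - df)
    if hi <= lo:
        warnings.warn("estimated band collapsed; falling back to defaults")
        return fallback
    return FrequencyWindows(kinetic=(0.0, lo), respiratory=(lo, hi), noise=(hi, nyq))


# --------------------------------------------------------------------------
# decomposition primitives
# --------------------------------------------------------------------------

def pca_decompose(
    series: SinogramSeries, n_components: int = 10
) -> list[Component]:
    """Principal components of the (time x bins) matrix via SVD.

    Per-bin time means are removed; components are the top right-singular
    vectors (mutually orthonormal over the bins). Sign convention: the
    largest-magnitude weight of each component is made positive, so the
    decomposition is deterministic.
    """
    if series.n_frames < 2:
        raise ParameterError("need at least 2 frames for PCA")
    X = series.as_matrix()
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise DegenerateInputError("constant series: PCA is undefined")
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            f"returning {k}"
        )
    comps = []
    for i in range(k):
        w = np.zeros(X.shape[1])
        w[keep] = Vt[i]
        w *= np.sign(w[np.argmax(np.abs(w))]) or 1.0
        comps.append(
            Component(
                weights=w.reshape(series.spatial_shape),
                origin="pca",
                time_support=(0, series.n_frames),
            )
        )
    return comps


def apply_component(component: Component, series: SinogramSeries) -> SurrogateSignal:
    """W_t = sum_bins(PC * S_t): project each frame onto the component."""
    if component.weights.shape != series.spatial_shape:
        raise ParameterError(
            f"component shape {component.weights.shape} does not match "
            f"series spatial shape {series.spatial_shape}"
        )
    values = np.tensordot(component.weights, series.data, axes=4)
    return SurrogateSignal(
        values,
        sampling_hz=series.sampling_hz,
        start_time_s=series.start_time_s + 0.5 * series.frame_duration_s,
    )


def sam_signed_mask(
    series: SinogramSeries,
    resp_window: tuple[float, float] = DEFAULT_RESP_WINDOW,
    alpha: float = 2.0,
) -> Component:
    """Signed spectral mask: bins with a respiratory-band spectral peak.

    A bin is included when the mean spectral magnitude of its TAC inside
    the respiratory band exceeds ``alpha`` times its mean magnitude
    elsewhere (DC excluded). Signs resolve the breathing phase: the
    strongest bin seeds the reference, and each further bin (in
    decreasing band-strength order) takes the sign of its correlation
    with the running mean of already-included signed TACs.
    """
    if series.n_frames < 64:
        raise ParameterError("need >= 64 frames for the spectral mask")
    X = series.as_matrix()
    Xc = X - X.mean(axis=0)
    F = np.abs(np.fft.rfft(Xc, axis=0))
    freqs = np.fft.rfftfreq(series.n_frames, d=series.frame_duration_s)
    lo, hi = resp_window
    in_band = (freqs >= lo) & (freqs < hi)
    out_band = ~in_band & (freqs > 0)
    if not in_band.any() or not out_band.any():
        raise ParameterError("respiratory window leaves an empty band")
    band_power = F[in_band].mean(axis=0)
    rest_power = F[out_band].mean(axis=0)
    include = band_power > alpha * rest_power
    if not include.any():
        raise DegenerateInputError("no bin passes the spectral criterion")

    order = np.argsort(band_power)[::-1]
    order = order[include[order]]
    signs = np.zeros(X.shape[1])
    ref = Xc[:, order[0]].copy()
    signs[order[0]] = 1.0
    n_ref = 1
    for b in order[1:]:
        tac = Xc[:, b]
        c = float(tac @ (ref / n_ref))
        s = 1.0 if c >= 0 else -1.0
        signs[b] = s
        ref += s * tac
        n_ref += 1
    return Component(
        weights=signs.reshape(series.spatial_shape),
        origin="sam",
        time_support=(0, series.n_frames),
    )


# --------------------------------------------------------------------------
# moving window
# --------------------------------------------------------------------------

@dataclass
class WindowSchedule:
    """Window length (frames) indexed by window start frame.

    Successive windows overlap by half their length. The default
    schedule uses short windows before the late-time cutoff (where
    kinetics are most severe) growing linearly to longer windows at the
    end of the scan.
    """

    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int).ravel()
        if self.sizes.min(initial=4) < 4:
            raise ParameterError("every window must span >= 4 samples")

    def size_at(self, index: int) -> int:
        return int(self.sizes[min(index, len(self.sizes) - 1)])

    @classmethod
    def default(
        cls,
        n_frames: int,
        sampling_hz: float = 2.0,
        early_s: float = 60.0,
        late_s: float = 120.0,
        cutoff_fraction: float = 0.62,
    ) -> "WindowSchedule":
        early = max(int(round(early_s * sampling_hz)), 8)
        late = max(int(round(late_s * sampling_hz)), early)
        cut = int(cutoff_fraction * n_frames)
        sizes = np.full(n_frames, early)
        if cut < n_frames - 1:
            ramp = np.linspace(early, late, n_frames - cut)
            sizes[cut:] = np.round(ramp).astype(int)
        sizes = np.minimum(sizes, max(n_frames, 8))
        return cls(sizes)


def _window_engine(engine, resp_window):
    """Resolve the per-window signal extractor to a callable."""
    if callable(engine):
        return engine
    if engine == "pca":
        def pca_first(window: SinogramSeries) -> np.ndarray:
            comp = pca_decompose(window, n_components=1)[0]
            return apply_component(comp, window).values
        return pca_first
    if engine == "sam":
        def sam_signal(window: SinogramSeries) -> np.ndarray:
            comp = sam_signed_mask(window, resp_window=resp_window)
            return apply_component(comp, window).values
        return sam_signal
    raise ParameterError(f"unknown engine {engine!r}")


def _slice_series(series: SinogramSeries, start: int, stop: int) -> SinogramSeries:
    out = series.with_data(series.data[..., start:stop])
    out.start_time_s = series.start_time_s + start * series.frame_duration_s
    return out


def moving_window_extract(
    series: SinogramSeries,
    schedule: WindowSchedule | None = None,
    engine="pca",
    resp_window: tuple[float, float] = DEFAULT_RESP_WINDOW,
) -> SurrogateSignal:
    """Half-overlapping windowed extraction with sign chaining.

    Each window contributes its first principal component's trace (or
    the spectral-mask trace), NaN-padded to the full record. A window's
    sign is flipped when its overlap with the previous window's trace
    correlates negatively. The final window is re-anchored to the end of
    the record, and the output is the NaN-ignoring mean of all padded
    window traces.
    """
    n = series.n_frames
    schedule = schedule or WindowSchedule.default(n, series.sampling_hz)
    extract_fn = _window_engine(engine, resp_window)

    signals: list[np.ndarray] = []
    index = 0
    running = True
    while running:
        wsize = min(schedule.size_at(index), n)
        if wsize < 8:
            raise ParameterError("every moving window needs >= 8 frames")
        if index + wsize >= n:
            index = n - wsize
            running = False
        padded = np.full(n, np.nan)
        window = _slice_series(series, index, index + wsize)
        try:
            padded[index : index + wsize] = extract_fn(window)
        except (DegenerateInputError, ParameterError) as exc:
            warnings.warn(f"window at frame {index} skipped: {exc}")
            index += max(wsize // 2, 1)
            continue
        if signals:
            prev = signals[-1]
            both = np.isfinite(padded) & np.isfinite(prev)
            if both.sum() >= 2:
                a, b = padded[both], prev[both]
                if a.std() > 0 and b.std() > 0:
                    if np.corrcoef(a, b)[0, 1] < 0.0:
                        padded = -padded
        signals.append(padded)
        index += max(wsize // 2, 1)

    if not signals:
        raise DegenerateInputError("no usable window in the series")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        values = np.nanmean(np.vstack(signals), axis=0)
    return SurrogateSignal(
        values,
        sampling_hz=series.sampling_hz,
        start_time_s=series.start_time_s + 0.5 * series.frame_duration_s,
    )


# --------------------------------------------------------------------------
# selection and combination
# --------------------------------------------------------------------------

def score_select(
    components: list[Component],
    series: SinogramSeries,
    scorer,
    threshold: float = 0.0,
) -> list[Component]:
    """Score components on their traces, drop weak ones, sort descending.

    A component is kept only when its score is strictly greater than the
    threshold. Ties keep their original order (stable sort).
    """
    scored = []
    for i, comp in enumerate(components):
        score = float(scorer(apply_component(comp, series)))
        comp.score = score
        if score > threshold:
            scored.append((i, comp))
    if not scored:
        raise NoCandidateError(
            f"no component scores above the threshold {threshold}"
        )
    scored.sort(key=lambda pair: -pair[1].score)  # stable: ties by index
    return [comp for _, comp in scored]


def combine(
    components: list[Component], series: SinogramSeries, scorer
) -> Component:
    """Greedy score-weighted combination of sorted components.

    Starting from the best-scoring component, each further component is
    both added to and subtracted from the score-weighted running best;
    a candidate replaces the running best only when it strictly improves
    the score, with the sum branch preferred on ties. The +/- branches
    make the search invariant to every input component's sign.
    """
    if not components:
        raise NoCandidateError("nothing to combine")
    best = components[0]
    best_score = (
        best.score
        if best.score is not None
        else float(scorer(apply_component(best, series)))
    )
    for nxt in components[1:]:
        nxt_score = (
            nxt.score
            if nxt.score is not None
            else float(scorer(apply_component(nxt, series)))
        )
        scaled_best = best.weights * best_score
        scaled_next = nxt.weights * nxt_score
        for cand_weights in (scaled_best + scaled_next, scaled_best - scaled_next):
            if not np.any(cand_weights):
                continue
            cand = Component(
                weights=cand_weights, origin=best.origin,
                time_support=best.time_support,
            )
            cand_score = float(scorer(apply_component(cand, series)))
            if cand_score > best_score:
                cand.score = cand_score
                best, best_score = cand, cand_score
                break  # sum branch preferred; do not also try subtract
    best.score = best_score
    return best


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class _BaseExtractor(BaseEstimator, TransformerMixin):
    """Shared plumbing: accept a SinogramSeries or a (time, bins) array."""

    frame_duration_s = 0.5

    def _as_series(self, X) -> SinogramSeries:
        if isinstance(X, SinogramSeries):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # (time, bins)
            data = X.T.reshape(X.shape[1], 1, 1, 1, X.shape[0])
            return SinogramSeries(
                data, frame_duration_s=self.frame_duration_s, transformed=True
            )
        if X.ndim == 5:
            return SinogramSeries(
                X, frame_duration_s=self.frame_duration_s, transformed=True
            )
        raise ParameterError("expected a SinogramSeries, 2-D or 5-D array")

    def transform(self, X) -> np.ndarray:
        return self.extract(self._as_series(X)).values

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y).transform(X)


class ConventionalPCAExtractor(_BaseExtractor):
    """Whole-record PCA; keeps the best respiratory-band component.

    Fitted attributes: ``components_`` (all candidates), ``scores_``
    (their respiratory-band scores) and ``component_`` (the winner).
    """

    def __init__(
        self,
        n_components: int = 10,
        resp_window: tuple[float, float] = DEFAULT_RESP_WINDOW,
    ):
        self.n_components = n_components
        self.resp_window = resp_window

    def fit(self, X, y=None) -> "ConventionalPCAExtractor":
        series = self._as_series(X)
        self.components_ = pca_decompose(series, self.n_components)
        self.scores_ = np.array(
            [
                conventional_score(apply_component(c, series), self.resp_window)
                for c in self.components_
            ]
        )
        best = int(np.argmax(self.scores_))
        self.component_ = self.components_[best]
        self.component_.score = float(self.scores_[best])
        return self

    def extract(self, series: SinogramSeries) -> SurrogateSignal:
        if not hasattr(self, "component_"):
            self.fit(series)
        return apply_component(self.component_, series)


class MovingWindowExtractor(_BaseExtractor):
    """Half-overlapping windowed PCA/SAM with sign chaining."""

    def __init__(
        self,
        engine: str = "pca",
        schedule: WindowSchedule | None = None,
        resp_window: tuple[float, float] = DEFAULT_RESP_WINDOW,
    ):
        self.engine = engine
        self.schedule = schedule
        self.resp_window = resp_window

    def fit(self, X, y=None) -> "MovingWindowExtractor":
        self.n_frames_in_ = self._as_series(X).n_frames
        return self

    def extract(self, series: SinogramSeries) -> SurrogateSignal:
        return moving_window_extract(
            series, schedule=self.schedule, engine=self.engine,
            resp_window=self.resp_window,
        )


class LateTimeExtractor(_BaseExtractor):
    """PCA on the late, kinetics-free interval; applied to all frames."""

    def __init__(
        self,
        cutoff_fraction: float = 0.62,
        n_components: int = 10,
        resp_window: tuple[float, float] = DEFAULT_RESP_WINDOW,
        min_late_frames: int = 64,
    ):
        self.cutoff_fraction = cutoff_fraction
        self.n_components = n_components
        self.resp_window = resp_window
        self.min_late_frames = min_late_frames

    def fit(self, X, y=None) -> "LateTimeExtractor":
        series = self._as_series(X)
        if not (0.0 <= self.cutoff_fraction < 1.0):
            raise ParameterError("cutoff_fraction must lie in [0, 1)")
        n = series.n_frames
        start = int(np.floor(self.cutoff_fraction * n))
        if n - start < self.min_late_frames:
            raise ParameterError(
                f"late interval has {n - start} frames; "
                f"need >= {self.min_late_frames}"
            )
        late = _slice_series(series, start, n)
        comps = pca_decompose(late, self.n_components)
        scores = [
            conventional_score(apply_component(c, late), self.resp_window)
            for c in comps
        ]
        best = int(np.argmax(scores))
        self.component_ = comps[best]
        self.component_.time_support = (start, n)
        self.component_.score = float(scores[best])
        self.cutoff_frame_ = start
        return self

    def extract(self, series: SinogramSeries) -> SurrogateSignal:
        if not hasattr(self, "component_"):
            self.fit(series)
        return apply_component(self.component_, series)


class ScoreSelectCombineExtractor(_BaseExtractor):
    """Score, select and combine components of a full-record PCA.

    The respiratory band is estimated from a late-time initial trace;
    components are scored (frequency score, or any callable mapping a
    trace to [0, 1]), thresholded, sorted, and greedily combined with
    score weights while the score strictly improves.
    """

    def __init__(
        self,
        scorer="frequency",
        n_components: int = 10,
        cutoff_fraction: float = 0.62,
        threshold: float | None = None,
        windows: FrequencyWindows | None = None,
    ):
        self.scorer = scorer
        self.n_components = n_components
        self.cutoff_fraction = cutoff_fraction
        self.threshold = threshold
        self.windows = windows

    def _resolve_scorer(self, windows: FrequencyWindows):
        if callable(self.scorer):
            return self.scorer, (0.5 if self.threshold is None else self.threshold)
        if self.scorer == "frequency":
            return (
                lambda sig: frequency_score(sig, windows),
                0.0 if self.threshold is None else self.threshold,
            )
        if self.scorer == "pluggable":
            return (
                FeatureScorer(windows),
                0.5 if self.threshold is None else self.threshold,
            )
        raise ParameterError(f"unknown scorer {self.scorer!r}")

    def fit(self, X, y=None) -> "ScoreSelectCombineExtractor":
        series = self._as_series(X)
        if self.windows is not None:
            self.windows_ = self.windows
        else:
            initial = LateTimeExtractor(
                cutoff_fraction=self.cutoff_fraction,
                n_components=self.n_components,
            ).extract(series)
            self.windows_ = estimate_resp_window(initial)
        scorer_fn, threshold = self._resolve_scorer(self.windows_)
        comps = pca_decompose(series, self.n_components)
        self.selected_ = score_select(comps, series, scorer_fn, threshold)
        self.component_ = combine(self.selected_, series, scorer_fn)
        logger.info(
            "ssc: band=[%.3f, %.3f] Hz, %d/%d selected, final score %.3g",
            *self.windows_.respiratory, len(self.selected_), len(comps),
            self.component_.score,
        )
        return self

    def extract(self, series: SinogramSeries) -> SurrogateSignal:
        if not hasattr(self, "component_"):
            self.fit(series)
        return apply_component(self.component_, series)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def conventional_extract(series: SinogramSeries, **params) -> SurrogateSignal:
    return ConventionalPCAExtractor(**params).fit(series).extract(series)


def late_time_extract(
    series: SinogramSeries, cutoff_fraction: float = 0.62, **params
) -> SurrogateSignal:
    est = LateTimeExtractor(cutoff_fraction=cutoff_fraction, **params)
    return est.fit(series).extract(series)


def ssc_extract(series: SinogramSeries, **params) -> SurrogateSignal:
    return ScoreSelectCombineExtractor(**params).fit(series).extract(series)
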