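"""Cleaning of extracted respiratory traces.

The raw trace from any extraction method still carries residual
tracer-kinetic amplitude swings, momentary spikes, and broadband noise.
The chain applied here, in order:

1. **parallel compression** — an audio-engineering trick: the trace is
   split into two channels, one is dynamic-range compressed against its
   running amplitude envelope, and the two are averaged back together.
   Large slow amplitude differences (kinetics, drift) shrink while
   breath-to-breath detail survives in the uncompressed channel;
2. **quartile outlier removal** — samples outside the Tukey fences
   ``[Q1 - k*IQR, Q3 + k*IQR]`` are replaced by linear interpolation
   from the nearest inliers;
3. **bandpass filtering** with a truncated, Hann-tapered sinc kernel
   ``h(t) = 2*B_H*sinc(2*B_H*t) - 2*B_L*sinc(2*B_L*t)``, zero-phase by
   symmetry, reflect edge handling;
4. **Savitzky-Golay smoothing** (order 3, window 5) for local
   smoothness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter

from .containers import DegenerateInputError, ParameterError, SurrogateSignal

logger = logging.getLogger(__name__)


@dataclass
class CompressorParams:
    """Two-channel parallel compressor settings.

    ``envelope_window_s`` is the running-maximum window used to estimate
    the amplitude envelope (a few breathing cycles); ``compression_ratio``
    R maps envelope excursions e to ``e**(1/R)`` relative to the median
    envelope, so R -> inf flattens the compressed channel's envelope
    completely; ``mix`` is the fraction of the compressed channel in the
    output average.
    """

    envelope_window_s: float = 8.0
    compression_ratio: float = 4.0
    mix: float = 0.5

    def __post_init__(self) -> None:
        if self.compression_ratio < 1.0:
            raise ParameterError("compression_ratio must be >= 1")
        if not (0.0 <= self.mix <= 1.0):
            raise ParameterError("mix must lie in [0, 1]")
        if self.envelope_window_s <= 0:
            raise ParameterError("envelope_window_s must be positive")


@dataclass
class BandpassParams:
    """Sinc band edges (Hz) and kernel truncation."""

    B_L: float = 0.1
    B_H: float = 0.4
    kernel_halfwidth_s: float | None = None  # default 8 / B_L

    def __post_init__(self) -> None:
        if not (0.0 < self.B_L < self.B_H):
            raise ParameterError("need 0 < B_L < B_H")

    @property
    def halfwidth_s(self) -> float:
        return (
            self.kernel_halfwidth_s
            if self.kernel_halfwidth_s is not None
            else 8.0 / self.B_L
        )


def _envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Running amplitude envelope: smoothed moving max of |x|."""
    env = ndimage.maximum_filter1d(np.abs(x), size=window, mode="reflect")
    return ndimage.uniform_filter1d(env, size=window, mode="reflect")


def parallel_compression(
    signal: SurrogateSignal, params: CompressorParams | None = None
) -> SurrogateSignal:
    """Mix a dynamic-range-compressed copy with the original trace."""
    params = params or CompressorParams()
    x = signal.values
    if x.size == 0:
        raise ParameterError("zero-length signal")
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal must be finite for compression")
    if not np.any(x):
        return SurrogateSignal(
            x.copy(), signal.sampling_hz, signal.start_time_s,
            signal.sign_arbitrary,
        )
    window = max(int(round(params.envelope_window_s * signal.sampling_hz)), 1)
    env = _envelope(x, window)
    ref = np.median(env)
    floor = 1e-12 * max(env.max(), 1.0)
    gain = (ref / np.maximum(env, floor)) ** (1.0 - 1.0 / params.compression_ratio)
    compressed = x * gain
    out = params.mix * compressed + (1.0 - params.mix) * x
    return SurrogateSignal(
        out, signal.sampling_hz, signal.start_time_s, signal.sign_arbitrary
    )


def remove_outliers(signal: SurrogateSignal, k: float = 1.5) -> SurrogateSignal:
    """Replace samples outside the Tukey fences by linear interpolation.

    Outliers at the record boundaries take the nearest inlier's value.
    Refuses to repair a signal in which more than half the samples are
    outliers. Idempotent: fences recomputed on the repaired signal
    contain every sample.
    """
    x = signal.values
    if x.size < 4:
        raise ParameterError("need at least 4 samples for quartile fences")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    inlier = (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
    n_out = int((~inlier).sum())
    if n_out > 0.5 * x.size:
        raise DegenerateInputError(
            f"{n_out}/{x.size} samples are outliers; signal unusable"
        )
    if n_out == 0:
        repaired = x.copy()
    else:
        idx = np.arange(x.size)
        repaired = x.copy()
        repaired[~inlier] = np.interp(idx[~inlier], idx[inlier], x[inlier])
    return SurrogateSignal(
        repaired, signal.sampling_hz, signal.start_time_s, signal.sign_arbitrary
    )


def bandpass_kernel(params: BandpassParams, sampling_hz: float) -> np.ndarray:
    """Truncated, Hann-tapered sinc bandpass kernel sampled at the rate.

    The untapered kernel is ``2*B_H*sinc(2*B_H*t) - 2*B_L*sinc(2*B_L*t)``
    (exactly ``2*B_H - 2*B_L`` at t = 0); samples are scaled by the
    sampling interval so discrete convolution approximates the continuous
    filter with unit passband gain.
    """
    if params.B_H > sampling_hz / 2 + 1e-12:
        raise ParameterError("upper band edge exceeds Nyquist")
    dt = 1.0 / sampling_hz
    half = int(round(params.halfwidth_s * sampling_hz))
    t = np.arange(-half, half + 1) * dt
    h = 2 * params.B_H * np.sinc(2 * params.B_H * t) - 2 * params.B_L * np.sinc(
        2 * params.B_L * t
    )
    taper = np.hanning(t.size + 2)[1:-1]  # nonzero at the kernel ends
    return h * taper


def bandpass(
    signal: SurrogateSignal, params: BandpassParams | None = None
) -> SurrogateSignal:
    """Zero-phase convolution with the truncated sinc kernel (reflect edges)."""
    params = params or BandpassParams()
    kernel = bandpass_kernel(params, signal.sampling_hz) / signal.sampling_hz
    x = signal.values
    half = (kernel.size - 1) // 2
    pad = min(half, x.size - 1)
    padded = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]])
    y = np.convolve(padded, kernel, mode="same")[pad : pad + x.size]
    return SurrogateSignal(
        y, signal.sampling_hz, signal.start_time_s, signal.sign_arbitrary
    )


def savgol(
    signal: SurrogateSignal, order: int = 3, window: int = 5
) -> SurrogateSignal:
    """Savitzky-Golay local least-squares smoothing."""
    if window % 2 == 0 or order >= window:
        raise ParameterError("window must be odd and larger than order")
    y = savgol_filter(signal.values, window_length=window, polyorder=order,
                      mode="interp")
    return SurrogateSignal(
        y, signal.sampling_hz, signal.start_time_s, signal.sign_arbitrary
    )


class TracePostprocessor:
    """Apply the full cleaning chain in the fixed order.

    compression -> outlier removal -> bandpass -> Savitzky-Golay. Each
    stage can be disabled; stage parameters are exposed directly.
    """

    def __init__(
        self,
        compressor: CompressorParams | None = None,
        outlier_k: float = 1.5,
        band: BandpassParams | None = None,
        savgol_order: int = 3,
        savgol_window: int = 5,
        enable: tuple[str, ...] = ("compress", "outliers", "bandpass", "savgol"),
    ):
        self.compressor = compressor or CompressorParams()
        self.outlier_k = outlier_k
        self.band = band or BandpassParams()
        self.savgol_order = savgol_order
        self.savgol_window = savgol_window
        self.enable = enable

    def transform(self, signal: SurrogateSignal) -> SurrogateSignal:
        out = signal
        if "compress" in self.enable:
            out = parallel_compression(out, self.compressor)
        if "outliers" in self.enable:
            out = remove_outliers(out, self.outlier_k)
        if "bandpass" in self.enable:
            out = bandpass(out, self.band)
        if "savgol" in self.enable:
            out = savgol(out, self.savgol_order, self.savgol_window)
        return out

    __call__ = transform


def postprocess(signal: SurrogateSignal, **params) -> SurrogateSignal:
    """One-shot cleaning with default or overridden stage parameters."""
    return TracePostprocessor(**params).transform(signal)
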