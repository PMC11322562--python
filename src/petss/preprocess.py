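"""Gaussianisation and spatial conditioning of raw count sinograms.

Raw sinogram bins are Poisson distributed, which violates the implicit
Gaussian-noise assumption of PCA. The chain applied here is:

1. temporal rebinning to the 2 Hz working rate (summing raw frames);
2. the Freeman-Tukey transform ``X -> sqrt(X+1) + sqrt(X)``, which
   stabilises Poisson variance to ~1;
3. a Yeo-Johnson power transform with a single lambda fitted over all
   bins by minimising the KL divergence between the transformed
   empirical distribution and a moment-matched Gaussian;
4. a static mask discarding the lowest-count bins (the same mask for
   every time point);
5. per-frame separable Gaussian smoothing over (radial, angle, plane)
   followed by linear-interpolation downsampling.

Both transforms are strictly increasing, so the chain preserves the
ranking of bin values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    DegenerateInputError,
    ParameterError,
    SinogramSeries,
)

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """Input outside the mathematical domain of a transform."""


@dataclass
class YJParams:
    """Fitted Yeo-Johnson parameter and the objective at the optimum."""

    lam: float
    fit_grid: np.ndarray | None = None
    fit_objective_value: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ParameterError("lambda must be finite")


@dataclass
class MaskSpec:
    """Static low-count mask over (radial, angle, plane, tof)."""

    percentile: float
    mask: np.ndarray
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DegenerateInputError("mask retains no bin")


@dataclass
class SmoothSpec:
    """Gaussian sigmas (radial, angle, plane) in bins plus downsampling."""

    sigmas: tuple[float, float, float] = (1.0, 0.5, 2.0)
    downsample_factor: tuple[float, float, float] = (2.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if min(self.sigmas) < 0:
            raise ParameterError("sigmas must be >= 0")
        if min(self.downsample_factor) <= 0:
            raise ParameterError("downsample factors must be positive")


# --------------------------------------------------------------------------
# element-wise transforms
# --------------------------------------------------------------------------

def freeman_tukey_values(x: np.ndarray) -> np.ndarray:
    """sqrt(X+1) + sqrt(X), element-wise; domain X >= 0."""
    x = np.asarray(x, dtype=float)
    if x.size and np.nanmin(x) < 0:
        raise DomainError("Freeman-Tukey requires non-negative input")
    return np.sqrt(x + 1.0) + np.sqrt(x)


def freeman_tukey(series: SinogramSeries) -> SinogramSeries:
    return series.with_data(freeman_tukey_values(series.data))


def yeo_johnson_values(x: np.ndarray, lam: float) -> np.ndarray:
    """Four-branch Yeo-Johnson power transform, element-wise."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    # expm1/log1p forms are exact for the printed branches and stay
    # stable as lam -> 0 (or 2), where the naive power form cancels
    if lam != 0:
        out[pos] = np.expm1(lam * np.log1p(x[pos])) / lam
    else:
        out[pos] = np.log1p(x[pos])
    neg = ~pos
    if lam != 2:
        out[neg] = -np.expm1((2.0 - lam) * np.log1p(-x[neg])) / (2.0 - lam)
    else:
        out[neg] = -np.log1p(-x[neg])
    return out


def yeo_johnson(series: SinogramSeries, params: YJParams) -> SinogramSeries:
    return series.with_data(
        yeo_johnson_values(series.data, params.lam), transformed=True
    )


def fit_lambda(
    series: SinogramSeries | np.ndarray,
    grid: np.ndarray | None = None,
    max_samples: int = 200_000,
    seed: int = 0,
) -> YJParams:
    """Grid-search lambda minimising KL(empirical || matched Gaussian).

    The objective is the KL divergence from the histogram (Freedman-
    Diaconis bins, capped at 512) of the transformed values to the
    Gaussian with the same mean and variance. A single lambda is fitted
    from all the data; large inputs are subsampled for speed.
    """
    x = series.data if isinstance(series, SinogramSeries) else np.asarray(series)
    x = x[np.isfinite(x)].ravel().astype(float)
    if x.size < 100:
        raise ParameterError("need at least 100 finite values to fit lambda")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant data: lambda is unidentifiable")
    if x.size > max_samples:
        x = np.random.default_rng(seed).choice(x, size=max_samples, replace=False)
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.05)
    objs = np.array([_kld_to_gaussian(yeo_johnson_values(x, lam)) for lam in grid])
    best = int(np.argmin(objs))
    return YJParams(
        lam=float(grid[best]), fit_grid=np.asarray(grid),
        fit_objective_value=float(objs[best]),
    )


def _kld_to_gaussian(y: np.ndarray) -> float:
    """KL divergence of the empirical distribution from N(mean, var)."""
    y = y[np.isfinite(y)]
    sd = y.std()
    if sd == 0 or not np.isfinite(sd):
        return np.inf
    iqr = np.subtract(*np.percentile(y, [75, 25]))
    width = 2.0 * iqr / len(y) ** (1 / 3) if iqr > 0 else 3.5 * sd / len(y) ** (1 / 3)
    n_bins = int(np.clip(np.ceil(np.ptp(y) / width), 8, 512))
    counts, edges = np.histogram(y, bins=n_bins)
    p = counts / counts.sum()
    q = np.diff(stats.norm.cdf(edges, loc=y.mean(), scale=sd))
    q = np.clip(q, 1e-12, None)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


# --------------------------------------------------------------------------
# temporal rebinning, mask, smoothing
# --------------------------------------------------------------------------

def rebin_time(series: SinogramSeries, target_hz: float) -> SinogramSeries:
    """Sum consecutive raw frames down to the target sampling rate.

    The ratio of target frame duration to input frame duration must be a
    whole number; a trailing partial group of frames is dropped. Counts in
    complete groups are conserved exactly.
    """
    if target_hz <= 0:
        raise ParameterError("target_hz must be positive")
    ratio = (1.0 / target_hz) / series.frame_duration_s
    if ratio < 1.0 - 1e-9:
        raise ParameterError("target_hz exceeds the acquisition frame rate")
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ParameterError(
            f"frame ratio {ratio:.4g} is not an integer; cannot rebin"
        )
    if r == 1:
        return series.with_data(series.data.copy())
    n_out = series.n_frames // r
    if n_out < 1:
        raise ParameterError("series shorter than one output frame")
    d = series.data[..., : n_out * r]
    d = d.reshape(*series.spatial_shape, n_out, r).sum(axis=-1)
    out = series.with_data(d)
    out.frame_duration_s = series.frame_duration_s * r
    return out


def compute_mask(series: SinogramSeries, percentile: float = 0.05) -> MaskSpec:
    """Static mask keeping bins whose time-mean exceeds the percentile.

    The threshold is the given percentile of the time-mean sinogram;
    bins strictly above it are retained, so the same mask applies to
    every time point. ``percentile=0`` keeps everything, and if the
    strict comparison would empty the mask (all values tied) every bin
    is retained.
    """
    if not (0.0 <= percentile < 1.0):
        raise ParameterError("percentile must lie in [0, 1)")
    mean = series.data.mean(axis=-1)
    if not np.any(mean):
        raise DegenerateInputError("all-zero series: mask is undefined")
    if percentile == 0.0:
        return MaskSpec(percentile, np.ones_like(mean, dtype=bool), -np.inf)
    thr = float(np.quantile(mean, percentile))
    mask = mean > thr
    if not mask.any():
        mask = np.ones_like(mean, dtype=bool)
    return MaskSpec(percentile, mask, thr)


def apply_mask(series: SinogramSeries, spec: MaskSpec) -> SinogramSeries:
    """Zero excluded bins; idempotent for a fixed mask."""
    if spec.mask.shape != series.spatial_shape:
        raise ParameterError("mask shape does not match the series")
    data = series.data * spec.mask[..., np.newaxis]
    return series.with_data(data, mask_applied=True)


def smooth_and_downsample(
    series: SinogramSeries, spec: SmoothSpec
) -> SinogramSeries:
    """Per-frame Gaussian smoothing then linear-interpolation resampling.

    Smoothing is separable over (radial, angle, plane) with reflect
    boundaries; the TOF and time axes are untouched. Downsampling places
    ``round(n / factor)`` output samples at positions
    ``linspace(0, n-1, n_out)`` along each spatial axis, which is exact
    on constant inputs.
    """
    data = series.data
    if any(s > 0 for s in spec.sigmas):
        data = ndimage.gaussian_filter(
            data, sigma=(*spec.sigmas, 0.0, 0.0), mode="reflect"
        )
    for axis, factor in enumerate(spec.downsample_factor):
        n = data.shape[axis]
        if factor == 1.0:
            continue
        if factor > n:
            raise ParameterError(
                f"downsample factor {factor} exceeds axis length {n}"
            )
        n_out = max(int(round(n / factor)), 1)
        data = _linear_resample(data, n_out, axis)
    return series.with_data(data)


def _linear_resample(arr: np.ndarray, n_out: int, axis: int) -> np.ndarray:
    n = arr.shape[axis]
    if n_out == n:
        return arr
    pos = np.linspace(0.0, n - 1.0, n_out)
    i0 = np.floor(pos).astype(int)
    f = pos - i0
    i1 = np.minimum(i0 + 1, n - 1)
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    fb = f.reshape(shape)
    return a0 * (1.0 - fb) + a1 * fb


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class SinogramPreprocessor(BaseEstimator, TransformerMixin):
    """Fit-and-apply wrapper around the full preprocessing chain.

    ``fit`` rebins to the working rate, fits lambda (unless given) and
    computes the static mask on the transformed data; ``transform``
    applies rebinning, Freeman-Tukey, Yeo-Johnson, the mask, smoothing
    and downsampling in that order.

    Parameters
    ----------
    lam : float or "fit"
        Yeo-Johnson lambda; ``"fit"`` grid-searches it on the data.
    mask_percentile : float
        Fraction of lowest time-mean bins to discard (default 0.05).
    sigmas, downsample : tuples
        Gaussian sigmas and per-axis downsampling factors over
        (radial, angle, plane).
    target_hz : float
        Working sampling rate after temporal rebinning.
    """

    def __init__(
        self,
        lam: float | str = "fit",
        mask_percentile: float = 0.05,
        sigmas: tuple[float, float, float] = (1.0, 0.5, 2.0),
        downsample: tuple[float, float, float] = (2.0, 1.0, 2.0),
        target_hz: float = 2.0,
    ):
        self.lam = lam
        self.mask_percentile = mask_percentile
        self.sigmas = sigmas
        self.downsample = downsample
        self.target_hz = target_hz

    def fit(self, X: SinogramSeries, y=None) -> "SinogramPreprocessor":
        series = rebin_time(X, self.target_hz)
        ft = freeman_tukey(series)
        if self.lam == "fit":
            self.yj_params_ = fit_lambda(ft)
        else:
            self.yj_params_ = YJParams(lam=float(self.lam))
        transformed = yeo_johnson(ft, self.yj_params_)
        self.mask_ = compute_mask(transformed, self.mask_percentile)
        logger.info(
            "preprocess fit: lambda=%.2f, mask keeps %d/%d bins",
            self.yj_params_.lam, int(self.mask_.mask.sum()), self.mask_.mask.size,
        )
        return self

    def transform(self, X: SinogramSeries) -> SinogramSeries:
        series = rebin_time(X, self.target_hz)
        series = yeo_johnson(freeman_tukey(series), self.yj_params_)
        series = apply_mask(series, self.mask_)
        return smooth_and_downsample(
            series, SmoothSpec(self.sigmas, self.downsample)
        )


def preprocess(series: SinogramSeries, **params) -> SinogramSeries:
    """One-shot preprocessing: fit the chain on the series and apply it."""
    pre = SinogramPreprocessor(**params)
    return pre.fit(series).transform(series)
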