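"""In-memory containers shared by all pipeline stages.

A :class:`SinogramSeries` holds a five-axis stack of low-resolution PET
sinograms, ``(radial, angle, plane, tof, time)``, together with frame
timing and flags recording which preprocessing steps have been applied.
A :class:`SurrogateSignal` is the one-dimensional respiratory trace the
extraction methods produce; its sign is arbitrary (a principal component
and its negation are equally valid), which every consumer must respect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class FormatError(ValueError):
    """Malformed container on disk (missing axes, bad metadata)."""


class ParameterError(ValueError):
    """A parameter outside its documented range."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (constant / all-zero data)."""


@dataclass
class SinogramSeries:
    """Time series of sinograms with axes (radial, angle, plane, tof, time).

    Parameters
    ----------
    data
        Non-negative counts when ``transformed`` is False; any real values
        after the Gaussianizing transforms.
    frame_duration_s
        Duration of one time frame in seconds (0.5 s at acquisition,
        possibly longer after temporal rebinning).
    start_time_s
        Acquisition time of the first frame's left edge.
    transformed
        True once the Freeman-Tukey + Yeo-Johnson chain has been applied.
    mask_applied
        True once low-count bins have been zeroed by the static mask.
    """

    data: np.ndarray
    frame_duration_s: float = 0.5
    start_time_s: float = 0.0
    transformed: bool = False
    mask_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 4:
            # promote (radial, angle, plane, time) -> tof axis of length 1
            self.data = self.data[:, :, :, np.newaxis, :]
        if self.data.ndim != 5:
            raise FormatError(
                f"sinogram series needs 5 axes (radial, angle, plane, tof, "
                f"time), got {self.data.ndim}"
            )
        if self.data.shape[-1] < 1:
            raise FormatError("time axis must have length >= 1")
        if self.frame_duration_s <= 0:
            raise ParameterError("frame_duration_s must be positive")
        if not self.transformed and self.data.size and np.nanmin(self.data) < 0:
            raise FormatError("raw count sinograms must be non-negative")

    @property
    def spatial_shape(self) -> tuple[int, int, int, int]:
        return self.data.shape[:4]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.frame_duration_s

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in seconds."""
        return (
            self.start_time_s
            + (np.arange(self.n_frames) + 0.5) * self.frame_duration_s
        )

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n_frames, n_bins) matrix (time-major)."""
        return self.data.reshape(-1, self.n_frames).T

    def with_data(self, data: np.ndarray, **flags) -> "SinogramSeries":
        """Copy of this series with new data and optionally new flags."""
        out = replace(self, data=data)
        for k, v in flags.items():
            setattr(out, k, v)
        return out


@dataclass
class SurrogateSignal:
    """A 1-D respiratory trace with uniform sampling.

    ``sign_arbitrary`` records that the trace's polarity carries no
    physical meaning; comparisons with references use |r| or explicit
    sign alignment. NaN values are allowed only as moving-window padding.
    """

    values: np.ndarray
    sampling_hz: float = 2.0
    start_time_s: float = 0.0
    sign_arbitrary: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sampling_hz <= 0:
            raise ParameterError("sampling_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.values)) / self.sampling_hz

    def slice_time(self, t0: float, t1: float) -> "SurrogateSignal":
        """Samples with t0 <= t < t1 (sample times, seconds)."""
        sel = (self.times >= t0) & (self.times < t1)
        first = int(np.argmax(sel)) if sel.any() else 0
        return SurrogateSignal(
            self.values[sel],
            sampling_hz=self.sampling_hz,
            start_time_s=self.start_time_s + first / self.sampling_hz,
            sign_arbitrary=self.sign_arbitrary,
        )


@dataclass
class Component:
    """A per-bin weight map over the sinogram (a PC or a SAM signed mask).

    ``weights`` has the spatial shape (radial, angle, plane, tof); bins
    excluded by the mask simply carry weight zero. ``time_support`` is the
    [start, stop) frame range the component was computed from.
    """

    weights: np.ndarray
    origin: str = "pca"
    time_support: tuple[int, int] | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ParameterError("component weights must be finite")
        if not np.any(self.weights):
            raise DegenerateInputError("component has no nonzero weight")


@dataclass
class FrequencyWindows:
    """Kinetic / respiratory / noise bands on [0, Nyquist], in Hz.

    Bands are half-open ``[lo, hi)`` so that adjacent windows are
    disjoint. Defaults follow the fixed windows used before adaptive
    estimation: kinetics below 0.1 Hz, respiration 0.1-0.4 Hz, noise
    above 0.4 Hz.
    """

    kinetic: tuple[float, float] = (0.0, 0.1)
    respiratory: tuple[float, float] = (0.1, 0.4)
    noise: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        for name in ("kinetic", "respiratory", "noise"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ParameterError(f"{name} window [{lo}, {hi}) is invalid")
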