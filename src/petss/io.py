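"""On-disk formats: HDF5 sinogram containers, CSV traces, YAML config.

The sinogram container is a single HDF5 file with one dataset
``"sinogram"`` of shape (radial, angle, plane, tof, time) plus scalar
attributes for timing and flags; traces are two-column CSV
(``time_s,value``, '.' decimal, UTF-8) so round trips are bit-exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import FormatError, ParameterError, SinogramSeries, SurrogateSignal

logger = logging.getLogger(__name__)

_SERIES_ATTRS = ("frame_duration_s", "start_time_s", "transformed", "mask_applied")


def write_series(series: SinogramSeries, path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("sinogram", data=series.data)
        for name in _SERIES_ATTRS:
            dset.attrs[name] = getattr(series, name)


def read_series(path) -> SinogramSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "sinogram" not in f:
            raise FormatError(f"{path}: missing 'sinogram' dataset")
        dset = f["sinogram"]
        if dset.ndim not in (4, 5):
            raise FormatError(
                f"{path}: sinogram has {dset.ndim} axes, expected 4 or 5"
            )
        data = dset[()]
        attrs = {
            name: dset.attrs[name] for name in _SERIES_ATTRS if name in dset.attrs
        }
    attrs["transformed"] = bool(attrs.get("transformed", False))
    attrs["mask_applied"] = bool(attrs.get("mask_applied", False))
    return SinogramSeries(data, **attrs)  # 4-axis data promoted to tof=1


def write_trace(signal: SurrogateSignal, path) -> None:
    rows = "\n".join(
        f"{float(t)!r},{float(v)!r}" for t, v in zip(signal.times, signal.values)
    )
    Path(path).write_text("time_s,value\n" + rows + "\n", encoding="utf-8")


def read_trace(path, sampling_hz: float = 2.0) -> SurrogateSignal:
    """Read a (time_s, value) CSV, resampling to ``sampling_hz`` if needed.

    Input time must be strictly increasing. Non-uniform or differently
    sampled input is linearly interpolated onto a uniform grid of
    ``floor(duration * sampling_hz) + 1`` samples starting at the first
    input time; input already on that grid is preserved exactly.
    """
    raw = np.genfromtxt(path, delimiter=",", names=True, dtype=float)
    if raw.ndim == 0:
        raise FormatError(f"{path}: need at least two samples")
    names = raw.dtype.names
    if names is None or len(names) < 2:
        raise FormatError(f"{path}: expected a 'time_s,value' header")
    t = np.asarray(raw[names[0]], dtype=float)
    v = np.asarray(raw[names[1]], dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time must be strictly increasing")
    dt = np.diff(t)
    if np.allclose(dt, 1.0 / sampling_hz, rtol=0, atol=1e-9):
        return SurrogateSignal(v, sampling_hz, start_time_s=float(t[0]))
    duration = t[-1] - t[0]
    n_out = int(np.floor(duration * sampling_hz)) + 1
    new_t = t[0] + np.arange(n_out) / sampling_hz
    return SurrogateSignal(
        np.interp(new_t, t, v), sampling_hz, start_time_s=float(t[0])
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings, loadable from YAML.

    ``methods`` selects which extractors run; ``phantom``, ``preprocess``,
    ``extract`` and ``postprocess`` are keyword overrides passed to the
    respective stages. ``seed`` drives every source of randomness.
    """

    methods: tuple[str, ...] = (
        "conventional", "moving_window_pca", "moving_window_sam",
        "late_time", "ssc_freq", "ssc_pluggable",
    )
    phantom: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    extract: dict = field(default_factory=dict)
    postprocess: dict = field(default_factory=dict)
    seed: int = 0

    KNOWN_METHODS = (
        "conventional", "moving_window_pca", "moving_window_sam",
        "late_time", "ssc_freq", "ssc_pluggable",
    )

    def __post_init__(self) -> None:
        bad = set(self.methods) - set(self.KNOWN_METHODS)
        if bad:
            raise ParameterError(f"unknown method(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "methods" in payload:
            payload["methods"] = tuple(payload["methods"])
        return cls(**payload)

    def config_hash(self) -> str:
        import hashlib

        blob = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
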