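"""Correlation-based agreement between a trace and a reference.

Extracted traces are compared with a reference (an external tracking
device's trace, or the phantom's ground truth) by Pearson correlation
over the usable record (20-840 s by default, the first ~20 s holding no
counts), over the early interval (20-140 s), and in contiguous 20 s
bins. Because every extracted trace has an arbitrary global sign, the
trace is sign-aligned to the reference using the full-record
correlation before any interval is reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ParameterError, SurrogateSignal

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A segment has zero variance: correlation is undefined."""


def _resample(sig: SurrogateSignal, sampling_hz: float) -> SurrogateSignal:
    if abs(sig.sampling_hz - sampling_hz) < 1e-12:
        return sig
    t = sig.times
    new_t = np.arange(t[0], t[-1] + 1e-12, 1.0 / sampling_hz)
    finite = np.isfinite(sig.values)
    if finite.sum() < 2:
        raise ParameterError("too few finite samples to resample")
    vals = np.interp(new_t, t[finite], sig.values[finite])
    return SurrogateSignal(vals, sampling_hz, start_time_s=float(new_t[0]))


def _pairwise(a: SurrogateSignal, b: SurrogateSignal, t0: float, t1: float):
    """Values of a and b on the common 2 Hz grid within [t0, t1)."""
    ta, tb = a.times, b.times
    lo = max(ta[0], tb[0], t0)
    hi_data = min(ta[-1], tb[-1]) + 1e-9  # inclusive of the last sample
    sel_a = (ta >= lo) & (ta < t1) & (ta <= hi_data)
    av = a.values[sel_a]
    bv = np.interp(ta[sel_a], tb, b.values)
    ok = np.isfinite(av) & np.isfinite(bv)
    return av[ok], bv[ok]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero-variance or empty segment")
    return float(np.corrcoef(x, y)[0, 1])


def align_and_correlate(
    a: SurrogateSignal,
    b: SurrogateSignal,
    t0: float,
    t1: float,
    sampling_hz: float = 2.0,
    sign_align: bool = True,
) -> float:
    """Pearson r of a against b over [t0, t1) at the common 2 Hz grid.

    With ``sign_align`` the global sign of ``a`` is flipped when the
    *full-record* correlation is negative, reflecting that the extracted
    trace's polarity is arbitrary. NaN samples are pairwise-deleted.
    """
    a = _resample(a, sampling_hz)
    b = _resample(b, sampling_hz)
    av, bv = _pairwise(a, b, t0, t1)
    if av.size < 8:
        raise ParameterError("fewer than 8 overlapping samples")
    r = _pearson(av, bv)
    if sign_align:
        fav, fbv = _pairwise(a, b, -np.inf, np.inf)
        if _pearson(fav, fbv) < 0:
            r = -r
    return r


def windowed_correlation(
    a: SurrogateSignal,
    b: SurrogateSignal,
    width_s: float = 20.0,
    t0: float = 20.0,
    t1: float = 140.0,
    sampling_hz: float = 2.0,
) -> list[tuple[tuple[float, float], float | None]]:
    """Per-bin Pearson r in contiguous windows of ``width_s`` seconds.

    The global sign alignment from the full record applies to every bin.
    A bin with fewer than 8 valid paired samples reports ``None``.
    """
    a = _resample(a, sampling_hz)
    b = _resample(b, sampling_hz)
    fav, fbv = _pairwise(a, b, -np.inf, np.inf)
    sign = 1.0 if _pearson(fav, fbv) >= 0 else -1.0
    out = []
    edges = np.arange(t0, t1 + 1e-9, width_s)
    for lo, hi in zip(edges[:-1], edges[1:]):
        av, bv = _pairwise(a, b, lo, hi)
        if av.size < 8:
            out.append(((float(lo), float(hi)), None))
            continue
        try:
            r = sign * _pearson(av, bv)
        except UndefinedCorrelationError:
            r = None
        out.append(((float(lo), float(hi)), r))
    return out


@dataclass
class EvalReport:
    """Agreement summary for one method against the reference."""

    r_full: float
    r_early: float
    r_by_interval: list = field(default_factory=list)
    sign_aligned: bool = True
    n_full: int = 0
    n_early: int = 0

    def to_dict(self) -> dict:
        return {
            "r_full": self.r_full,
            "r_early": self.r_early,
            "r_by_interval": [
                {"interval_s": list(iv), "r": r} for iv, r in self.r_by_interval
            ],
            "sign_aligned": self.sign_aligned,
            "n_full": self.n_full,
            "n_early": self.n_early,
        }


def evaluate_trace(
    trace: SurrogateSignal,
    reference: SurrogateSignal,
    full_interval: tuple[float, float] = (20.0, 840.0),
    early_interval: tuple[float, float] = (20.0, 140.0),
    width_s: float = 20.0,
) -> EvalReport:
    """Full/early/20 s-binned correlation of one trace with the reference."""
    r_full = align_and_correlate(trace, reference, *full_interval)
    r_early = align_and_correlate(trace, reference, *early_interval)
    by_interval = windowed_correlation(
        trace, reference, width_s=width_s,
        t0=early_interval[0], t1=early_interval[1],
    )
    a2 = _resample(trace, 2.0)
    n_full = _pairwise(a2, _resample(reference, 2.0), *full_interval)[0].size
    n_early = _pairwise(a2, _resample(reference, 2.0), *early_interval)[0].size
    return EvalReport(
        r_full=r_full, r_early=r_early, r_by_interval=by_interval,
        sign_aligned=True, n_full=int(n_full), n_early=int(n_early),
    )


def make_report(
    method_traces: dict[str, SurrogateSignal],
    reference: SurrogateSignal,
    **kwargs,
) -> dict[str, EvalReport]:
    """One EvalReport per method; deterministic ordering by method name."""
    if not method_traces:
        raise ParameterError("no method traces to evaluate")
    return {
        name: evaluate_trace(method_traces[name], reference, **kwargs)
        for name in sorted(method_traces)
    }


def report_to_json(reports: dict[str, EvalReport]) -> str:
    """Deterministic JSON serialisation (sorted keys, fixed precision)."""
    payload = {
        name: _round_floats(rep.to_dict()) for name, rep in sorted(reports.items())
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj
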