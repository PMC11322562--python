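"""Synthetic dynamic-PET phantom with known respiratory ground truth.

The generator emulates the features of a dynamic chest acquisition that
make surrogate-signal extraction hard: an initial interval with no counts
before tracer injection, a first-pass bolus whose kinetic variance dwarfs
the respiratory variance at early times, quasi-periodic breathing in the
0.1-0.4 Hz band with cycle-to-cycle irregularity (including breath holds
and drift), and Poisson count statistics in every sinogram bin.

Geometry is deliberately simple: ellipsoidal regions on a voxel grid,
rigidly translated along the axial (z) direction by the respiratory
trace, scaled by a per-region time-activity curve (TAC), and forward
projected by a nearest-neighbour line-integral projector into
(radial, angle, plane, TOF) bins. This is the simplest model in which
respiration is a low-rank component of the sinogram time series, which
is exactly what the PCA-based extraction methods exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .containers import ParameterError, SinogramSeries, SurrogateSignal

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Image grid too small for the requested structure or displacement."""


# --------------------------------------------------------------------------
# respiratory model
# --------------------------------------------------------------------------

@dataclass
class RespModel:
    """Quasi-periodic breathing model.

    Each breathing cycle draws its own period and amplitude:
    ``T_i = (1/base_freq_hz) * (1 + freq_jitter * N(0,1))`` and
    ``A_i = amplitude_voxels * (1 + amplitude_jitter * N(0,1))``, giving
    the irregular-breather behaviour seen in real traces. ``drift`` adds a
    slow baseline shift (displacement units per minute). During a breath
    hold the trace freezes at its hold-onset value and the breathing phase
    pauses, resuming afterwards.
    """

    base_freq_hz: float = 0.25
    amplitude_voxels: float = 0.5
    freq_jitter: float = 0.05
    amplitude_jitter: float = 0.05
    drift: float = 0.0
    breath_holds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.base_freq_hz < 1.0):
            raise ParameterError("base_freq_hz must lie in (0, 1) Hz")
        if self.amplitude_voxels < 0:
            raise ParameterError("amplitude_voxels must be >= 0")
        if self.freq_jitter < 0 or self.amplitude_jitter < 0:
            raise ParameterError("jitter fractions must be >= 0")


def simulate_resp_trace(
    model: RespModel, n_frames: int, dt: float, seed: int
) -> SurrogateSignal:
    """Simulate a noise-free respiratory displacement trace.

    The trace is evaluated at frame-centre times ``(i + 0.5) * dt``. It is
    a concatenation of sinusoidal half... full cycles ``A_i sin(2*pi*phase)``
    joined at their zero crossings, so per-cycle amplitude changes keep the
    trace continuous. Deterministic for a fixed seed.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    rng = np.random.default_rng(seed)
    total = n_frames * dt
    base_T = 1.0 / model.base_freq_hz
    n_cycles = int(np.ceil(total / (0.25 * base_T))) + 4
    periods = base_T * (1.0 + model.freq_jitter * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.2 * base_T, None)
    amps = model.amplitude_voxels * (
        1.0 + model.amplitude_jitter * rng.standard_normal(n_cycles)
    )
    amps = np.clip(amps, 0.0, None)

    t = (np.arange(n_frames) + 0.5) * dt
    # breathing-phase time: holds pause the clock, freezing the trace
    tau = t.copy()
    for start, dur in model.breath_holds:
        tau = tau - np.clip(t - start, 0.0, dur)

    edges = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, n_cycles - 1)
    phase = (tau - edges[idx]) / periods[idx]
    values = amps[idx] * np.sin(2.0 * np.pi * phase)
    values = values + model.drift * tau / 60.0
    return SurrogateSignal(values, sampling_hz=1.0 / dt, start_time_s=0.5 * dt)


# --------------------------------------------------------------------------
# kinetic model
# --------------------------------------------------------------------------

@dataclass
class TacModel:
    """Time-activity curve for one region.

    Forms
    -----
    constant
        ``scale`` from injection onward.
    bolus_washout
        A first-pass bolus ``(t/t_peak) * exp(1 - t/t_peak)`` (unit peak at
        ``t_peak`` seconds post injection) blended with a rising plateau:
        ``scale * ((1 - plateau_frac) * bolus + plateau_frac *
        (1 - exp(-t/t_peak)))``. Early activity is dominated by the bolus,
        emulating rapid tracer redistribution after injection.
    uptake
        Monoexponential approach ``scale * (1 - exp(-k * t))``.

    All forms are zero before the injection time and non-negative after.
    """

    form: str = "uptake"
    parameters: dict = field(default_factory=dict)

    _FORMS = ("constant", "bolus_washout", "uptake")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ParameterError(f"unknown TAC form {self.form!r}")
        if self.parameters.get("scale", 1.0) < 0:
            raise ParameterError("TAC scale must be >= 0")

    def __call__(self, t: np.ndarray, injection_time_s: float) -> np.ndarray:
        tp = np.clip(np.asarray(t, dtype=float) - injection_time_s, 0.0, None)
        p = self.parameters
        scale = p.get("scale", 1.0)
        if self.form == "constant":
            out = np.where(tp > 0, scale, 0.0)
        elif self.form == "bolus_washout":
            t_peak = p.get("t_peak_s", 40.0)
            frac = p.get("plateau_frac", 0.15)
            bolus = (tp / t_peak) * np.exp(1.0 - tp / t_peak)
            plateau = 1.0 - np.exp(-tp / t_peak)
            out = scale * ((1.0 - frac) * bolus + frac * plateau)
        else:  # uptake
            k = p.get("k_per_s", 1.0 / 200.0)
            out = scale * (1.0 - np.exp(-k * tp))
        return out


# --------------------------------------------------------------------------
# configuration and truth
# --------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in image-grid units."""

    center: tuple[float, float, float]
    axes: tuple[float, float, float]
    label: str

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ParameterError("ellipsoid axes must be positive")


def transit_chain_anatomy(
    n_path: int = 24,
    bolus_scale: float = 20.0,
    t_arrival_s: float = 3.0,
    t_transit_s: float = 7.0,
) -> tuple[list[Ellipsoid], dict[str, TacModel]]:
    """Default anatomy: slow-uptake organs plus a dispersed first-pass bolus.

    Three tissue regions take up tracer slowly (monoexponential), while a
    chain of small, axially elongated "vessel" ellipsoids carries a sharp
    first-pass bolus whose peak time increases smoothly along the path,
    emulating dispersion of the injected activity through the
    circulation. The axial elongation keeps the vessels' plane-direction
    projection gradients weak, so the chain contributes large kinetic
    variance but little respiratory variance - the regime in which
    whole-record PCA is dominated by tracer redistribution at early
    times while respiration is carried by the tissue structures.
    """
    geometry = [
        Ellipsoid(center=(31.5, 31.5, 7.5), axes=(26.0, 20.0, 5.0), label="body"),
        Ellipsoid(center=(22.0, 40.0, 7.0), axes=(10.0, 8.0, 3.5), label="liver"),
        Ellipsoid(
            center=(40.0, 28.0, 8.0), axes=(6.0, 5.0, 2.5), label="myocardium"
        ),
    ]
    tacs = {
        "body": TacModel("uptake", {"scale": 1.5, "k_per_s": 1.0 / 400.0}),
        "liver": TacModel("uptake", {"scale": 2.5, "k_per_s": 1.0 / 250.0}),
        "myocardium": TacModel("uptake", {"scale": 4.0, "k_per_s": 1.0 / 200.0}),
    }
    s = np.linspace(0.0, 1.0, n_path)
    xs = 44.0 - 22.0 * s
    ys = 22.0 + 16.0 * s + 6.0 * np.sin(3.0 * s)
    t_peaks = t_arrival_s + t_transit_s * s
    scales = bolus_scale * np.exp(-s) + 3.0
    for i in range(n_path):
        label = f"vessel{i:02d}"
        geometry.append(
            Ellipsoid(center=(xs[i], ys[i], 7.5), axes=(3.0, 3.0, 6.5), label=label)
        )
        tacs[label] = TacModel(
            "bolus_washout",
            {
                "scale": float(scales[i]),
                "t_peak_s": float(t_peaks[i]),
                "plateau_frac": 0.05,
            },
        )
    return geometry, tacs


def _default_geometry() -> list[Ellipsoid]:
    return transit_chain_anatomy()[0]


def _default_tacs() -> dict[str, TacModel]:
    return transit_chain_anatomy()[1]


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic acquisition.

    Defaults emulate a 14 min dynamic chest scan: 1680 frames of 500 ms,
    injection 20 s after scan start (so the first ~20 s hold no counts),
    a low-resolution sinogram of 24 radial bins x 16 angles x 8 planes
    (non-TOF), a sharp dispersed first-pass bolus an order of magnitude
    above the tissue plateau, quasi-periodic 0.25 Hz breathing of half a
    voxel amplitude, and 1e5 expected counts per frame at the activity
    peak (the bolus maximum; plateau frames carry a few tenths of that).
    """

    n_frames: int = 1680
    frame_duration_s: float = 0.5
    image_grid: tuple[int, int, int] = (64, 64, 16)
    n_radial: int = 24
    n_angles: int = 16
    n_planes: int = 8
    n_tof_bins: int = 1
    geometry: list[Ellipsoid] = field(default_factory=_default_geometry)
    tac_models: dict[str, TacModel] = field(default_factory=_default_tacs)
    resp_model: RespModel = field(default_factory=RespModel)
    count_scale: float = 1e5
    injection_time_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce plain dicts/lists (e.g. parsed YAML) into model objects
        self.image_grid = tuple(self.image_grid)
        self.geometry = [
            e if isinstance(e, Ellipsoid) else Ellipsoid(**e)
            for e in self.geometry
        ]
        self.tac_models = {
            k: v if isinstance(v, TacModel) else TacModel(**v)
            for k, v in self.tac_models.items()
        }
        if isinstance(self.resp_model, dict):
            self.resp_model = RespModel(**self.resp_model)
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.frame_duration_s <= 0:
            raise ParameterError("frame_duration_s must be positive")
        if self.count_scale < 0:
            raise ParameterError("count_scale must be >= 0")
        if self.image_grid[2] % self.n_planes != 0:
            raise ParameterError("n_planes must divide the z grid size")
        labels = {e.label for e in self.geometry}
        missing = labels - set(self.tac_models)
        if missing:
            raise ParameterError(f"no TAC model for region(s) {sorted(missing)}")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the simulated sinograms."""

    resp_trace: SurrogateSignal
    tacs: dict[str, np.ndarray]
    first_counts_time_s: float  # NaN when no counts at all


# --------------------------------------------------------------------------
# projector
# --------------------------------------------------------------------------

def build_projector(
    nx: int, ny: int, n_radial: int, n_angles: int, n_tof: int
) -> sparse.csr_matrix:
    """Sparse nearest-neighbour ray-summation projector.

    Maps a flattened (nx*ny) transaxial image to (radial*angle*tof) bins.
    For TOF, counts along each ray are split between bins by a Gaussian
    profile over the along-ray coordinate, normalised so the TOF axis sums
    to the non-TOF projection.
    """
    xs = np.arange(nx) - (nx - 1) / 2.0
    ys = np.arange(ny) - (ny - 1) / 2.0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r_fov = max(nx, ny) / 2.0
    cols_base = np.arange(nx * ny)
    rows, cols, vals = [], [], []
    if n_tof > 1:
        tof_centers = (np.arange(n_tof) + 0.5) * 2 * r_fov / n_tof - r_fov
        sigma_tof = 2 * r_fov / n_tof
    for a in range(n_angles):
        th = np.pi * a / n_angles
        s = X * np.cos(th) + Y * np.sin(th)
        rbin = np.floor((s + r_fov) / (2 * r_fov) * n_radial).astype(int)
        rbin = np.clip(rbin, 0, n_radial - 1).ravel()
        if n_tof == 1:
            rows.append((rbin * n_angles + a) * n_tof)
            cols.append(cols_base)
            vals.append(np.ones(nx * ny))
        else:
            u = (-X * np.sin(th) + Y * np.cos(th)).ravel()
            w = np.exp(
                -((u[:, None] - tof_centers[None, :]) ** 2) / (2 * sigma_tof**2)
            )
            w /= w.sum(axis=1, keepdims=True)
            for j in range(n_tof):
                rows.append((rbin * n_angles + a) * n_tof + j)
                cols.append(cols_base)
                vals.append(w[:, j])
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_radial * n_angles * n_tof, nx * ny),
    )
    return A.tocsr()


def _ellipsoid_mask(grid: tuple[int, int, int], ell: Ellipsoid) -> np.ndarray:
    nx, ny, nz = grid
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = ell.center
    ax, ay, az = ell.axes
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return (r2 <= 1.0).astype(float)


def _shift_axial(Q: np.ndarray, d: float) -> np.ndarray:
    """Shift the last axis by d voxels (linear interpolation, zero fill)."""
    nz = Q.shape[-1]
    src = np.arange(nz) - d
    i0 = np.floor(src).astype(int)
    f = src - i0
    i1 = i0 + 1
    v0 = (i0 >= 0) & (i0 < nz)
    v1 = (i1 >= 0) & (i1 < nz)
    out = (1.0 - f) * Q[..., np.clip(i0, 0, nz - 1)] * v0
    out += f * Q[..., np.clip(i1, 0, nz - 1)] * v1
    return out


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def generate_phantom(
    config: PhantomConfig, noise_free: bool = False
) -> tuple[SinogramSeries, PhantomTruth]:
    """Simulate a sinogram time series plus its ground truth.

    Per frame, every region is displaced axially by the respiratory trace
    (sub-voxel shifts via linear interpolation), scaled by its TAC value,
    and forward projected; counts are then drawn Poisson with mean
    proportional to the projection, normalised so the expected total
    counts in the peak-activity frame equal ``count_scale``. With
    ``noise_free=True`` (or an infinite ``count_scale``) the scaled
    noise-free means are returned instead of Poisson draws.
    """
    nx, ny, nz = config.image_grid
    dt = config.frame_duration_s
    trace = simulate_resp_trace(
        config.resp_model, config.n_frames, dt, seed=config.seed
    )
    d = trace.values

    A = build_projector(nx, ny, config.n_radial, config.n_angles, config.n_tof_bins)
    # per-region projections, axes (radial, angle, tof, z)
    projs, masses, labels = [], [], []
    zlo, zhi = [], []
    for ell in config.geometry:
        mask = _ellipsoid_mask(config.image_grid, ell)
        P = (A @ mask.reshape(nx * ny, nz)).reshape(
            config.n_radial, config.n_angles, config.n_tof_bins, nz
        )
        nz_support = np.nonzero(P.sum(axis=(0, 1, 2)))[0]
        if nz_support.size == 0:
            raise GeometryError(f"region {ell.label!r} projects to nothing")
        zlo.append(nz_support[0])
        zhi.append(nz_support[-1])
        projs.append(P)
        masses.append(P.sum())
        labels.append(ell.label)

    dmin, dmax = (float(d.min()), float(d.max())) if len(d) else (0.0, 0.0)
    if min(zlo) + dmin < 0 or max(zhi) + dmax > nz - 1:
        raise GeometryError(
            "axial displacement pushes a region outside the image grid; "
            "enlarge the grid or reduce the respiratory amplitude"
        )

    times = trace.times
    tacs = {
        lab: config.tac_models[lab](times, config.injection_time_s)
        for lab in labels
    }

    totals = np.zeros(config.n_frames)
    for lab, m in zip(labels, masses):
        totals += tacs[lab] * m
    peak = totals.max()
    use_noise_free = noise_free or not np.isfinite(config.count_scale)
    if peak > 0 and config.count_scale > 0:
        scale = (
            1.0 if not np.isfinite(config.count_scale)
            else config.count_scale / peak
        )
    else:
        scale = 0.0

    pz = nz // config.n_planes
    shape = (
        config.n_radial,
        config.n_angles,
        config.n_planes,
        config.n_tof_bins,
        config.n_frames,
    )
    data = np.zeros(shape, dtype=float)
    rng = np.random.default_rng(config.seed + 1_000_003)
    for t in range(config.n_frames):
        mean_t = np.zeros_like(projs[0])
        for lab, P in zip(labels, projs):
            a = tacs[lab][t]
            if a > 0:
                mean_t += a * _shift_axial(P, d[t])
        mean_t *= scale
        # rebin z voxels into sinogram planes; reorder to (r, a, plane, tof)
        planes = mean_t.reshape(
            config.n_radial, config.n_angles, config.n_tof_bins,
            config.n_planes, pz,
        ).sum(axis=-1).transpose(0, 1, 3, 2)
        data[..., t] = planes if use_noise_free else rng.poisson(planes)

    frame_totals = data.sum(axis=(0, 1, 2, 3))
    nonzero = np.nonzero(frame_totals > 0)[0]
    first_counts = float(times[nonzero[0]]) if nonzero.size else float("nan")

    series = SinogramSeries(data, frame_duration_s=dt, start_time_s=0.0)
    truth = PhantomTruth(resp_trace=trace, tacs=tacs, first_counts_time_s=first_counts)
    logger.info(
        "phantom: shape=%s, first_counts=%.1fs, peak_total=%.3g",
        shape, first_counts, frame_totals.max() if data.size else 0.0,
    )
    return series, truth


def phantom_bank(
    n_phantoms: int = 5, seed: int = 0, **overrides
) -> list[PhantomConfig]:
    """Standard seeded bank of phantoms spanning breathing rates.

    Base breathing frequencies are spread over 0.24-0.30 Hz (with the
    usual cycle-to-cycle jitter on top); each phantom gets its own
    deterministic seed derived from ``seed``. Keyword overrides are
    applied to every config.
    """
    fixed_resp = overrides.pop("resp_model", None)
    configs = []
    for i in range(n_phantoms):
        f0 = 0.24 + 0.06 * i / max(n_phantoms - 1, 1)
        cfg = PhantomConfig(
            seed=(seed * 101 + 7919 * i) % (2**31 - 1),
            resp_model=fixed_resp or RespModel(base_freq_hz=f0),
            **overrides,
        )
        configs.append(cfg)
    return configs
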