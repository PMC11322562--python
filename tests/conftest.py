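"""Shared fixtures: small deterministic phantoms and series."""

import warnings

import numpy as np
import pytest

from petss.containers import SinogramSeries
from petss.phantom import Ellipsoid, PhantomConfig, RespModel, TacModel, generate_phantom


def small_phantom_config(seed: int = 0, n_frames: int = 400, **overrides):
    """A fast low-resolution phantom: two uptake regions plus one bolus."""
    geometry = [
        Ellipsoid(center=(11.5, 11.5, 4.0), axes=(9.0, 7.0, 2.5), label="body"),
        Ellipsoid(center=(15.0, 9.0, 4.0), axes=(3.0, 3.0, 2.6), label="vessel"),
    ]
    tacs = {
        "body": TacModel("uptake", {"scale": 2.0, "k_per_s": 1 / 200.0}),
        "vessel": TacModel(
            "bolus_washout", {"scale": 12.0, "t_peak_s": 6.0, "plateau_frac": 0.1}
        ),
    }
    defaults = dict(
        n_frames=n_frames,
        image_grid=(24, 24, 8),
        n_radial=12,
        n_angles=8,
        n_planes=4,
        geometry=geometry,
        tac_models=tacs,
        resp_model=RespModel(base_freq_hz=0.25, amplitude_voxels=0.8),
        count_scale=3e4,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """(series, truth) for a 200 s low-resolution phantom."""
    return generate_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def preprocessed_small_phantom(small_phantom):
    from petss.preprocess import preprocess

    series, truth = small_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess(series), truth


def rank1_series(n_frames: int = 128, n_bins: int = 24, seed: int = 0,
                 freq_hz: float = 0.25, noise: float = 0.0) -> tuple:
    """A series whose only variation is one spatial pattern times a sinusoid."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / 2.0
    w = np.sin(2 * np.pi * freq_hz * t)
    pattern = rng.standard_normal(n_bins)
    base = 5.0 + rng.random(n_bins)
    data = base[:, None] + np.outer(pattern, w)
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    series = SinogramSeries(
        data.reshape(n_bins, 1, 1, 1, n_frames), frame_duration_s=0.5,
        transformed=True,
    )
    return series, w, pattern
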