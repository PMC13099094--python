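"""Shared fixtures: small white-noise stimuli and simulated cells.

Expensive fixtures are session-scoped so independent test modules reuse
the same synthetic recordings.
"""

from __future__ import annotations

import numpy as np
import pytest

from retinasc import cellsim, models, rf_estimation, stimgen

FRAME_RATE = 85.0
PX_UM = 15.0  # work at stimulus-square resolution


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_white_noise():
    """~60 s of 23x23 binary white noise."""
    return stimgen.gen_white_noise(
        n_frames=5100,
        squares_hw=(23, 23),
        square_px=1,
        pixel_size_um=PX_UM,
        frame_rate_hz=FRAME_RATE,
        seed=7,
    )


@pytest.fixture(scope="session")
def long_white_noise():
    """300 s of 23x23 binary white noise (training-length recording)."""
    return stimgen.gen_white_noise(
        n_frames=25500,
        squares_hw=(23, 23),
        square_px=1,
        pixel_size_um=PX_UM,
        frame_rate_hz=FRAME_RATE,
        seed=1,
    )


@pytest.fixture(scope="session")
def linear_cell():
    """Ground-truth cell that is exactly an LN model."""
    return cellsim.make_model_cell(
        layout="grid",
        n_subunits=69,
        subunit_diameter_um=PX_UM,
        rf_diameter_um=150.0,
        pixel_size_um=PX_UM,
        subunit_nl="linear",
        out_nl=(1.0, 2.0, -2.0),
        mean_rate_target_hz=10.0,
        field_hw=(23, 23),
        seed=0,
    )


@pytest.fixture(scope="session")
def rectified_cell():
    """Ground-truth cell with pixel-scale rectified subunits."""
    return cellsim.make_model_cell(
        layout="grid",
        n_subunits=69,
        subunit_diameter_um=PX_UM,
        rf_diameter_um=150.0,
        pixel_size_um=PX_UM,
        subunit_nl="relu",
        out_nl=(1.0, 2.0, -2.0),
        mean_rate_target_hz=10.0,
        field_hw=(23, 23),
        seed=0,
    )


@pytest.fixture(scope="session")
def ln_recording(long_white_noise, linear_cell):
    """(rate, spikes) of the linear cell on the long white noise."""
    rate = cellsim.cell_rate(linear_cell, long_white_noise)
    spikes = cellsim.sample_spikes(rate, FRAME_RATE, n_trials=1, seed=21)
    return rate, spikes


@pytest.fixture(scope="session")
def sta_components(long_white_noise, ln_recording):
    """STA-derived (spatial, temporal, GaussianRF, gaussian-fit filter)
    for the linear cell."""
    _, spikes = ln_recording
    sta = rf_estimation.compute_sta(long_white_noise, spikes, window_frames=30)
    spatial, temporal = rf_estimation.extract_components(sta)
    rf, gfit = rf_estimation.fit_gaussian_rf(spatial, PX_UM)
    return spatial, temporal, rf, gfit


@pytest.fixture(scope="session")
def true_spatial_filter():
    """Gaussian-fit-style spatial filter matching the fixture cells'
    pooling envelope (sigma = RF diameter / 3)."""
    from retinasc.core import SpatialFilter

    h = w = 23
    yy, xx = np.mgrid[0:h, 0:w]
    c = (h - 1) / 2
    sigma = 150.0 / (3.0 * PX_UM)
    u = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return SpatialFilter(u, normalization="gaussian_fit")


@pytest.fixture(scope="session")
def convolved_long(long_white_noise):
    kernel = cellsim.biphasic_kernel()
    return models.temporal_convolve(long_white_noise, kernel)
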