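"""Reverse-correlation receptive-field estimation.

Computes spatiotemporal spike-triggered averages (STA) from binned white
noise responses, separates them into unit-norm spatial and temporal
components, fits an elliptical Gaussian to the spatial component, and
builds spike-time autocorrelograms for cell typing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from retinasc.core import (
    GaussianRF,
    SpatialFilter,
    SpatialNormalization,
    SpikeTrain,
    Stimulus,
    TemporalFilter,
)

__all__ = [
    "STA",
    "Autocorrelogram",
    "compute_sta",
    "robust_std",
    "extract_components",
    "fit_gaussian_rf",
    "autocorrelogram",
    "upsample_nearest",
]


@dataclass
class STA:
    """Spatiotemporal spike-triggered average.

    ``kernel[tau]`` is the spike-weighted stimulus ``tau`` frames in the
    past; only spikes with full filter support (bin index >= M-1 within
    each trial) contribute.
    """

    kernel: np.ndarray  # (M, H, W)
    origin: tuple[int, int]
    n_spikes_used: int
    frame_rate_hz: float
    pixel_size_um: float


@dataclass
class Autocorrelogram:
    """Unit-sum spike-train autocorrelogram: 150 bins of 0.5 ms, 0-75 ms."""

    values: np.ndarray
    bin_s: float = 0.0005


def compute_sta(
    stimulus: Stimulus | Sequence[Stimulus],
    spikes: SpikeTrain,
    window_frames: int = 30,
) -> STA:
    """STA over the past ``window_frames`` stimulus frames.

    ``STA[tau] = sum_t n_t z_{t-tau} / sum_t n_t`` summed over all eligible
    bins of all training trials; the first ``window_frames - 1`` bins of
    each trial are excluded.  Pass one stimulus per trial (or a single
    stimulus for a single trial).
    """
    stimuli = [stimulus] if isinstance(stimulus, Stimulus) else list(stimulus)
    if len(stimuli) != spikes.n_trials:
        raise ValueError("need one stimulus per spike-train trial")
    m = window_frames
    shape = stimuli[0].shape[1:]
    acc = np.zeros((m,) + shape)
    total = 0.0
    for stim, n_t in zip(stimuli, spikes.counts):
        z = stim.frames
        t_len = z.shape[0]
        if t_len < m:
            raise ValueError("trial shorter than the STA window")
        n_valid = n_t[m - 1 : t_len].astype(np.float64)
        total += n_valid.sum()
        for tau in range(m):
            acc[tau] += np.tensordot(n_valid, z[m - 1 - tau : t_len - tau], axes=(0, 0))
    if total == 0:
        raise ValueError("no eligible spikes for the STA")
    return STA(
        kernel=acc / total,
        origin=(0, 0),
        n_spikes_used=int(total),
        frame_rate_hz=stimuli[0].frame_rate_hz,
        pixel_size_um=stimuli[0].pixel_size_um,
    )


def robust_std(values: np.ndarray) -> float:
    """1.4826 times the median absolute deviation — a consistent estimator
    of the standard deviation for normal data."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def extract_components(
    sta: STA,
    threshold_sds: float = 6.0,
    crop_squares: int = 40,
) -> tuple[SpatialFilter, TemporalFilter]:
    """Split an STA into unit-norm spatial and temporal components.

    Pixels whose absolute peak intensity over time exceeds the median by
    ``threshold_sds`` robust standard deviations are selected; the
    temporal component is their mean time course, and the spatial
    component is the projection of the 3D STA onto the temporal component,
    cropped to ``crop_squares`` x ``crop_squares`` around the pixel with
    the largest temporal variance.
    """
    kernel = sta.kernel
    peaks = np.abs(kernel).max(axis=0)
    thr = np.median(peaks) + threshold_sds * robust_std(peaks)
    selected = peaks > thr
    if not selected.any():
        raise ValueError(
            "no pixel exceeds the STA significance threshold; "
            "a longer recording may be needed"
        )
    temporal = kernel[:, selected].mean(axis=1)

    var_map = kernel.var(axis=0)
    cy, cx = np.unravel_index(np.argmax(var_map), var_map.shape)
    h, w = var_map.shape
    half = crop_squares // 2
    r0 = int(np.clip(cy - half, 0, max(0, h - crop_squares)))
    c0 = int(np.clip(cx - half, 0, max(0, w - crop_squares)))
    r1, c1 = min(h, r0 + crop_squares), min(w, c0 + crop_squares)

    spatial = np.tensordot(kernel[:, r0:r1, c0:c1], temporal, axes=(0, 0))
    spatial_norm = np.linalg.norm(spatial)
    temporal_norm = np.linalg.norm(temporal)
    if spatial_norm == 0 or temporal_norm == 0:
        raise ValueError("degenerate STA: zero-norm component")
    return (
        SpatialFilter(
            weights=spatial / spatial_norm,
            origin=(r0, c0),
            normalization=SpatialNormalization.unit_norm,
        ),
        TemporalFilter(temporal / temporal_norm, sta.frame_rate_hz),
    )


def upsample_nearest(grid: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upsampling: repeat each value ``factor`` times per
    axis (the same STA value for every pixel of a stimulus square)."""
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    return np.kron(grid, np.ones((factor, factor)))


def _elliptical_gaussian(coords, amp, x0, y0, sx, sy, theta):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (x - x0) + st * (y - y0)
    v = -st * (x - x0) + ct * (y - y0)
    return amp * np.exp(-0.5 * (u**2 / sx**2 + v**2 / sy**2))


def fit_gaussian_rf(
    spatial: SpatialFilter,
    pixel_size_um: float,
    upsample_factor: int = 1,
) -> tuple[GaussianRF, SpatialFilter]:
    """Least-squares elliptical Gaussian fit to a spatial component.

    Returns the fit parameters and the fit evaluated on the (optionally
    nearest-neighbor upsampled) grid, with values beyond the 3-sigma
    ellipse set exactly to zero.  The receptive-field size is the diameter
    of the circle matching the area of the 1.5-sigma ellipse.
    """
    weights = spatial.weights
    if upsample_factor > 1:
        weights = upsample_nearest(weights, upsample_factor)
        pixel_size_um = pixel_size_um / upsample_factor
    h, w = weights.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # moment-based initialization from the positive part
    pos = np.clip(weights, 0.0, None)
    mass = pos.sum()
    if mass <= 0:
        raise ValueError("spatial component has no positive lobe to fit")
    x0 = float((pos * xx).sum() / mass)
    y0 = float((pos * yy).sum() / mass)
    sx0 = float(np.sqrt((pos * (xx - x0) ** 2).sum() / mass)) or 1.0
    sy0 = float(np.sqrt((pos * (yy - y0) ** 2).sum() / mass)) or 1.0
    p0 = [float(weights.max()), x0, y0, max(sx0, 0.5), max(sy0, 0.5), 0.0]

    try:
        popt, _ = curve_fit(
            _elliptical_gaussian,
            (xx.ravel(), yy.ravel()),
            weights.ravel(),
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = np.linalg.norm(
            weights.ravel()
            - _elliptical_gaussian((xx.ravel(), yy.ravel()), *p0)
        )
        raise RuntimeError(
            f"Gaussian receptive-field fit did not converge "
            f"(initial residual {resid:.3g}): {exc}"
        ) from exc
    amp, x0, y0, sx, sy, theta = popt
    sx, sy = abs(float(sx)), abs(float(sy))

    fit_vals = _elliptical_gaussian((xx, yy), amp, x0, y0, sx, sy, theta)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (xx - x0) + st * (yy - y0)
    v = -st * (xx - x0) + ct * (yy - y0)
    outside = (u**2 / sx**2 + v**2 / sy**2) > 9.0  # beyond the 3-sigma ellipse
    fit_vals = np.where(outside, 0.0, fit_vals)
    fit_vals = np.clip(fit_vals, 0.0, None)

    rf = GaussianRF(
        center=(float(x0), float(y0)),
        sigma_x=sx,
        sigma_y=sy,
        angle=float(theta),
        amplitude=float(amp),
        pixel_size_um=pixel_size_um,
    )
    sf = SpatialFilter(
        weights=fit_vals,
        origin=spatial.origin if upsample_factor == 1 else (
            spatial.origin[0] * upsample_factor,
            spatial.origin[1] * upsample_factor,
        ),
        normalization=SpatialNormalization.gaussian_fit,
    )
    return rf, sf


def autocorrelogram(
    spike_times_s: np.ndarray,
    bin_s: float = 0.0005,
    n_bins: int = 150,
) -> Autocorrelogram:
    """Unit-sum autocorrelogram of a spike train.

    Counts ordered spike pairs with lags in ``[0, n_bins * bin_s)`` at
    ``bin_s`` resolution.  Zero-lag self-pairs are excluded.
    """
    times = np.sort(np.asarray(spike_times_s, dtype=np.float64).ravel())
    if times.size < 2:
        raise ValueError("need at least two spikes")
    max_lag = n_bins * bin_s
    counts = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_s
    for i, t in enumerate(times[:-1]):
        j = np.searchsorted(times, t + max_lag, side="left")
        lags = times[i + 1 : j] - t
        if lags.size:
            counts += np.histogram(lags, bins=edges)[0]
    total = counts.sum()
    if total == 0:
        raise ValueError("no spike pairs within the autocorrelogram range")
    return Autocorrelogram(values=counts / total, bin_s=bin_s)
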