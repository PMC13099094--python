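"""Ground-truth model ganglion cells.

Cells are rectified-subunit LNLN cascades with Poisson spiking: a bank of
unit-norm Gaussian subunit filters, a shared biphasic temporal kernel, a
per-subunit nonlinearity (ReLU or linear), Gaussian-envelope pooling
weights, and a softplus output rescaled to a target mean firing rate.
Setting the subunit nonlinearity to 'linear' with appropriate pooling
collapses the cascade to an exact LN cell, which anchors the
parameter-recovery and model-comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from retinasc.core import SpikeTrain, Stimulus, TemporalFilter
from retinasc.models import temporal_convolve

__all__ = [
    "GroundTruthCell",
    "biphasic_kernel",
    "make_model_cell",
    "cell_rate",
    "sample_spikes",
]


@dataclass
class GroundTruthCell:
    """A simulated rectified-subunit ganglion cell.

    ``subunit_filters`` has shape (n_subunits, H, W) with each filter
    normalized to unit Euclidean norm; ``subunit_weights`` are the
    non-negative Gaussian-envelope pooling weights.
    """

    subunit_centers: np.ndarray  # (n, 2) as (row, col) px
    subunit_sigma_px: float
    subunit_weights: np.ndarray  # (n,), >= 0
    subunit_filters: np.ndarray  # (n, H, W), unit norm each
    temporal_kernel: TemporalFilter
    subunit_nl: str  # 'relu' | 'linear'
    out_nl: tuple[float, float, float]  # softplus (a, b, c)
    polarity: str  # 'ON' | 'OFF'
    mean_rate_target_hz: float
    field_hw: tuple[int, int]
    # white-noise calibration of the pooled drive (mean, sd, rate gain);
    # computed lazily so the same gain applies to every stimulus
    _calibration: tuple[float, float, float] | None = None

    @property
    def n_subunits(self) -> int:
        return self.subunit_filters.shape[0]


def biphasic_kernel(
    n_taps: int = 30,
    tap_rate_hz: float = 85.0,
    peak_s: float = 0.05,
    trough_s: float = 0.12,
    trough_weight: float = 0.55,
) -> TemporalFilter:
    """Smooth biphasic temporal kernel (difference of two gamma lobes).

    Tap 0 corresponds to the current frame; the positive lobe peaks near
    ``peak_s`` in the past, followed by a weaker opposite-sign lobe.
    Returned with unit Euclidean norm.
    """
    t = np.arange(n_taps) / tap_rate_hz

    def gamma_lobe(peak: float, order: int = 5) -> np.ndarray:
        tau = peak / order
        g = (t / tau) ** order * np.exp(-t / tau)
        return g / g.max()

    taps = gamma_lobe(peak_s) - trough_weight * gamma_lobe(trough_s)
    return TemporalFilter(taps, tap_rate_hz).normalized()


def _hex_lattice(spacing: float, radius: float) -> np.ndarray:
    """Hexagonal lattice points (row, col) within ``radius`` of the origin."""
    pts = []
    n_rings = int(np.ceil(radius / (spacing * np.sqrt(3) / 2))) + 1
    for j in range(-n_rings, n_rings + 1):
        for i in range(-n_rings, n_rings + 1):
            x = spacing * (i + 0.5 * (j % 2))
            y = spacing * (np.sqrt(3) / 2) * j
            if np.hypot(x, y) <= radius + 1e-9:
                pts.append((y, x))
    pts = np.array(pts) if pts else np.zeros((0, 2))
    order = np.lexsort((pts[:, 1], pts[:, 0], np.hypot(pts[:, 0], pts[:, 1])))
    return pts[order]


def _grid_lattice(spacing: float, radius: float) -> np.ndarray:
    n = int(np.ceil(radius / spacing)) + 1
    pts = []
    for j in range(-n, n + 1):
        for i in range(-n, n + 1):
            y, x = spacing * j, spacing * i
            if np.hypot(x, y) <= radius + 1e-9:
                pts.append((y, x))
    pts = np.array(pts)
    order = np.lexsort((pts[:, 1], pts[:, 0], np.hypot(pts[:, 0], pts[:, 1])))
    return pts[order]


def make_model_cell(
    layout: str,
    n_subunits: int,
    subunit_diameter_um: float,
    rf_diameter_um: float,
    pixel_size_um: float,
    subunit_nl: str = "relu",
    polarity: str = "ON",
    mean_rate_target_hz: float = 5.0,
    out_nl: tuple[float, float, float] = (1.0, 1.0, -1.0),
    field_hw: tuple[int, int] | None = None,
    n_taps: int = 30,
    frame_rate_hz: float = 85.0,
    seed: int = 0,
) -> GroundTruthCell:
    """Build a ground-truth cell whose subunits tile a receptive-field disc.

    Subunit centers sit on a grid or hexagonal lattice with spacing equal
    to the subunit diameter, inside a disc of diameter ``rf_diameter_um``.
    Diameters follow the 3-sigma convention (diameter = 3 filter SDs).
    Pooling weights come from a circular Gaussian envelope whose 3-sigma
    diameter equals the receptive-field diameter.  OFF polarity negates
    the temporal kernel.
    """
    if n_subunits < 1:
        raise ValueError("need at least one subunit")
    if subunit_diameter_um >= rf_diameter_um and n_subunits > 1:
        raise ValueError("subunit diameter must be smaller than the RF diameter")
    if subunit_nl not in ("relu", "linear"):
        raise ValueError("subunit_nl must be 'relu' or 'linear'")
    if polarity not in ("ON", "OFF"):
        raise ValueError("polarity must be 'ON' or 'OFF'")

    spacing_px = subunit_diameter_um / pixel_size_um
    rf_radius_px = 0.5 * rf_diameter_um / pixel_size_um
    if n_subunits == 1:
        centers = np.zeros((1, 2))
    else:
        lattice = {"grid": _grid_lattice, "hex": _hex_lattice}.get(layout)
        if lattice is None:
            raise ValueError("layout must be 'grid' or 'hex'")
        pts = lattice(spacing_px, rf_radius_px)
        if pts.shape[0] < n_subunits:
            raise ValueError(
                f"only {pts.shape[0]} lattice sites fit in the receptive-field "
                f"disc; cannot place {n_subunits} subunits"
            )
        centers = pts[:n_subunits]

    sigma_sub_px = subunit_diameter_um / (3.0 * pixel_size_um)
    # pooling envelope: circular Gaussian whose 3-sigma span equals the RF
    sigma_env_px = rf_diameter_um / (3.0 * pixel_size_um)
    d = np.hypot(centers[:, 0], centers[:, 1])
    weights = np.exp(-(d**2) / (2.0 * sigma_env_px**2))

    if field_hw is None:
        margin = int(np.ceil(rf_radius_px + 4 * sigma_sub_px)) + 2
        side = 2 * margin + 1
        field_hw = (side, side)
    h, w = field_hw
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    filters = np.empty((n_subunits, h, w))
    for i, (dy, dx) in enumerate(centers):
        g = np.exp(
            -((yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2)
            / (2.0 * sigma_sub_px**2)
        )
        filters[i] = g / np.linalg.norm(g)

    kernel = biphasic_kernel(n_taps=n_taps, tap_rate_hz=frame_rate_hz)
    if polarity == "OFF":
        kernel = TemporalFilter(-kernel.taps, kernel.tap_rate_hz)

    return GroundTruthCell(
        subunit_centers=centers,
        subunit_sigma_px=sigma_sub_px,
        subunit_weights=weights,
        subunit_filters=filters,
        temporal_kernel=kernel,
        subunit_nl=subunit_nl,
        out_nl=out_nl,
        polarity=polarity,
        mean_rate_target_hz=mean_rate_target_hz,
        field_hw=field_hw,
    )


def _pooled_drive(cell: GroundTruthCell, stimulus: Stimulus) -> np.ndarray:
    t_frames, h, w = stimulus.shape
    if (h, w) != cell.field_hw:
        raise ValueError(
            f"stimulus frame size {(h, w)} does not match the cell's field "
            f"{cell.field_hw}"
        )
    conv = temporal_convolve(stimulus, cell.temporal_kernel)
    flat = conv.h.reshape(t_frames, -1)
    drives = flat @ cell.subunit_filters.reshape(cell.n_subunits, -1).T
    if cell.subunit_nl == "relu":
        drives = np.maximum(drives, 0.0)
    return drives @ cell.subunit_weights


_CALIBRATION_FRAMES = 8500
_CALIBRATION_SEED = 987_654_321


def _calibrate(cell: GroundTruthCell) -> tuple[float, float, float]:
    """Standardize the pooled drive and set the rate gain on a fixed
    internal white-noise stimulus, so the cell's input-output mapping is
    identical across stimuli and its white-noise mean rate hits the target.
    """
    if cell._calibration is not None:
        return cell._calibration
    from retinasc.stimgen import gen_white_noise

    h, w = cell.field_hw
    ref = gen_white_noise(
        _CALIBRATION_FRAMES, (h, w), 1, 15.0, cell.temporal_kernel.tap_rate_hz,
        seed=_CALIBRATION_SEED,
    )
    pooled = _pooled_drive(cell, ref)
    mu, sd = float(pooled.mean()), float(pooled.std())
    if sd == 0:
        sd = 1.0
    a, b, c = cell.out_nl
    lam = a * np.logaddexp(0.0, b * (pooled - mu) / sd + c)
    mean_lam = lam.mean()
    if mean_lam <= 0:
        raise RuntimeError("degenerate cell: zero mean rate during calibration")
    gain = cell.mean_rate_target_hz / float(mean_lam)
    cell._calibration = (mu, sd, gain)
    return cell._calibration


def cell_rate(cell: GroundTruthCell, stimulus: Stimulus) -> np.ndarray:
    """Firing rate (Hz) of the cell in response to a stimulus.

    The stimulus is temporally convolved with the cell's kernel, projected
    onto each subunit filter, passed through the subunit nonlinearity, and
    pooled with the envelope weights.  The pooled drive is standardized by
    the cell's white-noise calibration statistics and mapped through the
    softplus output, with a fixed gain that makes the white-noise mean
    rate equal ``mean_rate_target_hz``.
    """
    mu, sd, gain = _calibrate(cell)
    pooled = (_pooled_drive(cell, stimulus) - mu) / sd
    a, b, c = cell.out_nl
    return gain * a * np.logaddexp(0.0, b * pooled + c)


def sample_spikes(
    rate_hz: np.ndarray,
    frame_rate_hz: float,
    n_trials: int,
    seed: int = 0,
) -> SpikeTrain:
    """Draw Poisson spike counts per bin, i.i.d. across trials."""
    rate_hz = np.asarray(rate_hz, dtype=np.float64)
    if np.any(rate_hz < 0):
        raise ValueError("firing rates must be non-negative")
    rng = np.random.default_rng(seed)
    lam = rate_hz / frame_rate_hz
    counts = rng.poisson(lam, size=(n_trials, lam.size))
    return SpikeTrain(counts=counts, bin_rate_hz=frame_rate_hz)
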