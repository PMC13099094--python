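"""Shared domain types, spike binning, and file I/O.

Containers follow a few global conventions: stimuli are stored as
``T x H x W`` Weber-contrast arrays (dimensionless), time is in seconds
internally, and file metadata carries rates in Hz and pixel sizes in
micrometers.  Stimulus containers are HDF5 (``frames`` dataset plus root
attributes); spike lists are CSV with a ``trial,time_s`` header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "StimulusKind",
    "Stimulus",
    "SpikeTrain",
    "TemporalFilter",
    "SpatialFilter",
    "GaussianRF",
    "EyeTrace",
    "bin_spikes",
    "read_stimulus",
    "write_stimulus",
    "read_spikes",
    "write_spikes",
    "FormatError",
]


class FormatError(ValueError):
    """A container file is missing required structure or metadata."""


class StimulusKind(str, Enum):
    white_noise = "white_noise"
    grating = "grating"
    movie = "movie"


@dataclass
class Stimulus:
    """A spatiotemporal contrast movie.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Weber contrast per pixel (dimensionless).  A binary checkerboard
        takes values exactly {-1, +1}.
    frame_rate_hz : float
        Presentation rate of the frames.
    pixel_size_um : float
        Side length of one pixel on the retinal surface.
    origin : (int, int)
        (row, col) of this crop in full-field coordinates.
    kind : StimulusKind
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    origin: tuple[int, int] = (0, 0)
    kind: StimulusKind = StimulusKind.white_noise

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if min(self.frames.shape) < 1:
            raise ValueError("T, H, W must all be >= 1")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.kind = StimulusKind(self.kind)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_times_s(self) -> np.ndarray:
        """Start times of each frame bin, plus the end of the last bin."""
        return np.arange(self.n_frames + 1) / self.frame_rate_hz


@dataclass
class SpikeTrain:
    """Binned spike counts, one row per trial.

    ``counts`` has shape (n_trials, n_bins); all entries are non-negative
    integers.  When paired with a :class:`Stimulus`, ``bin_rate_hz`` equals
    the stimulus frame rate.
    """

    counts: np.ndarray
    bin_rate_hz: float
    spike_times_s: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim == 1:
            counts = counts[np.newaxis, :]
        if counts.ndim != 2:
            raise ValueError("counts must be 1D or 2D (trials x bins)")
        if np.any(counts < 0):
            raise ValueError("spike counts must be non-negative")
        if not np.all(counts == np.round(counts)):
            raise ValueError("spike counts must be integers")
        self.counts = counts.astype(np.int64)
        if not self.bin_rate_hz > 0:
            raise ValueError("bin_rate_hz must be positive")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())


@dataclass
class TemporalFilter:
    """Temporal stimulus filter, most-recent-first (tap 0 = current frame)."""

    taps: np.ndarray
    tap_rate_hz: float

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=np.float64).ravel()
        if self.taps.size < 1:
            raise ValueError("filter needs at least one tap")
        if not self.tap_rate_hz > 0:
            raise ValueError("tap_rate_hz must be positive")

    def __len__(self) -> int:
        return self.taps.size

    def normalized(self) -> "TemporalFilter":
        nrm = np.linalg.norm(self.taps)
        if nrm == 0:
            raise ValueError("cannot normalize an all-zero filter")
        return TemporalFilter(self.taps / nrm, self.tap_rate_hz)


class SpatialNormalization(str, Enum):
    unit_norm = "unit_norm"
    gaussian_fit = "gaussian_fit"


@dataclass
class SpatialFilter:
    """Spatial weights over a crop of the stimulus field.

    ``unit_norm`` filters have Euclidean norm 1.  ``gaussian_fit`` filters
    are non-negative with weights beyond the 3-sigma ellipse set exactly
    to zero.
    """

    weights: np.ndarray
    origin: tuple[int, int] = (0, 0)
    normalization: SpatialNormalization = SpatialNormalization.unit_norm

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("spatial weights must be a 2D grid")
        self.normalization = SpatialNormalization(self.normalization)
        if self.normalization is SpatialNormalization.gaussian_fit and np.any(
            self.weights < 0
        ):
            raise ValueError("gaussian_fit weights must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass
class GaussianRF:
    """Elliptical Gaussian receptive-field fit.

    ``rf_size_um`` is the diameter of the circle with the same area as the
    1.5-sigma ellipse of the fit: ``2 * 1.5 * sqrt(sx*sy) * pixel_size``.
    """

    center: tuple[float, float]  # (x, y) in pixels of the fitted grid
    sigma_x: float
    sigma_y: float
    angle: float  # radians
    amplitude: float
    pixel_size_um: float

    @property
    def rf_size_um(self) -> float:
        return 2.0 * 1.5 * np.sqrt(self.sigma_x * self.sigma_y) * self.pixel_size_um


@dataclass
class EyeTrace:
    """Per-frame gaze offsets (dx, dy) in monitor pixels with event labels.

    Offsets reset to (0, 0) at the start of each chunk.  Labels are
    ``'saccade'`` or ``'fixation'`` per frame.
    """

    offsets: np.ndarray  # (n_frames, 2) int
    labels: np.ndarray  # (n_frames,) '<U8'
    chunk_starts: np.ndarray = field(default_factory=lambda: np.array([0]))

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.labels = np.asarray(self.labels)
        self.chunk_starts = np.asarray(self.chunk_starts, dtype=np.int64)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must have shape (n_frames, 2)")
        if self.labels.shape[0] != self.offsets.shape[0]:
            raise ValueError("labels and offsets must have the same length")

    def __len__(self) -> int:
        return self.offsets.shape[0]


def bin_spikes(
    spike_times_s: Sequence[float] | np.ndarray,
    frame_times_s: Sequence[float] | np.ndarray,
) -> SpikeTrain:
    """Bin spike times at stimulus frame resolution.

    Bin *i* covers the half-open interval ``[frame_times[i],
    frame_times[i+1])``; spikes outside all bins are dropped, so the total
    count never exceeds the number of spikes.

    Parameters
    ----------
    spike_times_s : array-like
        Spike times in seconds.
    frame_times_s : array-like
        Strictly increasing bin edges (frame onsets plus final offset);
        ``len(frame_times_s) - 1`` bins result.

    Raises
    ------
    ValueError
        If frame times are not strictly increasing.
    """
    frame_times = np.asarray(frame_times_s, dtype=np.float64)
    if frame_times.ndim != 1 or frame_times.size < 2:
        raise ValueError("need at least two frame times (one bin)")
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    spikes = np.asarray(spike_times_s, dtype=np.float64)
    counts, _ = np.histogram(spikes, bins=frame_times)
    # np.histogram closes the last bin on the right; enforce half-open.
    counts[-1] -= int(np.count_nonzero(spikes == frame_times[-1]))
    n_bins = frame_times.size - 1
    dt = np.diff(frame_times)
    bin_rate = 1.0 / float(np.median(dt))
    return SpikeTrain(
        counts=counts.reshape(1, n_bins),
        bin_rate_hz=bin_rate,
        spike_times_s=[spikes],
    )


# ---------------------------------------------------------------------------
# File I/O


_STIM_ATTRS = ("frame_rate_hz", "pixel_size_um")


def write_stimulus(stimulus: Stimulus, path: str | Path) -> None:
    """Write a stimulus to HDF5 (``frames`` dataset + root attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stimulus.frames)
        f.attrs["frame_rate_hz"] = stimulus.frame_rate_hz
        f.attrs["pixel_size_um"] = stimulus.pixel_size_um
        f.attrs["origin"] = list(stimulus.origin)
        f.attrs["kind"] = stimulus.kind.value


def read_stimulus(path: str | Path) -> Stimulus:
    """Read a stimulus written by :func:`write_stimulus`.

    Raises :class:`FormatError` naming any missing metadata field.
    """
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise FormatError("stimulus file is missing the 'frames' dataset")
        for attr in _STIM_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"stimulus file is missing metadata field '{attr}'")
        frames = f["frames"][()]
        origin = tuple(int(v) for v in f.attrs.get("origin", (0, 0)))
        kind = str(f.attrs.get("kind", "white_noise"))
        return Stimulus(
            frames=frames,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            origin=origin,
            kind=StimulusKind(kind),
        )


def write_spikes(
    spike_times_by_trial: Sequence[np.ndarray], path: str | Path
) -> None:
    """Write spike times as CSV with columns ``trial,time_s``."""
    rows = [
        (trial, float(t))
        for trial, times in enumerate(spike_times_by_trial)
        for t in np.asarray(times).ravel()
    ]
    pd.DataFrame(rows, columns=["trial", "time_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path) -> list[np.ndarray]:
    """Read a ``trial,time_s`` CSV into per-trial spike-time arrays."""
    df = pd.read_csv(path)
    for col in ("trial", "time_s"):
        if col not in df.columns:
            raise FormatError(f"spike file is missing column '{col}'")
    if len(df) == 0:
        return []
    n_trials = int(df["trial"].max()) + 1
    return [
        np.sort(df.loc[df["trial"] == k, "time_s"].to_numpy(dtype=np.float64))
        for k in range(n_trials)
    ]
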