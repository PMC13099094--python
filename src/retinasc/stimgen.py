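"""Stimulus generators: checkerboard white noise, reversing gratings, and
surrogate naturalistic movies with simulated gaze shifts.

All generators are deterministic given their configuration and seed.
Intensities live on a [0, 1] display scale (white-noise mean 0.5) until the
final Weber-contrast conversion; analysis-ready stimuli are dimensionless
contrast movies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from retinasc.core import EyeTrace, Stimulus, StimulusKind

__all__ = [
    "GazeParams",
    "MovieConfig",
    "gen_white_noise",
    "gen_reversing_grating",
    "rgb_to_luminance",
    "frame_repeat_schedule",
    "sample_saccade_amplitudes",
    "simulate_gaze_trace",
    "apply_gaze_shifts",
    "gen_spectral_noise",
    "gen_surrogate_movie",
    "train_test_split_frames",
    "n_training_frames",
]

#: Display intensity of the white-noise mean on the [0, 1] scale.
WHITE_NOISE_MEAN_LEVEL = 0.5


@dataclass
class GazeParams:
    """Parameters of the simulated saccade/fixation gaze model."""

    saccade_amp_scale_um: float = 200.0
    saccade_dur_frames: tuple[int, ...] = (2, 3, 4)
    saccade_dur_probs: tuple[float, ...] = (0.35, 0.4, 0.25)
    fixation_scale_ms: float = 200.0
    fixation_refractory_ms: float = 100.0
    jitter_sd_px: float = 2.0
    chunk_s: float = 10.0
    max_drift_px: float = 200.0
    max_chunk_attempts: int = 1000

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.saccade_dur_probs), 1.0):
            raise ValueError("saccade duration probabilities must sum to 1")
        for name in ("saccade_amp_scale_um", "fixation_scale_ms", "chunk_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixation_refractory_ms < 0:
            raise ValueError("fixation_refractory_ms must be non-negative")


@dataclass
class MovieConfig:
    """Configuration of the surrogate naturalistic movie generator."""

    n_frames: int = 850
    height: int = 64
    width: int = 64
    spectral_exponent: float = 2.0
    mean_level_fraction: float = 0.76
    rms_contrast: float = 0.45
    temporal_corr_s: float = 0.2
    frame_rate_hz: float = 85.0
    pixel_size_um: float = 7.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms_contrast < 0:
            raise ValueError("rms_contrast must be non-negative")
        if self.n_frames < 1 or self.height < 1 or self.width < 1:
            raise ValueError("movie dimensions must be positive")


def gen_white_noise(
    n_frames: int,
    squares_hw: tuple[int, int],
    square_px: int,
    pixel_size_um: float,
    frame_rate_hz: float,
    seed: int,
    canvas_hw: tuple[int, int] | None = None,
) -> Stimulus:
    """Binary checkerboard white noise at 100% contrast.

    Each of ``squares_hw = (rows, cols)`` stimulus squares is drawn i.i.d.
    from {-1, +1} with equal probability and redrawn every frame; each
    square covers ``square_px`` monitor pixels per side.

    Parameters
    ----------
    canvas_hw : optional
        If given, the requested square layout must fit inside this
        (height, width) pixel canvas.
    """
    rows, cols = squares_hw
    if square_px < 1:
        raise ValueError("square_px must be >= 1")
    if rows < 1 or cols < 1:
        raise ValueError("need at least one stimulus square per dimension")
    h_px, w_px = rows * square_px, cols * square_px
    if canvas_hw is not None and (h_px > canvas_hw[0] or w_px > canvas_hw[1]):
        raise ValueError(
            f"{rows}x{cols} squares of {square_px} px exceed the "
            f"{canvas_hw[0]}x{canvas_hw[1]} px canvas"
        )
    rng = np.random.default_rng(seed)
    squares = rng.integers(0, 2, size=(n_frames, rows, cols)) * 2.0 - 1.0
    frames = np.repeat(np.repeat(squares, square_px, axis=1), square_px, axis=2)
    return Stimulus(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        kind=StimulusKind.white_noise,
    )


def gen_reversing_grating(
    stripe_width_px: int,
    phase_px: int,
    reversal_period_s: float,
    n_periods: int,
    frame_rate_hz: float,
    field_hw: tuple[int, int] = (600, 800),
    pixel_size_um: float = 7.5,
) -> Stimulus:
    """Contrast-reversing vertical square-wave grating at +/-1.

    Polarity flips every ``reversal_period_s``; one full temporal period of
    the stimulus is two reversals.  ``phase_px`` shifts the stripe
    boundaries horizontally.
    """
    if stripe_width_px < 1:
        raise ValueError("stripe_width_px must be >= 1")
    if reversal_period_s <= 0 or n_periods < 1:
        raise ValueError("need positive reversal period and at least one period")
    h, w = field_hw
    cols = np.arange(w)
    profile = np.where(((cols + phase_px) // stripe_width_px) % 2 == 0, 1.0, -1.0)
    pattern = np.broadcast_to(profile, (h, w))
    n_frames = int(round(n_periods * 2 * reversal_period_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    polarity = np.where((np.floor(t / reversal_period_s) % 2) == 0, 1.0, -1.0)
    frames = polarity[:, None, None] * pattern[None, :, :]
    return Stimulus(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        kind=StimulusKind.grating,
    )


def rgb_to_luminance(r, g, b):
    """Linear luminance from RGB: ``0.2126 R + 0.7152 G + 0.0722 B``."""
    return 0.2126 * np.asarray(r) + 0.7152 * np.asarray(g) + 0.0722 * np.asarray(b)


#: Repeat-count distribution used to bridge 24 Hz movie frames to the 85 Hz
#: projector: 3 repeats with probability 0.46, 4 with 0.54 (mean 3.54).
REPEAT_COUNTS = (3, 4)
REPEAT_PROBS = (0.46, 0.54)


def frame_repeat_schedule(n_movie_frames: int, seed: int) -> np.ndarray:
    """Number of projector frames for each movie frame (values in {3, 4})."""
    if n_movie_frames < 1:
        raise ValueError("need at least one movie frame")
    rng = np.random.default_rng(seed)
    return rng.choice(REPEAT_COUNTS, size=n_movie_frames, p=REPEAT_PROBS)


def expected_repeat_count() -> float:
    """Expectation of the frame-repeat distribution."""
    return float(np.dot(REPEAT_COUNTS, REPEAT_PROBS))


def sample_saccade_amplitudes(
    n: int, params: GazeParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw saccade amplitudes (micrometers) from the gaze model."""
    return rng.exponential(params.saccade_amp_scale_um, size=n)


def _gen_chunk(
    n_frames: int,
    frame_rate_hz: float,
    pixel_size_um: float,
    params: GazeParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gaze chunk: float offsets and labels, starting at (0, 0)."""
    offsets = np.zeros((n_frames, 2))
    labels = np.empty(n_frames, dtype="<U8")
    center = np.zeros(2)
    t = 0
    fixating = True
    while t < n_frames:
        if fixating:
            dur_s = (
                params.fixation_refractory_ms / 1000.0
                + rng.exponential(params.fixation_scale_ms / 1000.0)
            )
            dur = max(1, int(round(dur_s * frame_rate_hz)))
            stop = min(t + dur, n_frames)
            jitter = rng.normal(0.0, params.jitter_sd_px, size=(stop - t, 2))
            offsets[t:stop] = center + jitter
            labels[t:stop] = "fixation"
            t = stop
        else:
            amp_px = sample_saccade_amplitudes(1, params, rng)[0] / pixel_size_um
            theta = rng.uniform(0.0, 2.0 * np.pi)
            target = center + amp_px * np.array([np.cos(theta), np.sin(theta)])
            dur = int(rng.choice(params.saccade_dur_frames, p=params.saccade_dur_probs))
            stop = min(t + dur, n_frames)
            frac = np.arange(1, stop - t + 1) / dur
            offsets[t:stop] = center + frac[:, None] * (target - center)
            labels[t:stop] = "saccade"
            center = target
            t = stop
        fixating = not fixating
    offsets[0] = 0.0  # offsets reset to origin at the chunk start
    labels[0] = "fixation"
    return offsets, labels


def simulate_gaze_trace(
    duration_s: float,
    frame_rate_hz: float,
    pixel_size_um: float,
    params: GazeParams | None = None,
    seed: int = 0,
) -> EyeTrace:
    """Simulate a gaze trace of alternating fixations and saccades.

    Saccade amplitudes are exponential (scale ``saccade_amp_scale_um``),
    directions uniform, durations 2/3/4 frames with probabilities
    0.35/0.4/0.25, with linear interpolation from start to target during
    the saccade.  Fixation durations are a 100 ms refractory period plus an
    exponential with 200 ms scale; during fixation the position is jittered
    per frame by independent Gaussian noise with 2 px per-axis SD.  Traces
    are built in 10 s chunks with the offset reset to (0, 0) at every chunk
    start; chunks drifting beyond ``max_drift_px`` in any direction are
    rejected and regenerated.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    params = params or GazeParams()
    rng = np.random.default_rng(seed)
    total_frames = int(round(duration_s * frame_rate_hz))
    chunk_frames = max(1, int(round(params.chunk_s * frame_rate_hz)))
    all_offsets, all_labels, chunk_starts = [], [], []
    produced = 0
    while produced < total_frames:
        n = min(chunk_frames, total_frames - produced)
        for attempt in range(params.max_chunk_attempts):
            offsets, labels = _gen_chunk(n, frame_rate_hz, pixel_size_um, params, rng)
            rounded = np.rint(offsets).astype(np.int64)
            if np.abs(rounded).max() <= params.max_drift_px:
                break
        else:
            raise RuntimeError(
                f"no gaze chunk within the {params.max_drift_px} px drift bound "
                f"after {params.max_chunk_attempts} attempts"
            )
        chunk_starts.append(produced)
        all_offsets.append(rounded)
        all_labels.append(labels)
        produced += n
    return EyeTrace(
        offsets=np.concatenate(all_offsets, axis=0),
        labels=np.concatenate(all_labels),
        chunk_starts=np.array(chunk_starts, dtype=np.int64),
    )


def apply_gaze_shifts(
    frames: np.ndarray, trace: EyeTrace, fill_value: float
) -> np.ndarray:
    """Translate each frame by its integer (dx, dy) gaze offset.

    ``dx`` moves content along columns and ``dy`` along rows; border pixels
    uncovered by the shift are filled with ``fill_value`` (gray).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if len(trace) != frames.shape[0]:
        raise ValueError("trace length must equal the number of frames")
    _, h, w = frames.shape
    out = np.full_like(frames, fill_value)
    for i, (dx, dy) in enumerate(trace.offsets):
        dx, dy = int(dx), int(dy)
        if abs(dx) >= w or abs(dy) >= h:
            raise ValueError(f"gaze offset ({dx}, {dy}) exceeds the frame size")
        src_r = slice(max(0, -dy), min(h, h - dy))
        dst_r = slice(max(0, dy), min(h, h + dy))
        src_c = slice(max(0, -dx), min(w, w - dx))
        dst_c = slice(max(0, dx), min(w, w + dx))
        out[i, dst_r, dst_c] = frames[i, src_r, src_c]
    return out


def gen_spectral_noise(
    n_frames: int,
    height: int,
    width: int,
    spectral_exponent: float,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian fields with a 1/f^exponent spatial power spectrum.

    Frames are temporally correlated through an AR(1) recursion with
    coefficient ``rho`` (linear, so the spatial spectrum is unaffected).
    The output is standardized to zero mean and unit variance over the
    whole movie.
    """
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-spectral_exponent / 2.0)

    def one_field() -> np.ndarray:
        white = rng.normal(size=(height, width))
        return np.real(np.fft.ifft2(np.fft.fft2(white) * amp))

    frames = np.empty((n_frames, height, width))
    frames[0] = one_field()
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_frames):
        frames[t] = rho * frames[t - 1] + scale * one_field()
    frames -= frames.mean()
    frames /= frames.std()
    return frames


def gen_surrogate_movie(
    config: MovieConfig,
    gaze: GazeParams | None = None,
    seed: int | None = None,
) -> Stimulus:
    """Surrogate naturalistic movie: 1/f^exponent spatial statistics, slow
    temporal correlation, simulated gaze shifts, Weber-contrast output.

    Intensity frames are built on the [0, 1] display scale around a mean
    level of ``mean_level_fraction`` of the white-noise mean and calibrated
    (with clipping to the displayable range) so the realized space-time RMS
    contrast matches ``config.rms_contrast``; if clipping makes the target
    unreachable within 5%, a warning reports the realized contrast.  Global
    motion is added with :func:`apply_gaze_shifts`, after which every pixel
    is converted to Weber contrast by subtracting and dividing by its
    temporal mean.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rho = float(np.exp(-1.0 / (config.temporal_corr_s * config.frame_rate_hz)))
    g = gen_spectral_noise(
        config.n_frames,
        config.height,
        config.width,
        config.spectral_exponent,
        rho,
        rng,
    )
    mean_level = config.mean_level_fraction * WHITE_NOISE_MEAN_LEVEL

    # Calibrate the pre-clip contrast so the post-clip realized contrast
    # hits the target; a few fixed-point steps suffice for mild clipping.
    c_eff = config.rms_contrast
    intensity = None
    for _ in range(8):
        intensity = np.clip(mean_level * (1.0 + c_eff * g), 0.0, 1.0)
        realized = intensity.std() / intensity.mean()
        if realized <= 0:
            break
        if abs(realized - config.rms_contrast) / max(config.rms_contrast, 1e-12) < 0.01:
            break
        c_eff *= config.rms_contrast / realized
    realized = intensity.std() / intensity.mean()
    if (
        config.rms_contrast > 0
        and abs(realized - config.rms_contrast) / config.rms_contrast > 0.05
    ):
        warnings.warn(
            f"target RMS contrast {config.rms_contrast:.3f} not realizable "
            f"within the displayable range; realized {realized:.3f}",
            stacklevel=2,
        )

    if gaze is not None:
        trace = simulate_gaze_trace(
            duration_s=config.n_frames / config.frame_rate_hz,
            frame_rate_hz=config.frame_rate_hz,
            pixel_size_um=config.pixel_size_um,
            params=gaze,
            seed=seed + 1,
        )
        intensity = apply_gaze_shifts(intensity, trace, fill_value=mean_level)

    pixel_mean = intensity.mean(axis=0, keepdims=True)
    # a pixel clipped to zero for the whole movie has undefined contrast;
    # report it as zero (only reachable with unrealizable contrast targets)
    safe_mean = np.where(pixel_mean > 0, pixel_mean, 1.0)
    weber = np.where(pixel_mean > 0, (intensity - pixel_mean) / safe_mean, 0.0)
    return Stimulus(
        frames=weber,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
        kind=StimulusKind.movie,
    )


def train_test_split_frames(
    n_usable_frames: int, test_len: int, test_start: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Reserve a contiguous test segment from a usable-frame index list."""
    if not 0 <= test_start <= n_usable_frames - test_len:
        raise ValueError("test segment does not fit in the usable frames")
    idx = np.arange(n_usable_frames)
    test = idx[test_start : test_start + test_len]
    train = np.concatenate([idx[:test_start], idx[test_start + test_len :]])
    return train, test


def n_training_frames(
    n_trials: int, trial_duration_s: float, frame_rate_hz: float
) -> int:
    """Total stimulus frames across non-repeating training trials."""
    return int(round(n_trials * trial_duration_s * frame_rate_hz))
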