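"""Response-statistics suite: reversing-grating index, 2D firing-rate
histograms and LSC sensitivity, radially averaged power spectra, and
cell-feature clustering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "RGIResult",
    "Hist2D",
    "LSCSensitivityResult",
    "reversing_grating_index",
    "rate_histogram_2d",
    "fit_softplus_family",
    "lsc_sensitivity",
    "rapsd",
    "build_features_and_cluster",
]


@dataclass
class RGIResult:
    """Reversing-grating index: largest second-harmonic amplitude over
    largest fundamental amplitude, each maximized independently across all
    stripe-width/phase conditions."""

    f1: float
    f2: float
    index: float
    f1_condition: int
    f2_condition: int


def _harmonic_amplitude(psth: np.ndarray, harmonic_hz: float, bin_s: float) -> float:
    n = psth.size
    duration = n * bin_s
    idx = int(round(harmonic_hz * duration))
    spectrum = np.fft.rfft(psth)
    return 2.0 * np.abs(spectrum[idx]) / n


def reversing_grating_index(
    psths: np.ndarray,
    stim_freq_hz: float = 1.0,
    bin_s: float = 0.005,
) -> RGIResult:
    """F2/F1 index from trial-averaged PSTHs, one row per grating condition.

    For each condition the Fourier amplitudes at the stimulus frequency
    (F1) and twice the stimulus frequency (F2) are extracted; the index is
    the ratio of the across-condition maxima.
    """
    psths = np.atleast_2d(np.asarray(psths, dtype=np.float64))
    f1 = np.array([_harmonic_amplitude(p, stim_freq_hz, bin_s) for p in psths])
    f2 = np.array([_harmonic_amplitude(p, 2.0 * stim_freq_hz, bin_s) for p in psths])
    i1, i2 = int(np.argmax(f1)), int(np.argmax(f2))
    if f1[i1] == 0:
        raise ValueError("largest F1 amplitude is zero; index undefined")
    return RGIResult(
        f1=float(f1[i1]),
        f2=float(f2[i2]),
        index=float(f2[i2] / f1[i1]),
        f1_condition=i1,
        f2_condition=i2,
    )


@dataclass
class Hist2D:
    """2D firing-rate histogram over (I_mean, LSC) bins.

    Rows index LSC bins, columns I_mean bins.  ``mean_rate`` is NaN where
    ``count`` is zero.  In ``quantile_60_trimmed`` mode the signals are
    binned into 60 equal-count bins each and the first and last bin of
    each axis are dropped.
    """

    mean_rate: np.ndarray  # (n_lsc, n_imean)
    count: np.ndarray
    imean_edges: np.ndarray
    lsc_edges: np.ndarray
    row_levels: np.ndarray  # mean LSC of samples per row (l_i)
    col_levels: np.ndarray  # mean I_mean of samples per column
    mode: str

    @property
    def normalized(self) -> np.ndarray:
        """Rates normalized to the largest entry (display convention)."""
        peak = np.nanmax(self.mean_rate)
        return self.mean_rate / peak if peak > 0 else self.mean_rate


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    # order-statistic edges: bins hold equal sample counts (within one
    # for sample sizes not divisible by n_bins, exactly for distinct data)
    srt = np.sort(x)
    idx = (np.arange(1, n_bins) * srt.size) // n_bins
    return np.concatenate(
        [[srt[0]], srt[idx], [np.nextafter(srt[-1], np.inf)]]
    )


def rate_histogram_2d(
    imean: np.ndarray,
    lsc: np.ndarray,
    counts: np.ndarray,
    mode: str = "equal_40",
) -> Hist2D:
    """Bin I_mean and LSC independently and average the firing response in
    each bin pair.

    ``equal_40``: 40 equal-width bins per axis (display histograms).
    ``quantile_60_trimmed``: 60 equal-count bins per axis with the first
    and last bin of each axis excluded (used for the softplus-family fit).
    """
    imean = np.asarray(imean, dtype=np.float64).ravel()
    lsc = np.asarray(lsc, dtype=np.float64).ravel()
    rate = np.asarray(counts, dtype=np.float64).ravel()
    if imean.size == 0:
        raise ValueError("empty input")
    if not (imean.size == lsc.size == rate.size):
        raise ValueError("imean, lsc, and counts must have equal lengths")

    if mode == "equal_40":
        i_edges = np.linspace(imean.min(), np.nextafter(imean.max(), np.inf), 41)
        l_edges = np.linspace(lsc.min(), np.nextafter(lsc.max(), np.inf), 41)
        trim = False
    elif mode == "quantile_60_trimmed":
        i_edges = _quantile_edges(imean, 60)
        l_edges = _quantile_edges(lsc, 60)
        trim = True
    else:
        raise ValueError("mode must be 'equal_40' or 'quantile_60_trimmed'")

    ii = np.clip(np.digitize(imean, i_edges) - 1, 0, i_edges.size - 2)
    li = np.clip(np.digitize(lsc, l_edges) - 1, 0, l_edges.size - 2)
    n_i, n_l = i_edges.size - 1, l_edges.size - 1

    flat = li * n_i + ii
    cnt = np.bincount(flat, minlength=n_l * n_i).reshape(n_l, n_i)
    rate_sum = np.bincount(flat, weights=rate, minlength=n_l * n_i).reshape(n_l, n_i)
    with np.errstate(invalid="ignore"):
        mean_rate = np.where(cnt > 0, rate_sum / np.maximum(cnt, 1), np.nan)

    i_sum = np.bincount(ii, weights=imean, minlength=n_i)
    i_cnt = np.bincount(ii, minlength=n_i)
    col_levels = np.where(i_cnt > 0, i_sum / np.maximum(i_cnt, 1), np.nan)
    l_sum = np.bincount(li, weights=lsc, minlength=n_l)
    l_cnt = np.bincount(li, minlength=n_l)
    row_levels = np.where(l_cnt > 0, l_sum / np.maximum(l_cnt, 1), np.nan)

    if trim:
        mean_rate = mean_rate[1:-1, 1:-1]
        cnt = cnt[1:-1, 1:-1]
        i_edges, l_edges = i_edges[1:-1], l_edges[1:-1]
        row_levels, col_levels = row_levels[1:-1], col_levels[1:-1]

    return Hist2D(
        mean_rate=mean_rate,
        count=cnt,
        imean_edges=i_edges,
        lsc_edges=l_edges,
        row_levels=row_levels,
        col_levels=col_levels,
        mode=mode,
    )


def fit_softplus_family(hist: Hist2D) -> tuple[float, float, np.ndarray]:
    """Joint least-squares fit of ``f_i(x) = a ln(1 + e^(b (x - c_i)))``
    to the rows of a 2D rate histogram.

    The scale ``a`` and slope ``b`` are shared across rows; each row gets
    its own threshold ``c_i`` (NaN for empty rows).  Returns (a, b, c).
    """
    rate = hist.mean_rate
    x = hist.col_levels
    rows = [i for i in range(rate.shape[0]) if np.isfinite(rate[i]).any()]
    if len(rows) < 3:
        raise ValueError("need at least three non-empty histogram rows")

    xs, ys, row_of = [], [], []
    for ri, i in enumerate(rows):
        mask = np.isfinite(rate[i]) & np.isfinite(x)
        xs.append(x[mask])
        ys.append(rate[i][mask])
        row_of.append(np.full(mask.sum(), ri))
    xs = np.concatenate(xs)
    ys = np.concatenate(ys)
    row_of = np.concatenate(row_of).astype(int)

    x_scale = xs.std() or 1.0
    a0 = max(np.nanmax(ys), 1e-6)
    theta0 = np.concatenate([[a0, 1.0 / x_scale], np.full(len(rows), np.median(xs))])

    def residuals(theta):
        a, b = theta[0], theta[1]
        c = theta[2:][row_of]
        return a * np.logaddexp(0.0, b * (xs - c)) - ys

    res = least_squares(residuals, theta0, max_nfev=20000)
    if not res.success:
        raise RuntimeError(
            f"softplus-family fit failed (final cost {res.cost:.3g}): {res.message}"
        )
    a, b = float(res.x[0]), float(res.x[1])
    c_full = np.full(rate.shape[0], np.nan)
    c_full[rows] = res.x[2:]
    return a, b, c_full


@dataclass
class LSCSensitivityResult:
    """Sensitivity = -1/m, where m is the slope of the LSC level versus
    row-threshold regression after Local-Outlier-Factor removal."""

    slope: float
    sensitivity: float
    infinite: bool
    inlier_mask: np.ndarray
    c: np.ndarray = field(default_factory=lambda: np.array([]))
    l: np.ndarray = field(default_factory=lambda: np.array([]))


def lsc_sensitivity(
    c: np.ndarray,
    l: np.ndarray,
    n_neighbors: int = 5,
) -> LSCSensitivityResult:
    """LSC sensitivity from per-row thresholds ``c_i`` and LSC levels
    ``l_i``.

    Outlier (c_i, l_i) pairs are removed with a Local Outlier Factor score
    over 5 nearest neighbours, then ordinary least squares regresses l on
    c; the sensitivity is -1/slope (flagged infinite for a vanishing
    slope, larger positive values meaning more nonlinear cells).
    """
    c = np.asarray(c, dtype=np.float64).ravel()
    l = np.asarray(l, dtype=np.float64).ravel()
    finite = np.isfinite(c) & np.isfinite(l)
    c, l = c[finite], l[finite]
    if c.size < 3:
        raise ValueError("need at least three (c_i, l_i) pairs")

    mask = np.ones(c.size, dtype=bool)
    if c.size > n_neighbors + 1:
        pts = np.column_stack([c, l])
        # scale axes so the neighbour metric is not dominated by units
        scale = pts.std(axis=0)
        scale[scale == 0] = 1.0
        lof = LocalOutlierFactor(n_neighbors=n_neighbors)
        mask = lof.fit_predict(pts / scale) == 1
        if mask.sum() < 3:
            mask = np.ones(c.size, dtype=bool)

    m = float(np.polyfit(c[mask], l[mask], 1)[0])
    infinite = abs(m) < np.finfo(float).eps * max(1.0, np.abs(l).max())
    sensitivity = np.inf if infinite else -1.0 / m
    return LSCSensitivityResult(
        slope=m,
        sensitivity=float(sensitivity),
        infinite=bool(infinite),
        inlier_mask=mask,
        c=c,
        l=l,
    )


def rapsd(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectral density of square frames.

    Each N x N frame is Fourier transformed with a 1/N normalization, the
    power ``|h_kl|^2`` is averaged within unit-width radial frequency bins
    centered on the zero-frequency term, and the per-frame curves are
    averaged.  Returns (radial_bins, mean_power_per_bin).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3 or frames.shape[1] != frames.shape[2]:
        raise ValueError("input must be one or more square N x N frames")
    n = frames.shape[1]
    ky = np.fft.fftfreq(n, d=1.0 / n)
    kx = np.fft.fftfreq(n, d=1.0 / n)
    r = np.hypot(ky[:, None], kx[None, :])
    bins = np.floor(r).astype(np.int64).ravel()
    n_bins = bins.max() + 1
    bin_counts = np.bincount(bins, minlength=n_bins)

    fhat = np.fft.fft2(frames, axes=(1, 2)) / n
    power = np.abs(fhat) ** 2
    sums = np.vstack(
        [np.bincount(bins, weights=p.ravel(), minlength=n_bins) for p in power]
    )
    curve = (sums / bin_counts).mean(axis=0)
    return np.arange(n_bins), curve


def build_features_and_cluster(
    temporal_filters: np.ndarray,
    rf_sizes_um: np.ndarray,
    autocorrelograms: np.ndarray,
    k: int,
    seed: int = 0,
    n_acg_pcs: int = 10,
    variance_retained: float = 0.90,
) -> np.ndarray:
    """Cluster cells from temporal filters, RF sizes, and autocorrelograms.

    The feature vector per cell is: the temporal-filter taps, the
    receptive-field size, and the first ``n_acg_pcs`` PCA scores of the
    per-entry Z-scored autocorrelograms.  Every feature entry is Z-scored
    across cells, reduced by PCA retaining ``variance_retained`` of the
    variance, and clustered with KMeans++ (10 restarts, seeded).
    """
    tf = np.atleast_2d(np.asarray(temporal_filters, dtype=np.float64))
    rf = np.asarray(rf_sizes_um, dtype=np.float64).ravel()
    acg = np.atleast_2d(np.asarray(autocorrelograms, dtype=np.float64))
    n_cells = tf.shape[0]
    if not (rf.size == n_cells == acg.shape[0]):
        raise ValueError("feature inputs must agree on the number of cells")
    if k > n_cells:
        raise ValueError(f"cannot form {k} clusters from {n_cells} cells")
    if not np.all(np.isfinite(tf)) or not np.all(np.isfinite(rf)):
        raise ValueError("features must be finite")

    def zscore_cols(x: np.ndarray) -> np.ndarray:
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd[sd == 0] = 1.0
        return (x - mu) / sd

    acg_scores = PCA(
        n_components=min(n_acg_pcs, n_cells, acg.shape[1]), random_state=seed
    ).fit_transform(zscore_cols(acg))
    features = zscore_cols(np.column_stack([tf, rf, acg_scores]))

    max_comp = min(features.shape)
    pca = PCA(n_components=max_comp, random_state=seed).fit(features)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_retained) + 1)
    reduced = pca.transform(features)[:, :n_comp]

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(reduced)
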