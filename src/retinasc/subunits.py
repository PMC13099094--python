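"""Subunit-model pipeline: spike-triggered covariance, logical-OR subunit
recovery, and the LNLN subunit model.

Gradient-based training (Adam with mini-batches, plateau learning-rate
decay, early stopping, Group-Lasso / L1 regularization, and pruning) is
implemented directly on analytic gradients in NumPy, so no deep-learning
framework is required.  All training is deterministic given (data, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from retinasc.core import GaussianRF
from retinasc.models import ConvolvedStimulus

__all__ = [
    "STCResult",
    "prune_by_magnitude",
    "LogicalORParams",
    "SubunitModel",
    "TrainConfig",
    "crop_for_stc",
    "compute_stc",
    "select_basis",
    "fit_logical_or",
    "fit_subunit_model",
    "predict_subunit",
    "predict_logical_or",
]

_P_EPS = 1e-7


@dataclass
class STCResult:
    """Eigendecomposition of the spike-triggered covariance matrix.

    Eigenvalues are sorted in descending order; ``eigenvectors[:, k]``
    matches ``eigenvalues[k]`` and is a flattened spatial filter over the
    crop.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_pix, n_pix), columns
    crop_shape: tuple[int, int]
    crop_origin: tuple[int, int]


@dataclass
class LogicalORParams:
    """Fitted logical-OR model and the subunit filters derived from it."""

    U: np.ndarray  # (k, n_pix) basis rows (STC eigenvectors)
    A: np.ndarray  # (k, n_init) weight columns per subunit
    alpha: np.ndarray  # (n_init,) activation thresholds
    subunit_filters: np.ndarray  # (n_kept, n_pix), unit norm
    initial_weights: np.ndarray  # (n_kept,) pre-normalization norms
    kept: np.ndarray  # indices into the initial subunits
    train_history: dict = field(default_factory=dict)


@dataclass
class SubunitModel:
    """LNLN subunit model: unit-norm spatial filters ``q``, non-negative
    pooling weights ``p``, and a softplus output ``f(x) = a ln(1+e^(x+c))``."""

    q: np.ndarray  # (n, n_pix), unit norm rows
    p: np.ndarray  # (n,), >= 0
    out_a: float
    out_c: float
    crop_shape: tuple[int, int]
    train_history: dict = field(default_factory=dict)


@dataclass
class TrainConfig:
    """Shared mini-batch training hyperparameters."""

    lr: float = 5e-3
    batch_size: int = 512
    max_epochs: int = 500
    lr_decay: float = 0.8
    plateau_epochs: int = 5
    early_stop_epochs: int = 50
    warmup_epochs: int = 50
    val_fraction: float = 0.2


def prune_by_magnitude(values: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Indices of entries whose magnitude is at least ``fraction`` of the
    largest magnitude (the 10% pruning rule)."""
    mags = np.abs(np.asarray(values, dtype=np.float64))
    return np.flatnonzero(mags >= fraction * mags.max())


def crop_for_stc(
    conv: ConvolvedStimulus,
    rf: GaussianRF,
    max_side: int = 16,
) -> ConvolvedStimulus:
    """Crop the convolved stimulus to the smallest square enclosing the
    receptive field's 3-sigma ellipse, clamped to ``max_side`` pixels."""
    _, h, w = conv.h.shape
    x0, y0 = rf.center
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("receptive-field center lies outside the stimulus")
    ct, st = np.cos(rf.angle), np.sin(rf.angle)
    half_x = 3.0 * np.hypot(rf.sigma_x * ct, rf.sigma_y * st)
    half_y = 3.0 * np.hypot(rf.sigma_x * st, rf.sigma_y * ct)
    side = int(np.ceil(2.0 * max(half_x, half_y)))
    side = max(1, min(side, max_side, h, w))
    r0 = int(np.clip(round(y0 - side / 2.0), 0, h - side))
    c0 = int(np.clip(round(x0 - side / 2.0), 0, w - side))
    return ConvolvedStimulus(
        h=conv.h[:, r0 : r0 + side, c0 : c0 + side],
        valid_from=conv.valid_from,
        frame_rate_hz=conv.frame_rate_hz,
        pixel_size_um=conv.pixel_size_um,
    )


def compute_stc(conv: ConvolvedStimulus, counts: np.ndarray) -> STCResult:
    """Spike-triggered covariance of the cropped, temporally convolved
    stimulus, weighted by spike counts over valid bins."""
    t_len, h, w = conv.h.shape
    n = np.asarray(counts, dtype=np.float64).ravel()
    if n.size != t_len:
        raise ValueError("counts must align with the convolved stimulus")
    x = conv.h[conv.valid_from :].reshape(-1, h * w)
    n = n[conv.valid_from :]
    total = n.sum()
    if total <= h * w:
        raise ValueError(
            f"insufficient spikes ({total:.0f}) for a {h * w}-dimensional STC"
        )
    mu = (n @ x) / total
    xc = x - mu
    cov = (xc.T * n) @ xc / (total - 1.0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return STCResult(
        eigenvalues=evals[order],
        eigenvectors=evecs[:, order],
        crop_shape=(h, w),
        crop_origin=(0, 0),
    )


def select_basis(stc: STCResult, k: int = 16) -> np.ndarray:
    """Top-``k`` STC eigenvectors by absolute eigenvalue deviation from the
    median eigenvalue; returned as rows of an orthonormal basis ``U``."""
    evals = stc.eigenvalues
    if evals.size < k:
        raise ValueError(f"spectrum has {evals.size} eigenvalues, need {k}")
    scores = np.abs(evals - np.median(evals))
    order = np.argsort(-scores, kind="stable")[:k]
    return stc.eigenvectors[:, order].T.copy()


class _Adam:
    """Adam over a list of arrays, with per-parameter state."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _split_train_val(n_samples: int, val_fraction: float) -> tuple[slice, slice]:
    n_val = int(round(n_samples * val_fraction))
    if n_val < 1 or n_val >= n_samples:
        raise ValueError("validation split is empty; need more samples")
    return slice(0, n_samples - n_val), slice(n_samples - n_val, n_samples)


def predict_logical_or(
    U: np.ndarray, A: np.ndarray, alpha: np.ndarray, h_flat: np.ndarray
) -> np.ndarray:
    """Spike probability ``P = 1 - prod_i (1 - g_i(U^T A_i . h))`` with
    logistic subunit nonlinearities ``g_i(x) = 1 / (1 + e^-(alpha_i + x))``."""
    y = h_flat @ U.T  # (T, k)
    g = expit(y @ A + alpha)  # (T, n)
    return 1.0 - np.prod(1.0 - g, axis=1)


def _bernoulli_nll(n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    return float(-np.sum(n * np.log(p) + (1.0 - n) * np.log(1.0 - p)))


def fit_logical_or(
    U: np.ndarray,
    conv: ConvolvedStimulus,
    counts: np.ndarray,
    seed: int = 0,
    n_init: int = 16,
    group_lasso_base: float = 1e-4,
    prune_fraction: float = 0.1,
    config: TrainConfig | None = None,
) -> LogicalORParams:
    """Transform an STC basis into localized subunit filters.

    Spike counts are binarized and the Bernoulli likelihood of the
    logical-OR spiking model is minimized by mini-batch Adam (lr 5e-3,
    batch 512, x0.8 learning-rate decay on a 5-epoch validation plateau,
    up to 500 epochs, early stop after 50 stale epochs, best-validation
    state kept).  A Group-Lasso penalty on the subunit norms, with
    strength ``1e-4 * N_f / 400`` for ``N_f`` pixels per filter, is applied
    after a 50-epoch warm-up.  Subunits whose norm falls below 10% of the
    maximum are pruned; survivors are normalized to unit norm and their
    pre-normalization norms returned as initial pooling weights.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    t_len = conv.h.shape[0]
    n_pix = conv.h.shape[1] * conv.h.shape[2]
    n_all = np.asarray(counts, dtype=np.float64).ravel()
    if n_all.size != t_len:
        raise ValueError("counts must align with the convolved stimulus")
    h_flat = conv.h[conv.valid_from :].reshape(-1, n_pix)
    n_bin = (n_all[conv.valid_from :] > 0).astype(np.float64)

    y_all = h_flat @ U.T  # (T, k) projected stimulus
    tr, va = _split_train_val(y_all.shape[0], cfg.val_fraction)
    y_tr, n_tr = y_all[tr], n_bin[tr]
    y_va, n_va = y_all[va], n_bin[va]

    k = U.shape[0]
    lam_gl = group_lasso_base * n_pix / 400.0
    A = rng.normal(0.0, 0.01, size=(k, n_init))
    alpha = np.zeros(n_init)
    opt = _Adam([A, alpha], cfg.lr)

    def val_loss() -> float:
        g = expit(y_va @ A + alpha)
        p = 1.0 - np.prod(1.0 - g, axis=1)
        return _bernoulli_nll(n_va, p) / max(1, n_va.size)

    best = {"loss": np.inf, "A": A.copy(), "alpha": alpha.copy()}
    stale_lr = stale_stop = 0
    history = {"val_loss": []}
    n_train = y_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            yb, nb = y_tr[idx], n_tr[idx]
            g = expit(yb @ A + alpha)  # (B, n)
            one_minus_p = np.prod(1.0 - g, axis=1)
            p = np.clip(1.0 - one_minus_p, _P_EPS, 1.0 - _P_EPS)
            # dNLL/dP * dP/ddrive; dP/ddrive_i = (1 - P) * g_i
            dP = -nb / p + (1.0 - nb) / (1.0 - p)
            ddrive = (dP * (1.0 - p))[:, None] * g
            grad_A = yb.T @ ddrive / idx.size
            grad_alpha = ddrive.sum(axis=0) / idx.size
            if epoch >= cfg.warmup_epochs and lam_gl > 0:
                norms = np.linalg.norm(A, axis=0)
                nz = norms > 1e-12
                grad_A[:, nz] += lam_gl * A[:, nz] / norms[nz]
            opt.step([grad_A, grad_alpha])
        vl = val_loss()
        history["val_loss"].append(vl)
        if vl < best["loss"] - 1e-9:
            best = {"loss": vl, "A": A.copy(), "alpha": alpha.copy()}
            stale_lr = stale_stop = 0
        else:
            stale_lr += 1
            stale_stop += 1
        if stale_lr >= cfg.plateau_epochs:
            opt.lr *= cfg.lr_decay
            stale_lr = 0
        if stale_stop >= cfg.early_stop_epochs:
            break

    A, alpha = best["A"], best["alpha"]
    # subunit norms equal column norms of A because U has orthonormal rows
    q_all = (U.T @ A).T  # (n_init, n_pix)
    norms = np.linalg.norm(q_all, axis=1)
    kept = prune_by_magnitude(norms, prune_fraction)
    filters = q_all[kept] / norms[kept, None]
    return LogicalORParams(
        U=U,
        A=A,
        alpha=alpha,
        subunit_filters=filters,
        initial_weights=norms[kept],
        kept=kept,
        train_history=history,
    )


def _subunit_forward(y: np.ndarray, p: np.ndarray, a: float, c: float):
    s = np.maximum(y, 0.0)  # (T, n) rectified drives
    x = s @ p
    u = x + c
    lam = a * np.logaddexp(0.0, u)
    return s, x, u, lam


def predict_subunit(model: SubunitModel, conv: ConvolvedStimulus) -> np.ndarray:
    """Expected spike count per valid bin of the subunit model:
    ``f(sum_i p_i ReLU(q_i . h_t))`` with ``f(x) = a ln(1 + e^(x+c))``."""
    h, w = model.crop_shape
    if conv.h.shape[1:] != (h, w):
        raise ValueError(
            f"crop {conv.h.shape[1:]} does not match the training crop {(h, w)}"
        )
    flat = conv.h[conv.valid_from :].reshape(-1, h * w)
    y = flat @ model.q.T
    _, _, _, lam = _subunit_forward(y, model.p, model.out_a, model.out_c)
    return lam


def _train_subunit_stage(
    y_tr, n_tr, y_va, n_va, p0, a0, c0, l1, cfg, rng
) -> tuple[np.ndarray, float, float, list[float]]:
    p = p0.copy()
    ac = np.array([a0, c0])
    opt = _Adam([p, ac], cfg.lr)

    def val_loss() -> float:
        _, _, _, lam = _subunit_forward(y_va, p, ac[0], ac[1])
        lam = np.maximum(lam, 1e-12)
        return float(np.mean(lam - n_va * np.log(lam)))

    best = {"loss": np.inf, "p": p.copy(), "ac": ac.copy()}
    stale_lr = stale_stop = 0
    history = []
    n_train = y_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            yb, nb = y_tr[idx], n_tr[idx]
            s, x, u, lam = _subunit_forward(yb, p, ac[0], ac[1])
            lam_safe = np.maximum(lam, 1e-12)
            dlam = 1.0 - nb / lam_safe
            sp = np.logaddexp(0.0, u)
            sig = expit(u)
            da = float(np.sum(dlam * sp)) / idx.size
            common = dlam * ac[0] * sig
            dc = float(np.sum(common)) / idx.size
            grad_p = (common @ s) / idx.size
            if l1 > 0:
                grad_p = grad_p + l1 * np.sign(p)
            opt.step([grad_p, np.array([da, dc])])
            np.clip(p, 0.0, None, out=p)  # non-negativity after each update
            ac[0] = max(ac[0], 0.0)
        vl = val_loss()
        history.append(vl)
        if vl < best["loss"] - 1e-9:
            best = {"loss": vl, "p": p.copy(), "ac": ac.copy()}
            stale_lr = stale_stop = 0
        else:
            stale_lr += 1
            stale_stop += 1
        if stale_lr >= cfg.plateau_epochs:
            opt.lr *= cfg.lr_decay
            stale_lr = 0
        if stale_stop >= cfg.early_stop_epochs:
            break
    return best["p"], float(best["ac"][0]), float(best["ac"][1]), history


def fit_subunit_model(
    q: np.ndarray,
    conv: ConvolvedStimulus,
    counts: np.ndarray,
    seed: int = 0,
    p_init: np.ndarray | None = None,
    l1_strength: float = 1e-4,
    prune_fraction: float = 0.1,
    config: TrainConfig | None = None,
) -> SubunitModel:
    """Two-stage Poisson training of the LNLN subunit model.

    Stage one minimizes the Poisson likelihood over the pooling weights
    ``p`` and output nonlinearity (a, c) with an L1 penalty on ``p``
    (strength 1e-4, Adam lr 1e-3, the shared scheduler/early stopping,
    ``p`` clamped non-negative after every update), then prunes subunits
    whose weight falls below 10% of the maximum.  Stage two reinitializes
    with the survivors and retrains without regularization.
    """
    cfg = config or TrainConfig(lr=1e-3)
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if q.shape[0] < 1:
        raise ValueError("need at least one subunit filter")
    t_len, h, w = conv.h.shape
    n_all = np.asarray(counts, dtype=np.float64).ravel()
    if n_all.size != t_len:
        raise ValueError("counts must align with the convolved stimulus")
    flat = conv.h[conv.valid_from :].reshape(-1, h * w)
    n_valid = n_all[conv.valid_from :]
    y_all = flat @ q.T
    tr, va = _split_train_val(y_all.shape[0], cfg.val_fraction)
    rng = np.random.default_rng(seed)

    p0 = (
        np.asarray(p_init, dtype=np.float64).copy()
        if p_init is not None
        else np.ones(q.shape[0])
    )
    a0 = max(float(n_valid.max()), 1e-2)
    p1, a1, c1, hist1 = _train_subunit_stage(
        y_all[tr], n_valid[tr], y_all[va], n_valid[va],
        p0, a0, -2.0, l1_strength, cfg, rng,
    )
    kept = prune_by_magnitude(p1, prune_fraction)
    if kept.size == 0:
        raise RuntimeError("all subunits were pruned in stage one")
    p2, a2, c2, hist2 = _train_subunit_stage(
        y_all[tr][:, kept], n_valid[tr], y_all[va][:, kept], n_valid[va],
        p1[kept], a1, c1, 0.0, cfg, rng,
    )
    return SubunitModel(
        q=q[kept],
        p=p2,
        out_a=a2,
        out_c=c2,
        crop_shape=(h, w),
        train_history={"stage1_val": hist1, "stage2_val": hist2, "kept": kept},
    )
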