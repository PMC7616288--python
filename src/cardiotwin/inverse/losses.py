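"""Loss functions of the dual-branch VAE and the inference head.

Two layers are provided:

* plain-NumPy reference implementations of every term (chamfer
  reconstruction, QRS reconstruction, KL, segmentation, compactness,
  size, spatial, and their weighted totals), used for evaluation and as
  oracles in tests;
* differentiable counterparts on the autodiff engine
  (:mod:`.autodiff`) used by the training loop.  Counting losses use
  soft (probability-mass) counts during training since hard counts have
  zero gradient almost everywhere; the reference versions use the hard
  point sets as printed.

The size loss is implemented as |N_pre - N_gd| / N_gd: the signed ratio
would reward emptying the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor, cross_entropy, softmax


@dataclass
class TrainingConfig:
    """Loss weights and optimizer settings.  Defaults follow the
    full-scale training recipe: alpha = 5, lambda_KL = 0.01,
    lambda_compact = lambda_size = lambda_spa = lambda_VAE = 1,
    Adam with weight decay 1e-3, batch 4, lr 1e-4 halved every 6800
    iterations, 300 epochs.  All are scalable down for desk-size runs."""

    alpha: float = 5.0
    lam_kl: float = 0.01
    lam_compact: float = 1.0
    lam_size: float = 1.0
    lam_spa: float = 1.0
    lam_vae: float = 1.0
    lam_dice: float = 1.0
    lam_pc: float = 1.0
    lam_qrs: float = 1.0
    lr: float = 1e-4
    lr_decay: float = 0.5
    lr_decay_every: int = 6800
    weight_decay: float = 1e-3
    batch_size: int = 4
    epochs: int = 300
    soft_dtw_gamma: float = 1.0
    qrs_downsample: int = 8

    def validate(self):
        for name in ("alpha", "lam_kl", "lam_compact", "lam_size", "lam_spa",
                     "lam_vae", "lam_dice", "lam_pc", "lam_qrs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# reference (NumPy) implementations

def chamfer(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric chamfer distance: mean nearest-neighbour squared
    distance from a to b plus from b to a."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("chamfer distance of an empty point set")
    d = cdist(a, b, "sqeuclidean")
    return float(d.min(axis=1).mean() + d.min(axis=0).mean())


def chamfer_recon_loss(input_pcs, recon_coarse, recon_dense,
                       alpha: float = 5.0) -> float:
    """Sum over classes of (coarse chamfer + alpha * dense chamfer).

    ``input_pcs``, ``recon_coarse`` and ``recon_dense`` are sequences of
    per-class (n_k, 3) arrays; an empty class contributes 0 with a
    warning.
    """
    total = 0.0
    for k, (inp, rc, rd) in enumerate(zip(input_pcs, recon_coarse, recon_dense)):
        if len(inp) == 0 or len(rc) == 0 or len(rd) == 0:
            warnings.warn(f"class {k}: empty point set contributes 0",
                          stacklevel=2)
            continue
        total += chamfer(inp, rc) + alpha * chamfer(inp, rd)
    return float(total)


def qrs_recon_loss(qrs: np.ndarray, qrs_hat: np.ndarray,
                   lam_dur: float = 0.0) -> float:
    """MSE + (exact, path-normalized) DTW between two lead matrices."""
    from ..qrs_analysis import dtw_distance

    qrs = np.asarray(qrs, dtype=float)
    qrs_hat = np.asarray(qrs_hat, dtype=float)
    if qrs.shape != qrs_hat.shape:
        raise ValueError("QRS shapes differ")
    mse = float(np.mean((qrs - qrs_hat) ** 2))
    dtw = float(np.mean([dtw_distance(a, b, lam_dur)
                         for a, b in zip(np.atleast_2d(qrs), np.atleast_2d(qrs_hat))]))
    return mse + dtw


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, sigma^2) || N(0, 1) ), summed over dimensions:
    0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar))


def vae_loss(pc_rec: float, qrs_rec: float, kl: float,
             cfg: TrainingConfig | None = None) -> float:
    cfg = cfg or TrainingConfig()
    return cfg.lam_pc * pc_rec + cfg.lam_qrs * qrs_rec + cfg.lam_kl * kl


def soft_dice(pred_probs: np.ndarray, gt_labels: np.ndarray,
              n_classes: int = 3, eps: float = 1e-7) -> float:
    """Mean soft Dice over classes of per-point probabilities vs a
    one-hot ground truth."""
    p = np.asarray(pred_probs, dtype=float)
    gt = np.asarray(gt_labels, dtype=int)
    dices = []
    for c in range(n_classes):
        g = (gt == c).astype(float)
        inter = float((p[:, c] * g).sum())
        denom = float(p[:, c].sum() + g.sum())
        dices.append((2 * inter + eps) / (denom + eps))
    return float(np.mean(dices))


def seg_loss(pred_probs: np.ndarray, gt_labels: np.ndarray,
             lam_dice: float = 1.0) -> float:
    """Cross-entropy + lam_dice * (1 - mean soft Dice)."""
    p = np.asarray(pred_probs, dtype=float)
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("probabilities must sum to 1 per point")
    gt = np.asarray(gt_labels, dtype=int)
    picked = np.clip(np.take_along_axis(p, gt[:, None], axis=1)[:, 0], 1e-12, None)
    ce = float(-np.log(picked).mean())
    return ce + lam_dice * (1.0 - soft_dice(p, gt, p.shape[1]))


def compactness_loss(pred_mi_points: np.ndarray,
                     gt_mi_points: np.ndarray) -> float:
    """Mean over predicted infarct points of (distance to the predicted
    centroid + distance to the ground-truth centroid), normalized by the
    maximum ground-truth distance from its centroid.  Degenerate ground
    truth (coincident points) returns 0 with a warning."""
    pred = np.atleast_2d(np.asarray(pred_mi_points, dtype=float))
    gt = np.atleast_2d(np.asarray(gt_mi_points, dtype=float))
    if len(pred) < 1 or len(gt) < 2:
        warnings.warn("compactness loss undefined: too few points; returning 0",
                      stacklevel=2)
        return 0.0
    c_pre = pred.mean(axis=0)
    c_gd = gt.mean(axis=0)
    dmax = float(np.linalg.norm(gt - c_gd, axis=1).max())
    if dmax == 0.0:
        warnings.warn("compactness loss: coincident ground-truth points; "
                      "returning 0", stacklevel=2)
        return 0.0
    d_pre = np.linalg.norm(pred - c_pre, axis=1)
    d_gd = np.linalg.norm(pred - c_gd, axis=1)
    return float(np.mean((d_pre + d_gd) / dmax))


def size_loss(n_pre: float, n_gd: float) -> float:
    """|N_pre - N_gd| / N_gd; skipped (0, warning) when N_gd = 0."""
    if n_gd <= 0:
        warnings.warn("size loss skipped: no ground-truth infarct points",
                      stacklevel=2)
        return 0.0
    return float(abs(n_pre - n_gd) / n_gd)


def spatial_loss(n_rv_pre: float, n_pre: float) -> float:
    """Fraction of predicted infarct points lying in the RV (septal
    boundary excluded); 0 when nothing is predicted."""
    if n_pre <= 0:
        return 0.0
    return float(n_rv_pre / n_pre)


def total_inference_loss(vae: float, seg: float, compact: float,
                         size: float, spa: float,
                         cfg: TrainingConfig | None = None) -> float:
    """lam_VAE * L_VAE + L_seg + lam_compact * L_compact
    + lam_size * L_size + lam_spa * L_spa."""
    cfg = cfg or TrainingConfig()
    return (cfg.lam_vae * vae + seg + cfg.lam_compact * compact
            + cfg.lam_size * size + cfg.lam_spa * spa)


def rv_non_septal_mask(cobiveco: np.ndarray, eps: float = 0.02) -> np.ndarray:
    """RV points excluding the septal boundary band
    rt in [2/3 - eps, 2/3 + eps]."""
    tv, rt = cobiveco[:, 3], cobiveco[:, 2]
    return (tv == 1) & ~((rt >= 2.0 / 3.0 - eps) & (rt <= 2.0 / 3.0 + eps))


# ---------------------------------------------------------------------------
# differentiable training counterparts

def chamfer_ad(pred: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable symmetric chamfer: gradient w.r.t. the predicted
    points, nearest-neighbour assignments held fixed per step."""
    p = pred.data
    q = np.asarray(target, dtype=float)
    d = cdist(p, q, "sqeuclidean")
    nn_pq = d.argmin(axis=1)
    nn_qp = d.argmin(axis=0)
    val = d[np.arange(len(p)), nn_pq].mean() + d[nn_qp, np.arange(len(q))].mean()
    out = Tensor(val, True, (pred,))

    def bw(g):
        if pred.requires_grad:
            grad = 2.0 * (p - q[nn_pq]) / len(p)
            np.add.at(grad, nn_qp, 2.0 * (p[nn_qp] - q) / len(q))
            pred._accum(g * grad)
    out._backward = bw
    return out


def _softmin3(a, b, c, gamma):
    m = np.minimum(np.minimum(a, b), c)
    z = (np.exp(-(a - m) / gamma) + np.exp(-(b - m) / gamma)
         + np.exp(-(c - m) / gamma))
    return m - gamma * np.log(z)


def soft_dtw_ad(pred: Tensor, target: np.ndarray, gamma: float = 1.0) -> Tensor:
    """Batched soft-DTW between predicted and target signal batches of
    shape (B, T) with squared-difference local cost, averaged over the
    batch.  Forward and backward are the classical smoothed-DP
    recursions; the gradient w.r.t. the cost matrix is the expected
    alignment matrix."""
    a = pred.data
    b = np.asarray(target, dtype=float)
    B, T = a.shape
    Tb = b.shape[1]
    C = (a[:, :, None] - b[:, None, :]) ** 2
    # forward DP, vectorized over the batch axis
    R = np.full((B, T + 1, Tb + 1), np.inf)
    R[:, 0, 0] = 0.0
    for i in range(1, T + 1):
        for j in range(1, Tb + 1):
            R[:, i, j] = C[:, i - 1, j - 1] + _softmin3(
                R[:, i - 1, j - 1], R[:, i - 1, j], R[:, i, j - 1], gamma)
    val = R[:, T, Tb].mean()
    out = Tensor(val, True, (pred,))

    def bw(g):
        if not pred.requires_grad:
            return
        E = np.zeros((B, T + 2, Tb + 2))
        E[:, T + 1, Tb + 1] = 1.0
        Rp = np.full((B, T + 2, Tb + 2), -np.inf)
        Rp[:, 1:T + 1, 1:Tb + 1] = R[:, 1:, 1:]
        Rp[:, T + 1, Tb + 1] = R[:, T, Tb]
        Cp = np.zeros((B, T + 2, Tb + 2))
        Cp[:, 1:T + 1, 1:Tb + 1] = C
        for i in range(T, 0, -1):
            for j in range(Tb, 0, -1):
                wa = np.exp((Rp[:, i + 1, j] - Rp[:, i, j] - Cp[:, i + 1, j]) / gamma)
                wb = np.exp((Rp[:, i, j + 1] - Rp[:, i, j] - Cp[:, i, j + 1]) / gamma)
                wc = np.exp((Rp[:, i + 1, j + 1] - Rp[:, i, j]
                             - Cp[:, i + 1, j + 1]) / gamma)
                wa[~np.isfinite(wa)] = 0.0
                wb[~np.isfinite(wb)] = 0.0
                wc[~np.isfinite(wc)] = 0.0
                E[:, i, j] = (wa * E[:, i + 1, j] + wb * E[:, i, j + 1]
                              + wc * E[:, i + 1, j + 1])
        dC = E[:, 1:T + 1, 1:Tb + 1]
        grad_a = (dC * 2.0 * (a[:, :, None] - b[:, None, :])).sum(axis=2) / B
        pred._accum(g * grad_a)
    out._backward = bw
    return out


def soft_dtw_div_ad(pred: Tensor, target: np.ndarray,
                    gamma: float = 1.0) -> Tensor:
    """Soft-DTW divergence: sdtw(a, b) - 0.5 sdtw(a, a) - 0.5 sdtw(b, b).

    Removes the entropic bias of plain soft-DTW (which is negative even
    at a = b), so the term is approximately zero at a perfect
    reconstruction and bounded below.  The a-vs-a self term contributes
    twice its one-sided gradient (the expected-alignment matrix is
    symmetric for identical arguments).
    """
    ab = soft_dtw_ad(pred, target, gamma)
    aa = soft_dtw_ad(pred, pred.data, gamma)
    bb = float(soft_dtw_ad(Tensor(target), target, gamma).data)
    # aa's backward sees only its first argument; the true gradient of
    # sdtw(a, a) is twice that, so subtract the full aa tensor (gradient
    # -grad_first) and add back half its value as a constant.
    return ab - aa + (0.5 * float(aa.data) - 0.5 * bb)


def kl_gaussian_ad(mu: Tensor, logvar: Tensor) -> Tensor:
    return 0.5 * (mu * mu + logvar.exp() - 1.0 - logvar).sum()


def seg_loss_ad(logits: Tensor, gt_labels: np.ndarray,
                lam_dice: float = 1.0, eps: float = 1e-7) -> Tensor:
    """Differentiable CE + Dice on flat (N, C) logits."""
    ce = cross_entropy(logits, gt_labels)
    p = softmax(logits, axis=-1)
    gt = np.asarray(gt_labels, dtype=int)
    n_classes = logits.shape[-1]
    dice_sum = None
    for c in range(n_classes):
        g = (gt == c).astype(float)
        inter = (p[..., c] * Tensor(g)).sum()
        denom = p[..., c].sum() + float(g.sum())
        d = (2.0 * inter + eps) / (denom + eps)
        dice_sum = d if dice_sum is None else dice_sum + d
    dice_mean = dice_sum * (1.0 / n_classes)
    return ce + lam_dice * (1.0 - dice_mean)


def soft_counting_losses_ad(probs_mi: Tensor, xyz: np.ndarray,
                            gt_mi_mask: np.ndarray,
                            rv_mask: np.ndarray):
    """Soft-count versions of the compactness, size and spatial losses.

    ``probs_mi`` (N,) is the per-point predicted infarct probability
    (scar + BZ); counts become probability masses and the predicted
    centroid a probability-weighted mean.
    """
    n_gd = float(gt_mi_mask.sum())
    n_pre = probs_mi.sum()
    eps = 1e-8
    # size
    if n_gd > 0:
        diff = n_pre - n_gd
        size = (diff * diff + eps) ** 0.5 * (1.0 / n_gd)
    else:
        size = Tensor(0.0)
    # spatial
    n_rv = (probs_mi * Tensor(rv_mask.astype(float))).sum()
    spa = n_rv / (n_pre + eps)
    # compactness (soft): weighted distances to soft/pre and gt centroids
    gt_pts = xyz[gt_mi_mask]
    if len(gt_pts) >= 2:
        c_gd = gt_pts.mean(axis=0)
        dmax = float(np.linalg.norm(gt_pts - c_gd, axis=1).max())
    else:
        dmax = 0.0
    if dmax > 0:
        w = probs_mi
        wsum = w.sum() + eps
        cx = (w * Tensor(xyz[:, 0])).sum() / wsum
        cy = (w * Tensor(xyz[:, 1])).sum() / wsum
        cz = (w * Tensor(xyz[:, 2])).sum() / wsum
        dx = Tensor(xyz[:, 0]) - cx
        dy = Tensor(xyz[:, 1]) - cy
        dz = Tensor(xyz[:, 2]) - cz
        d_pre = (dx * dx + dy * dy + dz * dz + eps) ** 0.5
        d_gd = np.linalg.norm(xyz - c_gd, axis=1)
        compact = (w * (d_pre + Tensor(d_gd))).sum() / (wsum * dmax)
    else:
        compact = Tensor(0.0)
    return compact, size, spa
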