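"""Dual-branch variational autoencoder with an inference head.

The point-cloud branch is a PointNet-style shared-MLP encoder with
global max-pooling and a per-class fully-connected set decoder emitting
coarse and dense reconstructions.  The QRS branch is a bidirectional
Elman recurrent encoder over the temporally pooled 8-lead signal and a
recurrent decoder conditioned on the latent code.  The two latent
Gaussians are sampled with the reparameterization trick and
concatenated; the inference head propagates the fused code back to the
points (per-point features + tiled latent) and emits per-point logits
over {healthy, scar, border zone}.

Everything runs on the NumPy autodiff engine; sizes default to the
full-scale configuration (n = 4096, l_QRS = 512) and scale down for
desk-size experiments via :meth:`NetworkConfig.desk`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Parameter, Tensor, concat, glorot, softmax
from .losses import (TrainingConfig, chamfer_ad, kl_gaussian_ad, seg_loss_ad,
                     soft_counting_losses_ad, soft_dtw_div_ad,
                     rv_non_septal_mask)


@dataclass
class NetworkConfig:
    n: int = 4096               # input points
    d: int = 3                  # spatial features per point
    c: int = 4                  # Cobiveco features per point
    s: int = 3                  # output classes (healthy, scar, BZ)
    n_coarse: int = 1024
    n_dense: int = 4096
    n_lead: int = 8
    l_qrs: int = 512
    z_pc: int = 64
    z_qrs: int = 64
    pc_hidden: tuple = (64, 128)
    qrs_hidden: int = 32
    seg_hidden: int = 64
    dec_hidden: int = 128
    n_recon_classes: int = 2    # anatomy reconstruction classes (LV, RV)
    qrs_downsample: int = 8
    xyz_scale_mm: float = 50.0  # spatial normalization for the network

    def validate(self):
        if self.s != 3:
            raise ValueError("three tissue classes are required")
        if min(self.n, self.n_coarse, self.n_dense, self.z_pc, self.z_qrs) <= 0:
            raise ValueError("dimensions must be positive")

    @classmethod
    def desk(cls, n: int = 256, **kw) -> "NetworkConfig":
        """Reduced configuration for CPU-scale experiments."""
        return cls(n=n, n_coarse=max(n // 4, 16), n_dense=n,
                   z_pc=16, z_qrs=16, pc_hidden=(32, 64), qrs_hidden=16,
                   seg_hidden=48, dec_hidden=64, **kw)


@dataclass
class LatentState:
    mu_pc: Tensor
    logvar_pc: Tensor
    mu_qrs: Tensor
    logvar_qrs: Tensor
    z: Tensor                   # concatenated sample, dim z_pc + z_qrs


class DualBranchVAE:
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        p: dict[str, Parameter] = {}
        f_in = cfg.d + cfg.c
        h1, h2 = cfg.pc_hidden
        qh, zp, zq = cfg.qrs_hidden, cfg.z_pc, cfg.z_qrs
        zt = zp + zq
        T = cfg.l_qrs // cfg.qrs_downsample

        def lin(name, a, b):
            p[name + "_w"] = glorot(rng, a, b)
            p[name + "_b"] = Parameter(np.zeros(b))

        # point-cloud encoder
        lin("pc1", f_in, h1)
        lin("pc2", h1, h2)
        lin("pc_mu", h2, zp)
        lin("pc_lv", h2, zp)
        # QRS encoder (bidirectional recurrent + linear skip readout of
        # the pooled signal, easing gradient flow through the recursion)
        for tag in ("f", "b"):
            lin(f"qx{tag}", cfg.n_lead, qh)
            p[f"qh{tag}_w"] = glorot(rng, qh, qh)
        lin("q_skip", cfg.n_lead * T, 2 * qh)
        lin("q_mu", 4 * qh, zq)
        lin("q_lv", 4 * qh, zq)
        # point-cloud decoder (per reconstruction class)
        lin("dec_pc", zt, cfg.dec_hidden)
        nc = max(cfg.n_coarse // cfg.n_recon_classes, 1)
        nd = max(cfg.n_dense // cfg.n_recon_classes, 1)
        self.n_coarse_k, self.n_dense_k = nc, nd
        for k in range(cfg.n_recon_classes):
            lin(f"dec_c{k}", cfg.dec_hidden, nc * 3)
            lin(f"dec_d{k}", cfg.dec_hidden, nd * 3)
        # QRS decoder (recurrent, conditioned on z)
        lin("qd0", zt, qh)
        p["qdh_w"] = glorot(rng, qh, qh)
        lin("qdz", zt, qh)
        lin("qdy", qh, cfg.n_lead)
        # inference head
        lin("seg1", h2 + f_in + zt, cfg.seg_hidden)
        lin("seg1b", cfg.seg_hidden, cfg.seg_hidden)
        lin("seg2", cfg.seg_hidden, cfg.s)
        # start with tight posteriors (sigma ~ e^-2) so the latent code
        # carries signal, not noise, from the first epochs
        p["pc_lv_b"].data[:] = -4.0
        p["q_lv_b"].data[:] = -4.0
        self.params = p
        self.T = T

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    # -- submodules ---------------------------------------------------------
    def _lin(self, x, name):
        return x @ self.params[name + "_w"] + self.params[name + "_b"]

    def encode_pc(self, pts: Tensor):
        h1 = self._lin(pts, "pc1").relu()
        h2 = self._lin(h1, "pc2").relu()          # (B, n, h2) per-point feats
        g = h2.max(axis=1)                        # (B, h2)
        return self._lin(g, "pc_mu"), self._lin(g, "pc_lv"), h2

    def _pool_qrs(self, qrs: np.ndarray) -> np.ndarray:
        B, L, S = qrs.shape
        ds = self.cfg.qrs_downsample
        return qrs.reshape(B, L, S // ds, ds).mean(axis=3)

    def encode_qrs(self, qrs: np.ndarray):
        x = np.transpose(self._pool_qrs(qrs), (0, 2, 1))   # (B, T, leads)
        B, T, _ = x.shape
        qh = self.cfg.qrs_hidden
        finals = []
        for tag, order in (("f", range(T)), ("b", range(T - 1, -1, -1))):
            h = Tensor(np.zeros((B, qh)))
            wx, bx = self.params[f"qx{tag}_w"], self.params[f"qx{tag}_b"]
            wh = self.params[f"qh{tag}_w"]
            for t in order:
                h = (Tensor(x[:, t, :]) @ wx + h @ wh + bx).tanh()
            finals.append(h)
        skip = self._lin(Tensor(x.reshape(B, -1)), "q_skip").tanh()
        hb = concat(finals + [skip], axis=-1)
        return self._lin(hb, "q_mu"), self._lin(hb, "q_lv")

    def sample_latent(self, mu_pc, lv_pc, mu_qrs, lv_qrs,
                      rng: np.random.Generator | None) -> LatentState:
        if rng is None:  # inference: use the posterior mean
            z = concat([mu_pc, mu_qrs], axis=-1)
        else:
            e1 = Tensor(rng.standard_normal(mu_pc.shape))
            e2 = Tensor(rng.standard_normal(mu_qrs.shape))
            z = concat([mu_pc + (0.5 * lv_pc).exp() * e1,
                        mu_qrs + (0.5 * lv_qrs).exp() * e2], axis=-1)
        return LatentState(mu_pc, lv_pc, mu_qrs, lv_qrs, z)

    def decode_pc(self, z: Tensor):
        h = self._lin(z, "dec_pc").relu()
        B = z.shape[0]
        coarse, dense = [], []
        for k in range(self.cfg.n_recon_classes):
            coarse.append(self._lin(h, f"dec_c{k}").reshape(B, self.n_coarse_k, 3))
            dense.append(self._lin(h, f"dec_d{k}").reshape(B, self.n_dense_k, 3))
        return coarse, dense

    def decode_qrs(self, z: Tensor):
        B = z.shape[0]
        h = self._lin(z, "qd0").tanh()
        zin = self._lin(z, "qdz")
        ys = []
        for _ in range(self.T):
            h = (h @ self.params["qdh_w"] + zin + self.params["qd0_b"]).tanh()
            ys.append(self._lin(h, "qdy").reshape(B, 1, self.cfg.n_lead))
        y = concat(ys, axis=1)                       # (B, T, leads)
        y = y.transpose(0, 2, 1)                     # (B, leads, T)
        return y.repeat(self.cfg.qrs_downsample, axis=2)   # (B, leads, l_qrs)

    def segment(self, h2: Tensor, raw: Tensor, z: Tensor):
        B, n = h2.shape[0], h2.shape[1]
        ztile = z.reshape(B, 1, z.shape[-1]).repeat(n, axis=1)
        feat = concat([h2, raw, ztile], axis=-1)
        s1 = self._lin(feat, "seg1").relu()
        s1 = self._lin(s1, "seg1b").relu()
        return self._lin(s1, "seg2")                 # (B, n, s)

    # -- full passes --------------------------------------------------------
    def _normalize_pc(self, pc: np.ndarray) -> np.ndarray:
        out = pc.copy()
        out[..., :3] /= self.cfg.xyz_scale_mm
        return out

    def forward(self, pc: np.ndarray, qrs: np.ndarray,
                rng: np.random.Generator | None = None):
        """pc (B, n, 7), qrs (B, n_lead, l_qrs).  Returns
        (logits, latent, (coarse, dense), qrs_hat)."""
        pcn = Tensor(self._normalize_pc(pc))
        mu_pc, lv_pc, h2 = self.encode_pc(pcn)
        mu_q, lv_q = self.encode_qrs(qrs)
        lat = self.sample_latent(mu_pc, lv_pc, mu_q, lv_q, rng)
        logits = self.segment(h2, pcn, lat.z)
        recon = self.decode_pc(lat.z)
        qrs_hat = self.decode_qrs(lat.z)
        return logits, lat, recon, qrs_hat


# ---------------------------------------------------------------------------
# training

def _recon_targets(pc_norm: np.ndarray, n_classes: int):
    """Per-class (by tv) target point sets of one normalized cloud."""
    tv = pc_norm[:, 6]
    return [pc_norm[tv == k, :3] for k in range(n_classes)]


def recon_inputs(model: DualBranchVAE, pc: np.ndarray):
    """Per-class (by tv) input point sets of one cloud, in mm, matching
    the layout of the decoder's reconstructions."""
    tv = pc[:, 6]
    return [pc[tv == k, :3] for k in range(model.cfg.n_recon_classes)]


def batch_loss(model: DualBranchVAE, batch: list[dict],
               cfg: TrainingConfig, rng: np.random.Generator | None):
    """Differentiable total inference loss (Eq.-11 form) of a batch."""
    pc = np.stack([c["pc"] for c in batch])
    qrs = np.stack([c["qrs"] for c in batch])
    labels = np.stack([c["labels"] for c in batch])
    B = len(batch)
    logits, lat, (coarse, dense), qrs_hat = model.forward(pc, qrs, rng)

    # VAE reconstruction
    pc_rec = None
    for i in range(B):
        targets = _recon_targets(model._normalize_pc(pc[i]),
                                 model.cfg.n_recon_classes)
        for k, tgt in enumerate(targets):
            if len(tgt) == 0:
                continue
            term = (chamfer_ad(coarse[k][i], tgt)
                    + cfg.alpha * chamfer_ad(dense[k][i], tgt))
            pc_rec = term if pc_rec is None else pc_rec + term
    pc_rec = (pc_rec if pc_rec is not None else Tensor(0.0)) * (1.0 / B)

    mse = ((qrs_hat - Tensor(qrs)) ** 2).mean()
    pooled_hat = qrs_hat[:, :, ::model.cfg.qrs_downsample]
    pooled_tgt = model._pool_qrs(qrs)
    L = model.cfg.n_lead
    sdtw = soft_dtw_div_ad(pooled_hat.reshape(B * L, model.T),
                           pooled_tgt.reshape(B * L, model.T),
                           cfg.soft_dtw_gamma)
    qrs_rec = mse + sdtw

    kl = (kl_gaussian_ad(lat.mu_pc, lat.logvar_pc)
          + kl_gaussian_ad(lat.mu_qrs, lat.logvar_qrs)) * (1.0 / B)
    vae = cfg.lam_pc * pc_rec + cfg.lam_qrs * qrs_rec + cfg.lam_kl * kl

    seg = seg_loss_ad(logits.reshape(B * logits.shape[1], model.cfg.s),
                      labels.reshape(-1), cfg.lam_dice)

    compact = size = spa = None
    for i in range(B):
        probs = softmax(logits[i], axis=-1)
        probs_mi = probs[:, 1] + probs[:, 2]
        gt_mi = labels[i] > 0
        rv = rv_non_septal_mask(pc[i][:, 3:7])
        c_, s_, sp_ = soft_counting_losses_ad(probs_mi, pc[i][:, :3], gt_mi, rv)
        compact = c_ if compact is None else compact + c_
        size = s_ if size is None else size + s_
        spa = sp_ if spa is None else spa + sp_
    compact, size, spa = (t * (1.0 / B) for t in (compact, size, spa))

    total = (cfg.lam_vae * vae + seg + cfg.lam_compact * compact
             + cfg.lam_size * size + cfg.lam_spa * spa)
    parts = {"total": float(total.data), "vae": float(vae.data),
             "pc_rec": float(pc_rec.data), "qrs_rec": float(qrs_rec.data),
             "kl": float(kl.data), "seg": float(seg.data),
             "compact": float(compact.data), "size": float(size.data),
             "spa": float(spa.data)}
    return total, parts


def train(model: DualBranchVAE, dataset: list[dict],
          cfg: TrainingConfig | None = None, seed: int = 0,
          epochs: int | None = None, lr: float | None = None,
          verbose: bool = False) -> pd.DataFrame:
    """Train on a list of cases {pc, qrs, labels, subject}; returns the
    per-epoch loss history.  Deterministic per seed."""
    cfg = cfg or TrainingConfig()
    cfg.validate()
    epochs = epochs if epochs is not None else cfg.epochs
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr if lr is not None else cfg.lr,
               weight_decay=cfg.weight_decay)
    base_lr = opt.lr
    history = []
    it = 0
    for epoch in range(epochs):
        order = rng.permutation(len(dataset))
        ep_parts: dict[str, float] = {}
        nb = 0
        for start in range(0, len(dataset), cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            opt.zero_grad()
            loss, parts = batch_loss(model, batch, cfg, rng)
            loss.backward()
            opt.lr = base_lr * (cfg.lr_decay ** (it // cfg.lr_decay_every))
            opt.step()
            it += 1
            nb += 1
            for k, v in parts.items():
                ep_parts[k] = ep_parts.get(k, 0.0) + v
        row = {k: v / nb for k, v in ep_parts.items()}
        row["epoch"] = epoch
        history.append(row)
        if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:4d}  total {row['total']:.4f} "
                  f"seg {row['seg']:.4f}")
    return pd.DataFrame(history)


def infer(model: DualBranchVAE, pc: np.ndarray, qrs: np.ndarray):
    """Predict per-point tissue labels for one case; returns
    (labels, probs, reconstructions dict)."""
    logits, lat, (coarse, dense), qrs_hat = model.forward(
        pc[None], qrs[None], rng=None)
    probs = softmax(logits[0], axis=-1).data
    labels = probs.argmax(axis=-1).astype(np.int8)
    recon = {
        "coarse": [c.data[0] * model.cfg.xyz_scale_mm for c in coarse],
        "dense": [d.data[0] * model.cfg.xyz_scale_mm for d in dense],
        "qrs_hat": qrs_hat.data[0],
        "z": lat.z.data[0],
    }
    return labels, probs, recon


def split_by_subject(cases: list[dict], fractions=(34 / 49, 5 / 49, 10 / 49),
                     seed: int = 0):
    """Subject-level train/val/test split (never scenario-level).

    Rounding rule: train and validation counts are rounded to the
    nearest integer (validation at least 1 subject when possible); the
    remainder is the test set.  Raises if any subject leaks across
    splits.
    """
    subjects = sorted({c["subject"] for c in cases})
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    ns = len(subjects)
    n_train = int(round(ns * fractions[0]))
    n_val = max(int(round(ns * fractions[1])), 1 if ns - n_train >= 2 else 0)
    n_train = min(n_train, ns - n_val - 1) if ns > 2 else n_train
    tr = set(order[:n_train])
    va = set(order[n_train:n_train + n_val])
    te = set(order[n_train + n_val:])
    if tr & va or tr & te or va & te:
        raise RuntimeError("subject leakage between splits")
    pick = lambda s: [c for c in cases if c["subject"] in s]
    return pick(tr), pick(va), pick(te)
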