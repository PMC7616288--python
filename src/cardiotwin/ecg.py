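"""Pseudo-ECG synthesis from activation maps.

The extracellular potential at an electrode is approximated by the
infinite-medium 1D-cable pseudo-ECG integral

    phi_e = a^2 sigma_i / (4 sigma_e) * integral( -grad(Vm) . grad(1/r) ) dV,

with Vm the transmembrane potential, evaluated with linear shape
functions per tetrahedron and one-point (centroid) quadrature.  Because
grad(Vm) is linear in the nodal Vm values, the quadrature collapses to a
precomputed linear functional over nodal Vm per electrode, making the
time loop a single matrix product.

Only ventricular depolarization (the QRS complex) is modeled: Vm is a
smoothed resting-to-plateau upstroke triggered at the local activation
time; repolarization is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ElectrodeSet, LabeledMesh

LEAD_NAMES = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
L_QRS = 512


class ECGError(ValueError):
    pass


@dataclass
class ActionPotentialTemplate:
    """Depolarization upstroke: normalized-tanh smoothed step from the
    resting to the plateau potential over ``upstroke_ms``."""

    amplitude_mv: float = 100.0
    resting_mv: float = -85.0
    upstroke_ms: float = 1.0
    steepness: float = 3.0

    def shape(self, tau: np.ndarray) -> np.ndarray:
        """Monotone step S with S(tau <= 0) = 0 and S(tau >= upstroke) = 1."""
        tau = np.asarray(tau, dtype=float)
        h = 0.5 * self.upstroke_ms
        k = self.steepness / h
        lo = np.tanh(-k * h)
        s = (np.tanh(k * (tau - h)) - lo) / (np.tanh(k * h) - lo)
        return np.clip(s, 0.0, 1.0)

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        return self.resting_mv + self.amplitude_mv * self.shape(tau)


@dataclass
class PseudoECGConfig:
    """Kernel constants and sampling of the pseudo-ECG integral.  The
    factor a^2 sigma_i / (4 sigma_e) is folded into one scalar ``gain``;
    signals are amplitude-normalized downstream, so its value does not
    affect any derived quantity."""

    gain: float = 1.0
    dt_ms: float = 0.5
    pad_ms: float = 2.0

    def validate(self):
        if self.gain <= 0 or self.dt_ms <= 0:
            raise ECGError("gain and dt must be positive")


@dataclass
class QRSSignal:
    """Fixed-length amplitude-normalized 8-lead QRS matrix."""

    data: np.ndarray                     # (8, 512)
    duration_ms: float
    dt_ms: float
    lead_names: tuple = LEAD_NAMES

    def lead(self, name: str) -> np.ndarray:
        return self.data[self.lead_names.index(name)]


# ---------------------------------------------------------------------------

def _tet_geometry(mesh: LabeledMesh):
    """Per-tet volume, centroid and shape-function gradient matrix
    G (m, 3, 4) with grad(Vm) = G @ Vm[tet]."""
    p = mesh.nodes[mesh.tets]                       # (m, 4, 3)
    e = p[:, 1:] - p[:, :1]                         # (m, 3, 3) edge matrix
    vol = np.abs(np.linalg.det(e)) / 6.0
    einv = np.linalg.inv(e)
    # barycentric gradients: grad N_i (i = 1..3) is column i-1 of inv(e),
    # since lambda = inv(e)^T (x - p0); grad N_0 = -sum_i grad N_i
    gn = einv                                       # (m, 3, 3): columns gradN1..3
    g0 = -gn.sum(axis=2, keepdims=True)             # gradN0
    G = np.concatenate([g0, gn], axis=2)            # (m, 3, 4)
    centroid = p.mean(axis=1)
    return vol, centroid, G


def electrode_functional(mesh: LabeledMesh, electrode_pos: np.ndarray,
                         gain: float = 1.0) -> np.ndarray:
    """Nodal weight vector w with phi_e(t) = w . Vm(t).

    w_j = -gain * sum_tets vol * (G[:, :, j] . grad(1/r)|centroid).
    Raises if the electrode sits inside (or numerically on) the mesh,
    where the kernel is singular.
    """
    vol, centroid, G = _tet_geometry(mesh)
    d = centroid - np.asarray(electrode_pos)[None, :]
    r = np.linalg.norm(d, axis=1)
    if (r < 1e-6).any():
        raise ECGError("electrode inside an element: singular kernel")
    kern = -d / (r ** 3)[:, None]                   # grad(1/r) at centroid
    # contribution per tet and local node: -vol * gradN_j . kern
    contrib = -vol[:, None] * np.einsum("ti,tij->tj", kern, G)
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.tets.ravel(), contrib.ravel())
    return gain * w


def pseudo_ecg_at(mesh: LabeledMesh, atm: np.ndarray, electrode_pos,
                  template: ActionPotentialTemplate | None = None,
                  cfg: PseudoECGConfig | None = None):
    """Pseudo-ECG trace at one electrode.  Returns (times_ms, phi)."""
    template = template or ActionPotentialTemplate()
    cfg = cfg or PseudoECGConfig()
    cfg.validate()
    w = electrode_functional(mesh, electrode_pos, cfg.gain)
    times = _time_axis(atm, template, cfg)
    vm = template(times[:, None] - atm[None, :])    # (T, n)
    return times, vm @ w


def _time_axis(atm, template, cfg):
    t_end = float(np.max(atm)) + template.upstroke_ms + cfg.pad_ms
    return np.arange(0.0, t_end + cfg.dt_ms, cfg.dt_ms)


def simulate_electrode_traces(mesh: LabeledMesh, atm: np.ndarray,
                              electrodes: ElectrodeSet,
                              template: ActionPotentialTemplate | None = None,
                              cfg: PseudoECGConfig | None = None):
    """Traces at all 10 electrodes; returns (times, dict name -> phi)."""
    template = template or ActionPotentialTemplate()
    cfg = cfg or PseudoECGConfig()
    cfg.validate()
    times = _time_axis(atm, template, cfg)
    vm = template(times[:, None] - atm[None, :])
    out = {}
    for name in ElectrodeSet.NAMES:
        w = electrode_functional(mesh, electrodes[name], cfg.gain)
        out[name] = vm @ w
    return times, out


def derive_leads(phi_by_electrode: dict[str, np.ndarray]) -> np.ndarray:
    """Standard 8-lead derivation from the 10 electrode traces:
    I = LA - RA, II = LL - RA, Vi = phi(Vi) - Wilson central terminal
    (LA + RA + LL)/3.  RL is the ground and unused."""
    missing = set(ElectrodeSet.NAMES) - {"RL"} - set(phi_by_electrode)
    if missing:
        raise ECGError(f"missing electrode traces: {sorted(missing)}")
    la, ra, ll = (phi_by_electrode[k] for k in ("LA", "RA", "LL"))
    lengths = {len(v) for v in phi_by_electrode.values()}
    if len(lengths) != 1:
        raise ECGError("electrode traces differ in length")
    wct = (la + ra + ll) / 3.0
    rows = [la - ra, ll - ra]
    rows += [phi_by_electrode[f"V{i}"] - wct for i in range(1, 7)]
    return np.vstack(rows)


def normalize_and_resample(raw_leads: np.ndarray, dt_ms: float,
                           l_qrs: int = L_QRS,
                           active_rel_tol: float = 1e-9) -> QRSSignal:
    """Normalize by the global maximum absolute amplitude, trim the
    inactive head/tail, and zero-pad (never stretch) to ``l_qrs``
    samples, recording the pre-padding duration.  Signals longer than
    ``l_qrs`` samples are linearly resampled down."""
    raw = np.atleast_2d(np.asarray(raw_leads, dtype=float))
    peak = np.abs(raw).max()
    if peak == 0:
        raise ECGError("all-zero signal cannot be normalized")
    sig = raw / peak
    active = np.abs(sig).max(axis=0) > active_rel_tol
    first, last = np.flatnonzero(active)[[0, -1]]
    sig = sig[:, first:last + 1]
    duration = sig.shape[1] * dt_ms
    if sig.shape[1] > l_qrs:
        x_old = np.linspace(0.0, 1.0, sig.shape[1])
        x_new = np.linspace(0.0, 1.0, l_qrs)
        sig = np.vstack([np.interp(x_new, x_old, row) for row in sig])
        dt_eff = duration / l_qrs
    else:
        pad = l_qrs - sig.shape[1]
        sig = np.pad(sig, ((0, 0), (0, pad)))
        dt_eff = dt_ms
    return QRSSignal(data=sig, duration_ms=duration, dt_ms=dt_eff)


def qrs_duration(qrs: QRSSignal, theta_dur: float = 0.02) -> float:
    """Interval (ms) between the first and last sample at which any
    lead's |amplitude| exceeds ``theta_dur``."""
    active = np.abs(qrs.data).max(axis=0) > theta_dur
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return 0.0
    return float((idx[-1] - idx[0] + 1) * qrs.dt_ms)


def qrs_window(qrs: QRSSignal, theta_dur: float = 0.02):
    """(first, last+1) sample indices of the detected QRS window."""
    active = np.abs(qrs.data).max(axis=0) > theta_dur
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return 0, 0
    return int(idx[0]), int(idx[-1]) + 1
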