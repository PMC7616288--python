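"""QRS dissimilarity and abnormality analysis.

The global measure is dynamic time warping (DTW) between the trimmed
QRS of a scenario and the baseline, path-length normalized, with an
additive penalty on the QRS-duration difference.  Local detectors flag
the four classical post-infarct QRS abnormalities: duration
prolongation, pathological Q waves, poor R-wave progression (PRWP) and
fragmented QRS (fQRS).  All detectors are pure functions of
(signal, thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ecg import LEAD_NAMES, QRSSignal, qrs_duration, qrs_window


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dynamic time warping

def _dtw_dp(a: np.ndarray, b: np.ndarray):
    """Lexicographic DP: minimize accumulated |a_i - b_j| cost, breaking
    ties by shorter warping-path length.  Returns (cost, path_length).
    Vectorized over anti-diagonals."""
    la, lb = len(a), len(b)
    C = np.abs(a[:, None] - b[None, :])
    INF = np.inf
    # per-diagonal arrays indexed by i (0..la-1)
    d_prev2 = np.full(la, INF)
    l_prev2 = np.full(la, INF)
    d_prev = np.full(la, INF)
    l_prev = np.full(la, INF)
    for d in range(la + lb - 1):
        i0, i1 = max(0, d - lb + 1), min(la - 1, d)
        ii = np.arange(i0, i1 + 1)
        c = C[ii, d - ii]
        if d == 0:
            d_cur = np.full(la, INF)
            l_cur = np.full(la, INF)
            d_cur[0], l_cur[0] = c[0], 1.0
        else:
            # predecessors: (i-1, j) and (i, j-1) on diag d-1; (i-1, j-1) on d-2
            up = np.full((len(ii),), INF)
            up_l = np.full((len(ii),), INF)
            sel = ii - 1 >= 0
            up[sel] = d_prev[ii[sel] - 1]
            up_l[sel] = l_prev[ii[sel] - 1]
            left = np.where(d - ii - 1 >= 0, d_prev[ii], INF)
            left_l = np.where(d - ii - 1 >= 0, l_prev[ii], INF)
            diag = np.full((len(ii),), INF)
            diag_l = np.full((len(ii),), INF)
            sel2 = (ii - 1 >= 0) & (d - ii - 1 >= 0)
            diag[sel2] = d_prev2[ii[sel2] - 1]
            diag_l[sel2] = l_prev2[ii[sel2] - 1]
            cost3 = np.stack([up, left, diag])
            len3 = np.stack([up_l, left_l, diag_l])
            best = cost3.min(axis=0)
            len_best = np.where(cost3 == best[None, :], len3, INF).min(axis=0)
            d_cur = np.full(la, INF)
            l_cur = np.full(la, INF)
            d_cur[ii] = c + best
            l_cur[ii] = len_best + 1.0
        d_prev2, l_prev2, d_prev, l_prev = d_prev, l_prev, d_cur, l_cur
    return float(d_prev[la - 1]), float(l_prev[la - 1])


def dtw_distance(sig_a: np.ndarray, sig_b: np.ndarray,
                 lam_dur: float = 0.005,
                 duration_a_ms: float | None = None,
                 duration_b_ms: float | None = None) -> float:
    """Path-length-normalized DTW between two 1-D signals plus
    ``lam_dur`` times the absolute QRS-duration difference (ms).

    Signals are expected trimmed to their detected durations.  The
    distance is a pseudo-metric: non-negative, symmetric, and zero on
    identical signals of equal duration.
    """
    a = np.asarray(sig_a, dtype=float).ravel()
    b = np.asarray(sig_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise AnalysisError("empty signal")
    cost, length = _dtw_dp(a, b)
    penalty = 0.0
    if duration_a_ms is not None and duration_b_ms is not None:
        penalty = lam_dur * abs(duration_a_ms - duration_b_ms)
    return cost / length + penalty


# ---------------------------------------------------------------------------
# reports

@dataclass
class DissimilarityReport:
    scenario: str
    per_lead: dict[str, float]

    @property
    def dtw_max(self) -> float:
        return max(self.per_lead.values())

    @property
    def dtw_avg(self) -> float:
        return float(np.mean(list(self.per_lead.values())))


@dataclass
class Thresholds:
    theta_dur: float = 0.02          # QRS on/offset amplitude threshold
    prolong_factor: float = 1.1      # duration > baseline * factor
    q_width_ms: float = 40.0
    q_depth_frac: float = 0.25       # of the lead's R amplitude
    notch_prominence: float = 0.02
    extra_extrema: int = 2           # fQRS: extrema above baseline count


@dataclass
class AbnormalityFlags:
    prolongation: bool
    pathological_q: dict[str, bool]
    prwp: bool
    fqrs: dict[str, bool]

    def any_pathological_q(self) -> bool:
        return any(self.pathological_q.values())

    def any_fqrs(self) -> bool:
        return any(self.fqrs.values())


def _trimmed(qrs: QRSSignal, theta: float):
    i0, i1 = qrs_window(qrs, theta)
    if i1 <= i0:
        raise AnalysisError("no QRS activity above threshold")
    return qrs.data[:, i0:i1]


def dissimilarity_report(scenario_qrs: QRSSignal, baseline_qrs: QRSSignal,
                         lam_dur: float = 0.005,
                         theta_dur: float = 0.02,
                         scenario_name: str = "") -> DissimilarityReport:
    """Per-lead DTW of a scenario QRS to the baseline QRS."""
    if scenario_qrs.lead_names != baseline_qrs.lead_names:
        raise AnalysisError("lead sets differ")
    a = _trimmed(scenario_qrs, theta_dur)
    b = _trimmed(baseline_qrs, theta_dur)
    da = qrs_duration(scenario_qrs, theta_dur)
    db = qrs_duration(baseline_qrs, theta_dur)
    per_lead = {
        name: dtw_distance(a[i], b[i], lam_dur, da, db)
        for i, name in enumerate(scenario_qrs.lead_names)}
    return DissimilarityReport(scenario=scenario_name, per_lead=per_lead)


def _r_amplitude(lead: np.ndarray) -> float:
    return float(max(lead.max(), 0.0))


def _count_extrema(lead: np.ndarray, prominence: float) -> int:
    peaks, _ = find_peaks(lead, prominence=prominence)
    troughs, _ = find_peaks(-lead, prominence=prominence)
    return len(peaks) + len(troughs)


def detect_abnormalities(scenario_qrs: QRSSignal, baseline_qrs: QRSSignal,
                         thresholds: Thresholds | None = None) -> AbnormalityFlags:
    """Flag the four post-infarct QRS abnormalities.

    * prolongation: QRS duration exceeds baseline by the configured factor;
    * pathological Q: the lead's first deflection is negative and wider
      than 40 ms or deeper than 25 % of the lead's R amplitude;
    * PRWP: R amplitudes of V1..V4 not strictly increasing, or
      R(V6) > R(V5);
    * fQRS: at least ``extra_extrema`` more prominence-filtered local
      extrema inside the QRS window than the baseline lead shows.
    """
    th = thresholds or Thresholds()
    dur_s = qrs_duration(scenario_qrs, th.theta_dur)
    dur_b = qrs_duration(baseline_qrs, th.theta_dur)
    prolongation = dur_s > dur_b * th.prolong_factor

    sig = _trimmed(scenario_qrs, th.theta_dur)
    base = _trimmed(baseline_qrs, th.theta_dur)
    dt = scenario_qrs.dt_ms
    names = scenario_qrs.lead_names

    pathological_q: dict[str, bool] = {}
    fqrs: dict[str, bool] = {}
    for i, name in enumerate(names):
        lead = sig[i]
        flag = False
        onset = np.flatnonzero(np.abs(lead) > th.theta_dur)
        if onset.size:
            o = onset[0]
            if lead[o] < 0:
                after = np.flatnonzero(lead[o:] >= 0)
                end = o + (after[0] if after.size else len(lead) - o)
                width_ms = (end - o) * dt
                depth = float(-lead[o:end].min()) if end > o else 0.0
                r_amp = _r_amplitude(lead)
                ref = r_amp if r_amp > 0 else float(np.abs(lead).max())
                flag = width_ms > th.q_width_ms or depth > th.q_depth_frac * ref
        pathological_q[name] = bool(flag)
        n_s = _count_extrema(lead, th.notch_prominence)
        n_b = _count_extrema(base[i], th.notch_prominence)
        fqrs[name] = bool(n_s >= n_b + th.extra_extrema)

    r = {n: _r_amplitude(sig[names.index(n)]) for n in ("V1", "V2", "V3",
                                                        "V4", "V5", "V6")}
    v14 = [r["V1"], r["V2"], r["V3"], r["V4"]]
    prwp = any(v14[k + 1] <= v14[k] for k in range(3)) or r["V6"] > r["V5"]

    return AbnormalityFlags(prolongation=bool(prolongation),
                            pathological_q=pathological_q,
                            prwp=bool(prwp), fqrs=fqrs)


# ---------------------------------------------------------------------------
# cohort-level sensitivity study

def run_sensitivity_study(cohort, scenario_list, out_dir=None,
                          lam_dur: float = 0.005,
                          thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-subject, per-scenario QRS dissimilarity and abnormality flags.

    Returns a tidy table (subject, scenario, lead, dtw, flags, duration)
    and, if ``out_dir`` is given, writes the aggregated CSV plus a
    scenario-by-lead DTW heatmap (mean over subjects).
    """
    th = thresholds or Thresholds()
    rows = []
    for twin in cohort:
        baseline = twin.simulate(None)
        dur_b = qrs_duration(baseline.qrs, th.theta_dur)
        for scen in scenario_list:
            res = twin.simulate(scen)
            rep = dissimilarity_report(res.qrs, baseline.qrs, lam_dur,
                                       th.theta_dur, scen.name)
            flags = detect_abnormalities(res.qrs, baseline.qrs, th)
            dur = qrs_duration(res.qrs, th.theta_dur)
            for lead, val in rep.per_lead.items():
                rows.append({
                    "subject": twin.subject_id, "scenario": scen.name,
                    "lead": lead, "dtw": val,
                    "dtw_max": rep.dtw_max, "dtw_avg": rep.dtw_avg,
                    "duration_ms": dur, "baseline_duration_ms": dur_b,
                    "prolongation": flags.prolongation,
                    "pathological_q": flags.pathological_q[lead],
                    "prwp": flags.prwp, "fqrs": flags.fqrs[lead],
                })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sensitivity.csv", index=False)
        _save_heatmap(df, out / "dtw_heatmap.png")
    return df


def _save_heatmap(df: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = df.pivot_table(index="scenario", columns="lead", values="dtw",
                         aggfunc="mean")
    mat = mat.reindex(columns=[n for n in LEAD_NAMES if n in mat.columns])
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(mat) + 1.5))
    im = ax.imshow(mat.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks(range(mat.shape[0]), mat.index)
    fig.colorbar(im, ax=ax, label="DTW to baseline")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
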