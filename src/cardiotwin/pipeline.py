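"""End-to-end simulation plumbing: anatomy -> scenario -> QRS.

``SubjectTwin`` bundles one synthetic anatomy with its electrode set and
root nodes and caches the per-electrode pseudo-ECG functionals, which
depend only on the mesh, so that all infarct scenarios of a subject
reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ecg as ecg_mod
from .ecg import (ActionPotentialTemplate, PseudoECGConfig, QRSSignal,
                  derive_leads, normalize_and_resample)
from .forward import (CVConfig, RootNodeSet, assemble_conduction,
                      default_root_nodes, solve_eikonal)
from .geometry import (ElectrodeSet, LabeledMesh, ShapeParams, TorsoParams,
                       assign_fibers, build_synthetic_biventricular,
                       place_electrodes)
from .infarct import InfarctScenario, label_tissue


@dataclass
class SimulationResult:
    labels: np.ndarray            # per-node tissue class
    atm: np.ndarray               # activation time map (ms)
    qrs: QRSSignal


class SubjectTwin:
    """One synthetic subject: anatomy, electrodes, activation sites."""

    def __init__(self, mesh: LabeledMesh,
                 cv_config: CVConfig | None = None,
                 template: ActionPotentialTemplate | None = None,
                 ecg_config: PseudoECGConfig | None = None,
                 torso: TorsoParams | None = None,
                 roots: RootNodeSet | None = None,
                 subject_id: int = 0):
        if mesh.fibers is None:
            assign_fibers(mesh)
        self.mesh = mesh
        self.subject_id = subject_id
        self.cv_config = cv_config or CVConfig()
        self.template = template or ActionPotentialTemplate()
        self.ecg_config = ecg_config or PseudoECGConfig()
        self.electrodes = place_electrodes(mesh, torso)
        self.roots = roots or default_root_nodes(mesh)
        self._functionals: dict[str, np.ndarray] | None = None

    def _electrode_functionals(self) -> dict[str, np.ndarray]:
        if self._functionals is None:
            self._functionals = {
                name: ecg_mod.electrode_functional(
                    self.mesh, self.electrodes[name], self.ecg_config.gain)
                for name in ElectrodeSet.NAMES}
        return self._functionals

    def simulate(self, scenario: InfarctScenario | None = None) -> SimulationResult:
        """Simulate one scenario (None = healthy baseline)."""
        if scenario is None:
            labels = np.zeros(self.mesh.n_nodes, dtype=np.int8)
            conduction = assemble_conduction(self.mesh, labels, self.cv_config)
        else:
            labels = label_tissue(self.mesh, scenario)
            conduction = assemble_conduction(
                self.mesh, labels, self.cv_config,
                cv_scale_scar=scenario.cv_scale_scar,
                cv_scale_bz=scenario.cv_scale_bz)
        atm = solve_eikonal(self.mesh, conduction, self.roots)
        times = ecg_mod._time_axis(atm, self.template, self.ecg_config)
        vm = self.template(times[:, None] - atm[None, :])
        traces = {name: vm @ w for name, w in self._electrode_functionals().items()}
        leads = derive_leads(traces)
        qrs = normalize_and_resample(leads, self.ecg_config.dt_ms)
        return SimulationResult(labels=labels, atm=atm, qrs=qrs)


def make_cohort(n_subjects: int, resolution: str = "coarse",
                seed: int = 0, shape: ShapeParams | None = None,
                **twin_kwargs) -> list[SubjectTwin]:
    """Cohort of synthetic subjects with seeded anatomical variability."""
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)
    cohort = []
    for i, s in enumerate(subject_seeds):
        mesh = build_synthetic_biventricular(shape, resolution, seed=int(s))
        assign_fibers(mesh)
        cohort.append(SubjectTwin(mesh, subject_id=i, **twin_kwargs))
    return cohort
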