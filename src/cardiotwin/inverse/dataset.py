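"""Dataset assembly for inverse inference.

A case is one (subject, infarct scenario) pair: the subject's sampled
point cloud with Cobiveco features, the simulated 8-lead QRS, and the
per-point tissue labels.  Cases are stored in HDF5 under
``/subject_<i>/scenario_<name>/{pc, qrs, labels}``.
"""

from __future__ import annotations

import numpy as np

from ..geometry import resample_pointcloud


def build_dataset(cohort, scenarios, n_points: int, seed: int = 0) -> list[dict]:
    """Simulate every (subject, scenario) pair into a list of cases."""
    rng = np.random.default_rng(seed)
    cases = []
    for twin in cohort:
        pc = resample_pointcloud(twin.mesh, n_points, seed=int(rng.integers(2 ** 31)))
        for scen in scenarios:
            res = twin.simulate(scen)
            cases.append({
                "subject": twin.subject_id,
                "scenario": scen.name,
                "pc": pc.points.copy(),
                "labels": res.labels[pc.indices].astype(np.int8),
                "qrs": res.qrs.data.copy(),
                "duration_ms": res.qrs.duration_ms,
            })
    return cases


def save_dataset(cases: list[dict], path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for c in cases:
            g = f.require_group(f"subject_{c['subject']}").create_group(
                f"scenario_{c['scenario']}")
            g.create_dataset("pc", data=c["pc"])
            g.create_dataset("qrs", data=c["qrs"])
            g.create_dataset("labels", data=c["labels"])
            g.attrs["duration_ms"] = c.get("duration_ms", np.nan)


def load_dataset(path) -> list[dict]:
    import h5py

    cases = []
    with h5py.File(path, "r") as f:
        for sname, sg in f.items():
            sid = int(sname.split("_")[1])
            for scname, g in sg.items():
                cases.append({
                    "subject": sid,
                    "scenario": scname.removeprefix("scenario_"),
                    "pc": g["pc"][()],
                    "qrs": g["qrs"][()],
                    "labels": g["labels"][()],
                    "duration_ms": float(g.attrs.get("duration_ms", np.nan)),
                })
    cases.sort(key=lambda c: (c["subject"], c["scenario"]))
    return cases
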