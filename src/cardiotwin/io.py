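"""Text-based export of meshes, point clouds and signals.

Meshes are written as legacy-VTK ASCII unstructured grids (readable by
ParaView and meshio) with the Cobiveco coordinates as point data and
the fiber triad as cell data; point clouds and QRS matrices as CSV, QRS
additionally as an HDF5 dataset with a ``duration_ms`` attribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ecg import QRSSignal
from .geometry import LabeledMesh


def write_vtk(mesh: LabeledMesh, path,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-VTK ASCII unstructured grid with tm/ab/rt/tv point data,
    optional extra per-node scalar arrays, and fiber cell data."""
    pd_arrays = {"tm": mesh.tm, "ab": mesh.ab, "rt": mesh.rt, "tv": mesh.tv}
    if point_data:
        pd_arrays.update(point_data)
    lines = ["# vtk DataFile Version 3.0", "cardiotwin mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.8g}" for v in p) for p in mesh.nodes]
    m = len(mesh.tets)
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    for name, arr in pd_arrays.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.8g}" for v in np.asarray(arr, dtype=float)]
    if mesh.fibers is not None:
        lines.append(f"CELL_DATA {m}")
        for i, name in enumerate(("fiber", "sheet", "normal")):
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{v:.8g}" for v in vec)
                      for vec in mesh.fibers[:, i]]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def write_pointcloud_csv(points: np.ndarray, path,
                         labels: np.ndarray | None = None) -> None:
    cols = ["x", "y", "z", "tm", "ab", "rt", "tv"][:points.shape[1]]
    df = pd.DataFrame(points, columns=cols)
    if labels is not None:
        df["tissue"] = labels
    df.to_csv(path, index=False)


def write_qrs_csv(qrs: QRSSignal, path) -> None:
    pd.DataFrame(qrs.data.T, columns=list(qrs.lead_names)).to_csv(
        path, index=False)


def write_qrs_h5(qrs: QRSSignal, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("qrs", data=qrs.data)
        ds.attrs["duration_ms"] = qrs.duration_ms
        ds.attrs["dt_ms"] = qrs.dt_ms
        ds.attrs["leads"] = ",".join(qrs.lead_names)


def read_qrs_h5(path) -> QRSSignal:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["qrs"]
        return QRSSignal(data=ds[()],
                         duration_ms=float(ds.attrs["duration_ms"]),
                         dt_ms=float(ds.attrs["dt_ms"]),
                         lead_names=tuple(ds.attrs["leads"].split(",")))
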