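"""Synthetic biventricular anatomy with exact consistent coordinates.

Meshes are generated parametrically over the consistent biventricular
coordinate (Cobiveco) system — transmural ``tm``, apicobasal ``ab``,
rotational ``rt`` and transventricular ``tv`` — and mapped to truncated
ellipsoid shells in cartesian space, so every node carries exact
coordinates by construction.  Conventions:

* lengths in mm, 0-based node indexing;
* ``tm`` = 0 on the endocardium, 1 on the epicardium;
* ``ab`` = 0 at the apex, 1 at the base;
* ``rt`` in [0, 1) periodic, ``rt = 0`` at the anterior LV/RV junction,
  increasing such that the septum of the LV occupies rt in [0, 1/3) and
  the septal side of the RV occupies rt in (2/3, 1);
* ``tv`` = 0 for the LV, 1 for the RV.

The two ventricles are built as separate thick-walled half-ellipsoid
shells (each watertight); activation is initiated in both from their own
root nodes, so the absence of a shared septal wall does not prevent
physiological propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

HEALTHY, SCAR, BZ = 0, 1, 2

#: (n_tm, n_ab, n_rt) cell counts per ventricle, keyed by resolution name.
RESOLUTIONS = {
    "coarse": {"lv": (3, 8, 16), "rv": (2, 6, 12)},
    "fine": {"lv": (4, 12, 24), "rv": (3, 9, 18)},
    "dense": {"lv": (5, 16, 40), "rv": (4, 12, 28)},
}


class GeometryError(ValueError):
    """Raised for degenerate shape parameters or invalid queries."""


@dataclass(frozen=True)
class ShapeParams:
    """Semi-axes (mm) of the two truncated-ellipsoid shells.

    ``lv_endo`` / ``rv_endo`` are (x, y, z) endocardial semi-axes; walls
    are added isotropically.  ``rv_center`` shifts the RV shell so its
    septal side (rt > 2/3) faces the LV.
    """

    lv_endo: tuple[float, float, float] = (23.0, 23.0, 62.0)
    lv_wall: float = 10.0
    rv_endo: tuple[float, float, float] = (14.0, 26.0, 50.0)
    rv_wall: float = 4.0
    rv_center: tuple[float, float, float] = (52.0, 0.0, -4.0)
    #: azimuth (rad) of rt = 0 for each ventricle; chosen so the LV septum
    #: (rt in [0,1/3)) faces the RV and vice versa.
    lv_phi0: float = -np.pi / 3.0
    rv_phi0: float = -2.0 * np.pi / 3.0

    def validate(self) -> None:
        if self.lv_wall <= 0 or self.rv_wall <= 0:
            raise GeometryError("wall thickness must be positive")
        if min(self.lv_endo) <= 0 or min(self.rv_endo) <= 0:
            raise GeometryError("cavity semi-axes must be positive")


@dataclass
class AHABands:
    """Apicobasal band edges and rotational sector layout of the
    17-segment AHA division of the LV.  The apicobasal edges are not
    fixed by convention and are therefore configuration values."""

    cap_ab: float = 0.20       # below: segment 17 (apical cap)
    apical_ab: float = 0.45    # cap_ab..apical_ab: segments 13-16
    mid_ab: float = 0.70       # apical_ab..mid_ab: 7-12; above: 1-6
    #: rt at which the 6-sector wheel starts (anteroseptal boundary)
    sector_rt0: float = 0.0


@dataclass
class LabeledMesh:
    nodes: np.ndarray            # (n, 3) float mm
    tets: np.ndarray             # (m, 4) int
    cobiveco: np.ndarray         # (n, 4) columns tm, ab, rt, tv
    fibers: np.ndarray | None = None   # (m, 3, 3): rows f, s, n
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tm(self) -> np.ndarray:
        return self.cobiveco[:, 0]

    @property
    def ab(self) -> np.ndarray:
        return self.cobiveco[:, 1]

    @property
    def rt(self) -> np.ndarray:
        return self.cobiveco[:, 2]

    @property
    def tv(self) -> np.ndarray:
        return self.cobiveco[:, 3]

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the tetrahedral mesh, (e, 2) sorted."""
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.vstack([self.tets[:, p] for p in pairs])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)


@dataclass
class ElectrodeSet:
    """Named electrode positions (mm) of the standard 12-lead setup."""

    positions: dict[str, np.ndarray]

    NAMES = ("RA", "LA", "RL", "LL", "V1", "V2", "V3", "V4", "V5", "V6")

    def __post_init__(self) -> None:
        missing = set(self.NAMES) - set(self.positions)
        if missing:
            raise GeometryError(f"missing electrodes: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]


@dataclass
class PointCloud:
    points: np.ndarray                 # (n, 7): xyz + tm, ab, rt, tv
    labels: np.ndarray | None = None   # (n,) in {0 healthy, 1 scar, 2 BZ}

    @property
    def xyz(self) -> np.ndarray:
        return self.points[:, :3]

    @property
    def cobiveco(self) -> np.ndarray:
        return self.points[:, 3:7]


# ---------------------------------------------------------------------------
# parametric shell construction

def _shell_map(shape: ShapeParams, ventricle: str,
               tm: np.ndarray, ab: np.ndarray, rt: np.ndarray) -> np.ndarray:
    """Map (tm, ab, rt) of one ventricle to cartesian mm positions."""
    if ventricle == "lv":
        endo = np.asarray(shape.lv_endo)
        wall, phi0 = shape.lv_wall, shape.lv_phi0
        center = np.zeros(3)
    else:
        endo = np.asarray(shape.rv_endo)
        wall, phi0 = shape.rv_wall, shape.rv_phi0
        center = np.asarray(shape.rv_center)
    ax = endo[None, :] + wall * np.asarray(tm)[:, None]   # (n, 3) semi-axes
    theta = np.pi - (np.pi / 2.0) * np.asarray(ab)        # apex pi -> base pi/2
    phi = 2.0 * np.pi * np.asarray(rt) + phi0
    st, ct = np.sin(theta), np.cos(theta)
    xyz = np.stack(
        [ax[:, 0] * st * np.cos(phi), ax[:, 1] * st * np.sin(phi), ax[:, 2] * ct],
        axis=1,
    )
    return center[None, :] + xyz


def _build_shell(shape: ShapeParams, ventricle: str,
                 n_tm: int, n_ab: int, n_rt: int):
    """Structured hex grid over (tm, ab, rt) with a pinched apex, split
    into tetrahedra.  Returns (nodes, tets, cobiveco)."""
    tv = 0.0 if ventricle == "lv" else 1.0
    tm_v = np.linspace(0.0, 1.0, n_tm + 1)
    ab_v = np.linspace(0.0, 1.0, n_ab + 1)
    rt_v = np.arange(n_rt) / n_rt

    # node ids: apex column (one node per tm layer) + regular grid ab>0
    idx = np.full((n_tm + 1, n_ab + 1, n_rt), -1, dtype=int)
    coords = []
    nid = 0
    for i in range(n_tm + 1):
        idx[i, 0, :] = nid
        coords.append((tm_v[i], 0.0, 0.0))
        nid += 1
    for i in range(n_tm + 1):
        for j in range(1, n_ab + 1):
            for k in range(n_rt):
                idx[i, j, k] = nid
                coords.append((tm_v[i], ab_v[j], rt_v[k]))
                nid += 1
    coords = np.array(coords)
    cobiveco = np.column_stack([coords, np.full(len(coords), tv)])
    nodes = _shell_map(shape, ventricle, coords[:, 0], coords[:, 1], coords[:, 2])

    tets = []
    for i in range(n_tm):
        for j in range(n_ab):
            for k in range(n_rt):
                k1 = (k + 1) % n_rt
                if j == 0:
                    # prism: apex edge (a, b) + quad ring above
                    a, b = idx[i, 0, 0], idx[i + 1, 0, 0]
                    p0, p1 = idx[i, 1, k], idx[i, 1, k1]
                    q0, q1 = idx[i + 1, 1, k], idx[i + 1, 1, k1]
                    tets += [(a, p0, p1, b), (p0, p1, b, q0), (p1, b, q0, q1)]
                else:
                    c = {(di, dj, dk): idx[i + di, j + dj, k1 if dk else k]
                         for di in (0, 1) for dj in (0, 1) for dk in (0, 1)}
                    o, d = c[0, 0, 0], c[1, 1, 1]
                    ring = [c[1, 0, 0], c[1, 1, 0], c[0, 1, 0],
                            c[0, 1, 1], c[0, 0, 1], c[1, 0, 1]]
                    for r in range(6):
                        tets.append((o, ring[r], ring[(r + 1) % 6], d))
    tets = np.array(tets, dtype=int)

    # enforce positive orientation
    p = nodes[tets]
    vol = np.einsum("ij,ij->i",
                    np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                    p[:, 3] - p[:, 0])
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    keep = np.abs(vol) > 1e-12
    return nodes, tets[keep], cobiveco


def build_synthetic_biventricular(
    shape_params: ShapeParams | None = None,
    resolution: str | dict = "coarse",
    seed: int = 0,
    subject_variability: float = 0.08,
) -> LabeledMesh:
    """Generate an idealized biventricular tetrahedral mesh.

    ``resolution`` is a named preset or a dict with per-ventricle
    (n_tm, n_ab, n_rt) cell counts.  A seeded multiplicative
    perturbation (up to ``subject_variability``) of the shell semi-axes
    and wall thicknesses emulates inter-subject anatomical variation
    while the Cobiveco coordinates remain exact.  Deterministic for
    fixed (shape, resolution, seed).
    """
    shape = shape_params or ShapeParams()
    shape.validate()
    if isinstance(resolution, str) and resolution not in RESOLUTIONS:
        raise GeometryError(f"unknown resolution {resolution!r}")
    rng = np.random.default_rng(seed)
    if subject_variability > 0:
        f = 1.0 + subject_variability * rng.uniform(-1, 1, size=9)
        shape = replace(
            shape,
            lv_endo=tuple(np.asarray(shape.lv_endo) * f[0:3]),
            rv_endo=tuple(np.asarray(shape.rv_endo) * f[3:6]),
            lv_wall=shape.lv_wall * f[6],
            rv_wall=shape.rv_wall * f[7],
            rv_center=tuple(np.asarray(shape.rv_center) * f[8]),
        )
        shape.validate()

    res = RESOLUTIONS[resolution] if isinstance(resolution, str) else resolution
    ln, lt, lc = _build_shell(shape, "lv", *res["lv"])
    rn, rt_, rc = _build_shell(shape, "rv", *res["rv"])
    nodes = np.vstack([ln, rn])
    tets = np.vstack([lt, rt_ + len(ln)])
    cob = np.vstack([lc, rc])
    mesh = LabeledMesh(nodes=nodes, tets=tets, cobiveco=cob)
    mesh.surfaces = {
        "lv_endo": (cob[:, 0] <= 0.05) & (cob[:, 3] == 0),
        "rv_endo": (cob[:, 0] <= 0.05) & (cob[:, 3] == 1),
        "epi": cob[:, 0] >= 0.95,
    }
    mesh._shape = shape  # retained for electrode placement / fibers
    return mesh


def build_box_mesh(extent: float = 10.0, n: int = 5) -> LabeledMesh:
    """Regular tetrahedral box mesh, used as an analytic test anatomy."""
    g = np.linspace(0.0, extent, n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    idx = np.arange(n ** 3).reshape(n, n, n)
    tets = []
    for i in range(n - 1):
        for j in range(n - 1):
            for k in range(n - 1):
                c = {(a, b, d): idx[i + a, j + b, k + d]
                     for a in (0, 1) for b in (0, 1) for d in (0, 1)}
                o, d8 = c[0, 0, 0], c[1, 1, 1]
                ring = [c[1, 0, 0], c[1, 1, 0], c[0, 1, 0],
                        c[0, 1, 1], c[0, 0, 1], c[1, 0, 1]]
                for r in range(6):
                    tets.append((o, ring[r], ring[(r + 1) % 6], d8))
    tets = np.array(tets)
    p = nodes[tets]
    vol = np.einsum("ij,ij->i",
                    np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                    p[:, 3] - p[:, 0])
    tets[vol < 0] = tets[vol < 0][:, [0, 2, 1, 3]]
    cob = np.zeros((len(nodes), 4))
    cob[:, 0] = nodes[:, 0] / extent          # nominal tm ramp
    cob[:, 1] = nodes[:, 2] / extent
    return LabeledMesh(nodes=nodes, tets=tets, cobiveco=cob)


# ---------------------------------------------------------------------------
# fibers

def _circular_mean(rt: np.ndarray) -> float:
    ang = 2 * np.pi * rt
    return (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0


def assign_fibers(mesh: LabeledMesh,
                  helix_endo_deg: float = 60.0,
                  helix_epi_deg: float = -60.0) -> LabeledMesh:
    """Rule-based fiber architecture: the helix angle interpolates
    linearly in ``tm`` from the endocardial to the epicardial value, and
    the (fiber, sheet, sheet-normal) triad is orthonormal per element.

    The local frame is taken from the analytic shell mapping
    (circumferential, apicobasal, transmural directions); for box meshes
    without a shell the frame falls back to cartesian axes.
    """
    shape = getattr(mesh, "_shape", None)
    cob = mesh.cobiveco[mesh.tets]            # (m, 4, 4)
    tm_c = cob[:, :, 0].mean(axis=1)
    helix = np.deg2rad(helix_endo_deg + (helix_epi_deg - helix_endo_deg) * tm_c)

    m = len(mesh.tets)
    if shape is None:
        e_c = np.tile([1.0, 0, 0], (m, 1))
        e_l = np.tile([0, 1.0, 0], (m, 1))
        e_t = np.tile([0, 0, 1.0], (m, 1))
    else:
        ab_c = cob[:, :, 1].mean(axis=1)
        tv_c = cob[:, 0, 3]
        # rt circular mean over the non-apex corners of each element
        rt_c = np.empty(m)
        for e in range(m):
            mask = cob[e, :, 1] > 1e-12
            rt_c[e] = _circular_mean(cob[e, mask, 2]) if mask.any() else 0.0
        e_c = np.empty((m, 3))
        e_l = np.empty((m, 3))
        e_t = np.empty((m, 3))
        h = 1e-4
        for vent, tvv in (("lv", 0.0), ("rv", 1.0)):
            sel = tv_c == tvv
            if not sel.any():
                continue
            tm_s, ab_s, rt_s = tm_c[sel], np.clip(ab_c[sel], h, 1 - h), rt_c[sel]
            d_rt = (_shell_map(shape, vent, tm_s, ab_s, (rt_s + h) % 1.0)
                    - _shell_map(shape, vent, tm_s, ab_s, (rt_s - h) % 1.0))
            d_ab = (_shell_map(shape, vent, tm_s, ab_s + h, rt_s)
                    - _shell_map(shape, vent, tm_s, ab_s - h, rt_s))
            c = d_rt / np.linalg.norm(d_rt, axis=1, keepdims=True)
            l = d_ab - np.einsum("ij,ij->i", d_ab, c)[:, None] * c
            l /= np.linalg.norm(l, axis=1, keepdims=True)
            e_c[sel], e_l[sel] = c, l
            e_t[sel] = np.cross(c, l)
    f = np.cos(helix)[:, None] * e_c + np.sin(helix)[:, None] * e_l
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    s = e_t - np.einsum("ij,ij->i", e_t, f)[:, None] * f
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    n = np.cross(f, s)
    mesh.fibers = np.stack([f, s, n], axis=1)
    return mesh


# ---------------------------------------------------------------------------
# AHA 17-segment mapping

#: segment ids of the 6 basal sectors, ordered by increasing rt from the
#: anterior LV/RV junction: anteroseptal, inferoseptal, inferior,
#: inferolateral, anterolateral, anterior.
_BASAL_SECTORS = (2, 3, 4, 5, 6, 1)
_APICAL_SECTORS = (14, 15, 16, 13)  # septal, inferior, lateral, anterior


def lv_mask_coord(tm: float, ab: float, rt: float, tv: float) -> bool:
    """LV-region rule including the whole septum: tv = 0, or the septal
    side of the RV (tv = 1 and rt > 2/3)."""
    return tv == 0 or (tv == 1 and rt > 2.0 / 3.0)


def aha_segment_of(c, bands: AHABands | None = None) -> int:
    """AHA 17-segment index of an LV-region Cobiveco coordinate.

    ``c`` is (tm, ab, rt, tv).  Septal RV-side points (tv = 1, rt > 2/3)
    are folded onto the LV septal sectors.
    """
    bands = bands or AHABands()
    tm, ab, rt, tv = float(c[0]), float(c[1]), float(c[2]), float(c[3])
    if not lv_mask_coord(tm, ab, rt, tv):
        raise GeometryError("AHA segments are defined on the LV region only")
    if tv == 1:  # fold RV septal rt (2/3, 1) onto LV septal rt (0, 1/3)
        rt = rt - 2.0 / 3.0
    rt = (rt - bands.sector_rt0) % 1.0
    if ab < bands.cap_ab:
        return 17
    if ab < bands.apical_ab:
        return _APICAL_SECTORS[min(int(rt * 4), 3)]
    base = 0 if ab >= bands.mid_ab else 6
    return _BASAL_SECTORS[min(int(rt * 6), 5)] + base


def aha_segments(mesh: LabeledMesh, bands: AHABands | None = None) -> np.ndarray:
    """Per-node AHA segment (0 for non-LV-region nodes)."""
    bands = bands or AHABands()
    out = np.zeros(mesh.n_nodes, dtype=int)
    for i, c in enumerate(mesh.cobiveco):
        if lv_mask_coord(*c):
            out[i] = aha_segment_of(c, bands)
    return out


# ---------------------------------------------------------------------------
# point-cloud resampling and electrodes

def resample_pointcloud(mesh: LabeledMesh, n: int, seed: int = 0) -> PointCloud:
    """Farthest-point subsampling of the mesh nodes to ``n`` points.

    Carries positions and Cobiveco coordinates; deterministic per seed.
    ``n`` equal to the node count returns the identity ordering.
    """
    nn = mesh.n_nodes
    if n > nn:
        raise GeometryError(f"cannot sample {n} points from {nn} nodes")
    if n == nn:
        sel = np.arange(nn)
    else:
        rng = np.random.default_rng(seed)
        sel = np.empty(n, dtype=int)
        sel[0] = rng.integers(nn)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[sel[0]], axis=1)
        for i in range(1, n):
            sel[i] = int(np.argmax(d))
            d = np.minimum(d, np.linalg.norm(mesh.nodes - mesh.nodes[sel[i]], axis=1))
    pts = np.column_stack([mesh.nodes[sel], mesh.cobiveco[sel]])
    pc = PointCloud(points=pts)
    pc.indices = sel
    return pc


def chamfer_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric chamfer distance: mean nearest-neighbour squared
    distance in both directions."""
    d = cdist(a, b, "sqeuclidean")
    return float(d.min(axis=1).mean() + d.min(axis=0).mean())


@dataclass
class TorsoParams:
    """Ellipsoidal virtual torso enclosing the heart bounding box."""

    margin_mm: float = 60.0
    scale: float = 1.0


#: precordial azimuths (deg) in the transverse plane, 0 = anterior,
#: positive toward the patient's right; V1..V6 sweep monotonically left.
_PRECORDIAL_DEG = {"V1": 25.0, "V2": 8.0, "V3": -10.0, "V4": -30.0,
                   "V5": -52.0, "V6": -75.0}


def place_electrodes(mesh: LabeledMesh,
                     torso_params: TorsoParams | None = None) -> ElectrodeSet:
    """Standard 10 electrodes on an ellipsoidal virtual torso surface
    surrounding the heart bounding box (anterior = +y, right = +x,
    superior = +z)."""
    tp = torso_params or TorsoParams()
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) + tp.margin_mm
    half *= tp.scale
    pos = {}
    for name, deg in _PRECORDIAL_DEG.items():
        psi = np.deg2rad(deg)
        pos[name] = center + np.array(
            [half[0] * np.sin(psi), half[1] * np.cos(psi), 0.0])
    pos["RA"] = center + np.array([0.9 * half[0], 0.3 * half[1], 1.2 * half[2]])
    pos["LA"] = center + np.array([-0.9 * half[0], 0.3 * half[1], 1.2 * half[2]])
    pos["RL"] = center + np.array([0.9 * half[0], 0.2 * half[1], -1.6 * half[2]])
    pos["LL"] = center + np.array([-0.9 * half[0], 0.2 * half[1], -1.6 * half[2]])
    return ElectrodeSet(positions=pos)
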