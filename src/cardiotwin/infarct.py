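"""Infarct scar and border-zone parameterization in Cobiveco space.

A scar is an ellipsoidal region in (tm, ab, rt) coordinates around a
center (tm0, ab0, rt0) with radii (r_tm, r_ab, r_rt); the rotational
difference is taken on the circle (modulo 1).  The border zone (BZ) is
the same ellipsoid with radii scaled by ``bz_scale`` minus the scar
core.  Scars are restricted to the LV region, which includes the septal
side of the RV (tv = 1, rt > 2/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BZ, HEALTHY, SCAR, LabeledMesh

#: transmural radius of fully transmural vs subendocardial scars
R_TM_TRANSMURAL = 3.0
R_TM_SUBENDOCARDIAL = 0.5

#: conduction-velocity scaling of scar / border zone relative to healthy
CV_SCALE_STANDARD = (0.10, 0.50)
CV_SCALE_SLOW = (0.05, 0.25)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class InfarctScenario:
    name: str
    center: tuple[float, float, float]        # (tm0, ab0, rt0)
    radii: tuple[float, float, float]         # (r_tm, r_ab, r_rt)
    bz_scale: float = 1.5
    cv_scale_scar: float = CV_SCALE_STANDARD[0]
    cv_scale_bz: float = CV_SCALE_STANDARD[1]
    transmural: bool = True

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise ScenarioError(f"{self.name}: radii must be positive")
        if not (0 < self.cv_scale_scar <= 1 and 0 < self.cv_scale_bz <= 1):
            raise ScenarioError(f"{self.name}: cv scales must be in (0, 1]")
        if self.bz_scale < 1:
            raise ScenarioError(f"{self.name}: bz_scale must be >= 1")


def lv_mask(c) -> bool:
    """True iff the coordinate belongs to the LV region (whole septum
    included): tv = 0, or tv = 1 with rt > 2/3."""
    tv, rt = float(c[3]), float(c[2])
    return tv == 0 or (tv == 1 and rt > 2.0 / 3.0)


def lv_mask_nodes(cobiveco: np.ndarray) -> np.ndarray:
    tv, rt = cobiveco[:, 3], cobiveco[:, 2]
    return (tv == 0) | ((tv == 1) & (rt > 2.0 / 3.0))


def _wrapped_drt(rt: np.ndarray, rt0: float) -> np.ndarray:
    d = np.abs(np.asarray(rt) - rt0)
    return np.minimum(d, 1.0 - d)


def ellipsoid_membership(c, center, radii) -> bool:
    """Boundary-inclusive ellipsoid membership in Cobiveco space with
    the rotational difference wrapped on the circle."""
    if min(radii) <= 0:
        raise ScenarioError("radii must be positive")
    tm, ab, rt = float(c[0]), float(c[1]), float(c[2])
    tm0, ab0, rt0 = center
    r_tm, r_ab, r_rt = radii
    lhs = ((tm - tm0) / r_tm) ** 2 + ((ab - ab0) / r_ab) ** 2 \
        + (float(_wrapped_drt(rt, rt0)) / r_rt) ** 2
    return lhs <= 1.0


def label_tissue(mesh: LabeledMesh, scenario: InfarctScenario) -> np.ndarray:
    """Per-node tissue class: scar inside the scar ellipsoid, BZ inside
    the bz_scale-dilated ellipsoid outside the scar, restricted to the
    LV region; everything else healthy."""
    tm, ab, rt = mesh.tm, mesh.ab, mesh.rt
    tm0, ab0, rt0 = scenario.center
    r = np.asarray(scenario.radii)

    def inside(rad):
        return (((tm - tm0) / rad[0]) ** 2 + ((ab - ab0) / rad[1]) ** 2
                + (_wrapped_drt(rt, rt0) / rad[2]) ** 2) <= 1.0

    lv = lv_mask_nodes(mesh.cobiveco)
    scar = inside(r) & lv
    bz = inside(r * scenario.bz_scale) & lv & ~scar
    labels = np.full(mesh.n_nodes, HEALTHY, dtype=np.int8)
    labels[bz] = BZ
    labels[scar] = SCAR
    if not scar.any():
        warnings.warn(f"scenario {scenario.name}: empty scar set", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# scenario catalogue

#: default (ab0, rt0) centers and (r_ab, r_rt) radii of the seven infarct
#: locations.  The rotational layout follows the package convention
#: (rt = 0 at the anterior LV/RV junction, septum in [0, 1/3)); each
#: center's AHA segment is asserted to match its name in the test suite.
DEFAULT_CATALOGUE = {
    "septal": {"center": (0.5, 1.0 / 6.0), "radii": (0.20, 0.09)},
    "apical": {"center": (0.10, 0.50), "radii": (0.22, 0.50)},
    "extensive_anterior": {"center": (0.55, 11.0 / 12.0), "radii": (0.30, 0.13)},
    "limited_anterior": {"center": (0.55, 11.0 / 12.0), "radii": (0.15, 0.07)},
    "lateral": {"center": (0.50, 2.0 / 3.0), "radii": (0.25, 0.10)},
    "inferior": {"center": (0.50, 5.0 / 12.0), "radii": (0.22, 0.10)},
    "inferolateral": {"center": (0.50, 7.0 / 12.0), "radii": (0.25, 0.12)},
}

_LOCATION_ORDER = ("septal", "apical", "extensive_anterior", "limited_anterior",
                   "lateral", "inferior", "inferolateral")


def enumerate_scenarios(catalogue: dict | None = None,
                        include_slow_cv: bool = True,
                        bz_scale: float = 1.5) -> list[InfarctScenario]:
    """Enumerate the post-MI scenario set.

    7 locations x 2 transmural extents, plus the small lateral scar
    (r_ab and r_rt halved) at both extents, plus one slow-CV variant of
    the transmural large lateral scar: 17 scenarios in total, 16 when
    the slow-CV variant is excluded (the inference subset).
    """
    cat = catalogue or DEFAULT_CATALOGUE
    missing = set(_LOCATION_ORDER) - set(cat)
    if missing:
        raise ScenarioError(f"catalogue missing locations: {sorted(missing)}")
    scenarios: list[InfarctScenario] = []

    def make(name, loc, r_ab, r_rt, transmural, cv=CV_SCALE_STANDARD):
        ab0, rt0 = loc["center"]
        r_tm = R_TM_TRANSMURAL if transmural else R_TM_SUBENDOCARDIAL
        return InfarctScenario(
            name=name, center=(0.0, ab0, rt0), radii=(r_tm, r_ab, r_rt),
            bz_scale=bz_scale, cv_scale_scar=cv[0], cv_scale_bz=cv[1],
            transmural=transmural)

    for loc_name in _LOCATION_ORDER:
        loc = cat[loc_name]
        r_ab, r_rt = loc["radii"]
        for transmural in (True, False):
            ext = "transmural" if transmural else "subendocardial"
            scenarios.append(make(f"{loc_name}_{ext}", loc, r_ab, r_rt, transmural))
    # small lateral: half r_ab and r_rt of the large lateral scar
    lat = cat["lateral"]
    r_ab, r_rt = lat["radii"]
    for transmural in (True, False):
        ext = "transmural" if transmural else "subendocardial"
        scenarios.append(
            make(f"lateral_small_{ext}", lat, r_ab / 2.0, r_rt / 2.0, transmural))
    if include_slow_cv:
        scenarios.append(
            make("lateral_slow_cv_transmural", lat, r_ab, r_rt, True,
                 cv=CV_SCALE_SLOW))
    return scenarios


def scenario_to_dict(s: InfarctScenario) -> dict:
    return {"name": s.name, "center": list(s.center), "radii": list(s.radii),
            "bz_scale": s.bz_scale, "cv_scale_scar": s.cv_scale_scar,
            "cv_scale_bz": s.cv_scale_bz, "transmural": s.transmural}


def scenario_from_dict(d: dict) -> InfarctScenario:
    return InfarctScenario(
        name=d["name"], center=tuple(d["center"]), radii=tuple(d["radii"]),
        bz_scale=d.get("bz_scale", 1.5),
        cv_scale_scar=d.get("cv_scale_scar", CV_SCALE_STANDARD[0]),
        cv_scale_bz=d.get("cv_scale_bz", CV_SCALE_STANDARD[1]),
        transmural=d.get("transmural", True))
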