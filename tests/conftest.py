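import pytest

from cardiotwin.geometry import (assign_fibers, build_box_mesh,
                                 build_synthetic_biventricular)
from cardiotwin.pipeline import SubjectTwin

TINY_RES = {"lv": (2, 3, 6), "rv": (1, 2, 4)}


@pytest.fixture(scope="session")
def coarse_mesh():
    mesh = build_synthetic_biventricular(resolution="coarse", seed=7)
    assign_fibers(mesh)
    return mesh


@pytest.fixture(scope="session")
def fine_mesh():
    mesh = build_synthetic_biventricular(resolution="fine", seed=7)
    assign_fibers(mesh)
    return mesh


@pytest.fixture(scope="session")
def tiny_mesh():
    """< 200 nodes, for exhaustive solver oracles."""
    mesh = build_synthetic_biventricular(resolution=TINY_RES, seed=5)
    assign_fibers(mesh)
    return mesh


@pytest.fixture(scope="session")
def box_mesh():
    mesh = build_box_mesh(extent=10.0, n=5)
    assign_fibers(mesh, 0.0, 0.0)
    return mesh


@pytest.fixture(scope="session")
def twin(coarse_mesh):
    return SubjectTwin(coarse_mesh, subject_id=0)


@pytest.fixture(scope="session")
def baseline(twin):
    return twin.simulate(None)
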