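import numpy as np
import pytest

from cardiotwin.forward import (CM_PER_S_TO_MM_PER_MS, CVConfig, RootNodeSet,
                                SolverError, assemble_conduction,
                                build_travel_time_graph, default_root_nodes,
                                solve_eikonal, total_activation_time)
from cardiotwin.geometry import SCAR, build_box_mesh
from cardiotwin.infarct import enumerate_scenarios, label_tissue


def _scenario(name):
    return [s for s in enumerate_scenarios() if s.name == name][0]


def bellman_ford_oracle(graph, sources, offsets):
    """Brute-force repeated edge relaxation (independent of Dijkstra)."""
    g = graph.tocoo()
    n = graph.shape[0]
    dist = np.full(n, np.inf)
    dist[sources] = offsets
    for _ in range(n):
        changed = False
        for u, v, w in zip(g.row, g.col, g.data):
            if dist[u] + w < dist[v] - 1e-15:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    return dist


class TestConductionField:
    def test_healthy_directional_speeds(self, coarse_mesh):
        cond = assemble_conduction(coarse_mesh, None)
        f = coarse_mesh.fibers[:, 0]
        v_f = np.sqrt(np.einsum("ei,eij,ej->e", f, cond.tensors, f))
        assert np.allclose(v_f, 65 * CM_PER_S_TO_MM_PER_MS, rtol=1e-9)
        s = coarse_mesh.fibers[:, 1]
        v_s = np.sqrt(np.einsum("ei,eij,ej->e", s, cond.tensors, s))
        assert np.allclose(v_s, 48 * CM_PER_S_TO_MM_PER_MS, rtol=1e-9)

    def test_scar_elements_scaled_to_ten_percent(self, coarse_mesh):
        scen = _scenario("lateral_transmural")
        labels = label_tissue(coarse_mesh, scen)
        cond = assemble_conduction(coarse_mesh, labels,
                                   cv_scale_scar=scen.cv_scale_scar,
                                   cv_scale_bz=scen.cv_scale_bz)
        scar_elems = (labels[coarse_mesh.tets] == SCAR).all(axis=1)
        assert scar_elems.any()
        f = coarse_mesh.fibers[scar_elems, 0]
        v_f = np.sqrt(np.einsum("ei,eij,ej->e", f,
                                cond.tensors[scar_elems], f))
        assert np.allclose(v_f, 6.5 * CM_PER_S_TO_MM_PER_MS, rtol=1e-9)

    def test_slow_variant_bz_is_quarter_speed(self, coarse_mesh):
        scen = _scenario("lateral_slow_cv_transmural")
        labels = label_tissue(coarse_mesh, scen)
        cond = assemble_conduction(coarse_mesh, labels,
                                   cv_scale_scar=scen.cv_scale_scar,
                                   cv_scale_bz=scen.cv_scale_bz)
        bz_elems = (labels[coarse_mesh.tets] == 2).all(axis=1)
        if bz_elems.any():
            f = coarse_mesh.fibers[bz_elems, 0]
            v_f = np.sqrt(np.einsum("ei,eij,ej->e", f,
                                    cond.tensors[bz_elems], f))
            assert np.allclose(v_f, 0.25 * 65 * CM_PER_S_TO_MM_PER_MS,
                               rtol=1e-9)

    def test_nonpositive_cv_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            assemble_conduction(coarse_mesh, None, CVConfig(v_fiber=0.0))


class TestEikonalSolve:
    def test_isotropic_box_matches_analytic(self, box_mesh):
        """Uniform isotropic speed: t = |x - root| / v within 5 %."""
        v = 0.5  # mm/ms
        m = len(box_mesh.tets)
        tensors = np.tile(v ** 2 * np.eye(3), (m, 1, 1))
        from cardiotwin.forward import ConductionField

        cond = ConductionField(tensors=tensors,
                               layer_speed=np.zeros(box_mesh.n_nodes),
                               node_scale=np.ones(box_mesh.n_nodes))
        roots = RootNodeSet(indices=[0])
        t = solve_eikonal(box_mesh, cond, roots)
        exact = np.linalg.norm(box_mesh.nodes - box_mesh.nodes[0], axis=1) / v
        rel = np.abs(t[1:] - exact[1:]) / exact[1:]
        assert rel.max() <= 0.05

    def test_equal_delays_zero_at_roots(self, tiny_mesh):
        cond = assemble_conduction(tiny_mesh, None)
        roots = default_root_nodes(tiny_mesh,
                                   delays=np.full(7, 12.0))
        t = solve_eikonal(tiny_mesh, cond, roots)
        assert np.allclose(t[roots.indices], 0.0)
        assert t.min() == 0.0

    def test_halving_speeds_doubles_times(self, tiny_mesh):
        cond = assemble_conduction(tiny_mesh, None)
        roots = default_root_nodes(tiny_mesh)
        t1 = solve_eikonal(tiny_mesh, cond, roots)
        from cardiotwin.forward import ConductionField

        half = ConductionField(tensors=cond.tensors * 0.25,
                               layer_speed=cond.layer_speed * 0.5,
                               node_scale=cond.node_scale)
        t2 = solve_eikonal(tiny_mesh, half, roots)
        assert np.allclose(t2, 2 * t1, rtol=1e-9)

    def test_matches_bellman_ford_oracle(self, tiny_mesh):
        assert tiny_mesh.n_nodes <= 200
        cond = assemble_conduction(tiny_mesh, None)
        roots = default_root_nodes(tiny_mesh, delays=np.array(
            [0.0, 2.0, 1.0, 0.0, 3.0, 0.5, 0.0]))
        t = solve_eikonal(tiny_mesh, cond, roots)
        g = build_travel_time_graph(tiny_mesh, cond)
        offs = roots.delays - roots.delays.min()
        ref = bellman_ford_oracle(g, roots.indices, offs)
        assert np.allclose(t, ref, atol=1e-12)

    def test_monotone_under_cv_reduction(self, tiny_mesh):
        """Decreasing any speed never decreases any activation time
        (100 random single-node slowdowns)."""
        cond = assemble_conduction(tiny_mesh, None)
        roots = default_root_nodes(tiny_mesh)
        t0 = solve_eikonal(tiny_mesh, cond, roots)
        rng = np.random.default_rng(0)
        from cardiotwin.forward import ConductionField

        for _ in range(100):
            scale = np.ones(len(tiny_mesh.tets))
            hit = rng.integers(0, len(scale), size=rng.integers(1, 30))
            scale[hit] = rng.uniform(0.05, 0.95)
            slower = ConductionField(
                tensors=cond.tensors * scale[:, None, None] ** 2,
                layer_speed=cond.layer_speed * rng.uniform(0.5, 1.0),
                node_scale=cond.node_scale)
            t1 = solve_eikonal(tiny_mesh, slower, roots)
            assert (t1 >= t0 - 1e-9).all()

    def test_component_without_root_raises(self, tiny_mesh):
        cond = assemble_conduction(tiny_mesh, None)
        lv_only = np.flatnonzero(tiny_mesh.tv == 0)[:4]
        with pytest.raises(SolverError):
            solve_eikonal(tiny_mesh, cond, RootNodeSet(indices=lv_only))

    def test_root_set_shape(self, coarse_mesh):
        roots = default_root_nodes(coarse_mesh)
        tv = coarse_mesh.tv[roots.indices]
        assert (tv == 0).sum() == 4 and (tv == 1).sum() == 3
        assert (coarse_mesh.tm[roots.indices] == 0).all()


class TestTotalActivationTime:
    def test_single_node(self):
        assert total_activation_time(np.array([5.0])) == 0.0

    def test_scar_prolongs_activation(self, twin):
        t_healthy = total_activation_time(twin.simulate(None).atm)
        scar = twin.simulate(_scenario("lateral_transmural"))
        assert total_activation_time(scar.atm) > t_healthy

    def test_slow_cv_at_least_standard(self, twin):
        std = total_activation_time(
            twin.simulate(_scenario("lateral_transmural")).atm)
        slow = total_activation_time(
            twin.simulate(_scenario("lateral_slow_cv_transmural")).atm)
        assert slow >= std
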