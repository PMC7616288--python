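import numpy as np
import pytest

from cardiotwin.ecg import (ActionPotentialTemplate, ECGError, PseudoECGConfig,
                            QRSSignal, derive_leads, electrode_functional,
                            normalize_and_resample, pseudo_ecg_at,
                            qrs_duration)
from cardiotwin.forward import total_activation_time
from cardiotwin.geometry import build_box_mesh


@pytest.fixture(scope="module")
def small_source():
    """~50-tet mesh with a graded activation map and a far electrode."""
    mesh = build_box_mesh(extent=6.0, n=3)   # 48 tets
    atm = mesh.nodes[:, 0] * 2.0             # planar wavefront along x
    electrode = np.array([40.0, 25.0, 30.0])
    return mesh, atm, electrode


class TestTemplate:
    def test_step_limits_and_monotonicity(self):
        tpl = ActionPotentialTemplate()
        tau = np.linspace(-5, 6, 500)
        s = tpl.shape(tau)
        assert (np.diff(s) >= 0).all()
        assert (s[tau < 0] == 0).all()
        assert (s[tau > tpl.upstroke_ms] == 1).all()
        assert tpl(np.array([-10.0]))[0] == tpl.resting_mv
        assert tpl(np.array([10.0]))[0] == tpl.resting_mv + tpl.amplitude_mv


class TestPseudoECG:
    def test_linear_in_amplitude(self, small_source):
        mesh, atm, el = small_source
        t1, p1 = pseudo_ecg_at(mesh, atm, el, ActionPotentialTemplate())
        t2, p2 = pseudo_ecg_at(mesh, atm, el,
                               ActionPotentialTemplate(amplitude_mv=200.0))
        # doubling the upstroke amplitude doubles the deflection
        assert np.allclose(p2 - p2[0], 2 * (p1 - p1[0]), atol=1e-12)

    def test_uniform_vm_gives_zero(self, small_source):
        mesh, _, el = small_source
        atm = np.full(mesh.n_nodes, 3.0)   # synchronous activation
        _, phi = pseudo_ecg_at(mesh, atm, el)
        assert np.abs(phi).max() < 1e-12

    def test_farfield_decay_at_least_quadratic(self, small_source):
        mesh, atm, _ = small_source
        center = mesh.nodes.mean(axis=0)
        direction = np.array([1.0, 0.3, 0.2])
        direction /= np.linalg.norm(direction)
        e1 = center + 40.0 * direction
        e2 = center + 80.0 * direction
        _, p1 = pseudo_ecg_at(mesh, atm, e1)
        _, p2 = pseudo_ecg_at(mesh, atm, e2)
        assert np.abs(p1).max() / np.abs(p2).max() >= 4.0

    def test_centroid_vs_nodal_quadrature(self, small_source):
        """Independent quadrature oracle: evaluate grad(1/r) at the four
        vertices of each tet and average, instead of one centroid point."""
        mesh, atm, el = small_source
        tpl = ActionPotentialTemplate()
        cfg = PseudoECGConfig()
        times, phi = pseudo_ecg_at(mesh, atm, el, tpl, cfg)

        from cardiotwin.ecg import _tet_geometry

        vol, _, G = _tet_geometry(mesh)
        p = mesh.nodes[mesh.tets]
        d = p - el[None, None, :]
        r = np.linalg.norm(d, axis=2)
        kern = (-d / (r ** 3)[:, :, None]).mean(axis=1)   # vertex average
        w = np.zeros(mesh.n_nodes)
        contrib = -vol[:, None] * np.einsum("ti,tij->tj", kern, G)
        np.add.at(w, mesh.tets.ravel(), contrib.ravel())
        vm = tpl(times[:, None] - atm[None, :])
        phi_oracle = vm @ w
        num = np.linalg.norm(phi - phi_oracle)
        den = np.linalg.norm(phi_oracle)
        assert num / den <= 0.05

    def test_electrode_inside_mesh_rejected(self, small_source):
        mesh, atm, _ = small_source
        inside = mesh.nodes.mean(axis=0)
        centroids = mesh.nodes[mesh.tets].mean(axis=1)
        with pytest.raises(ECGError):
            electrode_functional(mesh, centroids[0])


class TestLeadDerivation:
    def _traces(self, rng):
        return {n: rng.standard_normal(20)
                for n in ("RA", "LA", "RL", "LL", "V1", "V2", "V3",
                          "V4", "V5", "V6")}

    def test_identical_traces_zero_limb_leads(self):
        tr = {n: np.ones(10) * 3.3 for n in ("RA", "LA", "RL", "LL", "V1",
                                             "V2", "V3", "V4", "V5", "V6")}
        leads = derive_leads(tr)
        assert np.abs(leads[0]).max() == 0     # I
        assert np.abs(leads[1]).max() == 0     # II

    def test_swapping_arms_negates_lead_one(self):
        rng = np.random.default_rng(0)
        tr = self._traces(rng)
        leads = derive_leads(tr)
        swapped = dict(tr, LA=tr["RA"], RA=tr["LA"])
        leads2 = derive_leads(swapped)
        assert np.allclose(leads2[0], -leads[0])

    def test_wilson_terminal_shift(self):
        """Shifting one unipolar electrode by delta changes the sum of
        the six precordial leads by -delta (through the terminal) plus
        delta on the shifted lead."""
        rng = np.random.default_rng(1)
        tr = self._traces(rng)
        delta = 0.7
        shifted = dict(tr, LA=tr["LA"] + delta)
        s1 = derive_leads(tr)[2:].sum(axis=0)
        s2 = derive_leads(shifted)[2:].sum(axis=0)
        assert np.allclose(s2 - s1, -6 * delta / 3)

    def test_missing_electrode_rejected(self):
        rng = np.random.default_rng(2)
        tr = self._traces(rng)
        del tr["V3"]
        with pytest.raises(ECGError):
            derive_leads(tr)


class TestNormalization:
    def test_unit_peak_and_512_samples(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((8, 100)) * 5
        qrs = normalize_and_resample(raw, dt_ms=0.5)
        assert qrs.data.shape == (8, 512)
        assert np.abs(qrs.data).max() == pytest.approx(1.0)

    def test_length_512_values_unchanged(self):
        rng = np.random.default_rng(1)
        raw = rng.standard_normal((8, 512))
        raw[:, 0] = 1.0
        raw[:, -1] = 1.0   # keep the window full-length
        qrs = normalize_and_resample(raw, dt_ms=0.5)
        assert np.allclose(qrs.data, raw / np.abs(raw).max())

    def test_all_zero_rejected(self):
        with pytest.raises(ECGError):
            normalize_and_resample(np.zeros((8, 50)), 0.5)

    def test_duration_matches_activation_span(self, twin, baseline):
        tat = total_activation_time(baseline.atm)
        expected = tat + twin.template.upstroke_ms
        assert abs(baseline.qrs.duration_ms - expected) <= 2 * twin.ecg_config.dt_ms


class TestQRSDuration:
    def _pulse(self, width_samples, dt=0.5):
        data = np.zeros((8, 512))
        data[0, 10:10 + width_samples] = 1.0
        return QRSSignal(data=data, duration_ms=width_samples * dt, dt_ms=dt)

    def test_square_pulse_width(self):
        qrs = self._pulse(60)
        assert qrs_duration(qrs) == pytest.approx(60 * 0.5)

    def test_zero_threshold_sees_padding(self):
        qrs = self._pulse(60)
        qrs.data += 1e-6     # padding no longer exactly zero
        assert qrs_duration(qrs, theta_dur=0.0) == pytest.approx(512 * 0.5)

    def test_scar_duration_not_shorter_than_healthy(self, twin, baseline):
        from cardiotwin.infarct import enumerate_scenarios

        scen = [s for s in enumerate_scenarios()
                if s.name == "extensive_anterior_transmural"][0]
        scar = twin.simulate(scen)
        assert qrs_duration(scar.qrs) >= qrs_duration(baseline.qrs)


class TestEndToEndDeterminism:
    def test_same_config_bitwise_identical(self, coarse_mesh):
        from cardiotwin.infarct import enumerate_scenarios
        from cardiotwin.pipeline import SubjectTwin

        scen = enumerate_scenarios()[0]
        a = SubjectTwin(coarse_mesh).simulate(scen)
        b = SubjectTwin(coarse_mesh).simulate(scen)
        assert a.qrs.data.tobytes() == b.qrs.data.tobytes()
        assert a.qrs.duration_ms == b.qrs.duration_ms
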