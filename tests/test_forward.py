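import numpy as np
import pytest

import vtexit as vx
from vtexit.forward import (
    ECG_CHANNEL_NAMES,
    ECG_LEADS,
    EGM_CHANNEL_NAMES,
    EGM_LEADS,
    LeadDefinition,
    TraceSet,
    compute_electrode_potentials,
    derive_ecg_leads,
    derive_egm_vectors,
    lead_field_matrix,
)
from vtexit.geometry import VentricularMesh


def _random_surface_potentials(seed=0, T=40):
    rng = np.random.default_rng(seed)
    return {n: rng.normal(size=T) for n in ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")}


def _random_device_potentials(seed=0, T=40):
    rng = np.random.default_rng(seed)
    return {
        n: rng.normal(size=T)
        for n in ("CAN", "SVC_COIL", "RV_COIL", "RV_TIP", "RV_RING", "LV1", "LV2", "LV3", "LV4")
    }


class TestLeadAlgebra:
    def test_all_leads_reference_invariant(self):
        for ld in ECG_LEADS + EGM_LEADS:
            assert abs(sum(c for _, c in ld.formula)) < 1e-12

    def test_invalid_lead_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            LeadDefinition(name="bad", formula=(("RA", 1.0), ("LA", 0.5)))

    def test_einthoven_closure(self):
        ecg = derive_ecg_leads(_random_surface_potentials())
        s = {n: ecg.samples[i] for i, n in enumerate(ecg.channel_names)}
        assert np.abs(s["II"] - s["I"] - s["III"]).max() < 1e-12

    def test_goldberger_closure(self):
        ecg = derive_ecg_leads(_random_surface_potentials(1))
        s = {n: ecg.samples[i] for i, n in enumerate(ecg.channel_names)}
        assert np.abs(s["aVR"] + s["aVL"] + s["aVF"]).max() < 1e-12

    def test_reference_invariance_under_offset(self):
        pots = _random_surface_potentials(2)
        shifted = {k: v + 123.456 for k, v in pots.items()}
        a = derive_ecg_leads(pots).samples
        b = derive_ecg_leads(shifted).samples
        assert np.allclose(a, b, atol=1e-9)

    def test_ecg_channel_contract(self):
        ecg = derive_ecg_leads(_random_surface_potentials())
        assert tuple(ecg.channel_names) == ECG_CHANNEL_NAMES
        assert ecg.samples.shape[0] == 16

    def test_missing_electrode_raises(self):
        pots = _random_surface_potentials()
        del pots["V3"]
        with pytest.raises(ValueError, match="missing"):
            derive_ecg_leads(pots)


class TestEgmVectors:
    def test_channel_contract(self):
        egm = derive_egm_vectors(_random_device_potentials())
        assert tuple(egm.channel_names) == EGM_CHANNEL_NAMES
        assert egm.samples.shape[0] == 8

    def test_bipolar_differences(self):
        pots = _random_device_potentials(3)
        egm = derive_egm_vectors(pots)
        for i, ld in enumerate(EGM_LEADS):
            (e1, c1), (e2, c2) = sorted(ld.formula, key=lambda t: -t[1])
            assert (c1, c2) == (1.0, -1.0)
            assert np.allclose(egm.samples[i], pots[e1] - pots[e2])

    def test_offset_invariance(self):
        pots = _random_device_potentials(4)
        shifted = {k: v - 55.0 for k, v in pots.items()}
        assert np.allclose(derive_egm_vectors(pots).samples, derive_egm_vectors(shifted).samples)

    def test_missing_electrode_raises(self):
        pots = _random_device_potentials()
        del pots["LV2"]
        with pytest.raises(ValueError, match="missing"):
            derive_egm_vectors(pots)


def _mirrored_tet_mesh():
    """Two tets mirrored about the y = 0 plane (exact symmetry)."""
    base = np.array([[0.0, 1.0, 0.0], [10.0, 2.0, 0.0], [3.0, 4.0, 8.0], [5.0, 6.0, -6.0]])
    mirror = base * np.array([1.0, -1.0, 1.0])
    nodes = np.vstack([base, mirror])
    elements = np.array([[0, 1, 2, 3], [4, 5, 6, 7]], dtype=np.int64)
    return VentricularMesh(
        nodes=nodes,
        elements=elements,
        endo_nodes=np.array([0]),
        epi_nodes=np.array([1]),
        base_nodes=np.array([2]),
        apex_node=0,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id="mirror",
        fiber_dirs=np.tile([1.0, 0.0, 0.0], (2, 1)),
    )


class TestPseudoEcg:
    def test_uniform_vm_zero_potential(self, mesh_coarse):
        els = vx.place_surface_electrodes(mesh_coarse)
        vm = np.full((mesh_coarse.n_nodes, 5), -85.0)
        pots = compute_electrode_potentials(mesh_coarse, vm, els)
        assert max(np.abs(v).max() for v in pots.values()) < 1e-9

    def test_repolarized_returns_to_zero(self, mesh_coarse, conduction):
        act = vx.solve_eikonal(mesh_coarse, conduction, [(0, 0.0)])
        dur = float(act.times.max()) + 330.0
        vm = vx.synthesize_vm_traces(act, vx.APTemplate(), dt=1.0, duration=dur)
        els = vx.place_surface_electrodes(mesh_coarse)
        pots = compute_electrode_potentials(mesh_coarse, vm, els)
        assert max(abs(v[-1]) for v in pots.values()) < 1e-9

    def test_mirror_symmetric_electrodes_equal(self):
        """A wavefront symmetric about a plane gives mirror-equal signals."""
        mesh = _mirrored_tet_mesh()
        rng = np.random.default_rng(0)
        vm_base = rng.normal(size=(4, 20))
        vm = np.vstack([vm_base, vm_base])  # Vm mirror-symmetric
        e1 = np.array([[20.0, 15.0, 5.0]])
        e2 = e1 * np.array([1.0, -1.0, 1.0])
        p1 = lead_field_matrix(mesh, e1) @ vm
        p2 = lead_field_matrix(mesh, e2) @ vm
        assert np.allclose(p1, p2, rtol=1e-6, atol=1e-12)

    def test_linearity_in_vm(self, mesh_coarse):
        els = vx.place_surface_electrodes(mesh_coarse)
        L = lead_field_matrix(mesh_coarse, els.positions)
        rng = np.random.default_rng(1)
        vm = rng.normal(size=(mesh_coarse.n_nodes, 7))
        assert np.allclose(L @ (3.5 * vm), 3.5 * (L @ vm))

    def test_far_field_decay(self, mesh_coarse, conduction):
        act = vx.solve_eikonal(mesh_coarse, conduction, [(10, 0.0)])
        dur = float(act.times.max()) + 330.0
        vm = vx.synthesize_vm_traces(act, vx.APTemplate(), dt=1.0, duration=dur)
        center = mesh_coarse.nodes.mean(axis=0)
        for direction in (np.array([1.0, 0.3, 0.2]), np.array([-0.5, 1.0, 0.5])):
            d = direction / np.linalg.norm(direction)
            near = (center + 80.0 * d)[None]
            far = (center + 160.0 * d)[None]
            rms_near = np.sqrt(np.mean((lead_field_matrix(mesh_coarse, near) @ vm) ** 2))
            rms_far = np.sqrt(np.mean((lead_field_matrix(mesh_coarse, far) @ vm) ** 2))
            assert rms_far < rms_near

    def test_electrode_at_centroid_raises(self, mesh_coarse):
        cent = mesh_coarse.element_centroids()[0]
        with pytest.raises(ValueError, match="singularity"):
            lead_field_matrix(mesh_coarse, cent[None])

    def test_electrode_inside_myocardium_raises(self, mesh_coarse):
        els = vx.place_surface_electrodes(mesh_coarse)
        inside = mesh_coarse.nodes[mesh_coarse.elements[40]].mean(axis=0)
        els.positions[0] = inside
        vm = np.zeros((mesh_coarse.n_nodes, 3))
        with pytest.raises(ValueError, match="singularity"):
            compute_electrode_potentials(mesh_coarse, vm, els)


class TestTraceSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            TraceSet(channel_names=["a"], samples=np.zeros((2, 5)), dt=1.0)
        with pytest.raises(ValueError):
            TraceSet(channel_names=["a"], samples=np.full((1, 5), np.nan), dt=1.0)
        with pytest.raises(ValueError):
            TraceSet(channel_names=["a"], samples=np.zeros((1, 5)), dt=-1.0)
        ts = TraceSet(channel_names=["a", "b"], samples=np.zeros((2, 5)), dt=1.0, beat_kind="vt")
        assert ts.samples.shape == (2, 5)
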