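import numpy as np
import pytest
from scipy.spatial import Delaunay

import vtexit as vx
from vtexit.geometry import VentricularMesh
from vtexit.propagation import (
    ActivationMap,
    APTemplate,
    ConductionModel,
    EikonalSolver,
    edge_traversal_time,
    solve_eikonal,
    synthesize_vm_traces,
)


def _mesh_from_points(points, fibers_seed=0, anatomy_id="synthetic"):
    """Tet mesh from a point cloud via Delaunay, with random unit fibers."""
    tri = Delaunay(points)
    elems = tri.simplices.astype(np.int64)
    x = points[elems]
    vol = np.abs(np.linalg.det(x[:, 1:] - x[:, :1])) / 6.0
    elems = elems[vol > 1e-9]
    rng = np.random.default_rng(fibers_seed)
    f = rng.normal(size=(len(elems), 3))
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return VentricularMesh(
        nodes=points,
        elements=elems,
        endo_nodes=np.array([0]),
        epi_nodes=np.array([1]),
        base_nodes=np.array([2]),
        apex_node=0,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id=anatomy_id,
        fiber_dirs=f,
    )


def _chain_mesh(n=10):
    """Tets strung along the x axis sharing spine edges of length 1 mm."""
    spine = np.array([[k, 0.0, 0.0] for k in range(n + 1)])
    wing_a = np.array([[k + 0.5, 3.0, 0.0] for k in range(n)])
    wing_b = np.array([[k + 0.5, 0.0, 3.0] for k in range(n)])
    nodes = np.vstack([spine, wing_a, wing_b])
    elems = np.array(
        [[k, k + 1, n + 1 + k, 2 * n + 1 + k] for k in range(n)], dtype=np.int64
    )
    fibers = np.tile([1.0, 0.0, 0.0], (n, 1))
    return VentricularMesh(
        nodes=nodes,
        elements=elems,
        endo_nodes=np.array([0]),
        epi_nodes=np.array([1]),
        base_nodes=np.array([2]),
        apex_node=0,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id="chain",
        fiber_dirs=fibers,
    )


def _structured_slab(nx, ny, nz, h=2.0, jitter=0.3, seed=0):
    """Slab tet mesh via the hex-fan decomposition, with node jitter."""
    rng = np.random.default_rng(seed)
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    pts = np.array(
        [[i * h, j * h, k * h] for i in range(nx) for j in range(ny) for k in range(nz)], float
    )
    pts += rng.uniform(-jitter, jitter, pts.shape)
    fan = [(1, 2), (2, 3), (3, 7), (7, 4), (4, 5), (5, 1)]
    tets = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                v = [
                    idx[i, j, k],
                    idx[i, j + 1, k],
                    idx[i, j + 1, k + 1],
                    idx[i, j, k + 1],
                    idx[i + 1, j, k],
                    idx[i + 1, j + 1, k],
                    idx[i + 1, j + 1, k + 1],
                    idx[i + 1, j, k + 1],
                ]
                for a, b in fan:
                    tets.append((v[0], v[6], v[a], v[b]))
    elems = np.array(tets, dtype=np.int64)
    mesh = VentricularMesh(
        nodes=pts,
        elements=elems,
        endo_nodes=np.array([0]),
        epi_nodes=np.array([1]),
        base_nodes=np.array([2]),
        apex_node=0,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id="slab",
        fiber_dirs=np.tile([1.0, 0.0, 0.0], (len(elems), 1)),
    )
    return mesh, pts


class TestEdgeTraversalTime:
    def test_along_fiber(self):
        cm = ConductionModel(cv_long=1.0, cv_trans=0.5)
        t = edge_traversal_time([0, 0, 0], [10, 0, 0], [1, 0, 0], cm, 1.0)
        assert t == pytest.approx(10.0)

    def test_across_fiber(self):
        cm = ConductionModel(cv_long=1.0, cv_trans=0.5)
        t = edge_traversal_time([0, 0, 0], [0, 10, 0], [1, 0, 0], cm, 1.0)
        assert t == pytest.approx(20.0)

    def test_isotropy_limit(self):
        cm = ConductionModel(cv_long=0.7, cv_trans=0.7)
        for ang in (0.0, np.pi / 4, 1.1):
            d = np.array([np.cos(ang), np.sin(ang), 0.0]) * 10
            t = edge_traversal_time([0, 0, 0], d, [1, 0, 0], cm, 1.0)
            assert t == pytest.approx(10 / 0.7)

    def test_zero_multiplier_infinite(self):
        cm = ConductionModel(cv_long=1.0, cv_trans=0.5)
        assert edge_traversal_time([0, 0, 0], [1, 0, 0], [1, 0, 0], cm, 0.0) == np.inf


class TestSolveEikonal:
    def test_chain_arrival_times(self):
        mesh = _chain_mesh(10)
        cm = ConductionModel(cv_long=1.0, cv_trans=1.0)
        act = solve_eikonal(mesh, cm, [(0, 0.0)])
        for k in range(11):
            assert act.times[k] == pytest.approx(k, abs=1e-9)

    def test_two_sources_min_superposition(self):
        mesh = _chain_mesh(10)
        cm = ConductionModel(cv_long=1.0, cv_trans=1.0)
        a = solve_eikonal(mesh, cm, [(0, 0.0)])
        b = solve_eikonal(mesh, cm, [(10, 5.0)])
        ab = solve_eikonal(mesh, cm, [(0, 0.0), (10, 5.0)])
        assert np.allclose(ab.times, np.minimum(a.times, b.times))

    def test_all_sources_inexcitable_raises(self):
        mesh = _chain_mesh(4)
        cm = ConductionModel(cv_long=1.0, cv_trans=1.0, element_multiplier=np.zeros(4))
        with pytest.raises(ValueError, match="inexcitable"):
            solve_eikonal(mesh, cm, [(0, 0.0)])

    def test_matches_bellman_ford(self):
        """Dijkstra on the edge graph equals a hand-rolled Bellman-Ford."""
        rng = np.random.default_rng(42)
        for trial in range(3):
            pts = rng.uniform(0, 30, size=(120, 3))
            mesh = _mesh_from_points(pts, fibers_seed=trial)
            mult = rng.uniform(0.2, 1.0, mesh.n_elements)
            mult[rng.random(mesh.n_elements) < 0.1] = 0.0
            cm = ConductionModel(cv_long=0.6, cv_trans=0.24, element_multiplier=mult)
            src = int(rng.integers(mesh.n_nodes))
            act = solve_eikonal(mesh, cm, [(src, 0.0)])
            oracle = bellman_ford_oracle(mesh, cm, src)
            assert np.array_equal(act.times, oracle) or np.allclose(
                act.times, oracle, rtol=0, atol=1e-9, equal_nan=False
            )

    def test_cv_scaling_linearity(self, mesh_coarse):
        cm1 = ConductionModel(cv_long=0.6, cv_trans=0.24)
        cm2 = ConductionModel(cv_long=1.2, cv_trans=0.48)
        a = solve_eikonal(mesh_coarse, cm1, [(5, 0.0)]).times
        b = solve_eikonal(mesh_coarse, cm2, [(5, 0.0)]).times
        assert np.allclose(a, 2 * b)

    def test_relaxation_property(self, mesh_coarse, conduction):
        solver = EikonalSolver(mesh_coarse, conduction)
        act = solver.solve([(0, 0.0)])
        g = solver.edge_graph().tocoo()
        slack = act.times[g.col] - act.times[g.row] - g.data
        assert slack.max() <= 1e-9

    def test_graph_overestimates_continuum_on_slab(self):
        """Shortest-path arrival >= straight-line time, within 15% on a
        slab meshed with the same hex-fan decomposition as the ventricle."""
        mesh, pts = _structured_slab(16, 8, 4, h=2.0)
        v = 0.6
        cm = ConductionModel(cv_long=v, cv_trans=v)
        src = 0
        act = solve_eikonal(mesh, cm, [(src, 0.0)])
        ref = np.linalg.norm(pts - pts[src], axis=1) / v
        far = ref > 5.0 / v
        ratio = act.times[far] / ref[far]
        assert ratio.min() >= 1.0 - 1e-9  # never beats the straight line
        assert ratio.max() <= 1.15


def bellman_ford_oracle(mesh, cm, src):
    """Edge relaxation until fixpoint; weights recomputed per element edge."""
    n = mesh.n_nodes
    best_w = {}
    for e, tet in enumerate(mesh.elements):
        mult = cm.multipliers(mesh.n_elements)[e]
        fib = mesh.fiber_dirs[e]
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(tet[i]), int(tet[j])
                w = edge_traversal_time(mesh.nodes[a], mesh.nodes[b], fib, cm, mult)
                key = (min(a, b), max(a, b))
                if w < best_w.get(key, np.inf):
                    best_w[key] = w
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    changed = True
    while changed:
        changed = False
        for (a, b), w in best_w.items():
            if dist[a] + w < dist[b] - 1e-15:
                dist[b] = dist[a] + w
                changed = True
            if dist[b] + w < dist[a] - 1e-15:
                dist[a] = dist[b] + w
                changed = True
    return dist


class TestVmTraces:
    def test_template_evaluation(self):
        act = ActivationMap(times=np.array([0.0]), sources=[(0, 0.0)])
        tpl = APTemplate(resting=-85.0, plateau=20.0, upstroke=2.0, apd=280.0, repolarization=40.0)
        vm = synthesize_vm_traces(act, tpl, dt=1.0, duration=350.0)
        assert vm[0, 0] == -85.0
        assert vm[0, 2] == 20.0  # plateau reached after the upstroke
        assert vm[0, 279] == 20.0
        assert vm[0, 340] == -85.0

    def test_unreached_node_constant_resting(self):
        act = ActivationMap(times=np.array([0.0, np.inf]), sources=[(0, 0.0)])
        vm = synthesize_vm_traces(act, APTemplate(), dt=1.0, duration=350.0)
        assert np.all(vm[1] == -85.0)

    def test_time_shift_invariance(self):
        tpl = APTemplate()
        a = synthesize_vm_traces(ActivationMap(np.array([0.0]), []), tpl, 1.0, 400.0)
        b = synthesize_vm_traces(ActivationMap(np.array([25.0]), []), tpl, 1.0, 400.0)
        assert np.array_equal(a[0, :-25], b[0, 25:])

    def test_bounds_piecewise(self):
        act = ActivationMap(times=np.array([3.0, 17.0, np.inf]), sources=[])
        vm = synthesize_vm_traces(act, APTemplate(), dt=0.5, duration=400.0)
        assert vm.min() >= -85.0 and vm.max() <= 20.0

    def test_truncation_error(self):
        act = ActivationMap(times=np.array([100.0]), sources=[])
        with pytest.raises(ValueError, match="truncation"):
            synthesize_vm_traces(act, APTemplate(), dt=1.0, duration=300.0)


def test_conduction_model_validation():
    with pytest.raises(ValueError):
        ConductionModel(cv_long=0.2, cv_trans=0.4)
    with pytest.raises(ValueError):
        ConductionModel(element_multiplier=np.array([1.5]))
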