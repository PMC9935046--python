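"""Anisotropic eikonal activation on the mesh edge graph.

Excitation spread is modelled as first-arrival propagation: each mesh
edge is assigned a traversal time from its length and a direction-
dependent conduction velocity

    v(theta) = sqrt((cv_long cos theta)^2 + (cv_trans sin theta)^2),

where theta is the angle between the edge and the local fiber direction,
scaled by a per-element conduction multiplier (0 = inexcitable scar,
values in (0, 1) = slow conduction). Activation times are shortest
arrival times over this weighted graph (Dijkstra), which is exact on its
own metric and overestimates the continuum front arrival by the usual
metric-graph factor. Transmembrane traces are synthesized by shifting a
stereotyped upstroke-plateau-repolarization action-potential template to
each node's activation time.

Units: positions mm, velocities m/s, times ms (mm / (m/s) = ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .geometry import VentricularMesh

__all__ = [
    "ConductionModel",
    "ActivationMap",
    "APTemplate",
    "edge_traversal_time",
    "solve_eikonal",
    "synthesize_vm_traces",
    "EikonalSolver",
]


@dataclass(frozen=True)
class ConductionModel:
    """Conduction velocities (m/s) along/across fibers and per-element
    multipliers in [0, 1] (None means 1 everywhere; 0 = inexcitable)."""

    cv_long: float = 0.6
    cv_trans: float = 0.24
    element_multiplier: Optional[np.ndarray] = None

    def __post_init__(self):
        if not (self.cv_long >= self.cv_trans > 0):
            raise ValueError("require cv_long >= cv_trans > 0")
        if self.element_multiplier is not None:
            m = np.asarray(self.element_multiplier, dtype=float)
            if np.any((m < 0) | (m > 1)):
                raise ValueError("multipliers must lie in [0, 1]")
            object.__setattr__(self, "element_multiplier", m)

    def multipliers(self, n_elements: int) -> np.ndarray:
        if self.element_multiplier is None:
            return np.ones(n_elements)
        if len(self.element_multiplier) != n_elements:
            raise ValueError("multiplier length does not match element count")
        return self.element_multiplier


@dataclass
class ActivationMap:
    """Per-node activation times in ms; unreached nodes are +inf."""

    times: np.ndarray
    sources: list

    @property
    def reached(self) -> np.ndarray:
        return np.isfinite(self.times)


def edge_traversal_time(p_a, p_b, fiber, cm: ConductionModel, mult: float = 1.0) -> float:
    """Traversal time (ms) of a single edge; +inf if mult == 0."""
    if mult == 0.0:
        return float("inf")
    d = np.asarray(p_b, dtype=float) - np.asarray(p_a, dtype=float)
    length = np.linalg.norm(d)
    if length == 0:
        return 0.0
    f = np.asarray(fiber, dtype=float)
    cos_t = abs(float(d @ f) / (length * np.linalg.norm(f)))
    cos_t = min(cos_t, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    v = np.hypot(cm.cv_long * cos_t, cm.cv_trans * sin_t)
    return float(length / (mult * v))


class EikonalSolver:
    """Edge-graph eikonal solver bound to a mesh and conduction model.

    The per-(element, edge) anisotropic speeds depend only on the mesh
    and CVs and are precomputed once; the element multipliers enter the
    final per-edge speed as max over incident elements of
    (mult_e * v(theta_e)), so a single conductive incident element keeps
    an edge conducting at that element's speed.
    """

    def __init__(self, mesh: VentricularMesh, cm: ConductionModel):
        if mesh.fiber_dirs is None:
            raise ValueError("mesh has no fiber directions")
        self.mesh = mesh
        self.cm = cm
        elems = mesh.elements
        pairs_idx = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
        # (M*6, 2) node pairs, each tagged with its parent element
        pairs = np.sort(elems[:, pairs_idx], axis=2).reshape(-1, 2)
        parent = np.repeat(np.arange(len(elems)), 6)
        d = mesh.nodes[pairs[:, 1]] - mesh.nodes[pairs[:, 0]]
        length = np.linalg.norm(d, axis=1)
        fib = mesh.fiber_dirs[parent]
        with np.errstate(invalid="ignore"):
            cos_t = np.abs(np.einsum("ij,ij->i", d, fib)) / np.where(length > 0, length, 1.0)
        cos_t = np.clip(cos_t, 0.0, 1.0)
        sin_t = np.sqrt(1.0 - cos_t**2)
        speed = np.hypot(cm.cv_long * cos_t, cm.cv_trans * sin_t)

        self._edges, inverse = np.unique(pairs, axis=0, return_inverse=True)
        self._edge_inverse = inverse
        self._parent = parent
        self._pair_speed = speed
        self._pair_length = length
        edge_len = np.zeros(len(self._edges))
        edge_len[inverse] = length  # identical for all incident elements
        self._edge_length = edge_len
        self._graph_cache: Optional[csr_matrix] = None

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def edge_graph(self) -> csr_matrix:
        """Symmetric sparse matrix of edge traversal times (ms)."""
        if self._graph_cache is None:
            mult = self.cm.multipliers(self.mesh.n_elements)
            eff = mult[self._parent] * self._pair_speed
            best = np.zeros(len(self._edges))
            np.maximum.at(best, self._edge_inverse, eff)
            keep = best > 0
            w = self._edge_length[keep] / best[keep]
            i, j = self._edges[keep, 0], self._edges[keep, 1]
            n = self.n_nodes
            g = coo_matrix(
                (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(n, n),
            )
            self._graph_cache = g.tocsr()
        return self._graph_cache

    def node_excitable(self) -> np.ndarray:
        """Nodes with at least one conductive incident element."""
        mult = self.cm.multipliers(self.mesh.n_elements)
        ok = np.zeros(self.n_nodes, dtype=bool)
        conductive = mult > 0
        ok[np.unique(self.mesh.elements[conductive])] = True
        return ok

    def solve(self, sources: Sequence[tuple[int, float]]) -> ActivationMap:
        """Arrival times from a set of (node, offset ms) sources."""
        if len(sources) == 0:
            raise ValueError("at least one source required")
        excitable = self.node_excitable()
        src = [(int(n), float(t)) for n, t in sources]
        if not any(excitable[n] for n, _ in src):
            raise ValueError("all sources inexcitable")
        g = self.edge_graph()
        n = self.n_nodes
        # virtual super-source with offset-weighted directed edges
        rows = np.full(len(src), n)
        cols = np.array([s[0] for s in src])
        # zero offsets become tiny positive weights: sparse graphs treat
        # explicit zeros as absent edges
        offs = np.maximum(np.array([s[1] for s in src]), 1e-300)
        gcoo = g.tocoo()
        aug = coo_matrix(
            (
                np.concatenate([gcoo.data, offs]),
                (np.concatenate([gcoo.row, rows]), np.concatenate([gcoo.col, cols])),
            ),
            shape=(n + 1, n + 1),
        ).tocsr()
        times = dijkstra(aug, directed=True, indices=n)[:n]
        times[times < 1e-200] = 0.0
        return ActivationMap(times=times, sources=src)

    def solve_many(self, source_nodes: np.ndarray) -> np.ndarray:
        """(S, N) arrival-time matrix for S independent single-node sources."""
        g = self.edge_graph()
        return dijkstra(g, directed=False, indices=np.asarray(source_nodes, dtype=int))


def solve_eikonal(
    mesh: VentricularMesh, cm: ConductionModel, sources: Sequence[tuple[int, float]]
) -> ActivationMap:
    """Shortest-arrival activation map from (node, offset ms) sources."""
    return EikonalSolver(mesh, cm).solve(sources)


# ---------------------------------------------------------------------------
# action-potential template


@dataclass(frozen=True)
class APTemplate:
    """Stereotyped transmembrane action potential.

    resting/plateau in mV; upstroke, apd (activation to end of plateau)
    and repolarization durations in ms. The trace is piecewise linear:
    resting before activation, linear upstroke, plateau until apd, then a
    linear return to resting over the repolarization duration.
    """

    resting: float = -85.0
    plateau: float = 20.0
    upstroke: float = 2.0
    apd: float = 280.0
    repolarization: float = 40.0

    def __post_init__(self):
        if not self.plateau > self.resting:
            raise ValueError("plateau must exceed resting potential")
        if min(self.upstroke, self.apd, self.repolarization) <= 0:
            raise ValueError("durations must be positive")
        if self.upstroke >= self.apd:
            raise ValueError("upstroke must be shorter than apd")

    def waveform_knots(self) -> tuple[np.ndarray, np.ndarray]:
        xp = np.array([0.0, self.upstroke, self.apd, self.apd + self.repolarization])
        fp = np.array([self.resting, self.plateau, self.plateau, self.resting])
        return xp, fp


def synthesize_vm_traces(
    act: ActivationMap, tpl: APTemplate, dt: float = 1.0, duration: float = 350.0
) -> np.ndarray:
    """Per-node transmembrane potential (N, T) in mV on a fixed time grid.

    Node i's trace is the template shifted by its activation time;
    unreached nodes stay at the resting potential.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    finite = act.times[np.isfinite(act.times)]
    max_act = finite.max() if finite.size else 0.0
    if duration < max_act + tpl.apd:
        raise ValueError("truncation error: duration shorter than activation + apd")
    t = np.arange(0.0, duration, dt)
    phase = t[None, :] - np.where(np.isfinite(act.times), act.times, np.inf)[:, None]
    xp, fp = tpl.waveform_knots()
    vm = np.interp(phase.ravel(), xp, fp, left=tpl.resting, right=tpl.resting)
    return vm.reshape(len(act.times), len(t))
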