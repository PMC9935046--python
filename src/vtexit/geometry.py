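"""Parametric thick-walled ventricular anatomy.

The ventricle is modelled as a truncated prolate-ellipsoid shell: two
concentric ellipsoids of revolution (endocardium and epicardium) truncated
by a flat base plane. The shell is meshed with a structured tetrahedral
grid (transmural layers x longitudinal rings x circumferential sectors,
each hexahedral cell split into six tetrahedra with conforming diagonals),
myofiber directions follow a rule-based linear transmural rotation of the
local circumferential direction, and ECG / implanted-device electrodes are
placed on geometric templates around the anatomy.

Coordinate convention: mm, right-handed, long axis = +z with the apex at
the origin and the base plane at z = truncation_fraction * lv_long_axis.
The septal reference direction (phi = 0, mid-anteroseptum) is +x and the
anterior direction is +y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GeometryError",
    "GeometryParams",
    "ShellGeometry",
    "VentricularMesh",
    "ElectrodeSet",
    "build_ventricle_mesh",
    "assign_fibers",
    "place_surface_electrodes",
    "place_device_electrodes",
    "perturb_geometry_params",
    "SURFACE_ELECTRODE_NAMES",
    "DEVICE_ELECTRODE_NAMES",
]

SURFACE_ELECTRODE_NAMES = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")
DEVICE_ELECTRODE_NAMES = (
    "CAN",
    "SVC_COIL",
    "RV_COIL",
    "RV_TIP",
    "RV_RING",
    "LV1",
    "LV2",
    "LV3",
    "LV4",
)


class GeometryError(ValueError):
    """Raised for invalid geometric parameters or placements."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the truncated prolate-ellipsoid ventricle.

    lv_long_axis is the full long-axis length (mm) of the endocardial
    ellipsoid; lv_endo_short_axis is its semi-short axis (mm);
    wall_thickness is the (radial) shell thickness (mm);
    truncation_fraction sets the base plane at that fraction of the long
    axis above the apex. Fiber angles are the helix angles (degrees) on
    the endo- and epicardial surfaces. The seed controls a small interior
    meshing jitter only.
    """

    lv_long_axis: float = 90.0
    lv_endo_short_axis: float = 25.0
    wall_thickness: float = 10.0
    truncation_fraction: float = 0.7
    target_edge_length: float = 3.0
    fiber_angle_endo: float = 60.0
    fiber_angle_epi: float = -60.0
    seed: int = 0

    def validate(self) -> None:
        if self.wall_thickness <= 0:
            raise GeometryError("wall_thickness must be positive")
        if self.target_edge_length <= 0:
            raise GeometryError("target_edge_length must be positive")
        if self.lv_endo_short_axis <= 0 or self.lv_long_axis <= 0:
            raise GeometryError("axes must be positive")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise GeometryError("truncation_fraction must lie in (0, 1)")
        if self.wall_thickness >= self.lv_endo_short_axis:
            raise GeometryError("self-intersecting wall: wall_thickness >= endo short axis")
        if self.target_edge_length > self.wall_thickness:
            raise GeometryError("unresolvable wall: target_edge_length > wall_thickness")


@dataclass(frozen=True)
class ShellGeometry:
    """Analytic description of the concentric truncated ellipsoid shell.

    Both ellipsoids share the center (0, 0, c); the endocardial one has
    semi-axes (a, a, c), the epicardial one (a + w, a + w, c + w). The
    myocardium occupies the region between them below the base plane
    z = z_base.
    """

    a: float
    c: float
    wall: float
    z_base: float

    def level(self, points: np.ndarray, t: float | np.ndarray) -> np.ndarray:
        """Implicit ellipsoid value at transmural fraction t (0=endo, 1=epi)."""
        p = np.atleast_2d(points)
        at = self.a + t * self.wall
        ct = self.c + t * self.wall
        return (p[:, 0] ** 2 + p[:, 1] ** 2) / at**2 + (p[:, 2] - self.c) ** 2 / ct**2

    def ray_radius(self, theta: np.ndarray, t: float | np.ndarray) -> np.ndarray:
        """Distance from the shared center to the t-family ellipsoid along
        the direction at polar angle theta (0 = +z, pi = apex)."""
        at = self.a + t * self.wall
        ct = self.c + t * self.wall
        return 1.0 / np.sqrt((np.sin(theta) / at) ** 2 + (np.cos(theta) / ct) ** 2)

    def layer_radius(self, theta, u) -> np.ndarray:
        """Radius of the transmural-fraction-u layer (radial interpolation)."""
        return (1 - u) * self.ray_radius(theta, 0.0) + u * self.ray_radius(theta, 1.0)

    def base_theta(self, u, n_iter: int = 80) -> np.ndarray:
        """Polar angle where the fraction-u layer meets the base plane."""
        u = np.asarray(u, dtype=float)
        lo = np.full(u.shape, 1e-6)
        hi = np.full(u.shape, np.pi / 2)
        target = self.z_base - self.c
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            above = self.layer_radius(mid, u) * np.cos(mid) > target
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
        return 0.5 * (lo + hi)

    def transmural_depth(self, points: np.ndarray, n_iter: int = 60) -> np.ndarray:
        """Normalized wall depth in [0, 1] by bisection on the shell family.

        Points outside the shell are returned extrapolated slightly
        (<0 inside the cavity, >1 outside the epicardium) up to the
        bisection bracket [-0.1, 1.1].
        """
        p = np.atleast_2d(points).astype(float)
        lo = np.full(p.shape[0], -0.1)
        hi = np.full(p.shape[0], 1.1)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            f = self.level(p, mid) - 1.0
            inside = f < 0.0  # point inside the mid-ellipsoid -> depth smaller
            hi = np.where(inside, mid, hi)
            lo = np.where(inside, lo, mid)
        return 0.5 * (lo + hi)

    def in_myocardium(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        p = np.atleast_2d(points)
        f_endo = self.level(p, 0.0)
        f_epi = self.level(p, 1.0)
        below_base = p[:, 2] <= self.z_base + tol
        return (f_endo >= 1.0 - tol) & (f_epi <= 1.0 + tol) & below_base


@dataclass
class VentricularMesh:
    """Volumetric tetrahedral mesh of a thick-walled ventricle.

    nodes: (N, 3) positions in mm; elements: (M, 4) 0-based tet
    connectivity; fiber_dirs: (M, 3) unit vectors (or None before fiber
    assignment); surface labels are node-index arrays; apex_node is the
    single designated apical node (endocardial apex pole);
    septal_ref_dir is the unit phi = 0 reference in the base plane.
    """

    nodes: np.ndarray
    elements: np.ndarray
    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    base_nodes: np.ndarray
    apex_node: int
    septal_ref_dir: np.ndarray
    anatomy_id: str = "anat"
    fiber_dirs: Optional[np.ndarray] = None
    shell: Optional[ShellGeometry] = None
    target_edge_length: float = 3.0
    _volumes: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_tets(self) -> np.ndarray:
        return self.nodes[self.elements]  # (M, 4, 3)

    def element_centroids(self) -> np.ndarray:
        return self.element_tets().mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        if self._volumes is None:
            x = self.element_tets()
            j = x[:, 1:] - x[:, :1]
            self._volumes = np.abs(np.linalg.det(j)) / 6.0
        return self._volumes

    def edge_list(self) -> np.ndarray:
        """Unique undirected node-index edges of the tetrahedral mesh."""
        pairs = self.elements[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def validate(self) -> None:
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise GeometryError("element index out of range")
        if np.any(self.element_volumes() <= 0):
            raise GeometryError("degenerate (zero-volume) element")
        if self.fiber_dirs is not None:
            norms = np.linalg.norm(self.fiber_dirs, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise GeometryError("fiber directions not unit-norm")
        if len(np.intersect1d(self.endo_nodes, self.epi_nodes)) > 0:
            raise GeometryError("endo and epi label sets overlap")
        if len(self.endo_nodes) == 0 or len(self.epi_nodes) == 0:
            raise GeometryError("empty surface label set")


@dataclass
class ElectrodeSet:
    """Named electrode positions (mm). kind is 'surface' or 'device'."""

    names: list
    positions: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != self.positions.shape[0]:
            raise GeometryError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise GeometryError("electrode names must be unique")
        expected = {
            "surface": set(SURFACE_ELECTRODE_NAMES),
            "device": set(DEVICE_ELECTRODE_NAMES),
        }.get(self.kind)
        if expected is None:
            raise GeometryError(f"unknown electrode kind {self.kind!r}")
        if set(self.names) != expected:
            raise GeometryError(f"{self.kind} electrode inventory must be {sorted(expected)}")
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("electrode positions must be finite")

    def position_of(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({n: list(map(float, p)) for n, p in zip(self.names, self.positions)}, fh, indent=1)

    @classmethod
    def from_json(cls, path, kind: str) -> "ElectrodeSet":
        with open(path) as fh:
            d = json.load(fh)
        names = list(d.keys())
        return cls(names=names, positions=np.array([d[n] for n in names]), kind=kind)


# ---------------------------------------------------------------------------
# mesh construction


def _meridian_theta_range(a: float, c: float, z_base: float) -> tuple[float, float]:
    # theta parametrizes (a sin t, ., c + c cos t); apex at t = pi
    cos_b = np.clip(z_base / c - 1.0, -1.0, 1.0)
    return float(np.arccos(cos_b)), float(np.pi)


def _surface_point(a: float, c: float, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.stack([a * st * np.cos(phi), a * st * np.sin(phi), c + c * ct], axis=-1)


def build_ventricle_mesh(params: GeometryParams, anatomy_id: str = "anat") -> VentricularMesh:
    """Mesh the truncated prolate-ellipsoid shell with tetrahedra.

    The grid resolution follows params.target_edge_length; node positions
    are deterministic for fixed params (the seed only jitters interior
    nodes by 5% of the edge length, which regularizes element shapes).
    Fibers are assigned with the params' endo/epi helix angles.
    """
    params.validate()
    a = params.lv_endo_short_axis
    c = params.lv_long_axis / 2.0
    w = params.wall_thickness
    z_base = params.truncation_fraction * params.lv_long_axis
    if z_base >= params.lv_long_axis:
        raise GeometryError("truncation above the endocardial apex of the base")
    shell = ShellGeometry(a=a, c=c, wall=w, z_base=z_base)
    h = params.target_edge_length

    n_layers = max(2, int(round(w / h)) + 1)

    # Nodes are placed along rays from the shared ellipsoid center: the
    # layer at transmural fraction u sits at radius
    # (1-u) r_endo(theta) + u r_epi(theta), which tiles the shell exactly
    # (concentric nested surfaces). theta is the polar angle from +z at
    # the center (apex at theta = pi); each layer starts at the angle
    # where it meets the flat base plane.
    # resolution from the outer (epicardial) surface so no spacing
    # exceeds the target edge length
    th0_epi = float(shell.base_theta(1.0))
    tt = np.linspace(th0_epi, np.pi, 512)
    rr = shell.layer_radius(tt, 1.0)
    pts = np.stack([rr * np.sin(tt), np.zeros_like(tt), c + rr * np.cos(tt)], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    n_s = max(4, int(np.ceil(arc[-1] / h)) + 1)
    # samples uniform in epicardial arc length, as a normalized parameter
    s_grid = np.interp(np.linspace(0, arc[-1], n_s), arc, (tt - th0_epi) / (np.pi - th0_epi))
    n_phi = max(8, int(round(2 * np.pi * (a + w) / h)))
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    phis = np.where(phis > np.pi, phis - 2 * np.pi, phis)  # phi = 0 on +x

    rng = np.random.default_rng(params.seed)

    nodes = []
    ring_index = np.full((n_layers, n_s - 1, n_phi), -1, dtype=np.int64)
    pole_index = np.full(n_layers, -1, dtype=np.int64)
    for i in range(n_layers):
        u = i / (n_layers - 1)
        th0 = float(shell.base_theta(u))
        for k in range(n_s):
            if k == n_s - 1:  # apical pole: single node per layer
                pole_index[i] = len(nodes)
                nodes.append(np.array([0.0, 0.0, (1 - u) * 0.0 + u * (-w)]))
                continue
            theta = th0 + s_grid[k] * (np.pi - th0)
            r = float(shell.layer_radius(theta, u))
            d = np.stack(
                [np.sin(theta) * np.cos(phis), np.sin(theta) * np.sin(phis), np.full(n_phi, np.cos(theta))],
                axis=1,
            )
            pos = np.array([0.0, 0.0, c]) + r * d
            if 0 < i < n_layers - 1 and 0 < k:
                pos = pos + rng.uniform(-0.05 * h, 0.05 * h, pos.shape)
            ring_index[i, k] = np.arange(len(nodes), len(nodes) + n_phi)
            nodes.extend(pos)
    nodes = np.asarray(nodes, dtype=float)

    # 6-tet decomposition of each hexahedral cell, fan around diagonal v0-v6;
    # pole cells reuse the same rule with v2 = v3 and v6 = v7 collapsed.
    tets = []
    fan = [(1, 2), (2, 3), (3, 7), (7, 4), (4, 5), (5, 1)]
    for i in range(n_layers - 1):
        for k in range(n_s - 1):
            for j in range(n_phi):
                j1 = (j + 1) % n_phi
                if k < n_s - 2:
                    v = [
                        ring_index[i, k, j],
                        ring_index[i, k, j1],
                        ring_index[i, k + 1, j1],
                        ring_index[i, k + 1, j],
                        ring_index[i + 1, k, j],
                        ring_index[i + 1, k, j1],
                        ring_index[i + 1, k + 1, j1],
                        ring_index[i + 1, k + 1, j],
                    ]
                else:  # ring adjacent to the pole
                    v = [
                        ring_index[i, k, j],
                        ring_index[i, k, j1],
                        pole_index[i],
                        pole_index[i],
                        ring_index[i + 1, k, j],
                        ring_index[i + 1, k, j1],
                        pole_index[i + 1],
                        pole_index[i + 1],
                    ]
                for e0, e1 in fan:
                    tet = (v[0], v[6], v[e0], v[e1])
                    if len(set(tet)) == 4:
                        tets.append(tet)
    elements = np.asarray(tets, dtype=np.int64)

    # orient all tets positively
    x = nodes[elements]
    det = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = det < 0
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]

    endo = np.concatenate([ring_index[0].ravel(), [pole_index[0]]])
    epi = np.concatenate([ring_index[-1].ravel(), [pole_index[-1]]])
    base = ring_index[:, 0].ravel()
    apex_node = int(pole_index[0])  # endocardial apex pole

    mesh = VentricularMesh(
        nodes=nodes,
        elements=elements,
        endo_nodes=np.sort(endo),
        epi_nodes=np.sort(epi),
        base_nodes=np.sort(base),
        apex_node=apex_node,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id=anatomy_id,
        shell=shell,
        target_edge_length=h,
    )
    mesh.validate()
    return assign_fibers(mesh, params.fiber_angle_endo, params.fiber_angle_epi)


# ---------------------------------------------------------------------------
# fibers


def _transmural_frame(mesh: VentricularMesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local outward transmural axis and circumferential direction at points."""
    if mesh.shell is not None:
        sh = mesh.shell
        d = mesh.shell.transmural_depth(points)
        at = sh.a + d * sh.wall
        ct = sh.c + d * sh.wall
        grad = np.stack(
            [
                2 * points[:, 0] / at**2,
                2 * points[:, 1] / at**2,
                2 * (points[:, 2] - sh.c) / ct**2,
            ],
            axis=1,
        )
    else:
        # fallback: radial direction from the long axis, tilted by nothing
        grad = points.copy()
        grad[:, 2] = 0.0
    n = np.linalg.norm(grad, axis=1, keepdims=True)
    n[n == 0] = 1.0
    et = grad / n
    zhat = np.array([0.0, 0.0, 1.0])
    ec = np.cross(np.broadcast_to(zhat, et.shape), et)
    nc = np.linalg.norm(ec, axis=1, keepdims=True)
    degenerate = nc[:, 0] < 1e-8
    if np.any(degenerate):
        alt = np.cross(np.broadcast_to(np.array([1.0, 0.0, 0.0]), et.shape), et)
        ec[degenerate] = alt[degenerate]
        nc = np.linalg.norm(ec, axis=1, keepdims=True)
    ec = ec / nc
    return et, ec


def transmural_depth_of_points(mesh: VentricularMesh, points: np.ndarray) -> np.ndarray:
    """Normalized wall depth of arbitrary points (0 endo, 1 epi)."""
    points = np.atleast_2d(points)
    if mesh.shell is not None:
        return mesh.shell.transmural_depth(points)
    from scipy.spatial import cKDTree

    d_endo = cKDTree(mesh.nodes[mesh.endo_nodes]).query(points)[0]
    d_epi = cKDTree(mesh.nodes[mesh.epi_nodes]).query(points)[0]
    tot = d_endo + d_epi
    tot[tot == 0] = 1.0
    return d_endo / tot


def assign_fibers(mesh: VentricularMesh, angle_endo: float, angle_epi: float) -> VentricularMesh:
    """Rule-based fibers: rotate the local circumferential direction about
    the transmural axis by a helix angle linear in normalized wall depth."""
    cent = mesh.element_centroids()
    depth = transmural_depth_of_points(mesh, cent)
    if np.any((depth < -0.05) | (depth > 1.05)):
        raise GeometryError("labelling error: element centroid outside the wall")
    depth = np.clip(depth, 0.0, 1.0)
    et, ec = _transmural_frame(mesh, cent)
    ang = np.deg2rad(angle_endo + depth * (angle_epi - angle_endo))[:, None]
    # Rodrigues rotation of ec about et (ec is perpendicular to et)
    fibers = np.cos(ang) * ec + np.sin(ang) * np.cross(et, ec)
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    out = replace(mesh, fiber_dirs=fibers)
    out._volumes = mesh._volumes
    return out


def fiber_helix_angles(mesh: VentricularMesh) -> np.ndarray:
    """Recompute per-element helix angles (degrees) from stored fibers."""
    if mesh.fiber_dirs is None:
        raise GeometryError("mesh has no fibers")
    cent = mesh.element_centroids()
    et, ec = _transmural_frame(mesh, cent)
    el = np.cross(et, ec)
    return np.rad2deg(np.arctan2(np.sum(mesh.fiber_dirs * el, axis=1), np.sum(mesh.fiber_dirs * ec, axis=1)))


# ---------------------------------------------------------------------------
# electrodes

# unit template directions (scaled by torso_scale); anterior = +y, septum = +x
_SURFACE_TEMPLATE = {
    "RA": (0.72, 0.10, 1.05),
    "LA": (-0.72, 0.10, 1.05),
    "LL": (-0.40, 0.05, -1.10),
    "V1": (0.18, 0.82, 0.50),
    "V2": (0.02, 0.88, 0.48),
    "V3": (-0.16, 0.90, 0.42),
    "V4": (-0.34, 0.88, 0.35),
    "V5": (-0.52, 0.80, 0.32),
    "V6": (-0.68, 0.62, 0.30),
}


def place_surface_electrodes(
    mesh: VentricularMesh,
    torso_scale: float = 120.0,
    jitter_mm: float = 0.0,
    seed: Optional[int] = None,
) -> ElectrodeSet:
    """Place the 9 measurement electrodes (limb RA/LA/LL + precordial
    V1..V6) on a virtual torso of radius torso_scale around the mesh."""
    max_radius = float(np.linalg.norm(mesh.nodes, axis=1).max())
    if torso_scale <= max_radius:
        raise GeometryError("placement error: torso_scale does not enclose the mesh")
    names = list(SURFACE_ELECTRODE_NAMES)
    pos = torso_scale * np.array([_SURFACE_TEMPLATE[n] for n in names])
    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.uniform(-jitter_mm, jitter_mm, pos.shape)
    _check_outside(mesh, pos, "surface electrode")
    return ElectrodeSet(names=names, positions=pos, kind="surface")


def _check_outside(mesh: VentricularMesh, pos: np.ndarray, what: str) -> None:
    if mesh.shell is not None:
        inside = mesh.shell.in_myocardium(pos)
        if np.any(inside):
            raise GeometryError(f"placement error: {what} inside the myocardium")


def _epi_meridian_arc_points(shell: ShellGeometry, phi: float, z_start: float, spacing: float, n: int) -> np.ndarray:
    """Points on the epicardial meridian at azimuth phi, walked apically
    from height z_start with the given arc spacing, offset 1 mm outward."""
    a, c = shell.a + shell.wall, shell.c + shell.wall  # epi semi-axes, center z = shell.c
    th0 = float(np.arccos(np.clip((z_start - shell.c) / c, -1, 1)))
    tt = np.linspace(th0, np.pi, 1024)
    st, ct = np.sin(tt), np.cos(tt)
    pts = np.stack([a * st * np.cos(phi), a * st * np.sin(phi), shell.c + c * ct], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    targets = spacing * np.arange(n)
    out = np.stack([np.interp(targets, arc, pts[:, k]) for k in range(3)], axis=1)
    # offset outward along the surface normal for a singularity margin
    grad = np.stack([2 * out[:, 0] / a**2, 2 * out[:, 1] / a**2, 2 * (out[:, 2] - shell.c) / c**2], axis=1)
    grad /= np.linalg.norm(grad, axis=1, keepdims=True)
    return out + 1.0 * grad


def place_device_electrodes(mesh: VentricularMesh) -> ElectrodeSet:
    """Place a generic implanted device: left-pectoral can, dual-coil RV
    lead (tip/ring/coil in the cavity along the septal side, SVC coil
    superior) and a quadripolar LV lead on the lateral epicardium with
    ~10 mm electrode spacing. Deterministic for a fixed mesh."""
    if mesh.shell is None:
        raise GeometryError("device placement requires shell geometry metadata")
    sh = mesh.shell
    a, zb, L = sh.a, sh.z_base, 2 * sh.c
    positions = {
        "RV_TIP": np.array([0.08 * a, 0.0, 0.03 * zb]),
        "RV_RING": np.array([0.15 * a, 0.0, 0.19 * zb]),
        "RV_COIL": np.array([0.12 * a, 0.0, 0.48 * zb]),
        "SVC_COIL": np.array([0.30 * a, 0.0, zb + 0.30 * L]),
        "CAN": np.array([-1.8 * a, 1.6 * a, zb + 0.45 * L]),
    }
    lv = _epi_meridian_arc_points(sh, np.pi, z_start=0.45 * zb, spacing=10.0, n=4)
    for i in range(4):
        positions[f"LV{i + 1}"] = lv[i]
    names = list(DEVICE_ELECTRODE_NAMES)
    pos = np.array([positions[n] for n in names])
    _check_outside(mesh, pos, "device electrode")
    return ElectrodeSet(names=names, positions=pos, kind="device")


# ---------------------------------------------------------------------------
# virtual cohorts


def perturb_geometry_params(base: GeometryParams, n: int, seed: int, rel: float = 0.10) -> list[GeometryParams]:
    """n geometry variants with axes/wall perturbed uniformly by +-rel.

    The first variant is the unperturbed base anatomy; this emulates a
    cohort of virtual patients with distinct (but comparable) anatomies.
    """
    rng = np.random.default_rng(seed)
    out = [replace(base, seed=int(base.seed))]
    for i in range(1, n):
        f = rng.uniform(1 - rel, 1 + rel, 3)
        out.append(
            replace(
                base,
                lv_long_axis=base.lv_long_axis * f[0],
                lv_endo_short_axis=base.lv_endo_short_axis * f[1],
                wall_thickness=base.wall_thickness * f[2],
                seed=int(base.seed + i),
            )
        )
    return out


def analytic_shell_volume(params: GeometryParams) -> float:
    """Closed-form volume (mm^3) of the truncated concentric-ellipsoid shell.

    Integral of pi * r(z)^2 between the apex of each ellipsoid and the
    base plane; the shell volume is the epicardial minus endocardial
    truncated volumes.
    """
    a = params.lv_endo_short_axis
    c = params.lv_long_axis / 2.0
    w = params.wall_thickness
    zb = params.truncation_fraction * params.lv_long_axis

    def trunc_vol(A: float, C: float, z0: float, z1: float) -> float:
        # integral of pi A^2 (1 - (z - C_center)^2 / C^2) dz, center at z=c
        def F(z: float) -> float:
            return z - (z - c) ** 3 / (3 * C**2)

        return np.pi * A**2 * (F(z1) - F(z0))

    v_endo = trunc_vol(a, c, 0.0, zb)
    v_epi = trunc_vol(a + w, c + w, -w, zb)
    return float(v_epi - v_endo)
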