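"""Universal ventricular coordinates (UVC) on the idealized ventricle.

Any myocardial point is located by the triple (z, rho, phi):

* ``z`` — apicobasal coordinate in [0, 1]: 0 at the apex node, 1 on the
  base plane (normalized long-axis position).
* ``rho`` — transmural coordinate in [0, 1]: 0 on the endocardium, 1 on
  the epicardium (normalized wall depth).
* ``phi`` — rotational coordinate in (-pi, pi], the signed azimuth about
  the long axis measured from the septal reference direction (phi = 0 at
  the mid-anteroseptum, positive toward the anterior wall).

On the parametric ellipsoidal anatomy the coordinates have closed-form
surrogates (long-axis fraction, implicit-shell wall depth, azimuth) with
the same semantics as PDE-based constructions on patient meshes. The
module also assigns standard 17-AHA segments from (z, phi) and defines
the localization-error metric (Euclidean distance in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VentricularMesh, transmural_depth_of_points

__all__ = [
    "UVCPoint",
    "UVCField",
    "ErrorSummary",
    "compute_uvc",
    "uvc_to_point",
    "uvc_nearest_node",
    "aha_segment_of",
    "segment_center",
    "ring_of_segment",
    "localization_error",
    "wrap_angle",
    "DEFAULT_UVC_WEIGHTS",
]

# weights of the UVC nearest-node metric: a half-turn in phi counts as 1,
# matching the unit span of z and rho
DEFAULT_UVC_WEIGHTS = (1.0, 1.0, 1.0 / np.pi**2)


def wrap_angle(phi):
    """Wrap angles to (-pi, pi]."""
    out = np.asarray((np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)
    out = np.where(np.isclose(out, -np.pi), np.pi, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class UVCPoint:
    """A (z, rho, phi) coordinate triple."""

    z: float
    rho: float
    phi: float

    def __post_init__(self):
        if not (0.0 <= self.z <= 1.0 and 0.0 <= self.rho <= 1.0):
            raise ValueError(f"UVC out of range: z={self.z}, rho={self.rho}")
        object.__setattr__(self, "phi", float(wrap_angle(self.phi)))

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.rho, self.phi])


@dataclass
class UVCField:
    """Per-node UVC arrays aligned with a VentricularMesh."""

    z: np.ndarray
    rho: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return len(self.z)

    def point(self, node: int) -> UVCPoint:
        return UVCPoint(float(self.z[node]), float(self.rho[node]), float(self.phi[node]))

    def as_array(self) -> np.ndarray:
        return np.stack([self.z, self.rho, self.phi], axis=1)


def compute_uvc(mesh: VentricularMesh) -> UVCField:
    """Compute UVC for every mesh node.

    Boundary conditions hold exactly on labelled nodes: z=0 at the apex
    node, z=1 on the base, rho=0 on the endocardium, rho=1 on the
    epicardium.
    """
    if len(mesh.base_nodes) == 0:
        raise ValueError("labelling error: mesh has no base label")
    p = mesh.nodes

    rho = np.clip(transmural_depth_of_points(mesh, p), 0.0, 1.0)
    rho[mesh.endo_nodes] = 0.0
    rho[mesh.epi_nodes] = 1.0

    if mesh.shell is not None:
        # apicobasal position as the normalized polar-angle fraction along
        # the node's own transmural layer, 1 at the base plane, 0 at the
        # apical pole; this keeps the apex cap non-degenerate (points
        # below the apex node still get distinct small z)
        sh = mesh.shell
        v = p - np.array([0.0, 0.0, sh.c])
        theta = np.arctan2(np.hypot(v[:, 0], v[:, 1]), v[:, 2])
        thb = sh.base_theta(rho)
        z = 1.0 - (theta - thb) / (np.pi - thb)
    else:
        z_apex = p[mesh.apex_node, 2]
        z_base = float(np.mean(p[mesh.base_nodes, 2]))
        if z_base <= z_apex:
            raise ValueError("labelling error: base not above apex")
        z = (p[:, 2] - z_apex) / (z_base - z_apex)
    z = np.clip(z, 0.0, 1.0)
    z[mesh.base_nodes] = 1.0
    z[mesh.apex_node] = 0.0

    ref = mesh.septal_ref_dir[:2]
    ref = ref / np.linalg.norm(ref)
    perp = np.array([-ref[1], ref[0]])  # +90 deg, toward the anterior wall
    phi = wrap_angle(np.arctan2(p[:, :2] @ perp, p[:, :2] @ ref))
    return UVCField(z=z, rho=rho, phi=np.asarray(phi, dtype=float))


def uvc_nearest_node(
    field: UVCField,
    q: UVCPoint,
    weights=DEFAULT_UVC_WEIGHTS,
    mask: np.ndarray | None = None,
) -> int:
    """Index of the node minimizing the weighted UVC distance to q.

    Ties break to the lowest node index. ``mask`` optionally restricts
    the candidate set (boolean per node).
    """
    wz, wr, wp = weights
    d2 = (
        wz * (field.z - q.z) ** 2
        + wr * (field.rho - q.rho) ** 2
        + wp * np.asarray(wrap_angle(field.phi - q.phi)) ** 2
    )
    if mask is not None:
        d2 = np.where(mask, d2, np.inf)
        if not np.any(mask):
            raise ValueError("empty candidate set")
    return int(np.argmin(d2))


def uvc_to_point(mesh: VentricularMesh, field: UVCField, q: UVCPoint) -> np.ndarray:
    """Cartesian position (mm) of the mesh node nearest to q in UVC space."""
    if mesh.n_nodes == 0:
        raise ValueError("empty mesh")
    return mesh.nodes[uvc_nearest_node(field, q)].copy()


# ---------------------------------------------------------------------------
# 17-AHA segments
#
# z ring cuts: apex cap z < 0.2 -> 17; apical 0.2..0.45 (quadrants 13-16);
# mid 0.45..0.7 (sextants 7-12); basal 0.7..1 (sextants 1-6). The phi
# sectors are anchored so phi = 0 is mid-anteroseptal (segment 2/8), with
# positive phi running anterior -> lateral -> inferior -> septal.

_SEXTANT_SEGMENTS = (2, 1, 6, 5, 4, 3)  # from phi = -30 deg, steps of 60 deg
_QUADRANT_SEGMENTS = (14, 13, 16, 15)  # from phi = -45 deg, steps of 90 deg


def aha_segment_of(q) -> int | np.ndarray:
    """Standard 17-AHA segment of a UVC point (or arrays z, phi)."""
    if isinstance(q, UVCPoint):
        z, phi = np.asarray([q.z]), np.asarray([q.phi])
        scalar = True
    else:
        z, phi = np.asarray(q[0], dtype=float), np.asarray(q[1], dtype=float)
        scalar = z.ndim == 0
        z, phi = np.atleast_1d(z), np.atleast_1d(phi)
    if np.any((z < 0) | (z > 1)):
        raise ValueError("z out of range [0, 1]")
    phi = np.asarray(wrap_angle(phi))
    seg = np.full(z.shape, 17, dtype=int)
    sext = np.floor(((phi + np.pi / 6) % (2 * np.pi)) / (np.pi / 3)).astype(int) % 6
    quad = np.floor(((phi + np.pi / 4) % (2 * np.pi)) / (np.pi / 2)).astype(int) % 4
    apical = (z >= 0.2) & (z < 0.45)
    mid = (z >= 0.45) & (z < 0.7)
    basal = z >= 0.7
    seg[apical] = np.asarray(_QUADRANT_SEGMENTS)[quad[apical]]
    seg[mid] = np.asarray(_SEXTANT_SEGMENTS)[sext[mid]] + 6
    seg[basal] = np.asarray(_SEXTANT_SEGMENTS)[sext[basal]]
    return int(seg[0]) if scalar else seg


def ring_of_segment(seg) -> np.ndarray:
    """Ring label of a segment: 'basal', 'mid', 'apical' or 'apex'."""
    seg = np.asarray(seg)
    rings = np.where(seg <= 6, "basal", np.where(seg <= 12, "mid", np.where(seg <= 16, "apical", "apex")))
    return rings if rings.ndim else str(rings)


_RING_Z_CENTER = {"basal": 0.85, "mid": 0.575, "apical": 0.325, "apex": 0.1}


def segment_center(segment: int) -> tuple[float, float]:
    """(z, phi) centroid of an AHA segment in UVC space."""
    if not 1 <= segment <= 17:
        raise ValueError("segment must be 1..17")
    ring = str(ring_of_segment(segment))
    zc = _RING_Z_CENTER[ring]
    if segment == 17:
        return zc, 0.0
    if ring == "apical":
        idx = _QUADRANT_SEGMENTS.index(segment)
        phic = -np.pi / 4 + (idx + 0.5) * np.pi / 2
    else:
        idx = _SEXTANT_SEGMENTS.index(segment if ring == "basal" else segment - 6)
        phic = -np.pi / 6 + (idx + 0.5) * np.pi / 3
    return zc, float(wrap_angle(phic))


# ---------------------------------------------------------------------------
# localization error


def localization_error(p_pred, p_true) -> float:
    """Euclidean distance (mm) between predicted and true positions."""
    a, b = np.asarray(p_pred, dtype=float), np.asarray(p_true, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite position")
    return float(np.linalg.norm(a - b))


@dataclass
class ErrorSummary:
    """Per-case localization errors with summary statistics (population sd)."""

    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)
    n: int = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty error list")
        if np.any(v < 0):
            raise ValueError("negative localization error")
        self.values = v
        self.mean = float(v.mean())
        self.sd = float(v.std())
        self.min = float(v.min())
        self.max = float(v.max())
        self.n = int(v.size)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "min": self.min, "max": self.max, "n": self.n}
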