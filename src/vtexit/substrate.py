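"""Virtual post-infarct substrates and figure-of-eight VT episodes.

A substrate is two inexcitable scar lobes framing a narrow corridor of
slowly conducting tissue (the isthmus), all defined as transmural boxes
in UVC space around a center placed inside a chosen AHA segment. A VT
"beat" is one eikonal activation initiated at the corridor's exit site
(the point of earliest systolic activation) on the scarred substrate:
wavefronts sweep around both lobes, the figure-of-eight surrogate of the
re-entrant systolic sequence. The corridor round-trip time (through the
isthmus plus back around the scar) is reported as the episode's cycle
length metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VentricularMesh
from .propagation import ActivationMap, ConductionModel, EikonalSolver
from .uvc import UVCField, UVCPoint, aha_segment_of, segment_center, uvc_nearest_node, wrap_angle

__all__ = ["SubstrateError", "ScarConfig", "VTEpisode", "generate_substrate", "apply_substrate", "make_vt_episode"]


class SubstrateError(ValueError):
    pass


@dataclass(frozen=True)
class ScarConfig:
    """Two-lobe scar with a slow-conduction isthmus corridor.

    center_uvc is the isthmus center; the corridor spans
    |phi - phi0| < isthmus_half_width and |z - z0| < lobe dz; each lobe
    is a (dz, dphi) half-extent box adjacent to the corridor on either
    phi side. The scar spans the full wall thickness when transmural.
    """

    center_uvc: UVCPoint
    lobe_half_extent: tuple = (0.12, 0.25)  # (dz, dphi radians)
    isthmus_half_width: float = 0.08  # radians
    isthmus_cv_multiplier: float = 0.25
    transmural: bool = True
    seed: int = 0
    aha_segment: int = 0

    def __post_init__(self):
        if not 0.0 < self.isthmus_cv_multiplier < 1.0:
            raise SubstrateError("isthmus_cv_multiplier must lie in (0, 1)")
        if self.isthmus_half_width <= 0 or min(self.lobe_half_extent) <= 0:
            raise SubstrateError("extents must be positive")

    # region membership -----------------------------------------------------
    def _dz_dphi(self, z: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return z - self.center_uvc.z, np.asarray(wrap_angle(phi - self.center_uvc.phi))

    def in_corridor(self, z, phi) -> np.ndarray:
        dz, dphi = self._dz_dphi(np.asarray(z), np.asarray(phi))
        return (np.abs(dz) <= self.lobe_half_extent[0]) & (np.abs(dphi) < self.isthmus_half_width)

    def in_lobes(self, z, phi) -> np.ndarray:
        dz, dphi = self._dz_dphi(np.asarray(z), np.asarray(phi))
        wc, dp = self.isthmus_half_width, self.lobe_half_extent[1]
        in_band = np.abs(dz) <= self.lobe_half_extent[0]
        side = (np.abs(dphi) >= wc) & (np.abs(dphi) <= wc + 2 * dp)
        return in_band & side


@dataclass
class VTEpisode:
    """One simulated VT beat with its labelled exit site."""

    substrate: ScarConfig
    exit_node: int
    exit_uvc: UVCPoint
    exit_xyz: np.ndarray
    cycle_length: float
    activation: ActivationMap


def generate_substrate(
    mesh: VentricularMesh,
    uvc_field: UVCField,
    aha_segment: int,
    seed: int = 0,
    min_lobe_nodes: int = 20,
    **scar_kwargs,
) -> ScarConfig:
    """Place a two-lobe scar centered in the given AHA segment (1..16).

    The isthmus center sits at the segment's (z, phi) centroid with a
    seeded jitter (kept inside the segment); both lobes must resolve to
    at least min_lobe_nodes mesh nodes each.
    """
    if aha_segment == 17:
        raise SubstrateError("apex cap (segment 17) excluded from scar centers")
    if not 1 <= aha_segment <= 16:
        raise SubstrateError("segment must be 1..16")
    zc, phic = segment_center(aha_segment)
    rng = np.random.default_rng(seed)
    # keep the corridor and both mouths inside z in [0, 1]
    dz_lobe = dict(scar_kwargs).get("lobe_half_extent", (0.12, 0.25))[0]
    z_lo, z_hi = dz_lobe + 0.06, 1.0 - dz_lobe - 0.06
    z0, phi0 = float(np.clip(zc, z_lo, z_hi)), phic
    for _ in range(32):
        cand_z = float(np.clip(zc + rng.uniform(-0.04, 0.04), z_lo, z_hi))
        cand_phi = float(wrap_angle(phic + rng.uniform(-0.12, 0.12)))
        if aha_segment_of((cand_z, cand_phi)) == aha_segment:
            z0, phi0 = cand_z, cand_phi
            break
    scar = ScarConfig(
        center_uvc=UVCPoint(z0, 0.5, phi0), seed=seed, aha_segment=aha_segment, **scar_kwargs
    )
    for sign in (-1.0, 1.0):
        dz, dphi = scar._dz_dphi(uvc_field.z, uvc_field.phi)
        wc, dp = scar.isthmus_half_width, scar.lobe_half_extent[1]
        lobe = (np.abs(dz) <= scar.lobe_half_extent[0]) & (sign * dphi >= wc) & (sign * dphi <= wc + 2 * dp)
        if lobe.sum() < min_lobe_nodes:
            raise SubstrateError(
                f"unresolvable substrate: lobe covers {int(lobe.sum())} nodes (< {min_lobe_nodes})"
            )
    return scar


def _element_uvc(mesh: VentricularMesh, uvc_field: UVCField) -> tuple[np.ndarray, np.ndarray]:
    """(z, phi) of element centroids; phi via circular mean of node phis."""
    z = uvc_field.z[mesh.elements].mean(axis=1)
    ph = uvc_field.phi[mesh.elements]
    phi = np.arctan2(np.sin(ph).mean(axis=1), np.cos(ph).mean(axis=1))
    return z, phi


def apply_substrate(
    cm: ConductionModel, mesh: VentricularMesh, uvc_field: UVCField, scar: ScarConfig
) -> ConductionModel:
    """Return a new conduction model with the scar stamped in:
    multiplier 0 inside the lobes, isthmus_cv_multiplier in the corridor,
    unchanged elsewhere. The input model is not modified."""
    mult = cm.multipliers(mesh.n_elements).copy()
    ez, ephi = _element_uvc(mesh, uvc_field)
    mult[scar.in_corridor(ez, ephi)] = scar.isthmus_cv_multiplier
    mult[scar.in_lobes(ez, ephi)] = 0.0
    return ConductionModel(cv_long=cm.cv_long, cv_trans=cm.cv_trans, element_multiplier=mult)


def make_vt_episode(
    mesh: VentricularMesh,
    uvc_field: UVCField,
    cm: ConductionModel,
    scar: ScarConfig,
) -> VTEpisode:
    """Simulate one VT beat on the scarred substrate.

    The exit node is the excitable node at the corridor mouth on the
    seeded exit side; the activation map is the eikonal solve initiated
    there. cycle_length = time through the corridor (exit -> entrance
    restricted to isthmus tissue plus a small mouth margin) + return
    time around the scar with the corridor blocked.
    """
    cm_sub = apply_substrate(cm, mesh, uvc_field, scar)
    solver = EikonalSolver(mesh, cm_sub)
    excitable = solver.node_excitable()

    ez, ephi = _element_uvc(mesh, uvc_field)
    in_corr = scar.in_corridor(ez, ephi)
    dz_e, dphi_e = scar._dz_dphi(ez, ephi)
    conducting = cm_sub.multipliers(mesh.n_elements) > 0
    in_band = np.abs(dphi_e) < scar.isthmus_half_width + 0.05
    beyond = np.abs(dz_e) > scar.lobe_half_extent[0]
    near = np.abs(dz_e) <= scar.lobe_half_extent[0] + 0.15
    mouth_of = {
        +1.0: in_band & beyond & near & (dz_e > 0) & conducting,
        -1.0: in_band & beyond & near & (dz_e < 0) & conducting,
    }

    rng = np.random.default_rng(scar.seed + 7919)
    side = 1.0 if rng.integers(2) == 1 else -1.0

    def mouth_node(s: float) -> int:
        els = mouth_of[s]
        if not np.any(els):
            raise SubstrateError("non-viable circuit: empty corridor mouth")
        cand = np.zeros(mesh.n_nodes, dtype=bool)
        cand[np.unique(mesh.elements[els])] = True
        in_scar = scar.in_lobes(uvc_field.z, uvc_field.phi) | scar.in_corridor(
            uvc_field.z, uvc_field.phi
        )
        cand &= excitable & ~np.asarray(in_scar)
        if not np.any(cand):
            raise SubstrateError("non-viable circuit: no excitable mouth node")
        z = float(np.clip(scar.center_uvc.z + s * (scar.lobe_half_extent[0] + 0.03), 0, 1))
        return uvc_nearest_node(uvc_field, UVCPoint(z, 0.5, scar.center_uvc.phi), mask=cand)

    exit_node = mouth_node(side)
    entrance_node = mouth_node(-side)
    if exit_node == entrance_node:
        raise SubstrateError("non-viable circuit: corridor mouths coincide")

    act = solver.solve([(exit_node, 0.0)])

    mult_corr = np.zeros(mesh.n_elements)
    mult_corr[mouth_of[+1.0] | mouth_of[-1.0]] = 1.0
    mult_corr[in_corr] = scar.isthmus_cv_multiplier
    cm_corr = ConductionModel(cm.cv_long, cm.cv_trans, mult_corr)
    try:
        t_through = EikonalSolver(mesh, cm_corr).solve([(exit_node, 0.0)]).times[entrance_node]
    except ValueError as e:
        raise SubstrateError(f"non-viable circuit: {e}") from e

    # return path: corridor blocked, go around the scar
    mult_ret = cm_sub.multipliers(mesh.n_elements).copy()
    mult_ret[in_corr] = 0.0
    cm_ret = ConductionModel(cm.cv_long, cm.cv_trans, mult_ret)
    t_around = EikonalSolver(mesh, cm_ret).solve([(entrance_node, 0.0)]).times[exit_node]
    if not (np.isfinite(t_through) and np.isfinite(t_around)):
        raise SubstrateError("non-viable circuit: no exit-entrance path")

    exit_uvc = uvc_field.point(exit_node)
    return VTEpisode(
        substrate=scar,
        exit_node=int(exit_node),
        exit_uvc=exit_uvc,
        exit_xyz=mesh.nodes[exit_node].copy(),
        cycle_length=float(t_through + t_around),
        activation=act,
    )
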