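"""Infinite-volume-conductor pseudo-ECG forward model and lead algebra.

Extracellular potentials at electrode positions are computed from the
transmembrane potential field with the classical pseudo-ECG source
integral on the tetrahedral mesh,

    phi_e(x, t) = k * sum_elements vol_e * grad Vm|_e . grad_c (1 / |x - c_e|),

with grad Vm from the element's linear shape functions and c_e the
element centroid. Because the mapping is linear in Vm, it collapses to a
precomputed lead-field matrix L (electrodes x nodes) so that
phi = L @ Vm for any trace matrix. From the 9 surface electrode
potentials the standard 12-lead ECG (Wilson central terminal, Einthoven
and Goldberger leads) plus 4 derived vector combinations is formed; from
the 9 device electrodes, 8 bipolar EGM sensing vectors. All derived
channels are reference-invariant (coefficients sum to zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ElectrodeSet, VentricularMesh

__all__ = [
    "LeadDefinition",
    "TraceSet",
    "lead_field_matrix",
    "compute_electrode_potentials",
    "derive_ecg_leads",
    "derive_egm_vectors",
    "ECG_CHANNEL_NAMES",
    "EGM_CHANNEL_NAMES",
    "ECG_LEADS",
    "EGM_LEADS",
]


@dataclass(frozen=True)
class LeadDefinition:
    """A derived channel: signed combination of electrode potentials."""

    name: str
    formula: tuple  # ((electrode, coefficient), ...)

    def __post_init__(self):
        total = sum(c for _, c in self.formula)
        if abs(total) > 1e-12:
            raise ValueError(f"lead {self.name}: coefficients sum to {total}, not 0")

    def coefficients(self, electrode_names) -> np.ndarray:
        out = np.zeros(len(electrode_names))
        for el, c in self.formula:
            if el not in electrode_names:
                raise ValueError(f"lead {self.name}: missing electrode {el}")
            out[list(electrode_names).index(el)] += c
        return out


def _lead(name: str, terms: dict) -> LeadDefinition:
    merged: dict = {}
    for el, c in terms.items():
        merged[el] = merged.get(el, 0.0) + c
    return LeadDefinition(name=name, formula=tuple(sorted(merged.items())))


def _wct(scale: float = 1.0) -> dict:
    return {"RA": -scale / 3, "LA": -scale / 3, "LL": -scale / 3}


def _precordial(v: str, scale: float = 1.0) -> dict:
    d = _wct(scale)
    d[v] = d.get(v, 0.0) + scale
    return d


def _merge(*dicts) -> dict:
    out: dict = {}
    for d in dicts:
        for k, v in d.items():
            out[k] = out.get(k, 0.0) + v
    return out


# 12 standard leads + 4 derived vector combinations:
#   X ~ horizontal axis (V6 - V1), Y ~ vertical axis (aVF),
#   Z ~ anteroposterior axis (V2 - (V6 + I)/2),
#   M ~ precordial magnitude-like combination (V1+V2+V3-V4-V5-V6).
ECG_LEADS = (
    _lead("I", {"LA": 1, "RA": -1}),
    _lead("II", {"LL": 1, "RA": -1}),
    _lead("III", {"LL": 1, "LA": -1}),
    _lead("aVR", {"RA": 1, "LA": -0.5, "LL": -0.5}),
    _lead("aVL", {"LA": 1, "RA": -0.5, "LL": -0.5}),
    _lead("aVF", {"LL": 1, "RA": -0.5, "LA": -0.5}),
    _lead("V1", _precordial("V1")),
    _lead("V2", _precordial("V2")),
    _lead("V3", _precordial("V3")),
    _lead("V4", _precordial("V4")),
    _lead("V5", _precordial("V5")),
    _lead("V6", _precordial("V6")),
    _lead("X", _merge(_precordial("V6"), _precordial("V1", -1.0))),
    _lead("Y", {"LL": 1, "RA": -0.5, "LA": -0.5}),
    _lead("Z", _merge(_precordial("V2"), _precordial("V6", -0.5), {"LA": -0.5, "RA": 0.5})),
    _lead(
        "M",
        _merge(
            *[_precordial(v) for v in ("V1", "V2", "V3")],
            *[_precordial(v, -1.0) for v in ("V4", "V5", "V6")],
        ),
    ),
)

# 8 device sensing vectors mixing near-field (tip-ring, LV bipoles) and
# far-field (coil-can) electrode pairs.
_EGM_PAIRS = (
    ("RV_TIP", "RV_RING"),
    ("RV_COIL", "CAN"),
    ("SVC_COIL", "CAN"),
    ("RV_COIL", "SVC_COIL"),
    ("LV1", "LV2"),
    ("LV2", "LV3"),
    ("LV3", "LV4"),
    ("LV4", "CAN"),
)
EGM_LEADS = tuple(_lead(f"{a}-{b}", {a: 1, b: -1}) for a, b in _EGM_PAIRS)

ECG_CHANNEL_NAMES = tuple(ld.name for ld in ECG_LEADS)
EGM_CHANNEL_NAMES = tuple(ld.name for ld in EGM_LEADS)


@dataclass
class TraceSet:
    """Fixed-rate multi-channel traces for one beat (mV)."""

    channel_names: list
    samples: np.ndarray  # (channels, T)
    dt: float
    beat_kind: str = "paced"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError("samples must be (channels, T) matching channel_names")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite trace values")
        if self.beat_kind not in ("paced", "vt"):
            raise ValueError("beat_kind must be 'paced' or 'vt'")


# ---------------------------------------------------------------------------
# lead fields


def lead_field_matrix(
    mesh: VentricularMesh, electrode_positions: np.ndarray, gain: float = 1.0
) -> np.ndarray:
    """(E, N) pseudo-ECG lead-field matrix; potentials = L @ Vm.

    Raises if an electrode (numerically) coincides with an element
    centroid, the singularity of the 1/r kernel.
    """
    pos = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    x = mesh.element_tets()
    jac = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # columns = edge vectors
    vol = np.abs(np.linalg.det(jac)) / 6.0
    jinv = np.linalg.inv(jac)  # rows: gradients of barycentric coords 1..3
    grad_n = np.empty((mesh.n_elements, 4, 3))
    grad_n[:, 1:, :] = jinv
    grad_n[:, 0, :] = -jinv.sum(axis=1)
    cent = x.mean(axis=1)

    L = np.zeros((pos.shape[0], mesh.n_nodes))
    for e, xe in enumerate(pos):
        d = xe[None, :] - cent
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-6):
            raise ValueError("singularity error: electrode coincides with an element centroid")
        g = d / r[:, None] ** 3  # grad_c (1/|x - c|)
        coeff = gain * vol[:, None] * np.einsum("ma,mia->mi", g, grad_n)
        np.add.at(L[e], mesh.elements.ravel(), coeff.ravel())
    return L


def compute_electrode_potentials(
    mesh: VentricularMesh,
    vm_traces: np.ndarray,
    electrodes: ElectrodeSet,
    sigma_ratio: float = 1.0,
    lead_field: np.ndarray | None = None,
) -> dict:
    """Per-electrode potential time series {name: (T,) array}.

    sigma_ratio is the fixed gain absorbing intra/extracellular
    conductivity ratios. A precomputed lead_field for these electrode
    positions may be supplied to amortize the geometric factor.
    """
    if mesh.shell is not None and np.any(mesh.shell.in_myocardium(electrodes.positions)):
        raise ValueError("singularity error: electrode inside the myocardium")
    if lead_field is None:
        lead_field = lead_field_matrix(mesh, electrodes.positions, gain=sigma_ratio)
        pots = lead_field @ vm_traces
    else:
        pots = sigma_ratio * (lead_field @ vm_traces)
    return {name: pots[i] for i, name in enumerate(electrodes.names)}


def _derive(potentials: dict, leads, dt: float, beat_kind: str) -> TraceSet:
    names = list(potentials.keys())
    mat = np.stack([np.asarray(potentials[n], dtype=float) for n in names])
    coeffs = np.stack([ld.coefficients(names) for ld in leads])
    return TraceSet(
        channel_names=[ld.name for ld in leads],
        samples=coeffs @ mat,
        dt=dt,
        beat_kind=beat_kind,
    )


def derive_ecg_leads(potentials: dict, dt: float = 1.0, beat_kind: str = "paced") -> TraceSet:
    """16-channel ECG TraceSet (12 standard leads + X, Y, Z, M) from the
    9 surface electrode potentials {name: (T,)}."""
    missing = {"RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"} - set(potentials)
    if missing:
        raise ValueError(f"missing surface electrodes: {sorted(missing)}")
    return _derive(potentials, ECG_LEADS, dt, beat_kind)


def derive_egm_vectors(potentials: dict, dt: float = 1.0, beat_kind: str = "paced") -> TraceSet:
    """8-channel device EGM TraceSet from the 9 device electrode potentials."""
    need = {e for pair in _EGM_PAIRS for e in pair}
    missing = need - set(potentials)
    if missing:
        raise ValueError(f"missing device electrodes: {sorted(missing)}")
    return _derive(potentials, EGM_LEADS, dt, beat_kind)
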