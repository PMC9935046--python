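"""Seeded libraries of paced-beat and VT-beat samples.

A library is a directory with one HDF5 trace file per virtual anatomy
(groups ``paced/<id>`` and ``vt/<id>``, datasets ``ecg`` (16 x T) and
``egm`` (8 x T)), a CSV manifest of labels, and a JSON config snapshot.
Every stage is seeded through a single global seed split with
numpy.random.SeedSequence, so a (config, seed) pair reproduces the
manifest byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .forward import (
    ECG_CHANNEL_NAMES,
    EGM_CHANNEL_NAMES,
    TraceSet,
    derive_ecg_leads,
    derive_egm_vectors,
    lead_field_matrix,
)
from .geometry import (
    ElectrodeSet,
    GeometryParams,
    VentricularMesh,
    build_ventricle_mesh,
    perturb_geometry_params,
    place_device_electrodes,
    place_surface_electrodes,
)
from .propagation import ActivationMap, APTemplate, ConductionModel, EikonalSolver
from .substrate import SubstrateError, generate_substrate, make_vt_episode
from .uvc import UVCField, aha_segment_of, compute_uvc

__all__ = [
    "LibraryConfig",
    "BeatSample",
    "BeatLibrary",
    "VirtualAnatomy",
    "make_cohort",
    "sample_pacing_sites",
    "build_pacing_library",
    "build_vt_library",
]


@dataclass
class VirtualAnatomy:
    """A virtual patient: mesh, UVC field, electrodes and lead fields."""

    anatomy_id: str
    params: GeometryParams
    mesh: VentricularMesh
    uvc_field: UVCField
    surface_electrodes: ElectrodeSet
    device_electrodes: ElectrodeSet
    lf_surface: np.ndarray
    lf_device: np.ndarray

    @classmethod
    def build(
        cls,
        params: GeometryParams,
        anatomy_id: str,
        torso_scale: float = 120.0,
        electrode_jitter_mm: float = 10.0,
        electrode_seed: Optional[int] = None,
    ) -> "VirtualAnatomy":
        mesh = build_ventricle_mesh(params, anatomy_id=anatomy_id)
        uvc_field = compute_uvc(mesh)
        surf = place_surface_electrodes(mesh, torso_scale, jitter_mm=electrode_jitter_mm, seed=electrode_seed)
        dev = place_device_electrodes(mesh)
        return cls(
            anatomy_id=anatomy_id,
            params=params,
            mesh=mesh,
            uvc_field=uvc_field,
            surface_electrodes=surf,
            device_electrodes=dev,
            lf_surface=lead_field_matrix(mesh, surf.positions),
            lf_device=lead_field_matrix(mesh, dev.positions),
        )


@dataclass(frozen=True)
class LibraryConfig:
    """Study conditions of a simulated beat library.

    Defaults are the desk-scale analog of the study protocol: 5 virtual
    anatomies (±10% geometric perturbations with ±10 mm electrode
    jitter), 500 focal paced beats and 60 two-lobe VT substrates per
    anatomy, 1 ms sampling over a 350 ms beat window, per-channel
    z-score normalization before storage.
    """

    n_paced_per_anatomy: int = 500
    n_vt_per_anatomy: int = 60
    anatomies: tuple = ()  # of GeometryParams; empty -> default cohort of 5
    n_anatomies: int = 5
    global_seed: int = 0
    trace_normalization: str = "zscore"  # or "none"
    noise_std: float = 0.0
    torso_scale: float = 120.0
    electrode_jitter_mm: float = 10.0
    cv_long: float = 0.6
    cv_trans: float = 0.24
    dt: float = 1.0
    window_ms: float = 350.0
    scar_kwargs: tuple = ()

    def __post_init__(self):
        if self.n_paced_per_anatomy <= 0 or self.n_vt_per_anatomy <= 0:
            raise ValueError("beat counts must be positive")
        if self.trace_normalization not in ("zscore", "none"):
            raise ValueError("trace_normalization must be 'zscore' or 'none'")

    def geometry_list(self) -> list[GeometryParams]:
        if self.anatomies:
            return [g if isinstance(g, GeometryParams) else GeometryParams(**g) for g in self.anatomies]
        return perturb_geometry_params(GeometryParams(), self.n_anatomies, seed=self.global_seed + 101)

    def conduction(self) -> ConductionModel:
        return ConductionModel(cv_long=self.cv_long, cv_trans=self.cv_trans)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anatomies"] = [dataclasses.asdict(g) for g in self.geometry_list()]
        return d


def make_cohort(cfg: LibraryConfig) -> list[VirtualAnatomy]:
    """Build the virtual-patient cohort of a library config."""
    out = []
    for i, gp in enumerate(cfg.geometry_list()):
        out.append(
            VirtualAnatomy.build(
                gp,
                anatomy_id=f"anat{i:02d}",
                torso_scale=cfg.torso_scale,
                electrode_jitter_mm=cfg.electrode_jitter_mm,
                electrode_seed=cfg.global_seed * 1000 + i,
            )
        )
    return out


@dataclass
class BeatSample:
    """One simulated beat with its site label."""

    traces: dict  # {"ecg": TraceSet, "egm": TraceSet}
    site_uvc: tuple
    site_xyz: np.ndarray
    anatomy_id: str
    beat_kind: str
    sample_id: str
    seed: int
    source_node: int
    cycle_length: float = float("nan")
    scar_segment: int = -1  # AHA segment of the scar center (VT beats only)


def sample_pacing_sites(mesh: VentricularMesh, n: int, seed: int) -> np.ndarray:
    """n uniformly random myocardial node indices without replacement."""
    if n > mesh.n_nodes:
        raise ValueError("n exceeds node count")
    rng = np.random.default_rng(seed)
    return rng.choice(mesh.n_nodes, size=n, replace=False)


def _normalize(x: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return x
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = x - mu
    const = sd[:, 0] < 1e-12
    sd[const] = 1.0
    out /= sd
    out[const] = 0.0  # constant channels stored as zeros
    return out


class BeatLibrary:
    """On-disk collection of BeatSamples (HDF5 traces + CSV manifest)."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._manifest_rows: list[dict] = []

    # -- write -------------------------------------------------------------
    def _h5path(self, anatomy_id: str) -> Path:
        return self.root / f"traces_{anatomy_id}.h5"

    def add_sample(self, s: BeatSample) -> None:
        with h5py.File(self._h5path(s.anatomy_id), "a") as fh:
            grp = fh.require_group(f"{s.beat_kind}/{s.sample_id}")
            for mode in ("ecg", "egm"):
                ts = s.traces[mode]
                d = grp.create_dataset(mode, data=ts.samples.astype(np.float32))
                d.attrs["dt"] = ts.dt
                d.attrs["channel_names"] = [n.encode() for n in ts.channel_names]
                d.attrs["beat_kind"] = ts.beat_kind
        z, rho, phi = s.site_uvc
        self._manifest_rows.append(
            {
                "sample_id": s.sample_id,
                "anatomy_id": s.anatomy_id,
                "kind": s.beat_kind,
                "source_node": s.source_node,
                "z": z,
                "rho": rho,
                "phi": phi,
                "x_mm": s.site_xyz[0],
                "y_mm": s.site_xyz[1],
                "z_mm": s.site_xyz[2],
                "segment": int(aha_segment_of((z, phi))),
                "seed": s.seed,
                "cycle_length_ms": s.cycle_length,
                "scar_segment": s.scar_segment,
            }
        )

    def flush_manifest(self, config: Optional[LibraryConfig] = None) -> None:
        path = self.root / "manifest.csv"
        df = pd.DataFrame(self._manifest_rows)
        if path.exists():
            old = pd.read_csv(path)
            df = pd.concat([old, df], ignore_index=True)
        df.to_csv(path, index=False, float_format="%.17g")
        self._manifest_rows = []
        if config is not None:
            with open(self.root / "config.json", "w") as fh:
                json.dump(config.to_dict(), fh, indent=1)

    # -- read --------------------------------------------------------------
    @property
    def manifest(self) -> pd.DataFrame:
        return pd.read_csv(self.root / "manifest.csv")

    def config(self) -> LibraryConfig:
        with open(self.root / "config.json") as fh:
            d = json.load(fh)
        d["anatomies"] = tuple(GeometryParams(**g) for g in d["anatomies"])
        d["scar_kwargs"] = tuple(d.get("scar_kwargs") or ())
        return LibraryConfig(**d)

    def get_traces(self, sample_id: str, mode: str) -> TraceSet:
        row = self.manifest.set_index("sample_id").loc[sample_id]
        with h5py.File(self._h5path(row["anatomy_id"]), "r") as fh:
            d = fh[f"{row['kind']}/{sample_id}/{mode}"]
            return TraceSet(
                channel_names=[n.decode() if isinstance(n, bytes) else str(n) for n in d.attrs["channel_names"]],
                samples=d[()].astype(float),
                dt=float(d.attrs["dt"]),
                beat_kind=str(d.attrs["beat_kind"]),
            )

    def load_stack(
        self,
        kind: str,
        mode: str,
        anatomy_ids: Optional[Sequence[str]] = None,
        exclude: Optional[Sequence[str]] = None,
    ):
        """(sample_ids, X (B, C, T) float32, labels DataFrame) for training."""
        man = self.manifest
        man = man[man["kind"] == kind]
        if anatomy_ids is not None:
            man = man[man["anatomy_id"].isin(list(anatomy_ids))]
        if exclude is not None:
            man = man[~man["anatomy_id"].isin(list(exclude))]
        man = man.sort_values("sample_id").reset_index(drop=True)
        xs = []
        for aid, sub in man.groupby("anatomy_id", sort=True):
            with h5py.File(self._h5path(aid), "r") as fh:
                for sid in sub["sample_id"]:
                    xs.append((sid, fh[f"{kind}/{sid}/{mode}"][()]))
        xs.sort(key=lambda t: t[0])
        ids = [t[0] for t in xs]
        X = np.stack([t[1] for t in xs]).astype(np.float32)
        man = man.set_index("sample_id").loc[ids].reset_index()
        return ids, X, man


# ---------------------------------------------------------------------------
# builders


def _beat_traces(
    anatomy: VirtualAnatomy,
    act: ActivationMap,
    tpl: APTemplate,
    cfg: LibraryConfig,
    beat_kind: str,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    from .propagation import synthesize_vm_traces

    # simulate long enough to satisfy the template, then crop to the beat
    # window: late plateau/repolarization outside the window is discarded
    finite = act.times[np.isfinite(act.times)]
    max_act = float(finite.max()) if finite.size else 0.0
    duration = max(cfg.window_ms, max_act + tpl.apd + tpl.repolarization + cfg.dt)
    n_keep = int(round(cfg.window_ms / cfg.dt))
    vm = synthesize_vm_traces(act, tpl, dt=cfg.dt, duration=duration)[:, :n_keep]
    out = {}
    for mode, lf, els, leads_fn in (
        ("ecg", anatomy.lf_surface, anatomy.surface_electrodes, derive_ecg_leads),
        ("egm", anatomy.lf_device, anatomy.device_electrodes, derive_egm_vectors),
    ):
        pots = lf @ vm
        pot_dict = {n: pots[i] for i, n in enumerate(els.names)}
        ts = leads_fn(pot_dict, dt=cfg.dt, beat_kind=beat_kind)
        x = ts.samples
        if cfg.noise_std > 0 and rng is not None:
            x = x + rng.normal(0.0, cfg.noise_std * max(np.abs(x).max(), 1e-12), x.shape)
        ts.samples = _normalize(x, cfg.trace_normalization)
        out[mode] = ts
    return out


def build_pacing_library(
    cfg: LibraryConfig, out_dir, cohort: Optional[list[VirtualAnatomy]] = None
) -> BeatLibrary:
    """Simulate the focal paced-beat library: for each anatomy, eikonal
    solves from seeded random myocardial sites, trace synthesis, and the
    16-channel ECG + 8-channel EGM per beat."""
    lib = BeatLibrary(out_dir)
    cohort = cohort if cohort is not None else make_cohort(cfg)
    cm = cfg.conduction()
    ss = np.random.SeedSequence([cfg.global_seed, 1])
    for anatomy, child in zip(cohort, ss.spawn(len(cohort))):
        seeds = child.generate_state(2)
        site_seed = int(seeds[0] % (2**31))
        noise_rng = np.random.default_rng(int(seeds[1] % (2**31)))
        sites = sample_pacing_sites(anatomy.mesh, cfg.n_paced_per_anatomy, seed=site_seed)
        solver = EikonalSolver(anatomy.mesh, cm)
        times = solver.solve_many(sites)
        for b, node in enumerate(sites):
            act = ActivationMap(times=times[b], sources=[(int(node), 0.0)])
            traces = _beat_traces(anatomy, act, APTemplate(), cfg, "paced", noise_rng)
            uvcf = anatomy.uvc_field
            lib.add_sample(
                BeatSample(
                    traces=traces,
                    site_uvc=(float(uvcf.z[node]), float(uvcf.rho[node]), float(uvcf.phi[node])),
                    site_xyz=anatomy.mesh.nodes[node],
                    anatomy_id=anatomy.anatomy_id,
                    beat_kind="paced",
                    sample_id=f"{anatomy.anatomy_id}_p{b:05d}",
                    seed=site_seed,
                    source_node=int(node),
                )
            )
    lib.flush_manifest(cfg)
    return lib


def build_vt_library(
    cfg: LibraryConfig, out_dir, cohort: Optional[list[VirtualAnatomy]] = None, max_retries: int = 8
) -> BeatLibrary:
    """Simulate the VT-beat library: per anatomy, substrates sampled
    round-robin over AHA segments 1-16 with seeded jitter; each episode
    is a figure-of-eight activation labelled with its exit site."""
    lib = BeatLibrary(out_dir)
    cohort = cohort if cohort is not None else make_cohort(cfg)
    cm = cfg.conduction()
    scar_kwargs = dict(cfg.scar_kwargs)
    ss = np.random.SeedSequence([cfg.global_seed, 2])
    for anatomy, child in zip(cohort, ss.spawn(len(cohort))):
        beat_seeds = child.generate_state(cfg.n_vt_per_anatomy * (max_retries + 1)) % (2**31)
        k = 0
        for b in range(cfg.n_vt_per_anatomy):
            segment = 1 + (b % 16)
            episode = None
            err = None
            for _ in range(max_retries):
                seed = int(beat_seeds[k])
                k += 1
                try:
                    scar = generate_substrate(
                        anatomy.mesh, anatomy.uvc_field, segment, seed=seed, **scar_kwargs
                    )
                    episode = make_vt_episode(anatomy.mesh, anatomy.uvc_field, cm, scar)
                    break
                except SubstrateError as e:
                    err = e
            if episode is None:
                raise SubstrateError(f"segment {segment} on {anatomy.anatomy_id}: {err}")
            traces = _beat_traces(anatomy, episode.activation, APTemplate(), cfg, "vt")
            lib.add_sample(
                BeatSample(
                    traces=traces,
                    site_uvc=(episode.exit_uvc.z, episode.exit_uvc.rho, episode.exit_uvc.phi),
                    site_xyz=episode.exit_xyz,
                    anatomy_id=anatomy.anatomy_id,
                    beat_kind="vt",
                    sample_id=f"{anatomy.anatomy_id}_v{b:04d}",
                    seed=int(episode.substrate.seed),
                    source_node=episode.exit_node,
                    cycle_length=episode.cycle_length,
                    scar_segment=int(episode.substrate.aha_segment),
                )
            )
    lib.flush_manifest(cfg)
    return lib
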