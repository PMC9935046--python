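"""Evaluation protocols for the two computational test scenarios.

Scenario ``seen_pacing_unseen_vt`` (scenario 1): the held-out anatomy's
paced beats are part of base training, its VT beats are excluded from
transfer learning, and testing uses its VT beats — the localizer knows
the anatomy only through pacing. Scenario ``fully_unseen`` (scenario 2):
the held-out anatomy is excluded from both training stages. Per-case
localization errors (Euclidean mm between predicted and true exit
sites) are summarized per anatomy and pooled, and predictions are
reported in the standard 17-AHA-segment model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .localizer import (
    ModelSpec,
    TrainConfig,
    TrainedLocalizer,
    predict_batch,
    train_base,
    transfer_finetune,
)
from .uvc import ErrorSummary, UVCPoint, aha_segment_of, localization_error, ring_of_segment, uvc_to_point

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "run_rotating_scenario",
    "summarize_errors",
    "segment_report",
]

SCENARIOS = ("seen_pacing_unseen_vt", "fully_unseen")


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str
    mode: str  # "ecg" | "egm"
    anatomies: tuple
    held_out_anatomy: str
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.held_out_anatomy not in self.anatomies:
            raise ValueError("held_out_anatomy must be one of anatomies")
        if self.mode not in ("ecg", "egm"):
            raise ValueError("mode must be 'ecg' or 'egm'")


def summarize_errors(values) -> ErrorSummary:
    """Mean / population sd / min / max / n of per-case LE values (mm)."""
    return ErrorSummary(values=np.asarray(values, dtype=float))


def segment_report(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-case AHA-segment comparison of prediction vs truth.

    cases must carry true (z, phi) and predicted (pred_z, pred_phi)
    UVC columns; adds segments, exact segment match and ring-level
    (apical/mid/basal/apex) match flags.
    """
    out = cases.copy()
    out["true_segment"] = aha_segment_of((out["z"].to_numpy(), out["phi"].to_numpy()))
    out["pred_segment"] = aha_segment_of((out["pred_z"].to_numpy(), out["pred_phi"].to_numpy()))
    out["segment_match"] = out["true_segment"] == out["pred_segment"]
    out["ring_match"] = ring_of_segment(out["true_segment"].to_numpy()) == ring_of_segment(
        out["pred_segment"].to_numpy()
    )
    return out


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    cases: pd.DataFrame  # per-case predictions with LE
    summary: ErrorSummary
    base_train_ids: tuple
    transfer_train_ids: tuple
    test_ids: tuple

    def audit(self, manifest: pd.DataFrame) -> dict:
        """Data-leakage audit of the scenario protocol."""
        anat = manifest.set_index("sample_id")["anatomy_id"]
        held = self.spec.held_out_anatomy
        base_anats = set(anat.loc[list(self.base_train_ids)])
        transfer_anats = set(anat.loc[list(self.transfer_train_ids)])
        test_anats = set(anat.loc[list(self.test_ids)])
        ok_transfer = held not in transfer_anats
        ok_test = test_anats == {held}
        ok_base = (held in base_anats) if self.spec.scenario == "seen_pacing_unseen_vt" else (held not in base_anats)
        no_overlap = not (set(self.test_ids) & (set(self.base_train_ids) | set(self.transfer_train_ids)))
        return {
            "base_ok": bool(ok_base),
            "transfer_ok": bool(ok_transfer),
            "test_ok": bool(ok_test),
            "no_overlap": bool(no_overlap),
            "passed": bool(ok_base and ok_transfer and ok_test and no_overlap),
        }


def _evaluate_on_anatomy(tl: TrainedLocalizer, library, anatomy, test_ids, X, labels) -> pd.DataFrame:
    pred = predict_batch(tl, X)
    rows = []
    for i, sid in enumerate(test_ids):
        q = UVCPoint(float(pred[i, 0]), float(pred[i, 1]), float(pred[i, 2]))
        xyz = uvc_to_point(anatomy.mesh, anatomy.uvc_field, q)
        truth = labels.iloc[i][["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sid,
                "anatomy_id": labels.iloc[i]["anatomy_id"],
                "z": labels.iloc[i]["z"],
                "rho": labels.iloc[i]["rho"],
                "phi": labels.iloc[i]["phi"],
                "pred_z": q.z,
                "pred_rho": q.rho,
                "pred_phi": q.phi,
                "pred_x_mm": xyz[0],
                "pred_y_mm": xyz[1],
                "pred_z_mm": xyz[2],
                "le_mm": localization_error(xyz, truth),
            }
        )
    return segment_report(pd.DataFrame(rows))


def run_scenario(
    spec: ScenarioSpec,
    paced_library,
    vt_library,
    anatomies: dict,
    model_spec: ModelSpec,
    tc_base: TrainConfig,
    tc_transfer: TrainConfig,
    base_model: Optional[TrainedLocalizer] = None,
) -> ScenarioResult:
    """Run one scenario for one held-out anatomy.

    anatomies maps anatomy_id -> VirtualAnatomy (for UVC back-mapping).
    A precomputed base model may be passed for scenario 1 (its base
    training set does not depend on the held-out anatomy).
    """
    held = spec.held_out_anatomy
    exclude_base = None if spec.scenario == "seen_pacing_unseen_vt" else [held]
    if base_model is None:
        base_model = train_base(
            paced_library, model_spec, tc_base, mode=spec.mode, exclude_anatomies=exclude_base
        )
    tuned = transfer_finetune(base_model, vt_library, tc_transfer, exclude_anatomies=[held])
    test_ids, X, labels = vt_library.load_stack("vt", spec.mode, anatomy_ids=[held])
    cases = _evaluate_on_anatomy(tuned, vt_library, anatomies[held], test_ids, X, labels)
    base_ids = tuple(base_model.train_ids) + tuple(base_model.val_ids)
    transfer_ids = tuple(tuned.train_ids) + tuple(tuned.val_ids)
    return ScenarioResult(
        spec=spec,
        cases=cases,
        summary=summarize_errors(cases["le_mm"].to_numpy()),
        base_train_ids=base_ids,
        transfer_train_ids=transfer_ids,
        test_ids=tuple(test_ids),
    )


def run_rotating_scenario(
    scenario: str,
    mode: str,
    paced_library,
    vt_library,
    anatomies: dict,
    model_spec: ModelSpec,
    tc_base: TrainConfig,
    tc_transfer: TrainConfig,
    seed: int = 0,
) -> dict:
    """Rotate the held-out anatomy over the cohort.

    Returns per-anatomy results plus pooled statistics. Both flavours of
    the "mean +- sd" summary are computed and labelled: across-torso
    (mean/sd of per-anatomy mean LEs, the study's headline format) and
    pooled over all episodes.
    """
    ids = tuple(sorted(anatomies.keys()))
    shared_base = None
    if scenario == "seen_pacing_unseen_vt":
        shared_base = train_base(
            paced_library, model_spec, replace_seed(tc_base, seed), mode=mode
        )
    results = {}
    for k, held in enumerate(ids):
        spec = ScenarioSpec(scenario=scenario, mode=mode, anatomies=ids, held_out_anatomy=held, seed=seed)
        results[held] = run_scenario(
            spec,
            paced_library,
            vt_library,
            anatomies,
            model_spec,
            replace_seed(tc_base, seed + 17 * k),
            replace_seed(tc_transfer, seed + 17 * k + 1),
            base_model=shared_base,
        )
    per_torso_means = np.array([results[a].summary.mean for a in ids])
    pooled = np.concatenate([results[a].summary.values for a in ids])
    return {
        "per_anatomy": results,
        "per_torso_mean_le": dict(zip(ids, per_torso_means)),
        "across_torso": summarize_errors(per_torso_means),
        "pooled": summarize_errors(pooled),
        "base_model": shared_base,  # scenario 1 only (shared across rotations)
    }


def replace_seed(tc: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(tc, seed=int(seed) % (2**31))
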