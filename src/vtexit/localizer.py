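"""Trace-to-exit-site localizer with transfer learning.

A 1-D convolutional encoder with a dense head regresses the UVC triple
of a beat's source site from its multi-channel traces. The rotational
coordinate is regressed as (sin phi, cos phi) so that sites across the
phi = +-pi seam are not penalized as full-turn errors; the four targets
(z, rho, sin phi, cos phi) are comparably scaled and trained with equal-
weight mean squared error.

Transfer learning re-trains part of the network on VT beats after base
training on paced beats: the freeze policy selects which parameter
tensors stay bit-identical ('freeze_encoder' keeps the conv stack,
'freeze_all_but_last' keeps everything except the output layer, 'none'
continues ordinary training).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .forward import TraceSet
from .nn import Adam, ConvRegressor, mse_loss
from .uvc import UVCField, UVCPoint, localization_error, uvc_to_point, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "PredictionResult",
    "TrainedLocalizer",
    "targets_from_labels",
    "train_base",
    "transfer_finetune",
    "predict_exit_site",
]

FREEZE_POLICIES = ("none", "freeze_encoder", "freeze_all_but_last")


@dataclass(frozen=True)
class ModelSpec:
    """Reference localizer architecture.

    n_channels is 16 (ECG mode) or 8 (EGM mode); window is the trace
    length in samples; conv_blocks are (out_channels, kernel, stride)
    stages of the encoder; dense_sizes the hidden head widths. The head
    always emits 4 outputs: (z, rho, sin phi, cos phi).
    """

    n_channels: int = 16
    window: int = 350
    conv_blocks: tuple = ((24, 7, 2), (32, 5, 2), (48, 5, 2))
    dense_sizes: tuple = (32,)
    param_seed: int = 0

    def build(self) -> ConvRegressor:
        return ConvRegressor(
            n_channels=self.n_channels,
            window=self.window,
            conv_blocks=self.conv_blocks,
            dense_sizes=self.dense_sizes,
            n_outputs=4,
            param_seed=self.param_seed,
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 2e-3
    validation_fraction: float = 0.15
    patience: int = 10
    freeze_policy: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError("validation fraction must lie in (0, 0.5]")
        if self.freeze_policy not in FREEZE_POLICIES:
            raise ValueError(f"freeze_policy must be one of {FREEZE_POLICIES}")


@dataclass
class PredictionResult:
    pred_uvc: UVCPoint
    pred_xyz: np.ndarray
    sample_id: str = ""
    le_mm: Optional[float] = None
    clipped: bool = False


@dataclass
class TrainedLocalizer:
    """A trained model plus everything needed to apply it consistently."""

    model: ConvRegressor
    spec: ModelSpec
    mode: str  # "ecg" | "egm"
    channel_names: tuple
    train_log: pd.DataFrame
    train_ids: tuple = ()
    val_ids: tuple = ()

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.model.params)
        meta = {
            "spec": {
                "n_channels": self.spec.n_channels,
                "window": self.spec.window,
                "conv_blocks": [list(b) for b in self.spec.conv_blocks],
                "dense_sizes": list(self.spec.dense_sizes),
                "param_seed": self.spec.param_seed,
            },
            "mode": self.mode,
            "channel_names": list(self.channel_names),
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
        }
        with open(path / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        self.train_log.to_csv(path / "train_log.csv", index=False)

    @classmethod
    def load(cls, path) -> "TrainedLocalizer":
        path = Path(path)
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec(
            n_channels=meta["spec"]["n_channels"],
            window=meta["spec"]["window"],
            conv_blocks=tuple(tuple(b) for b in meta["spec"]["conv_blocks"]),
            dense_sizes=tuple(meta["spec"]["dense_sizes"]),
            param_seed=meta["spec"]["param_seed"],
        )
        model = spec.build()
        with np.load(path / "params.npz") as npz:
            model.set_params({k: npz[k] for k in npz.files})
        return cls(
            model=model,
            spec=spec,
            mode=meta["mode"],
            channel_names=tuple(meta["channel_names"]),
            train_log=pd.read_csv(path / "train_log.csv"),
            train_ids=tuple(meta["train_ids"]),
            val_ids=tuple(meta["val_ids"]),
        )


def targets_from_labels(labels: pd.DataFrame) -> np.ndarray:
    """(B, 4) regression targets (z, rho, sin phi, cos phi)."""
    phi = labels["phi"].to_numpy(dtype=float)
    return np.stack(
        [
            labels["z"].to_numpy(dtype=float),
            labels["rho"].to_numpy(dtype=float),
            np.sin(phi),
            np.cos(phi),
        ],
        axis=1,
    ).astype(np.float32)


def _frozen_set(model: ConvRegressor, policy: str) -> set:
    if policy == "none":
        return set()
    if policy == "freeze_encoder":
        return set(model.encoder_param_names())
    if policy == "freeze_all_but_last":
        return set(model.params) - set(model.last_layer_param_names())
    raise ValueError(f"unknown freeze policy {policy!r}")


def _fit(
    model: ConvRegressor,
    X: np.ndarray,
    Y: np.ndarray,
    ids: list,
    tc: TrainConfig,
    frozen: set = frozenset(),
):
    """Mini-batch Adam with an id-level validation split and early stopping.

    Returns (log DataFrame, train_ids, val_ids); the model ends at the
    parameters with the best validation loss.
    """
    if len(frozen) == len(model.params):
        raise ValueError("freeze policy leaves no trainable parameters")
    rng = np.random.default_rng(tc.seed)
    n = len(X)
    order = rng.permutation(n)
    n_val = max(1, int(round(tc.validation_fraction * n)))
    if n - n_val < 1:
        raise ValueError("not enough samples to train")
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, Ytr, Xval, Yval = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]

    opt = Adam(model.params.keys(), lr=tc.learning_rate)
    best_val, best_params, since_best = np.inf, model.get_params(), 0
    rows = []
    for epoch in range(tc.epochs):
        perm = rng.permutation(len(Xtr))
        tr_loss, n_batches = 0.0, 0
        for start in range(0, len(Xtr), tc.batch_size):
            sel = perm[start : start + tc.batch_size]
            pred = model.forward(Xtr[sel], keep_cache=True)
            loss, dy = mse_loss(pred, Ytr[sel])
            grads = model.backward(dy)
            opt.step(model.params, grads, frozen=frozen)
            tr_loss += loss
            n_batches += 1
        val_loss = mse_loss(model.predict(Xval), Yval)[0]
        rows.append({"epoch": epoch, "train_loss": tr_loss / max(n_batches, 1), "val_loss": val_loss})
        if val_loss < best_val - 1e-7:
            best_val, best_params, since_best = val_loss, model.get_params(), 0
        else:
            since_best += 1
            if since_best > tc.patience:
                break
    model.set_params(best_params)
    log = pd.DataFrame(rows)
    return log, [ids[i] for i in tr_idx], [ids[i] for i in val_idx]


def train_base(library, spec: ModelSpec, tc: TrainConfig, mode: str = "ecg", exclude_anatomies=None) -> TrainedLocalizer:
    """Base training on the paced-beat library (MSE on the UVC targets)."""
    ids, X, labels = library.load_stack("paced", mode, exclude=exclude_anatomies)
    if len(ids) == 0:
        raise ValueError("empty paced library")
    if X.shape[1] != spec.n_channels:
        raise ValueError(f"channel mismatch: data has {X.shape[1]}, spec expects {spec.n_channels}")
    Y = targets_from_labels(labels)
    model = spec.build()
    log, tr, val = _fit(model, X, Y, ids, tc)
    names = tuple(library.get_traces(ids[0], mode).channel_names)
    return TrainedLocalizer(
        model=model,
        spec=spec,
        mode=mode,
        channel_names=names,
        train_log=log,
        train_ids=tuple(tr),
        val_ids=tuple(val),
    )


def transfer_finetune(base: TrainedLocalizer, vt_library, tc: TrainConfig, exclude_anatomies=None) -> TrainedLocalizer:
    """Re-train part of the base model on VT beats (transfer learning).

    Only the parameter subsets selected by tc.freeze_policy are updated;
    frozen tensors are asserted bit-identical to the base model.
    """
    ids, X, labels = vt_library.load_stack("vt", base.mode, exclude=exclude_anatomies)
    if len(ids) == 0:
        raise ValueError("empty VT library")
    if X.shape[1] != base.spec.n_channels:
        raise ValueError("channel mismatch between VT library and model")
    Y = targets_from_labels(labels)
    model = base.model.clone()
    frozen = _frozen_set(model, tc.freeze_policy)
    log, tr, val = _fit(model, X, Y, ids, tc, frozen=frozen)
    for name in frozen:
        assert np.array_equal(model.params[name], base.model.params[name]), name
    return TrainedLocalizer(
        model=model,
        spec=base.spec,
        mode=base.mode,
        channel_names=base.channel_names,
        train_log=log,
        train_ids=tuple(tr),
        val_ids=tuple(val),
    )


def _uvc_from_outputs(raw: np.ndarray):
    z, rho = float(raw[0]), float(raw[1])
    clipped = not (0.0 <= z <= 1.0 and 0.0 <= rho <= 1.0)
    phi = float(np.arctan2(raw[2], raw[3]))
    return UVCPoint(z=float(np.clip(z, 0, 1)), rho=float(np.clip(rho, 0, 1)), phi=phi), clipped


def predict_exit_site(
    tl: TrainedLocalizer,
    traces: TraceSet,
    mesh,
    uvc_field: UVCField,
    true_xyz=None,
    sample_id: str = "",
) -> PredictionResult:
    """Predict the source/exit site of one beat and map it back to mm.

    Channel names must match the training mode exactly (no silent
    reordering); traces of a different length are linearly resampled to
    the model window. le_mm is filled when the true site is supplied.
    """
    if tuple(traces.channel_names) != tl.channel_names:
        raise ValueError(
            f"channel mismatch: expected {list(tl.channel_names)}, got {list(traces.channel_names)}"
        )
    x = traces.samples.astype(np.float32)
    if x.shape[1] != tl.spec.window:
        t_old = np.linspace(0.0, 1.0, x.shape[1])
        t_new = np.linspace(0.0, 1.0, tl.spec.window)
        x = np.stack([np.interp(t_new, t_old, ch) for ch in x]).astype(np.float32)
    raw = tl.model.forward(x[None])[0]
    uvc, clipped = _uvc_from_outputs(raw)
    if clipped:
        logger.warning("prediction %s: z/rho outside [0,1], clipped", sample_id or "<unnamed>")
    xyz = uvc_to_point(mesh, uvc_field, uvc)
    le = localization_error(xyz, true_xyz) if true_xyz is not None else None
    return PredictionResult(pred_uvc=uvc, pred_xyz=xyz, sample_id=sample_id, le_mm=le, clipped=clipped)


def predict_batch(tl: TrainedLocalizer, X: np.ndarray) -> np.ndarray:
    """(B, 3) predicted UVC triples (z, rho, phi) for a stacked batch."""
    raw = tl.model.predict(X.astype(np.float32))
    z = np.clip(raw[:, 0], 0, 1)
    rho = np.clip(raw[:, 1], 0, 1)
    phi = np.asarray(wrap_angle(np.arctan2(raw[:, 2], raw[:, 3])))
    return np.stack([z, rho, phi], axis=1)
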