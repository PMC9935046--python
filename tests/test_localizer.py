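import logging

import numpy as np
import pandas as pd
import pytest

import vtexit as vx
from vtexit.localizer import (
    ModelSpec,
    TrainConfig,
    TrainedLocalizer,
    _fit,
    predict_batch,
    predict_exit_site,
    targets_from_labels,
    train_base,
    transfer_finetune,
)
from vtexit.nn import ConvRegressor, mse_loss


@pytest.fixture(scope="module")
def small_spec():
    return ModelSpec(n_channels=16, window=350, conv_blocks=((12, 7, 3), (16, 5, 3)), dense_sizes=(16,))


@pytest.fixture(scope="module")
def base_model(tiny_paced_library, small_spec):
    tc = TrainConfig(epochs=25, batch_size=8, learning_rate=2e-3, patience=25, seed=0)
    return train_base(tiny_paced_library, small_spec, tc, mode="ecg")


def test_target_encoding_identity(tiny_paced_library):
    _, _, labels = tiny_paced_library.load_stack("paced", "ecg")
    y = targets_from_labels(labels)
    assert np.allclose(y[:, 2] ** 2 + y[:, 3] ** 2, 1.0, atol=1e-6)


def test_phi_seam_not_penalized():
    """Sites straddling phi = +-pi have nearly identical targets."""
    eps = 1e-3
    df = pd.DataFrame({"z": [0.5, 0.5], "rho": [0.5, 0.5], "phi": [np.pi - eps, -np.pi + eps]})
    y = targets_from_labels(df)
    assert float(np.sum((y[0] - y[1]) ** 2)) < 1e-5  # sin/cos encoding
    assert abs(df["phi"][0] - df["phi"][1]) > 6.0  # naive difference is a full turn


class TestTraining:
    def test_overfit_sanity(self, tiny_paced_library, small_spec):
        """A small model memorizes a 50-beat library (loss drops 10x)."""
        tc = TrainConfig(epochs=200, batch_size=8, learning_rate=2e-3, patience=200, seed=1)
        tl = train_base(tiny_paced_library, small_spec, tc, mode="ecg")
        log = tl.train_log
        assert log["train_loss"].iloc[-1] < 0.1 * log["train_loss"].iloc[0]

    def test_validation_split_disjoint(self, base_model):
        assert set(base_model.train_ids).isdisjoint(base_model.val_ids)
        assert len(base_model.train_ids) + len(base_model.val_ids) == 50

    def test_training_deterministic(self, tiny_paced_library, small_spec):
        tc = TrainConfig(epochs=3, batch_size=8, seed=7)
        a = train_base(tiny_paced_library, small_spec, tc, mode="ecg")
        b = train_base(tiny_paced_library, small_spec, tc, mode="ecg")
        for k in a.model.params:
            assert np.array_equal(a.model.params[k], b.model.params[k])

    def test_channel_mismatch_raises(self, tiny_paced_library):
        spec = ModelSpec(n_channels=8, window=350)
        with pytest.raises(ValueError, match="channel"):
            train_base(tiny_paced_library, spec, TrainConfig(epochs=1), mode="ecg")


class TestTransfer:
    def test_freeze_encoder(self, base_model, tiny_vt_library):
        tc = TrainConfig(epochs=3, batch_size=8, freeze_policy="freeze_encoder", seed=0)
        tuned = transfer_finetune(base_model, tiny_vt_library, tc)
        for name in base_model.model.encoder_param_names():
            assert np.array_equal(tuned.model.params[name], base_model.model.params[name])
        changed = [
            n
            for n in base_model.model.params
            if not np.array_equal(tuned.model.params[n], base_model.model.params[n])
        ]
        assert changed  # the head did train

    def test_freeze_all_but_last(self, base_model, tiny_vt_library):
        tc = TrainConfig(epochs=3, batch_size=8, freeze_policy="freeze_all_but_last", seed=0)
        tuned = transfer_finetune(base_model, tiny_vt_library, tc)
        for name in base_model.model.params:
            same = np.array_equal(tuned.model.params[name], base_model.model.params[name])
            assert same == (name not in ("out_W", "out_b"))

    def test_policy_none_trains_everything(self, base_model, tiny_vt_library):
        tc = TrainConfig(epochs=3, batch_size=8, freeze_policy="none", seed=0)
        tuned = transfer_finetune(base_model, tiny_vt_library, tc)
        changed = [
            n
            for n in base_model.model.params
            if not np.array_equal(tuned.model.params[n], base_model.model.params[n])
        ]
        assert len(changed) == len(base_model.model.params)

    def test_all_frozen_raises(self, small_spec):
        model = small_spec.build()
        X = np.zeros((8, 16, 350), dtype=np.float32)
        Y = np.zeros((8, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="no trainable"):
            _fit(model, X, Y, list(range(8)), TrainConfig(epochs=1), frozen=set(model.params))


class TestPrediction:
    def test_memorization_localizes_training_beat(self, tiny_paced_library, tiny_cohort, small_spec):
        """After heavy overfit, a training beat maps near its true site."""
        tc = TrainConfig(epochs=300, batch_size=8, learning_rate=2e-3, patience=300, seed=2)
        tl = train_base(tiny_paced_library, small_spec, tc, mode="ecg")
        man = tiny_paced_library.manifest.set_index("sample_id")
        anat = {a.anatomy_id: a for a in tiny_cohort}
        les = []
        for sid in tl.train_ids[:10]:
            row = man.loc[sid]
            a = anat[row["anatomy_id"]]
            ts = tiny_paced_library.get_traces(sid, "ecg")
            res = predict_exit_site(
                tl, ts, a.mesh, a.uvc_field, true_xyz=row[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            )
            les.append(res.le_mm)
        assert np.mean(les) < 3 * a.mesh.target_edge_length

    def test_inference_deterministic(self, base_model, tiny_paced_library, tiny_cohort):
        sid = base_model.train_ids[0]
        a = tiny_cohort[0]
        ts = tiny_paced_library.get_traces(sid, "ecg")
        r1 = predict_exit_site(base_model, ts, a.mesh, a.uvc_field)
        r2 = predict_exit_site(base_model, ts, a.mesh, a.uvc_field)
        assert r1.pred_uvc == r2.pred_uvc
        assert np.array_equal(r1.pred_xyz, r2.pred_xyz)

    def test_channel_mismatch_raises(self, base_model, tiny_paced_library, tiny_cohort):
        sid = base_model.train_ids[0]
        ts = tiny_paced_library.get_traces(sid, "ecg")
        ts.channel_names = list(reversed(ts.channel_names))  # no silent reordering
        with pytest.raises(ValueError, match="channel"):
            predict_exit_site(base_model, ts, tiny_cohort[0].mesh, tiny_cohort[0].uvc_field)

    def test_window_resampling(self, base_model, tiny_paced_library, tiny_cohort):
        sid = base_model.train_ids[0]
        ts = tiny_paced_library.get_traces(sid, "ecg")
        short = vx.TraceSet(channel_names=ts.channel_names, samples=ts.samples[:, ::2], dt=2.0)
        res = predict_exit_site(base_model, short, tiny_cohort[0].mesh, tiny_cohort[0].uvc_field)
        assert 0 <= res.pred_uvc.z <= 1

    def test_clipping_logged(self, base_model, tiny_paced_library, tiny_cohort, caplog):
        import dataclasses

        forced = dataclasses.replace(base_model, model=base_model.model.clone())
        forced.model.params["out_b"] = np.array([5.0, -5.0, 0.0, 1.0], dtype=np.float32)
        sid = base_model.train_ids[0]
        ts = tiny_paced_library.get_traces(sid, "ecg")
        with caplog.at_level(logging.WARNING, logger="vtexit.localizer"):
            res = predict_exit_site(forced, ts, tiny_cohort[0].mesh, tiny_cohort[0].uvc_field)
        assert res.clipped
        assert res.pred_uvc.z in (0.0, 1.0) or res.pred_uvc.rho in (0.0, 1.0)
        assert any("clipped" in r.message for r in caplog.records)


def test_save_load_roundtrip(base_model, tiny_paced_library, tmp_path):
    base_model.save(tmp_path / "model")
    back = TrainedLocalizer.load(tmp_path / "model")
    _, X, _ = tiny_paced_library.load_stack("paced", "ecg")
    assert np.allclose(predict_batch(base_model, X[:5]), predict_batch(back, X[:5]))


def test_conv_regressor_gradient_check():
    """Backprop gradients match finite differences on a tiny net."""
    rng = np.random.default_rng(0)
    model = ConvRegressor(n_channels=2, window=20, conv_blocks=((3, 5, 2),), dense_sizes=(4,), n_outputs=2, param_seed=0)
    X = rng.normal(size=(3, 2, 20)).astype(np.float32)
    Y = rng.normal(size=(3, 2)).astype(np.float32)
    pred = model.forward(X, keep_cache=True)
    loss, dy = mse_loss(pred, Y)
    grads = model.backward(dy)
    for name in ("conv0_W", "fc0_b", "out_W"):
        p = model.params[name]
        idx = tuple(0 for _ in p.shape)
        eps = 1e-3
        p64 = p.astype(np.float64)
        for sign in (+1,):
            p[idx] = p64[idx] + eps
            lp = mse_loss(model.forward(X), Y)[0]
            p[idx] = p64[idx] - eps
            lm = mse_loss(model.forward(X), Y)[0]
            p[idx] = p64[idx]
            fd = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=0.05, abs=1e-4)
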