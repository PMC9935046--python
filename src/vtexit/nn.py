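"""Minimal NumPy neural-network core for the trace localizer.

Implements exactly what the reference architecture needs: strided 1-D
convolutions (im2col), ReLU, global average pooling, dense layers, mean
squared error and Adam. Forward/backward passes are fully deterministic
for a fixed parameter seed and batch order; parameters live in a flat
name -> array dict so that transfer-learning freeze policies can address
exact tensor subsets.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvRegressor", "Adam", "mse_loss"]


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class ConvRegressor:
    """Stacked strided 1-D conv blocks -> global average pool -> dense head.

    conv_blocks: sequence of (out_channels, kernel, stride); dense_sizes:
    hidden widths of the head; the output layer has n_outputs units.
    Input x is (batch, channels, time) float32.
    """

    def __init__(
        self,
        n_channels: int,
        window: int,
        conv_blocks: Iterable[tuple] = ((24, 7, 2), (32, 5, 2), (48, 5, 2)),
        dense_sizes: Iterable[int] = (32,),
        n_outputs: int = 4,
        param_seed: int = 0,
    ):
        self.n_channels = int(n_channels)
        self.window = int(window)
        self.conv_blocks = [tuple(map(int, b)) for b in conv_blocks]
        self.dense_sizes = [int(d) for d in dense_sizes]
        self.n_outputs = int(n_outputs)
        self.param_seed = int(param_seed)

        rng = np.random.default_rng(param_seed)
        self.params: dict[str, np.ndarray] = {}
        c_in, t = self.n_channels, self.window
        for i, (c_out, k, s) in enumerate(self.conv_blocks):
            t_out = (t - k) // s + 1
            if t_out < 1:
                raise ValueError("window too short for the conv stack")
            self.params[f"conv{i}_W"] = _he_init(rng, (c_out, c_in * k), c_in * k)
            self.params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            c_in, t = c_out, t_out
        d_in = c_in
        for i, d in enumerate(self.dense_sizes):
            self.params[f"fc{i}_W"] = _he_init(rng, (d, d_in), d_in)
            self.params[f"fc{i}_b"] = np.zeros(d, dtype=np.float32)
            d_in = d
        self.params["out_W"] = _he_init(rng, (self.n_outputs, d_in), d_in)
        self.params["out_b"] = np.zeros(self.n_outputs, dtype=np.float32)

    # -- parameter bookkeeping ---------------------------------------------
    def encoder_param_names(self) -> list[str]:
        return [n for n in self.params if n.startswith("conv")]

    def last_layer_param_names(self) -> list[str]:
        return ["out_W", "out_b"]

    def get_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def clone(self) -> "ConvRegressor":
        m = ConvRegressor(
            self.n_channels,
            self.window,
            self.conv_blocks,
            self.dense_sizes,
            self.n_outputs,
            self.param_seed,
        )
        m.set_params(self.params)
        return m

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """(B, C, T) -> (B, n_outputs); caches activations when training."""
        if x.shape[1] != self.n_channels or x.shape[2] != self.window:
            raise ValueError(
                f"expected input (B, {self.n_channels}, {self.window}), got {x.shape}"
            )
        cache = {"x": x} if keep_cache else None
        h = x.astype(np.float32, copy=False)
        for i, (c_out, k, s) in enumerate(self.conv_blocks):
            W, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            win = sliding_window_view(h, k, axis=2)[:, :, ::s]  # (B, C, To, K)
            col = win.transpose(0, 2, 1, 3).reshape(win.shape[0], win.shape[2], -1)
            z = col @ W.T + b  # (B, To, C_out)
            a = np.maximum(z, 0.0)
            if keep_cache:
                cache[f"col{i}"] = col
                cache[f"relu{i}"] = z > 0
                cache[f"in_shape{i}"] = h.shape
            h = a.transpose(0, 2, 1)  # (B, C_out, To)
        t_final = h.shape[2]
        g = h.mean(axis=2)  # global average pool (B, C)
        if keep_cache:
            cache["t_final"] = t_final
        a = g
        for i in range(len(self.dense_sizes)):
            W, b = self.params[f"fc{i}_W"], self.params[f"fc{i}_b"]
            z = a @ W.T + b
            if keep_cache:
                cache[f"fc_in{i}"] = a
                cache[f"fc_relu{i}"] = z > 0
            a = np.maximum(z, 0.0)
        if keep_cache:
            cache["out_in"] = a
        y = a @ self.params["out_W"].T + self.params["out_b"]
        if keep_cache:
            self._cache = cache
        return y

    def backward(self, dy: np.ndarray) -> dict:
        """Gradients w.r.t. all parameters from d(loss)/d(output)."""
        cache = self._cache
        grads = {}
        grads["out_W"] = dy.T @ cache["out_in"]
        grads["out_b"] = dy.sum(axis=0)
        da = dy @ self.params["out_W"]
        for i in reversed(range(len(self.dense_sizes))):
            dz = da * cache[f"fc_relu{i}"]
            grads[f"fc{i}_W"] = dz.T @ cache[f"fc_in{i}"]
            grads[f"fc{i}_b"] = dz.sum(axis=0)
            da = dz @ self.params[f"fc{i}_W"]
        # through global average pool
        t_final = cache["t_final"]
        dh = np.repeat(da[:, :, None] / t_final, t_final, axis=2)  # (B, C, To)
        for i in reversed(range(len(self.conv_blocks))):
            c_out, k, s = self.conv_blocks[i]
            W = self.params[f"conv{i}_W"]
            dz = dh.transpose(0, 2, 1) * cache[f"relu{i}"]  # (B, To, C_out)
            col = cache[f"col{i}"]
            grads[f"conv{i}_W"] = np.einsum("bto,btk->ok", dz, col)
            grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
            dcol = dz @ W  # (B, To, C_in*K)
            b_sz, t_out = dcol.shape[0], dcol.shape[1]
            in_shape = cache[f"in_shape{i}"]
            dcol = dcol.reshape(b_sz, t_out, in_shape[1], k)
            dx = np.zeros(in_shape, dtype=np.float32)
            for kk in range(k):
                dx[:, :, kk : kk + s * t_out : s] += dcol[:, :, :, kk].transpose(0, 2, 1)
            dh = dx
        return grads

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


class Adam:
    """Adam optimizer over a parameter dict; frozen names are skipped."""

    def __init__(self, param_names, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: None for n in param_names}
        self.v = {n: None for n in param_names}
        self.t = 0

    def step(self, params: dict, grads: dict, frozen: set = frozenset()) -> None:
        self.t += 1
        for n in params:
            if n in frozen or n not in grads:
                continue
            g = grads[n].astype(np.float32)
            if self.m[n] is None:
                self.m[n] = np.zeros_like(g)
                self.v[n] = np.zeros_like(g)
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g**2
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            params[n] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
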