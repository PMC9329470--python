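"""Minimal numpy implementation of a small multi-task convolutional regressor.

No autograd framework is assumed: convolutions are im2col matrix products and
gradients are written out by hand. The net is deliberately desk-scale (a few
conv layers, ~10^5 parameters) so nested cross-validation runs on one CPU.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetSpec", "OptimizerConfig", "MultiTaskNet", "Adam", "train_net"]


@dataclass(frozen=True)
class NetSpec:
    """Architecture of the shared trunk + linear multi-task head.

    All task heads consume the same trunk embedding; ``n_tasks`` linear outputs
    are produced by one final affine layer (equivalent to per-task heads on a
    shared trunk).
    """

    input_pool: int = 4
    channels: tuple = (8, 16, 32)
    kernels: tuple = (5, 3, 3)
    strides: tuple = (2, 2, 2)
    hidden: int = 64
    n_tasks: int = 4


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 10
    loss_weights: tuple | None = None  # default: 1.0 per task


def _conv_out(n, k, s):
    return (n + 2 * (k // 2) - k) // s + 1


def _im2col(x, k, s):
    """(N, C, H, W) -> column view (N, Ho, Wo, C, k, k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::s, ::s].transpose(0, 2, 3, 1, 4, 5)


def _col2im(dcols, x_shape, k, s):
    """Scatter-add column gradients back to the input tensor."""
    n, c, h, w = x_shape
    p = k // 2
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += d[..., i, j]
    return dxp[:, :, p : p + h, p : p + w]


class MultiTaskNet:
    """Conv trunk (ReLU, strided) -> dense ReLU -> linear multi-task output."""

    def __init__(self, spec: NetSpec, in_shape=(237, 256), seed: int = 0):
        self.spec = spec
        self.in_shape = in_shape
        rng = np.random.default_rng(seed)
        h = in_shape[0] // spec.input_pool
        w = in_shape[1] // spec.input_pool
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for li, (c_out, k, s) in enumerate(zip(spec.channels, spec.kernels, spec.strides)):
            fan_in = c_in * k * k
            self.params[f"W{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(np.float32)
            self.params[f"b{li}"] = np.zeros(c_out, dtype=np.float32)
            h, w = _conv_out(h, k, s), _conv_out(w, k, s)
            c_in = c_out
        self.flat_dim = c_in * h * w
        self.params["Wd"] = rng.normal(
            0.0, np.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, spec.hidden)).astype(np.float32)
        self.params["bd"] = np.zeros(spec.hidden, dtype=np.float32)
        self.params["Wo"] = rng.normal(
            0.0, np.sqrt(1.0 / spec.hidden), size=(spec.hidden, spec.n_tasks)).astype(np.float32)
        self.params["bo"] = np.zeros(spec.n_tasks, dtype=np.float32)

    # -- forward -----------------------------------------------------------
    def _pool_input(self, X):
        """Average-pool raw (N, H, W) input; a 4-D input is assumed pre-pooled."""
        X = np.asarray(X, dtype=self.params["bo"].dtype)
        if X.ndim == 4:
            return X
        p = self.spec.input_pool
        if X.ndim == 2:
            X = X[None]
        h = (X.shape[1] // p) * p
        w = (X.shape[2] // p) * p
        Xc = X[:, :h, :w].reshape(X.shape[0], h // p, p, w // p, p)
        return Xc.mean(axis=(2, 4))[:, None]  # (N, 1, h/p, w/p)

    def forward(self, X, want_cache: bool = False):
        a = self._pool_input(X)
        cache = {"a0": a}
        for li, (k, s) in enumerate(zip(self.spec.kernels, self.spec.strides)):
            cols = _im2col(a, k, s)
            n, ho, wo = cols.shape[:3]
            flat = cols.reshape(n * ho * wo, -1)
            z = flat @ self.params[f"W{li}"] + self.params[f"b{li}"]
            z = z.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
            a_new = np.maximum(z, 0.0)
            if want_cache:
                cache[f"flat{li}"] = flat
                cache[f"z{li}"] = z
                cache[f"in_shape{li}"] = a.shape
            a = a_new
        flat = a.reshape(a.shape[0], -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        ad = np.maximum(zd, 0.0)
        out = ad @ self.params["Wo"] + self.params["bo"]
        if want_cache:
            cache.update(conv_out_shape=a.shape, flat=flat, zd=zd, ad=ad)
            return out, cache
        return out

    def predict(self, X, batch: int = 256):
        X = np.asarray(X)
        outs = [self.forward(X[i : i + batch]) for i in range(0, X.shape[0], batch)]
        return np.concatenate(outs, axis=0)

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dout):
        g = {}
        g["Wo"] = cache["ad"].T @ dout
        g["bo"] = dout.sum(axis=0)
        dad = dout @ self.params["Wo"].T
        dzd = dad * (cache["zd"] > 0)
        g["Wd"] = cache["flat"].T @ dzd
        g["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        da = dflat.reshape(cache["conv_out_shape"])
        for li in reversed(range(len(self.spec.channels))):
            k, s = self.spec.kernels[li], self.spec.strides[li]
            dz = da * (cache[f"z{li}"] > 0)
            n, c, ho, wo = dz.shape
            dz_flat = dz.transpose(0, 2, 3, 1).reshape(n * ho * wo, c)
            g[f"W{li}"] = cache[f"flat{li}"].T @ dz_flat
            g[f"b{li}"] = dz_flat.sum(axis=0)
            if li > 0:
                dcols = (dz_flat @ self.params[f"W{li}"].T).reshape(
                    n, ho, wo, -1, k, k)
                da = _col2im(dcols, cache[f"in_shape{li}"], k, s)
        return g

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    def copy_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params):
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            gk = grads[k].astype(params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_net(X, y, X_val, y_val, spec: NetSpec, opt: OptimizerConfig,
              seed: int = 0, in_shape=(237, 256)):
    """Train one net with Adam, MSE loss, early stopping on the validation set.

    Returns ``(net, history)`` where history holds per-epoch train/val losses.
    The best-validation parameters are restored before returning.
    """
    rng = np.random.default_rng(seed)
    net = MultiTaskNet(spec, in_shape=in_shape, seed=seed)
    optimizer = Adam(net.params, lr=opt.lr)
    X = net._pool_input(X)  # pool once, not per batch
    X_val = net._pool_input(X_val)
    weights = np.asarray(opt.loss_weights if opt.loss_weights is not None
                         else np.ones(spec.n_tasks), dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    n = y.shape[0]
    best = (np.inf, net.copy_params())
    history = {"train_loss": [], "val_loss": []}
    stall = 0
    for epoch in range(opt.max_epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, opt.batch_size):
            idx = order[i : i + opt.batch_size]
            out, cache = net.forward(X[idx], want_cache=True)
            err = out - y[idx]
            loss = float(np.mean(weights * err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {nb}")
            dout = (2.0 * weights * err / err.shape[0]).astype(np.float32)
            grads = net.backward(cache, dout)
            optimizer.step(net.params, grads)
            ep_loss += loss
            nb += 1
        val_out = net.predict(X_val)
        val_loss = float(np.mean(weights * (val_out - np.asarray(y_val)) ** 2))
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best[0] - 1e-6:
            best = (val_loss, net.copy_params())
            stall = 0
        else:
            stall += 1
            if stall >= opt.patience:
                break
    net.set_params(best[1])
    return net, history
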