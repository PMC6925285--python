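"""Minimal numpy neural-network layer library with analytic backprop.

Implements exactly the pieces the acoustic transcriber and the assessment
classifier need: dense, 2-D convolution, batch norm, layer norm, clipped
ReLU, simple/GRU/LSTM recurrences (uni- and bidirectional with
variable-length masking), Glorot-normal initialization, Adam, and global
gradient-norm clipping.  Everything is float64 and deterministic given a
seeded ``numpy.random.Generator``.

Layers follow a forward/backward contract: ``forward`` caches what the
backward pass needs; ``backward`` consumes the upstream gradient, stores
parameter gradients in ``self.grads`` (same keys as ``self.params``) and
returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_normal",
    "sigmoid",
    "Adam",
    "clip_global_norm",
    "Dense",
    "Conv2D",
    "BatchNorm2D",
    "LayerNorm",
    "ClippedReLU",
    "RecurrentLayer",
    "BiRecurrentLayer",
    "log_softmax",
]


def glorot_normal(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    """Glorot (Xavier) normal initializer: N(0, 2/(fan_in + fan_out))."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    z = x - m
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Adam:
    """Adam over a flat {name: array} parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Dense(Layer):
    """Affine map applied over the last axis."""

    def __init__(self, rng, d_in: int, d_out: int):
        super().__init__()
        self.params = {"W": glorot_normal(rng, (d_in, d_out)),
                       "b": np.zeros(d_out)}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class ClippedReLU(Layer):
    """min(max(x, 0), cap) — the activation used after the conv stack."""

    def __init__(self, cap: float = 20.0):
        super().__init__()
        self.cap = cap

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < self.cap)
        return np.clip(x, 0.0, self.cap)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Conv2D(Layer):
    """2-D convolution over (batch, channels, time, freq) with 'same' padding.

    Implemented as a sum of shifted pointwise products over the kernel
    support, which keeps the backward pass a mirror-image loop.
    """

    def __init__(self, rng, c_in: int, c_out: int,
                 kernel: tuple[int, int], stride: tuple[int, int] = (1, 1)):
        super().__init__()
        kt, kf = kernel
        fan_in = c_in * kt * kf
        fan_out = c_out * kt * kf
        self.params = {
            "W": glorot_normal(rng, (c_out, c_in, kt, kf), fan_in, fan_out),
            "b": np.zeros(c_out),
        }
        self.kernel, self.stride = kernel, stride
        self.zero_grads()

    def _pad(self, t: int, f: int) -> tuple[tuple[int, int], tuple[int, int], int, int]:
        kt, kf = self.kernel
        st, sf = self.stride
        t_out = -(-t // st)
        f_out = -(-f // sf)
        pad_t = max((t_out - 1) * st + kt - t, 0)
        pad_f = max((f_out - 1) * sf + kf - f, 0)
        return ((pad_t // 2, pad_t - pad_t // 2), (pad_f // 2, pad_f - pad_f // 2), t_out, f_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        kt, kf = self.kernel
        st, sf = self.stride
        b, c, t, f = x.shape
        (pt, pf, t_out, f_out) = self._pad(t, f)
        xp = np.pad(x, ((0, 0), (0, 0), pt, pf))
        self._xp, self._x_shape, self._pads = xp, x.shape, (pt, pf)
        self._out_shape = (t_out, f_out)
        W = self.params["W"]
        y = np.zeros((b, W.shape[0], t_out, f_out))
        for i in range(kt):
            for j in range(kf):
                patch = xp[:, :, i:i + st * t_out:st, j:j + sf * f_out:sf]
                y += np.einsum("oc,bctf->botf", W[:, :, i, j], patch)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kt, kf = self.kernel
        st, sf = self.stride
        t_out, f_out = self._out_shape
        xp = self._xp
        W = self.params["W"]
        dxp = np.zeros_like(xp)
        for i in range(kt):
            for j in range(kf):
                patch = xp[:, :, i:i + st * t_out:st, j:j + sf * f_out:sf]
                self.grads["W"][:, :, i, j] += np.einsum("botf,bctf->oc", dout, patch)
                dxp[:, :, i:i + st * t_out:st, j:j + sf * f_out:sf] += np.einsum(
                    "oc,botf->bctf", W[:, :, i, j], dout)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        (pt, pf) = self._pads
        _, _, t, f = self._x_shape
        return dxp[:, :, pt[0]:pt[0] + t, pf[0]:pf[0] + f]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (batch, time, freq)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_channels), "beta": np.zeros(n_channels)}
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        axes = (0, 2, 3)
        n = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"][None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        return term * inv[None, :, None, None]


class LayerNorm(Layer):
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.eps = eps
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        red = tuple(range(dout.ndim - 1))
        self.grads["gamma"] += (dout * xhat).sum(axis=red)
        self.grads["beta"] += dout.sum(axis=red)
        dxhat = dout * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv


class RecurrentLayer(Layer):
    """Unidirectional recurrence over (batch, time, dim) inputs.

    ``cell_type``: 'gru' (sigmoid gates, tanh candidate, reset applied to
    the previous state before its candidate projection), 'lstm' (standard,
    forget-gate bias 0), or 'simple' (tanh of an affine map).
    """

    def __init__(self, rng, cell_type: str, d_in: int, d_hidden: int):
        super().__init__()
        if cell_type not in ("gru", "lstm", "simple"):
            raise ValueError(f"unknown cell type {cell_type!r}")
        self.cell_type, self.d_in, self.d_hidden = cell_type, d_in, d_hidden
        H = d_hidden
        g = {"gru": 3, "lstm": 4, "simple": 1}[cell_type]
        self.params = {
            "Wx": glorot_normal(rng, (d_in, g * H), d_in, H),
            "Wh": glorot_normal(rng, (H, g * H), H, H),
            "b": np.zeros(g * H),
        }
        self.zero_grads()

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, ids: np.ndarray | None = None) -> np.ndarray:
        """Run over (B, T, d_in) inputs, or over (B, T) token ids.

        The id path treats the input as one-hot without materializing it:
        the input projection becomes a row gather of ``Wx`` and its
        gradient a scatter-add, which is what makes token-sequence
        training cheap.  ``backward`` returns None in that mode.
        """
        if ids is not None:
            B, T = ids.shape
            x = None
        else:
            B, T, _ = x.shape
        H = self.d_hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        px = Wx[ids] + b if ids is not None else x @ Wx + b  # (B, T, g*H)
        h = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        if self.cell_type == "gru":
            Whzr, Whc = Wh[:, :2 * H], Wh[:, 2 * H:]
            for t in range(T):
                zr = sigmoid(px[:, t, :2 * H] + h @ Whzr)
                z, r = zr[:, :H], zr[:, H:]
                rh = r * h
                c = np.tanh(px[:, t, 2 * H:] + rh @ Whc)
                h_new = (1 - z) * h + z * c
                cache.append((h, z, r, c, rh))
                h = h_new
                hs[:, t] = h
        elif self.cell_type == "lstm":
            cstate = np.zeros((B, H))
            for t in range(T):
                pre = px[:, t] + h @ Wh
                i = sigmoid(pre[:, :H])
                f = sigmoid(pre[:, H:2 * H])
                o = sigmoid(pre[:, 2 * H:3 * H])
                g_ = np.tanh(pre[:, 3 * H:])
                c_new = f * cstate + i * g_
                tc = np.tanh(c_new)
                cache.append((h, cstate, i, f, o, g_, tc))
                cstate = c_new
                h = o * tc
                hs[:, t] = h
        else:  # simple
            for t in range(T):
                h_new = np.tanh(px[:, t] + h @ Wh)
                cache.append((h, h_new))
                h = h_new
                hs[:, t] = h
        self._cache = (x, ids, cache)
        return hs

    # -- backward ----------------------------------------------------------
    def backward(self, dhs: np.ndarray) -> np.ndarray | None:
        x, ids, cache = self._cache
        B, T = dhs.shape[:2]
        H = self.d_hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        g = Wx.shape[1] // H
        dpre_all = np.zeros((B, T, g * H))
        dWh = np.zeros_like(Wh)
        dh = np.zeros((B, H))
        if self.cell_type == "gru":
            Whzr, Whc = Wh[:, :2 * H], Wh[:, 2 * H:]
            for t in range(T - 1, -1, -1):
                h_prev, z, r, c, rh = cache[t]
                dht = dh + dhs[:, t]
                dz = dht * (c - h_prev)
                dc = dht * z
                dh_prev = dht * (1 - z)
                dc_pre = dc * (1 - c * c)
                drh = dc_pre @ Whc.T
                dr = drh * h_prev
                dh_prev += drh * r
                dzr_pre = dpre_all[:, t, :2 * H]
                dzr_pre[:, :H] = dz * z * (1 - z)
                dzr_pre[:, H:] = dr * r * (1 - r)
                dh_prev += dzr_pre @ Whzr.T
                dpre_all[:, t, 2 * H:] = dc_pre
                dWh[:, :2 * H] += h_prev.T @ dzr_pre
                dWh[:, 2 * H:] += rh.T @ dc_pre
                dh = dh_prev
        elif self.cell_type == "lstm":
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, o, g_, tc = cache[t]
                dht = dh + dhs[:, t]
                do = dht * tc
                dc = dht * o * (1 - tc * tc) + dc_next
                dpre = np.concatenate([
                    dc * g_ * i * (1 - i), dc * c_prev * f * (1 - f),
                    do * o * (1 - o), dc * i * (1 - g_ * g_)], axis=1)
                dc_next = dc * f
                dpre_all[:, t] = dpre
                dh = dpre @ Wh.T
                dWh += h_prev.T @ dpre
        else:
            for t in range(T - 1, -1, -1):
                h_prev, h_t = cache[t]
                dht = dh + dhs[:, t]
                dpre = dht * (1 - h_t * h_t)
                dpre_all[:, t] = dpre
                dh = dpre @ Wh.T
                dWh += h_prev.T @ dpre
        self.grads["Wh"] += dWh
        self.grads["b"] += dpre_all.sum(axis=(0, 1))
        flat = dpre_all.reshape(-1, g * H)
        if ids is not None:
            np.add.at(self.grads["Wx"], ids.reshape(-1), flat)
            return None
        self.grads["Wx"] += x.reshape(-1, x.shape[-1]).T @ flat
        return dpre_all @ Wx.T

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _reverse_indices(lengths: np.ndarray, T: int) -> np.ndarray:
    """Per-row index map reversing the first ``len`` positions of a padded row."""
    B = lengths.shape[0]
    idx = np.tile(np.arange(T), (B, 1))
    for b, L in enumerate(lengths):
        idx[b, :L] = np.arange(L - 1, -1, -1)
    return idx


class BiRecurrentLayer(Layer):
    """Bidirectional recurrence honouring per-sequence valid lengths.

    The backward direction runs over each sequence's reversed valid
    prefix, so its step ``len-1`` state summarizes the sequence from the
    end — padding can never leak into either direction's final state.
    Outputs are re-aligned to input time order and concatenated to
    (batch, time, 2*hidden).
    """

    def __init__(self, rng, cell_type: str, d_in: int, d_hidden: int):
        super().__init__()
        self.fwd = RecurrentLayer(rng, cell_type, d_in, d_hidden)
        self.bwd = RecurrentLayer(rng, cell_type, d_in, d_hidden)
        self.d_hidden = d_hidden

    @property
    def sublayers(self):
        return {"fwd": self.fwd, "bwd": self.bwd}

    def forward(self, x: np.ndarray | None, lengths: np.ndarray,
                ids: np.ndarray | None = None) -> np.ndarray:
        B, T = ids.shape if ids is not None else x.shape[:2]
        self._ridx = _reverse_indices(np.asarray(lengths), T)
        rows = np.arange(B)[:, None]
        if ids is not None:
            hf = self.fwd.forward(None, ids=ids)
            hb_rev = self.bwd.forward(None, ids=ids[rows, self._ridx])
        else:
            hf = self.fwd.forward(x)
            hb_rev = self.bwd.forward(x[rows, self._ridx])
        hb = hb_rev[rows, self._ridx]  # involution: same map un-reverses
        self._B_T = (B, T)
        self._ids_mode = ids is not None
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        H = self.d_hidden
        B, T = self._B_T
        rows = np.arange(B)[:, None]
        dhf = dout[..., :H]
        dhb = dout[..., H:][rows, self._ridx]
        dx = self.fwd.backward(dhf)
        dx_rev = self.bwd.backward(dhb)
        if self._ids_mode:
            return None
        dx += dx_rev[rows, self._ridx]
        return dx

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()


def collect_params(layers: dict[str, Layer]) -> dict[str, np.ndarray]:
    """Flatten {layer_name: Layer} into {"layer.param": array} (shared refs)."""
    flat = {}
    for name, layer in layers.items():
        if isinstance(layer, BiRecurrentLayer):
            for d, sub in layer.sublayers.items():
                for k, v in sub.params.items():
                    flat[f"{name}.{d}.{k}"] = v
        else:
            for k, v in layer.params.items():
                flat[f"{name}.{k}"] = v
    return flat


def collect_grads(layers: dict[str, Layer]) -> dict[str, np.ndarray]:
    flat = {}
    for name, layer in layers.items():
        if isinstance(layer, BiRecurrentLayer):
            for d, sub in layer.sublayers.items():
                for k, v in sub.grads.items():
                    flat[f"{name}.{d}.{k}"] = v
        else:
            for k, v in layer.grads.items():
                flat[f"{name}.{k}"] = v
    return flat
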