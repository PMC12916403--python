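"""Neural-network building blocks on top of the in-package autodiff engine.

Layers follow the usual conventions: 1-D convolutions operate on ``(B, C, T)``
maps, attention on ``(B, S, d)`` token sequences, LSTMs on ``(B, T, F)``.
All parameters are float64 and initialised from an explicit
``numpy.random.Generator`` so model construction is fully deterministic.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal container: tracks sub-modules/parameters by attribute name."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def save_checkpoint(path, module: Module, header: dict | None = None):
    """Single-file checkpoint: npz of parameters plus a JSON header."""
    state = module.state_dict()
    state["__header__"] = np.frombuffer(
        json.dumps(header or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path, module: Module) -> dict:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode()) if "__header__" in z else {}
        module.load_state_dict({k: z[k] for k in z.files if k != "__header__"})
    return header


def _uniform_init(rng: np.random.Generator, shape, fan_in: int):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = parameter(_uniform_init(rng, (in_features, out_features), in_features))
        self.bias = parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


def _pad_time(x: Tensor, left: int, right: int) -> Tensor:
    if left == 0 and right == 0:
        return x
    b, c, _ = x.shape
    parts = []
    if left:
        parts.append(Tensor(np.zeros((b, c, left))))
    parts.append(x)
    if right:
        parts.append(Tensor(np.zeros((b, c, right))))
    return ad.concat(parts, axis=2)


class Conv1d(Module):
    """1-D convolution on (B, C, T) via gather (im2col) + matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | str = "same", bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        if padding == "same":
            padding = (kernel - 1) // 2
        self.padding = int(padding)
        self.weight = parameter(_uniform_init(rng, (out_ch, in_ch * kernel), in_ch * kernel))
        self.bias = parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        xp = _pad_time(x, p, p)
        t_p = xp.shape[2]
        starts = np.arange(0, t_p - k + 1, s)
        idx = starts[:, None] + np.arange(k)[None, :]
        cols = ad.take(xp, idx, axis=2)                     # (B, C, T_out, k)
        cols = cols.transpose(0, 2, 1, 3)                   # (B, T_out, C, k)
        cols = cols.reshape(cols.shape[0], cols.shape[1], self.in_ch * k)
        y = cols @ self.weight.transpose(1, 0)              # (B, T_out, C_out)
        if self.bias is not None:
            y = y + self.bias
        return y.transpose(0, 2, 1)


class ConvTranspose1d(Module):
    """Fractionally-strided convolution: zero-dilation then stride-1 conv."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 1, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.padding = stride, padding
        self.weight = parameter(_uniform_init(rng, (in_ch, out_ch, kernel), in_ch * kernel))
        self.bias = parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b, c, t = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        if s > 1:
            z = Tensor(np.zeros((b, c, t, s - 1)))
            xd = ad.concat([x.reshape(b, c, t, 1), z], axis=3).reshape(b, c, t * s)
            xd = xd[:, :, : t * s - (s - 1)]
        else:
            xd = x
        xd = _pad_time(xd, k - 1 - p, k - 1 - p)
        # conv with flipped kernel and swapped channel roles
        w = ad.take(self.weight, np.arange(k - 1, -1, -1), axis=2)  # flip taps
        w = w.transpose(1, 0, 2).reshape(self.out_ch, self.in_ch * k)
        t_p = xd.shape[2]
        starts = np.arange(0, t_p - k + 1)
        idx = starts[:, None] + np.arange(k)[None, :]
        cols = ad.take(xd, idx, axis=2).transpose(0, 2, 1, 3)
        cols = cols.reshape(cols.shape[0], cols.shape[1], self.in_ch * k)
        y = cols @ w.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y.transpose(0, 2, 1)


class LayerNorm(Module):
    """Normalize over one axis with learnable gain/bias of that axis' width."""

    def __init__(self, dim: int, axis: int = -1, eps: float = 1e-5):
        super().__init__()
        self.axis, self.eps, self.dim = axis, eps, dim
        self.gain = parameter(np.ones(dim))
        self.bias = parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        ax = self.axis % x.ndim
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        xn = xc / ad.sqrt(var + self.eps)
        shape = [1] * x.ndim
        shape[ax] = self.dim
        return xn * self.gain.reshape(shape) + self.bias.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self._rng = np.random.default_rng(int(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = Tensor((self._rng.random(x.shape) < keep) / keep)
        return x * mask


class MaxPool1d(Module):
    def __init__(self, pool: int = 2, stride: int | None = None):
        super().__init__()
        if stride is not None and stride != pool:
            raise ValueError("only stride == pool supported")
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        b, c, t = x.shape
        t2 = (t // self.pool) * self.pool
        x = x[:, :, :t2]
        return ad.tmax(x.reshape(b, c, t2 // self.pool, self.pool), axis=3)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 causal: bool = False):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads, self.causal = d_model, n_heads, causal
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, s, d = x.shape
        h, dh = self.n_heads, d // self.n_heads
        qkv = self.qkv(x).reshape(b, s, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]            # (B, h, S, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if self.causal:
            mask = np.triu(np.full((s, s), -1e9), k=1)
            att = att + Tensor(mask)
        att = ad.softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm residual block: LN→MHSA→+x, LN→MLP(GELU, dropout)→+x."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dropout: float = 0.0, causal: bool = False):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng, causal=causal)
        self.ln2 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, ffn_dim, rng)
        self.fc2 = Linear(ffn_dim, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        h = self.drop(ad.gelu(self.fc1(self.ln2(x))))
        return x + self.fc2(h)


class LSTM(Module):
    """Single-direction LSTM over (B, T, F); returns (outputs, final hidden)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.wx = parameter(_uniform_init(rng, (input_size, 4 * hidden_size), input_size))
        self.wh = parameter(_uniform_init(rng, (hidden_size, 4 * hidden_size), hidden_size))
        self.b = parameter(np.zeros(4 * hidden_size))

    def forward(self, x: Tensor, reverse: bool = False):
        b, t, _ = x.shape
        hsz = self.hidden_size
        h = Tensor(np.zeros((b, hsz)))
        c = Tensor(np.zeros((b, hsz)))
        pre_x = x @ self.wx + self.b                     # (B, T, 4H)
        order = range(t - 1, -1, -1) if reverse else range(t)
        outs = [None] * t
        for ti in order:
            gates = pre_x[:, ti, :] + h @ self.wh
            i = ad.sigmoid(gates[:, :hsz])
            f = ad.sigmoid(gates[:, hsz:2 * hsz])
            g = ad.tanh(gates[:, 2 * hsz:3 * hsz])
            o = ad.sigmoid(gates[:, 3 * hsz:])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs[ti] = h.reshape(b, 1, hsz)
        return ad.concat(outs, axis=1), h
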