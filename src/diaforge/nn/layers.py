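"""Neural layers built on the autograd engine.

Initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so training is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, embedding, softmax, stack


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch on load")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch on load")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.w = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n: int, d: int):
        self.w = Tensor(rng.normal(0.0, 0.02, size=(n, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.w, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        """``x``: (B, L, D); ``pad_mask``: (B, L) True at padded positions."""
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
        attn = softmax(scores + Tensor(bias), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int, d_ff: int):
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, d_ff)
        self.ff2 = Linear(rng, d_ff, d_model)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.attn(x, pad_mask))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class Conv1d(Module):
    """Same-padded 1-D convolution over (B, L, C_in) via shifted slices."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, kernel: int = 3):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.w = Tensor(_glorot(rng, kernel * c_in, c_out), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        k = self.kernel
        pad = k // 2
        zeros = Tensor(np.zeros((B, pad, C)))
        xp = concat([zeros, x, zeros], axis=1)
        windows = concat([xp[:, off : off + L, :] for off in range(k)], axis=-1)
        return windows @ self.w + self.b


class LSTM(Module):
    """Single-layer LSTM; returns the full hidden sequence (B, L, H)."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.wx = Tensor(_glorot(rng, d_in, 4 * hidden), requires_grad=True)
        self.wh = Tensor(_glorot(rng, hidden, 4 * hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def __call__(
        self, x: Tensor, valid: np.ndarray | None = None, reverse: bool = False
    ) -> Tensor:
        """``valid`` (B, L): state is carried through, not updated, at padded
        positions so padded and unpadded batches give identical outputs."""
        B, L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(L - 1, -1, -1) if reverse else range(L)
        outputs: list[Tensor] = [None] * L  # type: ignore[list-item]
        for t in steps:
            gates = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            if valid is None:
                c, h = c_new, h_new
            else:
                v = valid[:, t].astype(float)[:, None]
                c = Tensor(v) * c_new + Tensor(1.0 - v) * c
                h = Tensor(v) * h_new + Tensor(1.0 - v) * h
            outputs[t] = h
        return stack(outputs, axis=1)


class BiLSTM(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.fwd = LSTM(rng, d_in, hidden)
        self.bwd = LSTM(rng, d_in, hidden)

    def __call__(self, x: Tensor, valid: np.ndarray | None = None) -> Tensor:
        return concat(
            [self.fwd(x, valid), self.bwd(x, valid, reverse=True)], axis=-1
        )
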