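"""Neural layers used by the contact predictor and the graph encoder.

All layers operate on batched tensors ``(B, n, d)``; adjacency inputs
are dense constant tensors ``(B, n, n)``.  Weight initialization is
Xavier-uniform from a caller-supplied numpy Generator, which is the
single source of randomness.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Tiny container base: collects Parameters from attributes, in order."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(
                    f"shape mismatch loading checkpoint: {p.data.shape} vs {a.shape}"
                )
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True) -> None:
        self.weight = Parameter(xavier(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5) -> None:
        self.gain = Parameter(np.ones(d))
        self.shift = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gain + self.shift


class MLP(Module):
    """Two-layer ReLU perceptron."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int,
                 d_out: int) -> None:
        self.fc1 = Linear(rng, d_in, d_hidden)
        self.fc2 = Linear(rng, d_hidden, d_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    """Standard fixed sine/cosine positional encodings, shape (length, d_model)."""
    pos = np.arange(length)[:, None].astype(float)
    i = np.arange(d_model // 2)[None, :].astype(float)
    angles = pos / np.power(10000.0, 2 * i / d_model)
    enc = np.zeros((length, d_model))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : (d_model - d_model // 2)])
    return enc


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int) -> None:
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        return x.reshape(batch, length, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        batch, length, d_model = x.shape
        q = self._split(self.wq(x), batch, length)
        k = self._split(self.wk(x), batch, length)
        v = self._split(self.wv(x), batch, length)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        mixed = (attn @ v).swapaxes(1, 2).reshape(batch, length, d_model)
        return self.wo(mixed)


class TransformerBlock(Module):
    """Pre-norm self-attention block with a ReLU feed-forward sublayer."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int,
                 d_ff: int | None = None) -> None:
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.norm2 = LayerNorm(d_model)
        self.ff = MLP(rng, d_model, d_ff or 2 * d_model, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff(self.norm2(x))


class GINLayer(Module):
    """Graph isomorphism layer: h' = MLP((1 + eps) h + A h)."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int) -> None:
        self.eps = Parameter(np.zeros(1))
        self.mlp = MLP(rng, d_in, d_out, d_out)

    def __call__(self, h: Tensor, adj: Tensor) -> Tensor:
        agg = adj @ h
        return self.mlp(h * (1.0 + self.eps) + agg).relu()


class GATLayer(Module):
    """Single-head dense graph attention layer (self-loops included)."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int) -> None:
        self.w = Linear(rng, d_in, d_out, bias=False)
        self.a_src = Linear(rng, d_out, 1, bias=False)
        self.a_dst = Linear(rng, d_out, 1, bias=False)

    def __call__(self, h: Tensor, adj: Tensor) -> Tensor:
        wh = self.w(h)                                  # (B, n, d)
        s_src = self.a_src(wh)                          # (B, n, 1)
        s_dst = self.a_dst(wh).swapaxes(-1, -2)         # (B, 1, n)
        e = (s_src + s_dst).leaky_relu(0.2)             # (B, n, n)
        n = adj.data.shape[-1]
        mask = adj.data + np.eye(n)                     # attend to self too
        e = e * mask + Tensor((1.0 - mask) * (-1e9))
        attn = e.softmax(axis=-1)
        attn = attn * mask  # exact zeros outside the neighbourhood
        attn = attn / (attn.sum(axis=-1, keepdims=True) + 1e-12)
        return (attn @ wh).relu()


class AttentionReadout(Module):
    """Attention-weighted mean pooling over nodes -> graph embedding."""

    def __init__(self, rng: np.random.Generator, d: int) -> None:
        self.proj = Linear(rng, d, d)
        self.score = Linear(rng, d, 1, bias=False)

    def __call__(self, h: Tensor) -> Tensor:
        weights = self.score(self.proj(h).tanh()).softmax(axis=-2)  # (B, n, 1)
        return (h * weights).sum(axis=-2)                           # (B, d)


class MeanReadout(Module):
    def __call__(self, h: Tensor) -> Tensor:
        return h.mean(axis=-2)
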