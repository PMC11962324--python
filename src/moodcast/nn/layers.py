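"""Transformer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from moodcast.nn.autodiff import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; masks are drawn from the rng passed at call time so
    training is deterministic given the model seed and call order."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.training = True

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads.

    ``mask`` is an additive (T_q, T_k) array (0 where allowed, -inf where
    blocked) applied to the attention logits; pass the strictly-upper-
    triangular -inf mask for causal self-attention.
    """

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.q_proj = Linear(embed_dim, embed_dim, rng)
        self.k_proj = Linear(embed_dim, embed_dim, rng)
        self.v_proj = Linear(embed_dim, embed_dim, rng)
        self.out_proj = Linear(embed_dim, embed_dim, rng)

    def _split_heads(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, Tq, D = query.shape
        Tk = key.shape[1]
        q = self._split_heads(self.q_proj(query), B, Tq)
        k = self._split_heads(self.k_proj(key), B, Tk)
        v = self._split_heads(self.v_proj(value), B, Tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, H, Tq, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.out_proj(out)


class FeedForward(Module):
    def __init__(self, embed_dim: int, ff_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(embed_dim, ff_dim, rng)
        self.fc2 = Linear(ff_dim, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def causal_mask(T: int) -> np.ndarray:
    """(T, T) additive mask: position t may attend only to positions <= t."""
    mask = np.zeros((T, T))
    mask[np.triu_indices(T, k=1)] = -np.inf
    return mask


def sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed (non-learned) sine/cosine positional encoding, (length, dim)."""
    position = np.arange(length)[:, None].astype(float)
    div = np.exp(np.arange(0, dim, 2) * (-np.log(10000.0) / dim))
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: pe[:, 1::2].shape[1]])
    return pe


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
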