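"""Minimal neural-network core in numpy.

Implements exactly what the Siamese encoder needs — linear layers,
layer normalization, multi-head self-attention, GELU, dropout, a vision
transformer built from them, and Adam/AdamW — with hand-derived backward
passes.  Everything runs in float64 on the CPU; for fixed seeds and inputs
training is bitwise reproducible.

Layers cache their most recent forward activations, so a module instance
handles one forward/backward round at a time (the usual training-step
pattern).  Gradients accumulate into ``Parameter.grad`` until
``zero_grad`` is called, which is what lets one shared-weight encoder
serve several Siamese branches in a single step.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "VisionTransformer",
    "Adam",
    "gelu",
    "gelu_grad",
]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape


class Module:
    def parameters(self) -> dict[str, Parameter]:
        """Flat name -> Parameter map, recursing into child modules."""
        out: dict[str, Parameter] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                out[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            if state[k].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {state[k].shape} vs {p.value.shape}"
                )
            p.value[...] = state[k]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(rng.normal(0.0, 0.02, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        gx = g * self.gamma.value
        self.gamma.grad += (g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        m1 = gx.mean(axis=-1, keepdims=True)
        m2 = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (gx - m1 - xhat * m2)


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden dim must be divisible by the head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, hd = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * hd)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, d = x.shape
        qkv = self.qkv.forward(x)
        q, k, v = (self._split(a) for a in np.split(qkv, 3, axis=-1))
        scale = 1.0 / math.sqrt(self.head_dim)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale  # (B, h, T, T)
        scores -= scores.max(axis=-1, keepdims=True)
        att = np.exp(scores)
        att /= att.sum(axis=-1, keepdims=True)
        out = att @ v
        self._cache = (q, k, v, att, scale)
        return self.proj.forward(self._merge(out))

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, att, scale = self._cache
        g_out = self._split(self.proj.backward(g))
        g_att = g_out @ v.transpose(0, 1, 3, 2)
        g_v = att.transpose(0, 1, 3, 2) @ g_out
        # softmax backward per row
        g_scores = att * (g_att - (g_att * att).sum(axis=-1, keepdims=True))
        g_scores *= scale
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        g_qkv = np.concatenate(
            [self._merge(g_q), self._merge(g_k), self._merge(g_v)], axis=-1
        )
        return self.qkv.backward(g_qkv)


class TransformerBlock(Module):
    """Pre-norm transformer block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.drop1 = Dropout(dropout)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 4 * dim, rng)
        self.fc2 = Linear(4 * dim, dim, rng)
        self.drop2 = Dropout(dropout)

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x)), train, rng)
        h = self.fc1.forward(self.ln2.forward(x))
        self._pre_act = h
        x = x + self.drop2.forward(self.fc2.forward(gelu(h)), train, rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        g_mlp = self.fc2.backward(self.drop2.backward(g))
        g_mlp = self.fc1.backward(g_mlp * gelu_grad(self._pre_act))
        g = g + self.ln2.backward(g_mlp)
        g_att = self.attn.backward(self.drop1.backward(g))
        return g + self.ln1.backward(g_att)


class VisionTransformer(Module):
    """ViT feature extractor: patch embedding, class token, pre-norm blocks.

    ``forward`` returns the penultimate representation (final LayerNorm of
    the pooled token); a projection head on top is the caller's business.
    ``pool`` selects the class-token readout (standard) or mean pooling
    over patch tokens.
    """

    def __init__(
        self,
        image_size: int = 224,
        patch_size: int = 16,
        n_layers: int = 2,
        n_heads: int = 4,
        hidden_dim: int = 64,
        dropout: float = 0.1,
        in_channels: int = 3,
        pool: str = "cls",
        rng: np.random.Generator | None = None,
    ):
        if image_size % patch_size:
            raise ValueError("image size must be divisible by patch size")
        if pool not in ("cls", "mean"):
            raise ValueError("pool must be 'cls' or 'mean'")
        rng = rng or np.random.default_rng(0)
        self.image_size = image_size
        self.patch_size = patch_size
        self.in_channels = in_channels
        self.n_patches = (image_size // patch_size) ** 2
        self.hidden_dim = hidden_dim
        self.pool = pool
        self.patch_embed = Linear(in_channels * patch_size**2, hidden_dim, rng)
        self.cls_token = Parameter(rng.normal(0.0, 0.02, size=(hidden_dim,)))
        self.pos_embed = Parameter(
            rng.normal(0.0, 0.02, size=(self.n_patches + 1, hidden_dim))
        )
        self.blocks = [
            TransformerBlock(hidden_dim, n_heads, dropout, rng)
            for _ in range(n_layers)
        ]
        self.ln_f = LayerNorm(hidden_dim)

    # -- patch helpers -------------------------------------------------
    def _patchify(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.patch_size
        x = x.reshape(B, C, H // p, p, W // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)
        return x.reshape(B, (H // p) * (W // p), C * p * p)

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = np.asarray(x, dtype=self.patch_embed.W.value.dtype)
        if x.ndim == 3:
            x = x[None]
        B, C, H, W = x.shape
        if C != self.in_channels or H != self.image_size or W != self.image_size:
            raise ValueError(
                f"expected ({self.in_channels}, {self.image_size}, "
                f"{self.image_size}) images, got {x.shape[1:]}"
            )
        tokens = self.patch_embed.forward(self._patchify(x))
        # one class token + one token per patch (197 for 224/16 inputs)
        assert tokens.shape[1] == self.n_patches
        cls = np.broadcast_to(self.cls_token.value, (B, 1, self.hidden_dim))
        h = np.concatenate([cls, tokens], axis=1) + self.pos_embed.value
        for blk in self.blocks:
            h = blk.forward(h, train, rng)
        if self.pool == "cls":
            pooled = h[:, 0]
        else:
            pooled = h[:, 1:].mean(axis=1)
        self._batch = B
        return self.ln_f.forward(pooled)

    def backward(self, g: np.ndarray) -> None:
        B = self._batch
        g = self.ln_f.backward(g)
        g_tokens = np.zeros((B, self.n_patches + 1, self.hidden_dim))
        if self.pool == "cls":
            g_tokens[:, 0] = g
        else:
            g_tokens[:, 1:] = g[:, None, :] / self.n_patches
        for blk in reversed(self.blocks):
            g_tokens = blk.backward(g_tokens)
        self.pos_embed.grad += g_tokens.sum(axis=0)
        self.cls_token.grad += g_tokens[:, 0].sum(axis=0)
        self.patch_embed.backward(g_tokens[:, 1:])


class Adam:
    """Adam / AdamW over a flat parameter dict.

    ``weight_decay`` applies decoupled decay (AdamW); 0 gives plain Adam.
    """

    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, p in self.params.items():
            g = p.grad
            m, v = self._m[k], self._v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0
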