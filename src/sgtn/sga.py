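"""Semantic-guided attention (SGA) block.

The block turns an s x s x c stage input into an s x s spatial weight map in
(0, 1) that multiplicatively gates the main (MSIE) branch:

1. flatten the feature map row-major into s^2 tokens of width c;
2. channel gate: x_c[i, j] = sigmoid(w_c[j]) * x[i, j] with a learnable
   per-channel weight w_c (suppresses redundant bands);
3. append a learnable per-pixel weight column w_p (length s^2), giving
   tokens of width d = c + 1;
4. run one pre-normalized transformer encoder layer — multi-head scaled
   dot-product attention and a GELU MLP, each behind layer norm and a
   residual — with NO positional encoding (the w_p column already carries
   per-position identity, and the map must stay permutation-consistent);
5. read the w_p column back out, reshape to s x s, squash with a sigmoid.

Defaults are one head and one encoder layer.
"""

from __future__ import annotations

import math

import numpy as np

from .layers import DTYPE, LayerNorm, Linear, Module, kaiming_uniform
from .nn import Tensor, concat

__all__ = ["channel_gate", "append_pixel_weight", "scaled_dot_attention",
           "MultiHeadAttention", "EncoderBlock", "extract_weight_map",
           "SGABlock"]


def channel_gate(x: Tensor, w_c: Tensor) -> Tensor:
    """Scale column j of the tokens by sigmoid(w_c[j])."""
    if x.shape[-1] != w_c.data.shape[-1]:
        raise ValueError(
            f"channel mismatch: tokens have {x.shape[-1]}, w_c has "
            f"{w_c.data.shape[-1]}")
    return x * w_c.sigmoid()


def append_pixel_weight(x_c: Tensor, w_p: Tensor) -> Tensor:
    """Concatenate the pixel-weight column as the LAST token column."""
    n_tok = x_c.shape[-2]
    col = w_p.reshape(n_tok, 1)
    if x_c.ndim == 3:   # batched tokens: broadcast w_p across the batch
        batch = x_c.shape[0]
        col = concat([col.reshape(1, n_tok, 1)] * batch, axis=0) \
            if batch > 1 else col.reshape(1, n_tok, 1)
    return concat([x_c, col], axis=-1)


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with a row-wise softmax."""
    if not (Q.shape[-1] == K.shape[-1] == V.shape[-1]):
        raise ValueError("Q, K, V widths must match")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    d_k = Q.shape[-1]
    scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    return scores.softmax(axis=-1) @ V


class MultiHeadAttention(Module):
    """Learned Q/K/V maps, h parallel attention heads, output map W_O."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"token dim {dim} not divisible by {heads} heads")
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.dim, self.heads = dim, heads

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        h = self.heads
        if h == 1:
            out = scaled_dot_attention(q, k, v)
        else:
            dk = self.dim // h
            parts = []
            for i in range(h):
                sl = (Ellipsis, slice(i * dk, (i + 1) * dk))
                parts.append(scaled_dot_attention(q[sl], k[sl], v[sl]))
            out = concat(parts, axis=-1)
        return self.wo(out)


class EncoderBlock(Module):
    """One pre-norm transformer encoder layer (attention + GELU MLP)."""

    def __init__(self, dim: int, mlp_hidden: int, heads: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_hidden, rng)
        self.fc2 = Linear(mlp_hidden, dim, rng)
        # Zero-init the residual projections so the encoder starts as the
        # identity and the extracted map starts flat at sigmoid(w_p) = 0.5;
        # otherwise the random initial map can saturate low for whole
        # classes and the sigmoid kills their gradient.
        self.attn.wo.weight.data = np.zeros_like(self.attn.wo.weight.data)
        self.fc2.weight.data = np.zeros_like(self.fc2.weight.data)

    def __call__(self, x: Tensor) -> Tensor:
        z = x + self.attn(self.ln1(x))
        return z + self.fc2(self.fc1(self.ln2(z)).gelu())


def extract_weight_map(encoded: Tensor, s: int) -> Tensor:
    """Sigmoid of the last token column, reshaped row-major to s x s."""
    if encoded.shape[-2] != s * s:
        raise ValueError(f"token count {encoded.shape[-2]} is not {s}^2")
    col = encoded[..., -1]
    shape = encoded.shape[:-2] + (s, s)
    return col.reshape(shape).sigmoid()


class SGABlock(Module):
    """Full SGA pipeline: gate -> append w_p -> encoder -> weight map."""

    def __init__(self, channels: int, s: int, rng: np.random.Generator,
                 heads: int = 1, depth: int = 1, mlp_hidden: int = 152):
        if s % 2 != 1:
            raise ValueError("patch side s must be odd")
        self.w_p = Tensor(np.zeros((s * s, 1), dtype=DTYPE), requires_grad=True)
        self.w_c = Tensor(np.zeros((1, channels), dtype=DTYPE),
                          requires_grad=True)
        self.encoders = [EncoderBlock(channels + 1, mlp_hidden, heads, rng)
                         for _ in range(depth)]
        self.channels, self.s = channels, s

    def __call__(self, x: Tensor) -> Tensor:
        """(N, s, s, c) or (s, s, c) -> weight map (N, s, s) or (s, s)."""
        s, c = self.s, self.channels
        if x.shape[-3:] != (s, s, c):
            raise ValueError(f"expected trailing shape ({s}, {s}, {c}), "
                             f"got {x.shape}")
        tokens = x.reshape(x.shape[:-3] + (s * s, c))
        gated = channel_gate(tokens, self.w_c)
        x_p = append_pixel_weight(gated, self.w_p)
        for enc in self.encoders:
            x_p = enc(x_p)
        return extract_weight_map(x_p, s)
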