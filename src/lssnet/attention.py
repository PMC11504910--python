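"""The three attention branches of the classifier body.

* **CBAM** — sequential channel attention (shared two-layer MLP on pooled
  per-channel statistics; the average- and max-pooled paths are summed after
  the first layer and pass once through the second, then a sigmoid) followed
  by spatial attention (channel-mean and channel-max maps concatenated and
  convolved to a per-pixel gate).
* **MHSA** — multi-head self-attention over the flattened spatial positions
  of the feature map, per-head weights ``softmax(Q K^T / sqrt(d/h))``.
* **Slot attention** — ``num_slots`` learned vectors compete (softmax over
  the slot axis) for pooled input tokens and are refined by a residual MLP
  for a fixed number of iterations; the branch summary is the mean slot.

Each block is shape-contract-safe for any N x C x H x W input within its
configuration constraints, and each exposes an optional ``return_state`` so
the intermediate quantities (gates, attention matrices, slots) can be
inspected and tested against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, concat, global_avg_pool, global_max_pool, softmax
from .nn import Conv2d, LayerNorm, Linear, Module

__all__ = [
    "ConfigurationError",
    "ChannelAttention", "SpatialAttention", "CBAM",
    "MultiHeadSelfAttention", "SlotAttention",
    "ChannelAttentionState", "SpatialAttentionState", "MHSAState", "SlotState",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class ChannelAttentionState:
    x_avg: np.ndarray   # (N, C) global average pool
    x_max: np.ndarray   # (N, C) global max pool
    x_fc1: np.ndarray   # (N, C/r) hidden activation, average path
    x_fc2: np.ndarray   # (N, C/r) hidden activation, max path
    m_c: np.ndarray     # (N, C) channel gate in (0, 1)
    x_c: np.ndarray     # (N, C, H, W) gated map


@dataclass
class SpatialAttentionState:
    x_avg_ch: np.ndarray  # (N, 1, H, W) channel mean
    x_max_ch: np.ndarray  # (N, 1, H, W) channel max
    m_s: np.ndarray       # (N, 1, H, W) spatial gate in (0, 1)
    x_s: np.ndarray       # (N, C, H, W) output


@dataclass
class MHSAState:
    attention: np.ndarray  # (N, h, T, T) row-stochastic per head
    output: np.ndarray     # (N, C, H, W)


@dataclass
class SlotState:
    tokens: np.ndarray     # (N, T, dim) projected input tokens
    slots_init: np.ndarray  # (N, K, dim) S0
    attn: list             # per-iteration (N, K, T), columns sum to 1 over slots
    slots: np.ndarray      # final (N, K, dim)


class ChannelAttention(Module):
    """Channel gate: M_c = sigmoid(FC2(ReLU(FC1(GAP)) + ReLU(FC1(GMP))))."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ConfigurationError(
                f"reduction {reduction} leaves no hidden units for C={channels}")
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor, return_state: bool = False):
        x_avg = global_avg_pool(x)          # (N, C)
        x_max = global_max_pool(x)
        h_avg = self.fc1(x_avg).relu()
        h_max = self.fc1(x_max).relu()
        m_c = self.fc2(h_avg + h_max).sigmoid()
        n, c = m_c.shape
        x_c = x * m_c.reshape(n, c, 1, 1)
        if return_state:
            state = ChannelAttentionState(
                x_avg=x_avg.data, x_max=x_max.data,
                x_fc1=h_avg.data, x_fc2=h_max.data,
                m_c=m_c.data, x_c=x_c.data)
            return x_c, state
        return x_c


class SpatialAttention(Module):
    """Spatial gate from the channel-pooled maps through a same-padded conv."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ConfigurationError("spatial attention kernel must be odd")
        self.conv = Conv2d(2, 1, kernel, rng, padding=kernel // 2)

    def forward(self, x_c: Tensor, return_state: bool = False):
        avg_ch = x_c.mean(axis=1, keepdims=True)   # (N, 1, H, W)
        max_ch = x_c.max(axis=1, keepdims=True)
        cat = concat([avg_ch, max_ch], axis=1)
        m_s = self.conv(cat).sigmoid()
        x_s = x_c * m_s
        if return_state:
            state = SpatialAttentionState(
                x_avg_ch=avg_ch.data, x_max_ch=max_ch.data,
                m_s=m_s.data, x_s=x_s.data)
            return x_s, state
        return x_s


class CBAM(Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16, spatial_kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class MultiHeadSelfAttention(Module):
    """Self-attention over flattened spatial tokens of an NCHW feature map."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 heads: int = 4, dim: int | None = None):
        super().__init__()
        d = channels if dim is None else dim
        if heads < 1:
            raise ConfigurationError("heads must be >= 1")
        if d % heads != 0:
            raise ConfigurationError(f"embedding dim {d} not divisible by {heads} heads")
        self.heads = heads
        self.dim = d
        self.q_proj = Linear(channels, d, rng)
        self.k_proj = Linear(channels, d, rng)
        self.v_proj = Linear(channels, d, rng)
        self.out_proj = Linear(d, channels, rng)

    def forward(self, x: Tensor, return_state: bool = False):
        n, c, hh, ww = x.shape
        t = hh * ww
        dh = self.dim // self.heads
        tokens = x.reshape(n, c, t).transpose(0, 2, 1)  # (N, T, C)

        def split(z):
            return z.reshape(n, t, self.heads, dh).transpose(0, 2, 1, 3)

        q = split(self.q_proj(tokens))
        k = split(self.k_proj(tokens))
        v = split(self.v_proj(tokens))
        # scale Q before the T x T product (cheaper than scaling the scores)
        scores = (q * (1.0 / np.sqrt(dh))) @ k.transpose(0, 1, 3, 2)
        attn = softmax(scores, axis=-1)            # rows sum to 1 over keys
        ctx = attn @ v                             # (N, h, T, dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(n, t, self.dim)
        out = self.out_proj(merged)                # (N, T, C)
        out_map = out.transpose(0, 2, 1).reshape(n, c, hh, ww)
        if return_state:
            return out_map, MHSAState(attention=attn.data, output=out_map.data)
        return out_map


class SlotAttention(Module):
    """Iterative slot refinement over pooled input tokens.

    ``mode="grid"`` (default) pools the feature map to a token_grid x
    token_grid token set before projection, preserving a nontrivial
    attention structure; ``mode="literal"`` pools to a single global token.
    Slot initial noise is sampled only in training mode — evaluation uses the
    deterministic mean initialisation S0 = mu.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 num_slots: int = 4, dim: int = 64, iters: int = 3,
                 token_grid: int = 7, mode: str = "grid"):
        super().__init__()
        if num_slots < 1 or dim < 1 or iters < 0:
            raise ConfigurationError("num_slots, dim >= 1 and iters >= 0 required")
        if mode not in ("grid", "literal"):
            raise ConfigurationError("mode must be 'grid' or 'literal'")
        self.num_slots = num_slots
        self.dim = dim
        self.iters = iters
        self.token_grid = token_grid
        self.mode = mode
        self.proj = Linear(channels, dim, rng)
        self.mu = Tensor(rng.normal(0, 0.1, size=dim), requires_grad=True)
        # sigma = softplus(rho) >= 0; rho chosen so initial sigma ~ 0.1
        self.rho = Tensor(np.full(dim, np.log(np.expm1(0.1))), requires_grad=True)
        self.norm = LayerNorm(dim)
        self.mlp_in = Linear(dim, dim, rng)
        self.mlp_out = Linear(dim, dim, rng)
        self.rng = np.random.default_rng(rng.integers(2**31))

    def _tokens(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.mode == "literal":
            pooled = global_avg_pool(x).reshape(n, 1, c)   # one token
        else:
            g = min(self.token_grid, h, w)
            grid = ag.adaptive_avg_pool2d(x, g)            # (N, C, g, g)
            pooled = grid.reshape(n, c, g * g).transpose(0, 2, 1)
        return self.proj(pooled)                           # (N, T, dim)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                return_state: bool = False):
        n = x.shape[0]
        tokens = self._tokens(x)
        sigma = (self.rho.exp() + 1.0).log()  # softplus, keeps sigma >= 0
        if self.training:
            gen = rng if rng is not None else self.rng
            eps = gen.standard_normal((n, self.num_slots, self.dim))
        else:
            eps = np.zeros((n, self.num_slots, self.dim))
        slots = self.mu + sigma * Tensor(eps)              # (N, K, dim) via broadcast
        s0 = slots.data.copy()
        attns = []
        scale = 1.0 / np.sqrt(self.dim)
        for _ in range(self.iters):
            slots = self.norm(slots)
            scores = (slots @ tokens.transpose(0, 2, 1)) * scale  # (N, K, T)
            attn = softmax(scores, axis=1)  # slots compete: columns sum to 1
            updates = attn @ tokens                                # (N, K, dim)
            slots = slots + self.mlp_out(self.mlp_in(updates).relu())
            attns.append(attn.data)
        summary = slots.mean(axis=1)                               # (N, dim)
        if return_state:
            return summary, SlotState(tokens=tokens.data, slots_init=s0,
                                      attn=attns, slots=slots.data)
        return summary
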