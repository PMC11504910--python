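"""Attention blocks vs independent brute-force oracles, plus their
normalization and shape invariants."""

import numpy as np
import pytest

from lssnet.attention import (
    CBAM,
    ChannelAttention,
    ConfigurationError,
    MultiHeadSelfAttention,
    SlotAttention,
    SpatialAttention,
)
from lssnet.autograd import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# oracles: explicit scalar loops, no shared code with the implementation
# ---------------------------------------------------------------------------


def channel_attention_oracle(x: np.ndarray, mod: ChannelAttention) -> np.ndarray:
    """Gate per channel: sigma(FC2(ReLU(FC1(gap)) + ReLU(FC1(gmp))))."""
    w1, b1 = mod.fc1.weight.data, mod.fc1.bias.data
    w2, b2 = mod.fc2.weight.data, mod.fc2.bias.data
    n, c, h, w = x.shape
    out = np.zeros_like(x)
    for i in range(n):
        gap = np.array([x[i, ch].mean() for ch in range(c)])
        gmp = np.array([x[i, ch].max() for ch in range(c)])
        h_avg = np.maximum(0.0, gap @ w1 + b1)
        h_max = np.maximum(0.0, gmp @ w1 + b1)
        m_c = _sigmoid((h_avg + h_max) @ w2 + b2)
        for ch in range(c):
            out[i, ch] = x[i, ch] * m_c[ch]
    return out


def spatial_attention_oracle(xc: np.ndarray, mod: SpatialAttention) -> np.ndarray:
    """Per-pixel gate from channel mean/max maps through a same-padded conv."""
    wt, bias = mod.conv.weight.data, mod.conv.bias.data
    k = wt.shape[-1]
    pad = k // 2
    n, c, h, w = xc.shape
    out = np.zeros_like(xc)
    for i in range(n):
        maps = np.stack([xc[i].mean(axis=0), xc[i].max(axis=0)])
        padded = np.pad(maps, ((0, 0), (pad, pad), (pad, pad)))
        gate = np.zeros((h, w))
        for r in range(h):
            for cc in range(w):
                acc = bias[0]
                for ch in range(2):
                    for dr in range(k):
                        for dc in range(k):
                            acc += padded[ch, r + dr, cc + dc] * wt[0, ch, dr, dc]
                gate[r, cc] = _sigmoid(acc)
        out[i] = xc[i] * gate
    return out


def mhsa_oracle(x: np.ndarray, mod: MultiHeadSelfAttention) -> np.ndarray:
    """Triple loop over heads, query positions, and key positions."""
    n, c, hh, ww = x.shape
    t, d, heads = hh * ww, mod.dim, mod.heads
    dh = d // heads
    out = np.zeros_like(x)
    for i in range(n):
        tokens = x[i].reshape(c, t).T  # (T, C)
        q = tokens @ mod.q_proj.weight.data + mod.q_proj.bias.data
        k = tokens @ mod.k_proj.weight.data + mod.k_proj.bias.data
        v = tokens @ mod.v_proj.weight.data + mod.v_proj.bias.data
        ctx = np.zeros((t, d))
        for a in range(heads):
            sl = slice(a * dh, (a + 1) * dh)
            for qi in range(t):
                logits = np.array([
                    q[qi, sl] @ k[kj, sl] / np.sqrt(dh) for kj in range(t)])
                weights = np.exp(logits - logits.max())
                weights /= weights.sum()
                for kj in range(t):
                    ctx[qi, sl] += weights[kj] * v[kj, sl]
        proj = ctx @ mod.out_proj.weight.data + mod.out_proj.bias.data
        out[i] = proj.T.reshape(c, hh, ww)
    return out


def slot_oracle(x: np.ndarray, mod: SlotAttention, eps: np.ndarray) -> np.ndarray:
    """Hand-unrolled refinement (literal pooling, explicit matrix arithmetic)."""
    n, c, _, _ = x.shape
    k_slots, dim = mod.num_slots, mod.dim
    wp, bp = mod.proj.weight.data, mod.proj.bias.data
    sigma = np.log1p(np.exp(mod.rho.data))
    out = np.zeros((n, dim))
    for i in range(n):
        token = (x[i].mean(axis=(1, 2)) @ wp + bp)[None, :]  # (1, dim)
        slots = mod.mu.data + sigma * eps[i]                  # (K, dim)
        for _ in range(mod.iters):
            mu_s = slots.mean(axis=1, keepdims=True)
            var_s = slots.var(axis=1, keepdims=True)
            slots_n = ((slots - mu_s) / np.sqrt(var_s + mod.norm.eps)
                       * mod.norm.gamma.data + mod.norm.beta.data)
            logits = slots_n @ token.T / np.sqrt(dim)         # (K, 1)
            attn = np.exp(logits - logits.max(axis=0, keepdims=True))
            attn /= attn.sum(axis=0, keepdims=True)           # over slots
            updates = attn @ token                            # (K, dim)
            hidden = np.maximum(
                0.0, updates @ mod.mlp_in.weight.data + mod.mlp_in.bias.data)
            slots = slots_n + hidden @ mod.mlp_out.weight.data + mod.mlp_out.bias.data
        out[i] = slots.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


@pytest.mark.usefixtures("float64_engine")
def test_channel_attention_matches_loop_oracle(rng):
    mod = ChannelAttention(4, reduction=2, rng=np.random.default_rng(0))
    x = rng.normal(size=(1, 4, 2, 2))
    got, state = mod(Tensor(x), return_state=True)
    np.testing.assert_allclose(got.data, channel_attention_oracle(x, mod),
                               atol=1e-6)
    assert np.all(state.m_c > 0) and np.all(state.m_c < 1)


@pytest.mark.usefixtures("float64_engine")
def test_spatial_attention_matches_conv_oracle(rng):
    mod = SpatialAttention(3, rng=np.random.default_rng(1))
    x = rng.normal(size=(1, 3, 4, 4))
    got, state = mod(Tensor(x), return_state=True)
    np.testing.assert_allclose(got.data, spatial_attention_oracle(x, mod),
                               atol=1e-6)
    assert np.all(np.abs(state.x_s) <= np.abs(x) + 1e-12)


@pytest.mark.usefixtures("float64_engine")
def test_mhsa_matches_triple_loop_oracle(rng):
    mod = MultiHeadSelfAttention(8, np.random.default_rng(2), heads=2)
    x = rng.normal(size=(2, 8, 2, 2))
    got = mod(Tensor(x))
    np.testing.assert_allclose(got.data, mhsa_oracle(x, mod), atol=1e-5)


@pytest.mark.usefixtures("float64_engine")
def test_slot_attention_matches_unrolled_oracle(rng):
    mod = SlotAttention(3, np.random.default_rng(3), num_slots=2, dim=3,
                        iters=1, mode="literal")
    x = rng.normal(size=(1, 3, 1, 1))
    eps = rng.normal(size=(1, 2, 3))

    class FixedGen:
        def standard_normal(self, shape):
            assert shape == eps.shape
            return eps

    got = mod(Tensor(x), rng=FixedGen())
    np.testing.assert_allclose(got.data, slot_oracle(x, mod, eps), atol=1e-6)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_cbam_zero_input_zero_output(rng):
    mod = CBAM(4, np.random.default_rng(4), reduction=2, spatial_kernel=3)
    out = mod(Tensor(np.zeros((2, 4, 3, 3))))
    np.testing.assert_array_equal(out.data, 0.0)


def test_cbam_attenuates_elementwise(rng):
    mod = CBAM(6, np.random.default_rng(5), reduction=2, spatial_kernel=3)
    x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
    out = mod(Tensor(x))
    assert np.all(np.abs(out.data) <= np.abs(x) + 1e-6)


def test_cbam_equals_sequential_composition(rng):
    mod = CBAM(4, np.random.default_rng(6), reduction=2, spatial_kernel=3)
    x = Tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32))
    combined = mod(x)
    staged = mod.spatial(mod.channel(x))
    np.testing.assert_array_equal(combined.data, staged.data)


def test_spatially_constant_input_gives_constant_gate(rng):
    mod = SpatialAttention(3, np.random.default_rng(7))
    x = np.tile(rng.normal(size=(1, 3, 1, 1)), (1, 1, 5, 5)).astype(np.float32)
    _, state = mod(Tensor(x), return_state=True)
    # interior only: zero same-padding breaks the symmetry at the border
    inner = state.m_s[..., 1:-1, 1:-1]
    np.testing.assert_allclose(inner, np.full_like(inner, inner.flat[0]),
                               atol=1e-6)


def test_mhsa_rows_sum_to_one(rng):
    mod = MultiHeadSelfAttention(8, np.random.default_rng(8), heads=4)
    x = rng.normal(size=(2, 8, 3, 2)).astype(np.float32)
    _, state = mod(Tensor(x), return_state=True)
    np.testing.assert_allclose(state.attention.sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_single_token_attention_is_one(rng):
    mod = MultiHeadSelfAttention(4, np.random.default_rng(9), heads=2)
    x = rng.normal(size=(1, 4, 1, 1)).astype(np.float32)
    out, state = mod(Tensor(x), return_state=True)
    np.testing.assert_allclose(state.attention, 1.0, atol=1e-7)
    # single token: output = Linear_out(Linear_V(x))
    tok = x[0, :, 0, 0]
    v = tok @ mod.v_proj.weight.data + mod.v_proj.bias.data
    expect = v @ mod.out_proj.weight.data + mod.out_proj.bias.data
    np.testing.assert_allclose(out.data[0, :, 0, 0], expect, atol=1e-5)


def test_mhsa_dim_not_divisible_rejected():
    with pytest.raises(ConfigurationError):
        MultiHeadSelfAttention(6, np.random.default_rng(0), heads=4)


def test_channel_attention_reduction_too_large_rejected():
    with pytest.raises(ConfigurationError):
        ChannelAttention(4, reduction=8, rng=np.random.default_rng(0))


def test_slot_columns_sum_to_one_over_slots(rng):
    mod = SlotAttention(5, np.random.default_rng(10), num_slots=3, dim=4,
                        iters=2, token_grid=2)
    x = rng.normal(size=(2, 5, 6, 6)).astype(np.float32)
    _, state = mod(Tensor(x), rng=np.random.default_rng(1), return_state=True)
    for attn in state.attn:
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


def test_slot_zero_iters_returns_mean_initial_slots(rng):
    mod = SlotAttention(3, np.random.default_rng(11), num_slots=2, dim=4,
                        iters=0)
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    out, state = mod(Tensor(x), rng=np.random.default_rng(2), return_state=True)
    np.testing.assert_allclose(out.data, state.slots_init.mean(axis=1),
                               atol=1e-7)


def test_slot_sigma_zero_is_deterministic(rng):
    mod = SlotAttention(3, np.random.default_rng(12), num_slots=2, dim=4,
                        iters=2, token_grid=2)
    mod.rho.data = np.full_like(mod.rho.data, -40.0)  # softplus -> ~0
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    a = mod(Tensor(x), rng=np.random.default_rng(1))
    b = mod(Tensor(x), rng=np.random.default_rng(999))
    np.testing.assert_allclose(a.data, b.data, atol=1e-7)


def test_eval_mode_slot_attention_is_deterministic(rng):
    mod = SlotAttention(3, np.random.default_rng(13), num_slots=2, dim=4,
                        iters=2, token_grid=2).eval()
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    np.testing.assert_array_equal(mod(Tensor(x)).data, mod(Tensor(x)).data)


@pytest.mark.parametrize("shape", [(1, 2, 1, 1), (2, 4, 3, 5), (1, 6, 7, 2)])
def test_shape_contracts(shape, rng):
    """All three blocks return documented shapes for arbitrary NCHW inputs."""
    n, c, h, w = shape
    gen = np.random.default_rng(14)
    x = Tensor(rng.normal(size=shape).astype(np.float32))
    assert CBAM(c, gen, reduction=1, spatial_kernel=3)(x).shape == shape
    assert MultiHeadSelfAttention(c, gen, heads=c)(x).shape == shape
    sam = SlotAttention(c, gen, num_slots=2, dim=5, iters=1, token_grid=3)
    assert sam(x, rng=np.random.default_rng(0)).shape == (n, 5)


@pytest.mark.usefixtures("float64_engine")
def test_every_block_parameter_receives_gradient(rng):
    """Generic input: nonzero gradient reaches every learnable parameter."""
    gen = np.random.default_rng(15)
    blocks = [
        CBAM(4, gen, reduction=2, spatial_kernel=3),
        MultiHeadSelfAttention(4, gen, heads=2),
        SlotAttention(4, gen, num_slots=3, dim=4, iters=2, token_grid=2),
    ]
    for block in blocks:
        x = Tensor(rng.normal(size=(2, 4, 4, 4)), requires_grad=True)
        out = block(x)
        (out * Tensor(rng.normal(size=out.shape))).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, f"{type(block).__name__}.{name}"
            assert np.any(p.grad != 0), f"{type(block).__name__}.{name}"
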