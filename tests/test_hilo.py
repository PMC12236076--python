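"""HiLo attention branch semantics and AIFI parameter neutrality."""

import numpy as np
import pytest

from phrfdet.nn import Tensor, no_grad
from phrfdet.hilo import (AIFI, HiLoAttention, HiLoSpec,
                          MultiHeadSelfAttention,
                          sincos_position_embedding_2d)


def _tokens(rng, b, h, w, d):
    return Tensor(rng.standard_normal((b, h * w, d)).astype(np.float32))


def test_output_shape_preserved(rng):
    spec = HiLoSpec(dim=32, num_heads=4, lo_fraction=0.5, window=2)
    for h, w in [(6, 6), (5, 7), (4, 10)]:
        x = _tokens(rng, 2, h, w, 32)
        assert HiLoAttention(spec)(x, h, w).shape == (2, h * w, 32)


def test_single_window_equals_global_attention_on_hi_heads(rng):
    """With s = H = W the Hi-Fi branch is full attention over all tokens."""
    d, heads = 32, 4
    spec_win = HiLoSpec(dim=d, num_heads=heads, lo_fraction=0.0, window=4)
    attn = HiLoAttention(spec_win)
    x = _tokens(rng, 1, 4, 4, d)
    windowed = attn(x, 4, 4)

    # reference: plain MHSA sharing the same projection weights
    ref = MultiHeadSelfAttention(d, heads)
    qkv = attn.hi_qkv.weight.data  # (3d, d)
    ref.q.weight.data = qkv[:d]
    ref.k.weight.data = qkv[d:2 * d]
    ref.v.weight.data = qkv[2 * d:]
    ref.q.bias.data = attn.hi_qkv.bias.data[:d]
    ref.k.bias.data = attn.hi_qkv.bias.data[d:2 * d]
    ref.v.bias.data = attn.hi_qkv.bias.data[2 * d:]
    ref.out.weight.data = attn.hi_proj.weight.data
    ref.out.bias.data = attn.hi_proj.bias.data
    np.testing.assert_allclose(windowed.data, ref(x).data, atol=1e-5)


def test_window_locality_blocks_cross_window_influence(rng):
    """Perturbing a token in one window leaves other windows unchanged."""
    spec = HiLoSpec(dim=16, num_heads=4, lo_fraction=0.0, window=2)
    attn = HiLoAttention(spec)
    h = w = 4
    x = rng.standard_normal((1, h * w, 16)).astype(np.float32)
    base = attn(Tensor(x), h, w).data
    x2 = x.copy()
    x2[0, 0] += 5.0  # token (0,0) lives in the top-left window
    pert = attn(Tensor(x2), h, w).data
    grid = np.abs(pert - base).reshape(h, w, 16).sum(-1)
    assert grid[:2, :2].sum() > 0
    np.testing.assert_array_equal(grid[2:, :], 0)
    np.testing.assert_array_equal(grid[:, 2:], 0)


def test_lofi_window1_equals_global_attention(rng):
    """s=1 pooling is the identity, so Lo-Fi is plain global attention."""
    spec = HiLoSpec(dim=16, num_heads=4, lo_fraction=1.0, window=1)
    attn = HiLoAttention(spec)
    x = _tokens(rng, 1, 3, 5, 16)
    out = attn(x, 3, 5)
    ref = MultiHeadSelfAttention(16, 4)
    ref.q.weight.data = attn.lo_q.weight.data
    ref.q.bias.data = attn.lo_q.bias.data
    kv = attn.lo_kv.weight.data
    ref.k.weight.data = kv[:16]
    ref.v.weight.data = kv[16:]
    ref.k.bias.data = attn.lo_kv.bias.data[:16]
    ref.v.bias.data = attn.lo_kv.bias.data[16:]
    ref.out.weight.data = attn.lo_proj.weight.data
    ref.out.bias.data = attn.lo_proj.bias.data
    np.testing.assert_allclose(out.data, ref(x).data, atol=1e-5)


def test_lofi_pooled_key_count(rng):
    spec = HiLoSpec(dim=16, num_heads=4, lo_fraction=1.0, window=2)
    attn = HiLoAttention(spec)
    h, w = 6, 8
    x = _tokens(rng, 1, h, w, 16)
    grid = x.reshape(1, h, w, 16)
    pooled = grid.reshape(1, h // 2, 2, w // 2, 2, 16).mean(axis=4).mean(axis=2)
    assert pooled.shape[1] * pooled.shape[2] == (h // 2) * (w // 2)
    assert attn(x, h, w).shape == (1, h * w, 16)


def test_constant_field_gives_constant_output(rng):
    spec = HiLoSpec(dim=16, num_heads=4, lo_fraction=0.5, window=2)
    attn = HiLoAttention(spec)
    x = Tensor(np.ones((1, 16, 16), dtype=np.float32))
    out = attn(x, 4, 4).data
    assert np.allclose(out, out[:, :1, :], atol=1e-5)


def test_lofi_pooling_is_permutation_invariant_within_cells(rng):
    """Permuting tokens inside one s x s pooling cell leaves Lo-Fi K/V alone."""
    spec = HiLoSpec(dim=16, num_heads=4, lo_fraction=1.0, window=2)
    attn = HiLoAttention(spec)
    h = w = 4
    x = rng.standard_normal((1, h * w, 16)).astype(np.float32)
    xs = x.reshape(h, w, 16).copy()
    # swap the two top-left-cell rows (tokens (0,0)/(0,1) with (1,0)/(1,1))
    xs[[0, 1], :2] = xs[[1, 0], :2]
    out_a = attn(Tensor(x), h, w).data
    out_b = attn(Tensor(xs.reshape(1, h * w, 16)), h, w).data
    # outputs at unpermuted query positions must agree exactly
    np.testing.assert_allclose(
        out_a.reshape(h, w, 16)[2:], out_b.reshape(h, w, 16)[2:], atol=1e-5
    )


@pytest.mark.parametrize("a", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_projection_parameters_never_exceed_standard_attention(a):
    d, heads = 256, 8
    hilo = HiLoAttention(HiLoSpec(dim=d, num_heads=heads, lo_fraction=a, window=2))
    mhsa = MultiHeadSelfAttention(d, heads)
    assert hilo.param_count() <= mhsa.param_count()


def test_aifi_swap_does_not_increase_parameters():
    base = AIFI(256, 8, 1024, attention="mhsa")
    swapped = AIFI(256, 8, 1024, attention="hilo")
    assert swapped.param_count() <= base.param_count()


def test_aifi_preserves_shape(rng):
    for kind in ("mhsa", "hilo"):
        aifi = AIFI(64, 4, 128, attention=kind,
                    hilo=HiLoSpec(64, 4, 0.5, 2))
        x = Tensor(rng.standard_normal((1, 64, 5, 5)).astype(np.float32))
        with no_grad():
            assert aifi(x).shape == (1, 64, 5, 5)


def test_sincos_table_shape_and_range():
    emb = sincos_position_embedding_2d(5, 7, 64)
    assert emb.shape == (35, 64)
    assert np.abs(emb).max() <= 1.0


def test_lofi_cost_scales_with_pooled_token_count(rng):
    """Doubling the pooling window quarters the pooled-KV token count, so the
    KV-dependent multiply-accumulate cost scales by exactly 1/4."""
    from phrfdet.nn import no_grad
    from phrfdet.nn import modules as _m

    def macs(window):
        spec = HiLoSpec(dim=32, num_heads=4, lo_fraction=1.0, window=window)
        attn = HiLoAttention(spec)
        x = _tokens(rng, 1, 16, 16, 32)
        c = [0]
        _m.set_mac_counter(c)
        try:
            with no_grad():
                attn(x, 16, 16)
        finally:
            _m.set_mac_counter(None)
        return c[0]

    m2, m4, m8 = macs(2), macs(4), macs(8)
    assert m2 > m4 > m8
    # cost = fixed query-side part + (pooled tokens) x per-token KV part:
    # successive window doublings change pooled tokens 64 -> 16 -> 4
    assert (m2 - m4) == 4 * (m4 - m8)
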