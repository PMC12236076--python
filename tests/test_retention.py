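"""Spatial decay mask, MaSA locality/complexity, RetBlock and RetC3."""

import numpy as np
import pytest

from phrfdet.nn import Tensor, no_grad
from phrfdet.nn import modules as _m
from phrfdet.retention import (MaSAttention, RetBlock, RetBlockSpec, RetC3,
                               RepC3, spatial_decay_mask, default_gammas)


class TestDecayMask:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            spatial_decay_mask(3, 0.5),
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
        )

    def test_no_decay_limit_is_all_ones(self):
        np.testing.assert_array_equal(spatial_decay_mask(4, 1.0), np.ones((4, 4)))

    def test_single_token(self):
        np.testing.assert_array_equal(spatial_decay_mask(1, 0.3), [[1.0]])

    @pytest.mark.parametrize("length,gamma", [(2, 0.9), (7, 0.6), (16, 0.98)])
    def test_symmetry_diagonal_and_range(self, length, gamma):
        m = spatial_decay_mask(length, gamma)
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), np.ones(length))
        assert (m > 0).all() and (m <= 1).all()

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            spatial_decay_mask(4, 0.0)
        with pytest.raises(ValueError):
            RetBlockSpec(dim=16, heads=4, gammas=(0.5, 0.5, 1.5, 0.5))


def _masa(dim=16, heads=4, gammas=None):
    return MaSAttention(RetBlockSpec(dim=dim, heads=heads,
                                     gammas=gammas or default_gammas(heads)))


def test_masa_preserves_shape(rng):
    attn = _masa()
    x = Tensor(rng.standard_normal((2, 6 * 5, 16)).astype(np.float32))
    assert attn(x, 6, 5).shape == (2, 30, 16)


def test_masa_single_token_is_value_projection_path(rng):
    attn = _masa()
    x = Tensor(rng.standard_normal((1, 1, 16)).astype(np.float32))
    out = attn(x, 1, 1)
    ref = attn.out(attn.v(x))  # softmax over one element is 1
    np.testing.assert_allclose(out.data, ref.data, atol=1e-6)


def test_axis_attention_gamma_one_equals_plain_softmax_attention(rng):
    """An all-ones mask followed by renormalisation is a no-op."""
    attn = _masa()
    L, dh = 6, 4
    q = Tensor(rng.standard_normal((2, L, dh)).astype(np.float32))
    k = Tensor(rng.standard_normal((2, L, dh)).astype(np.float32))
    v = Tensor(rng.standard_normal((2, L, dh)).astype(np.float32))
    out = attn._axis_attention(q, k, v, np.ones((L, L), dtype=np.float32))
    # independent numpy oracle: scaled-dot-product softmax attention
    s = (q.data @ k.data.transpose(0, 2, 1)) / np.sqrt(dh)
    e = np.exp(s - s.max(-1, keepdims=True))
    p = e / e.sum(-1, keepdims=True)
    np.testing.assert_allclose(out.data, p @ v.data, atol=1e-5)


def test_masa_gamma_to_zero_approaches_per_token_transform(rng):
    """As γ ↓ 0 every token attends only to itself along each axis."""
    x = Tensor(rng.standard_normal((1, 16, 16)).astype(np.float32))
    weights = None
    errs = []
    for g in (0.5, 0.1, 0.01, 1e-4):
        attn = _masa(gammas=(g,) * 4)
        if weights is None:
            weights = [(n, p.data.copy()) for n, p in attn.named_parameters()]
        else:
            for (n, p), (_, w) in zip(attn.named_parameters(), weights):
                p.data = w.copy()
        out = attn(x, 4, 4)
        ref = attn.out(attn.v(x))
        errs.append(np.abs(out.data - ref.data).max())
    assert all(a >= b for a, b in zip(errs, errs[1:]))  # monotone convergence
    assert errs[-1] < 5e-3


def _count_macs(fn):
    c = [0]
    _m.set_mac_counter(c)
    try:
        with no_grad():
            fn()
    finally:
        _m.set_mac_counter(None)
    return c[0]


def test_masa_cost_subquadratic_vs_full_2d_attention(rng):
    """Score cost grows ~N^1.5 for the decomposed form vs N^2 for full 2-D."""
    from phrfdet.hilo import MultiHeadSelfAttention

    sizes = [8, 16, 32]
    masa_costs, full_costs = [], []
    for s in sizes:
        x = Tensor(rng.standard_normal((1, s * s, 16)).astype(np.float32))
        masa_costs.append(_count_macs(lambda: _masa()(x, s, s)))
        full = MultiHeadSelfAttention(16, 4)
        full_costs.append(_count_macs(lambda: full(x)))
    for i in range(1, len(sizes)):
        growth_masa = masa_costs[i] / masa_costs[i - 1]
        growth_full = full_costs[i] / full_costs[i - 1]
        assert growth_masa < growth_full
    # effective exponents in the token count N over the measured range
    n_ratio = (sizes[-1] / sizes[0]) ** 2
    exp_masa = np.log(masa_costs[-1] / masa_costs[0]) / np.log(n_ratio)
    exp_full = np.log(full_costs[-1] / full_costs[0]) / np.log(n_ratio)
    assert exp_masa < 1.6 < exp_full  # sub-quadratic vs quadratic-dominated


class TestRetBlock:
    def test_shape_preservation(self, rng):
        block = RetBlock(RetBlockSpec(dim=16, heads=4))
        x = Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32))
        assert block(x).shape == x.shape

    def test_zeroed_weights_reduce_to_identity(self, rng):
        block = RetBlock(RetBlockSpec(dim=16, heads=4))
        x = Tensor(rng.standard_normal((1, 16, 5, 5)).astype(np.float32))
        # zero MaSA output projection and FFN: only the positional term remains
        block.attn.out.weight.data[...] = 0
        block.attn.out.bias.data[...] = 0
        block.fc2.weight.data[...] = 0
        block.fc2.bias.data[...] = 0
        out = block(x)
        pos = x + block.cpe(x)
        np.testing.assert_allclose(out.data, pos.data, atol=1e-6)
        # with the positional conv zeroed too: exact identity
        block.cpe.weight.data[...] = 0
        block.cpe.bias.data[...] = 0
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_parameter_count_matches_closed_form(self):
        d, heads, ratio = 24, 4, 2.0
        block = RetBlock(RetBlockSpec(dim=d, heads=heads, ffn_ratio=ratio))
        hidden = int(d * ratio)
        expected = (
            d * 9 + d                      # depthwise 3x3 positional conv
            + 4 * (d * d + d)              # q,k,v,out projections
            + 2 * 2 * d                    # two layer norms
            + d * hidden + hidden          # ffn in
            + hidden * d + d               # ffn out
        )
        assert block.param_count() == expected


class TestRetC3:
    def test_shape_preserved_across_pyramid_levels(self, rng):
        spec = RetBlockSpec(dim=16, heads=4)
        block = RetC3(32, 16, spec)
        for hw in (8, 12, 20):
            x = Tensor(rng.standard_normal((1, 32, hw, hw)).astype(np.float32))
            assert block(x).shape == (1, 16, hw, hw)

    def test_depth_zero_degenerates_to_bottleneck_pair(self, rng):
        spec = RetBlockSpec(dim=16, heads=4, depth_in_retc3=0)
        block = RetC3(32, 16, spec)
        x = Tensor(rng.standard_normal((1, 32, 6, 6)).astype(np.float32))
        import phrfdet.nn as nn

        ref = block.cv3(nn.concat([block.cv1(x), block.cv2(x)], axis=1))
        np.testing.assert_allclose(block(x).data, ref.data, atol=1e-6)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError):
            RetC3(33, 16)

    def test_lighter_than_repc3_at_default_widths(self):
        from phrfdet.model import ModelConfig

        cfg = ModelConfig()
        rep = RepC3(512, 256, cfg.fusion_depth, cfg.repc3_expansion)
        ret = RetC3(512, 256, RetBlockSpec(dim=cfg.retc3_dims[0],
                                           heads=cfg.retc3_heads))
        assert ret.param_count() < rep.param_count()
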