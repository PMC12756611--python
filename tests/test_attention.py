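"""StarMA attention block: operation contracts, invariants and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import _oracles as O
from starma.attention import (
    StarMA,
    StarMAConfig,
    StarStructure,
    StackedConvBranch,
    axial_pool,
    group_features,
    ungroup_features,
)
from starma.errors import ConfigurationError, ContractError
from starma.nn.autodiff import Tensor


def _t(a):
    return Tensor(np.asarray(a, dtype=np.float32))


# ---------------------------------------------------------------------------
# feature grouping
# ---------------------------------------------------------------------------

class TestGrouping:
    def test_single_group_is_identity(self, rng):
        x = rng.normal(size=(3, 6, 4, 5)).astype(np.float32)
        g = group_features(_t(x), 1)
        assert g.values.shape == x.shape
        np.testing.assert_array_equal(g.values.data, x)

    def test_contiguous_channel_assignment(self):
        x = np.zeros((1, 4, 2, 2), dtype=np.float32)
        for c in range(4):
            x[0, c] = c
        g = group_features(_t(x), 2)
        assert g.values.shape == (2, 2, 2, 2)
        # group 0 holds source channels {0,1}, group 1 holds {2,3}
        np.testing.assert_array_equal(g.values.data[0, 0], 0)
        np.testing.assert_array_equal(g.values.data[0, 1], 1)
        np.testing.assert_array_equal(g.values.data[1, 0], 2)
        np.testing.assert_array_equal(g.values.data[1, 1], 3)

    def test_round_trip_bit_exact(self, rng):
        x = rng.normal(size=(2, 8, 3, 3)).astype(np.float32)
        back = ungroup_features(group_features(_t(x), 4))
        assert np.array_equal(back.data, x)
        # index bookkeeping: channel k of group g == source channel g*(C/G)+k
        g = group_features(_t(x), 4)
        for grp in range(4):
            for k in range(2):
                np.testing.assert_array_equal(
                    g.values.data[grp, k], x[0, grp * 2 + k]) if False else None
        gv = g.values.data.reshape(2, 4, 2, 3, 3)
        for b in range(2):
            for grp in range(4):
                for k in range(2):
                    np.testing.assert_array_equal(gv[b, grp, k],
                                                  x[b, grp * 2 + k])

    def test_indivisible_channels_error_names_both(self):
        with pytest.raises(ConfigurationError, match="C=6.*G=4"):
            group_features(_t(np.zeros((1, 6, 2, 2))), 4)


# ---------------------------------------------------------------------------
# axial pooling
# ---------------------------------------------------------------------------

class TestAxialPool:
    def test_constant_input(self):
        pair = axial_pool(_t(np.full((1, 2, 3, 4), 7.0)))
        np.testing.assert_allclose(pair.x_h.data, 7.0)
        np.testing.assert_allclose(pair.x_w.data, 7.0)

    def test_hand_means_2x2(self):
        pair = axial_pool(_t([[[[1.0, 2.0], [3.0, 4.0]]]]))
        np.testing.assert_allclose(pair.x_h.data.ravel(), [1.5, 3.5])
        np.testing.assert_allclose(pair.x_w.data.ravel(), [2.0, 3.0])

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(1, 3, 5, 7)).astype(np.float32)
        pair = axial_pool(_t(x))
        oh, ow = O.axial_pool(x)
        np.testing.assert_allclose(pair.x_h.data, oh, atol=1e-6)
        np.testing.assert_allclose(pair.x_w.data, ow, atol=1e-6)


# ---------------------------------------------------------------------------
# star-shape structure
# ---------------------------------------------------------------------------

class TestStarStructure:
    def test_zero_input_zero_weights_gives_half_gates(self):
        star = StarStructure(3)
        for p in star.parameters():
            p.data = np.zeros_like(p.data)
        gates = star(_t(np.zeros((2, 3, 4, 1))), _t(np.zeros((2, 3, 1, 5))))
        np.testing.assert_allclose(gates.gate_h.data, 0.5)
        np.testing.assert_allclose(gates.gate_w.data, 0.5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        star = StarStructure(2, rng=np.random.default_rng(0))
        for p in star.parameters():  # larger-than-init weights; gates stay in (0,1)
            p.data = rng.normal(size=p.data.shape).astype(np.float32) * 0.5
        gates = star(_t(rng.normal(size=(2, 2, 6, 1)) * 3),
                     _t(rng.normal(size=(2, 2, 1, 3)) * 3))
        for g in (gates.gate_h.data, gates.gate_w.data):
            assert np.all(g > 0) and np.all(g < 1)

    def test_matches_straight_line_oracle(self):
        star = StarStructure(2, rng=np.random.default_rng(7))
        rng = np.random.default_rng(8)
        x_h = rng.normal(size=(3, 2, 4, 1)).astype(np.float32)
        x_w = rng.normal(size=(3, 2, 1, 6)).astype(np.float32)
        gates = star(_t(x_h), _t(x_w))
        weights = {f"star.{k}": v for k, v in star.state_dict().items()}
        oh, ow = O.star_structure(x_h, x_w, weights)
        np.testing.assert_allclose(gates.gate_h.data, oh, atol=1e-6)
        np.testing.assert_allclose(gates.gate_w.data, ow, atol=1e-6)
        assert gates.gate_h.data.shape == (3, 2, 4, 1)
        assert gates.gate_w.data.shape == (3, 2, 1, 6)


# ---------------------------------------------------------------------------
# branch outputs
# ---------------------------------------------------------------------------

class TestCCIB:
    def test_zero_input_gives_zero(self):
        m = StarMA(8, StarMAConfig(groups=2, seed=0))
        xg = group_features(_t(np.zeros((1, 8, 3, 3))), 2)
        np.testing.assert_array_equal(m.ccib(xg).data, 0.0)

    def test_attenuates_any_input(self, rng):
        m = StarMA(8, StarMAConfig(groups=2, seed=1))
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32) * 4
        xg = group_features(_t(x), 2)
        x1 = m.ccib(xg)
        assert np.max(np.abs(x1.data)) <= np.max(np.abs(x))
        assert np.all(np.abs(x1.data) <= np.abs(xg.values.data) + 1e-7)

    def test_matches_loop_oracle(self):
        m = StarMA(8, StarMAConfig(groups=4, seed=2))
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        xg = group_features(_t(x), 4)
        x1 = m.ccib(xg)
        weights = {k: v for k, v in m.state_dict().items()}
        expected = O.ccib(xg.values.data, weights)
        np.testing.assert_allclose(x1.data, expected, atol=1e-5)


class TestSCB:
    def test_output_shape_equals_input_shape(self):
        scb = StackedConvBranch(4, rng=np.random.default_rng(0))
        out = scb(_t(np.random.default_rng(1).normal(size=(1, 4, 7, 5))))
        assert out.shape == (1, 4, 7, 5)

    def test_zero_input_zero_bias_gives_zero(self):
        scb = StackedConvBranch(3, rng=np.random.default_rng(0))
        out = scb(_t(np.zeros((2, 3, 6, 6))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_matches_naive_convolution_oracle(self):
        scb = StackedConvBranch(1, rng=np.random.default_rng(5))
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
        out = scb(_t(x))
        weights = {f"scb.{k}": v for k, v in scb.state_dict().items()}
        expected = O.scb(x, weights)
        np.testing.assert_allclose(out.data, expected, atol=1e-5)


class TestCSFA:
    def _module(self, cp=3, seed=0):
        return StarMA(cp * 2, StarMAConfig(groups=2, seed=seed))

    def test_constant_branches_closed_form(self, rng):
        m = self._module()
        c1, c2 = 0.7, -0.3
        n, c, h, w = 4, 3, 5, 5
        xg_arr = rng.normal(size=(n, c, h, w)).astype(np.float32)
        xg = group_features(_t(xg_arr.reshape(2, 6, h, w)), 2)
        x1 = _t(np.full((n, c, h, w), c1))
        x2 = _t(np.full((n, c, h, w), c2))
        maps = m.csfa_maps(x1, x2)
        np.testing.assert_allclose(maps.x11.data, 1 / 3, atol=1e-6)
        np.testing.assert_allclose(maps.x22.data, 1 / 3, atol=1e-6)
        np.testing.assert_allclose(maps.x12.data, c2, atol=1e-5)
        np.testing.assert_allclose(maps.x21.data, c1, atol=1e-5)
        np.testing.assert_allclose(maps.weight.data, c1 + c2, atol=1e-5)
        out = m.csfa(x1, x2, xg)
        sig = 1 / (1 + np.exp(-(c1 + c2)))
        np.testing.assert_allclose(out.data, sig * xg.values.data, atol=1e-5)

    def test_zero_branches_give_half_gate(self, rng):
        m = self._module()
        xg_arr = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
        xg = group_features(_t(xg_arr), 2)
        z = _t(np.zeros((4, 3, 4, 4)))
        out = m.csfa(z, z, xg)
        np.testing.assert_allclose(out.data, 0.5 * xg.values.data, atol=1e-6)

    def test_softmax_rows_sum_to_one(self, rng):
        m = self._module(seed=4)
        x1 = _t(rng.normal(size=(6, 3, 4, 4)))
        x2 = _t(rng.normal(size=(6, 3, 4, 4)))
        maps = m.csfa_maps(x1, x2)
        np.testing.assert_allclose(maps.x11.data.sum(axis=2), 1.0, atol=1e-6)
        np.testing.assert_allclose(maps.x22.data.sum(axis=2), 1.0, atol=1e-6)

    def test_matches_algorithm_oracle(self):
        m = self._module(seed=9)
        rng = np.random.default_rng(10)
        x1a = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        x2a = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        xga = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        from starma.attention import GroupedFeatureMap
        xg = GroupedFeatureMap(_t(xga), 2, 6)
        out = m.csfa(_t(x1a), _t(x2a), xg)
        expected = O.csfa(x1a, x2a, xga, m.state_dict())
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_shape_mismatch_raises(self):
        m = self._module()
        with pytest.raises(ContractError):
            m.csfa_maps(_t(np.zeros((2, 3, 4, 4))), _t(np.zeros((2, 3, 5, 4))))


# ---------------------------------------------------------------------------
# full block
# ---------------------------------------------------------------------------

class TestStarMA:
    def test_shape_preserved(self, rng):
        m = StarMA(16, StarMAConfig(seed=0))
        x = rng.normal(size=(2, 16, 8, 8)).astype(np.float32)
        assert m(_t(x)).shape == x.shape

    def test_zero_input_zero_output(self):
        m = StarMA(16, StarMAConfig(seed=1))
        out = m(_t(np.zeros((1, 16, 6, 6))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_determinism_same_seed_bit_identical(self, rng):
        x = rng.normal(size=(1, 16, 5, 5)).astype(np.float32)
        outs = []
        for _ in range(2):
            m = StarMA(16, StarMAConfig(seed=33))
            m.eval()
            outs.append(m(_t(x)).data)
        assert np.array_equal(outs[0], outs[1])

    def test_gradient_reaches_every_parameter(self, rng):
        m = StarMA(16, StarMAConfig(groups=4, seed=2))
        x = Tensor(rng.normal(size=(2, 16, 6, 6)).astype(np.float32),
                   requires_grad=True)
        m(x).sum().backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"

    @given(st.sampled_from([(1, 8, 3, 5), (2, 16, 4, 4), (1, 24, 7, 2)]),
           st.integers(0, 3))
    def test_attenuation_property(self, shape, seed):
        rng = np.random.default_rng(seed)
        m = StarMA(shape[1], StarMAConfig(groups=4, seed=seed))
        m.eval()
        x = rng.normal(size=shape).astype(np.float32) * 3
        out = m(_t(x))
        assert out.shape == shape
        assert np.all(np.abs(out.data) <= np.abs(x) + 1e-6)
        nz = x != 0
        assert np.all(np.abs(out.data[nz]) < np.abs(x[nz]) + 1e-6)

    @pytest.mark.parametrize("shape,groups", [((2, 16, 8, 8), 8),
                                              ((1, 32, 7, 5), 8),
                                              ((3, 8, 14, 14), 8)])
    def test_matches_end_to_end_oracle(self, shape, groups):
        m = StarMA(shape[1], StarMAConfig(groups=groups, seed=17))
        m.eval()
        x = np.random.default_rng(18).normal(size=shape).astype(np.float32)
        out = m(_t(x))
        expected = O.starma(m, x)
        assert np.max(np.abs(out.data - expected)) < 1e-5

    def test_linear_strip_upsample_supported(self, rng):
        m = StarMA(8, StarMAConfig(groups=2, star_upsample="linear", seed=5))
        x = rng.normal(size=(1, 8, 5, 7)).astype(np.float32)
        out = m(_t(x))
        assert out.shape == x.shape
        assert np.all(np.abs(out.data) <= np.abs(x) + 1e-6)


class TestAblation:
    def _x(self):
        return np.random.default_rng(40).normal(size=(1, 8, 5, 5)).astype(np.float32)

    def test_all_flags_equal_default(self):
        x = self._x()
        full = StarMA(8, StarMAConfig(groups=2, seed=6))
        flagged = StarMA(8, StarMAConfig(groups=2, seed=6), use_ccib=True,
                         use_sss=True, use_scb=True, use_csfa=True)
        full.eval(), flagged.eval()
        assert np.array_equal(full(_t(x)).data, flagged(_t(x)).data)

    def test_disabling_sss_removes_exactly_the_star_factors(self):
        x = self._x()
        cfg = StarMAConfig(groups=2, seed=7)
        with_sss = StarMA(8, cfg)
        without = StarMA(8, cfg, use_sss=False)
        xg_w = group_features(_t(x), 2)
        x1_with = with_sss.ccib(xg_w).data
        x1_without = without.ccib(xg_w).data
        gates = with_sss.star(*_axial(x))
        restored = x1_without * gates.gate_h.data * gates.gate_w.data
        np.testing.assert_allclose(x1_with, restored, atol=1e-6)

    def test_no_csfa_uses_sigmoid_sum_gate(self):
        x = self._x()
        cfg = StarMAConfig(groups=2, seed=8)
        m = StarMA(8, cfg, use_csfa=False)
        m.eval()
        xg = group_features(_t(x), 2)
        x1, x2 = m.ccib(xg).data, m.scb(xg).data
        gate = 1 / (1 + np.exp(-(x1 + x2)))
        expected = (gate * xg.values.data).reshape(x.shape)
        np.testing.assert_allclose(m(_t(x)).data, expected, atol=1e-6)

    def test_single_branch_variants_run(self):
        x = self._x()
        for flags in [dict(use_scb=False, use_csfa=False),
                      dict(use_ccib=False, use_sss=False, use_csfa=False)]:
            m = StarMA(8, StarMAConfig(groups=2, seed=9), **flags)
            m.eval()
            out = m(_t(x))
            assert out.shape == x.shape
            np.testing.assert_allclose(out.data, O.starma(m, x), atol=1e-5)

    def test_invalid_flag_combinations(self):
        with pytest.raises(ConfigurationError):
            StarMA(8, StarMAConfig(groups=2), use_ccib=False, use_scb=False)
        with pytest.raises(ConfigurationError):
            StarMA(8, StarMAConfig(groups=2), use_scb=False, use_csfa=True)


def _axial(x):
    from starma.attention import axial_pool as ap
    pair = ap(group_features(_t(x), 2))
    return pair.x_h, pair.x_w
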