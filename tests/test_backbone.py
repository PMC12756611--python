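"""StarMA Net backbone: block contracts, spatial schedule, ablation, configs."""

import dataclasses
import math

import numpy as np
import pytest

import _oracles as O
from starma.attention import StarMAConfig
from starma.backbone import (
    BackboneConfig,
    BaseBlock,
    NormalBlock,
    StarMABlock,
    apply_ablation,
    build_starma_net,
)
from starma.errors import ConfigurationError, ContractError, DegenerateInputError
from starma.nn import AdamW
from starma.nn import functional as F
from starma.nn.autodiff import Tensor


def _t(a):
    return Tensor(np.asarray(a, dtype=np.float32))


def tiny_config(**kw):
    """Smallest config exercising every component (G=2, 14x14-free)."""
    defaults = dict(stem_widths=(4, 6), stage_widths=(8, 10, 12), trunk_width=12,
                    mlp_ratio=2.0, out_widths=(16, 16), num_classes=3,
                    starma=StarMAConfig(groups=2, seed=0))
    defaults.update(kw)
    return BackboneConfig(**defaults)


class TestBaseBlock:
    def test_shape_contract(self, rng):
        blk = BaseBlock(4, 6, rng=np.random.default_rng(0))
        blk.eval()
        out = blk(_t(rng.normal(size=(1, 4, 8, 8))))
        assert out.shape == (1, 6, 4, 4)

    def test_deterministic_at_zero_drop_path(self, rng):
        blk = BaseBlock(3, 5, drop_path=0.0, rng=np.random.default_rng(1))
        blk.eval()
        x = _t(rng.normal(size=(2, 3, 6, 6)))
        assert np.array_equal(blk(x).data, blk(x).data)

    def test_pooling_takes_block_maxima(self):
        """With an identity-like kernel the pooled output equals the 2x2 block
        maxima of the BN/GELU image (checked by explicit loop)."""
        blk = BaseBlock(1, 1, rng=np.random.default_rng(2))
        blk.eval()
        w = np.zeros((1, 1, 3, 3), dtype=np.float32)
        w[0, 0, 1, 1] = 1.0  # identity kernel
        blk.conv.weight.data = w
        blk.conv.bias.data = np.zeros(1, dtype=np.float32)
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        out = blk(_t(x)).data
        # eval-mode BN with fresh running stats, then exact GELU
        bn = (x - 0.0) / np.sqrt(1.0 + 1e-5)
        gelu_img = np.vectorize(
            lambda v: 0.5 * v * (1 + math.erf(v / math.sqrt(2))))(bn)
        for i in range(2):
            for j in range(2):
                expected = gelu_img[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
                assert abs(out[0, 0, i, j] - expected) < 1e-5

    def test_degenerate_spatial_input_raises(self):
        blk = BaseBlock(2, 2, rng=np.random.default_rng(3))
        with pytest.raises(DegenerateInputError):
            blk(_t(np.zeros((1, 2, 1, 4))))


class TestStarMABlock:
    def _block(self, seed=0, drop=0.0):
        return StarMABlock(8, 16, StarMAConfig(groups=2, seed=seed),
                           drop_path=drop, rng=np.random.default_rng(seed))

    def test_shape_preserved(self, rng):
        blk = self._block()
        blk.eval()
        assert blk(_t(rng.normal(size=(2, 8, 6, 6)))).shape == (2, 8, 6, 6)

    def test_full_drop_reduces_to_gelu_of_input(self, rng):
        """With both residual branches force-dropped the block is GELU(x)."""
        blk = self._block()
        blk.drop_attn.forced_mask = np.zeros(2, dtype=np.float32)
        blk.drop_mlp.forced_mask = np.zeros(2, dtype=np.float32)
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        out = blk(_t(x))
        np.testing.assert_allclose(out.data, F.gelu(_t(x)).data, atol=1e-7)

    def test_matches_equation_transcription(self, rng):
        """x_a -> D_A -> x_attn -> M -> D_M chain transcribed step by step."""
        blk = self._block(seed=4)
        blk.eval()
        x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
        out = blk(_t(x)).data

        def conv(m, v):
            return O.conv2d(v, m.weight.data, m.bias.data,
                            padding=(m.padding[0], m.padding[1]))

        h = conv(blk.conv2, conv(blk.conv1, x))
        # eval-mode BN with fresh running stats (mean 0, var 1)
        gamma = blk.bn.weight.data.reshape(1, -1, 1, 1)
        beta = blk.bn.bias.data.reshape(1, -1, 1, 1)
        h = h / np.sqrt(1.0 + 1e-5) * gamma + beta
        h = O.starma(blk.attn, h)
        x_a = conv(blk.conv3, O.gelu(h))
        x_attn = x_a + x                                   # DropPath rate 0
        m = conv(blk.mlp_down, O.gelu(conv(blk.mlp_up, x_attn)))
        expected = O.gelu(m + x_attn)
        assert np.max(np.abs(out - expected)) < 1e-5

    def test_channel_mismatch_raises(self):
        with pytest.raises(ContractError):
            self._block()(_t(np.zeros((1, 6, 5, 5))))


class TestStarMANet:
    def test_end_to_end_logits_shape(self, rng):
        model = build_starma_net(tiny_config())
        model.eval()
        out = model(_t(rng.normal(size=(1, 3, 64, 64))))
        assert out.shape == (1, 3)
        assert np.all(np.isfinite(out.data))

    def test_any_multiple_of_32_input(self, rng):
        model = build_starma_net(tiny_config())
        model.eval()
        assert model(_t(rng.normal(size=(2, 3, 32, 32)))).shape == (2, 3)

    def test_spatial_schedule_at_224(self):
        model = build_starma_net(tiny_config())
        model.eval()
        capture = {}
        from starma.complexity import Profiler
        with Profiler(model, shapes_only=True):
            model(_t(np.zeros((1, 3, 224, 224))), capture=capture)
        sizes = {k: v.shape[2] for k, v in capture.items()}
        assert sizes["stem"] == 112
        assert sizes["base1"] == 56
        assert sizes["base2"] == 28
        assert sizes["base3"] == 14
        assert sizes["starma_blocks.3"] == 14
        assert sizes["normal"] == 14
        assert sizes["down"] == 7

    def test_one_optimizer_step_updates_every_parameter(self, rng):
        model = build_starma_net(tiny_config())
        before = {k: v.copy() for k, v in model.state_dict().items()}
        opt = AdamW(model.parameters(), lr=1e-3)
        x = _t(rng.normal(size=(4, 3, 32, 32)))
        loss = F.cross_entropy(model(x), np.array([0, 1, 2, 0]))
        loss.backward()
        opt.step()
        after = model.state_dict()
        params = dict(model.named_parameters())
        unchanged = [k for k in params if np.array_equal(before[k], after[k])]
        assert unchanged == [], f"parameters not updated: {unchanged}"

    def test_determinism_with_fixed_weights(self, rng):
        model = build_starma_net(tiny_config())
        model.eval()
        x = _t(rng.normal(size=(1, 3, 32, 32)))
        assert np.array_equal(model(x).data, model(x).data)

    def test_width_multiplier_half_quarters_parameters(self):
        from starma.complexity import count_params
        full = count_params(build_starma_net(BackboneConfig()))
        half = count_params(build_starma_net(BackboneConfig(width_multiplier=0.5)))
        assert 3.5 < full / half < 4.5

    def test_indivisible_width_raises(self):
        with pytest.raises(ConfigurationError):
            build_starma_net(tiny_config(stage_widths=(8, 10, 13), trunk_width=13))


class TestAblationMatrix:
    ROWS = [  # the published ablation rows: (ccib, sss, scb, csfa)
        (True, True, False, False),
        (False, False, True, False),
        (True, True, True, False),
        (True, False, True, True),
        (True, True, True, True),
    ]

    def test_all_rows_build_and_run(self, rng):
        x = _t(rng.normal(size=(1, 3, 64, 64)))
        for ccib, sss, scb, csfa in self.ROWS:
            model = apply_ablation(tiny_config(use_ccib=ccib, use_sss=sss,
                                               use_scb=scb, use_csfa=csfa))
            model.eval()
            out = model(x)
            assert out.shape == (1, 3)
            assert np.all(np.isfinite(out.data))

    def test_full_flags_identical_to_default(self, rng):
        x = _t(rng.normal(size=(1, 3, 32, 32)))
        a = apply_ablation(tiny_config())
        b = apply_ablation(tiny_config(use_ccib=True, use_sss=True,
                                       use_scb=True, use_csfa=True))
        a.eval(), b.eval()
        assert np.array_equal(a(x).data, b(x).data)

    def test_all_branches_disabled_raises(self):
        with pytest.raises(ConfigurationError):
            apply_ablation(tiny_config(use_ccib=False, use_scb=False,
                                       use_csfa=False))


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(drop_path=0.1, width_multiplier=0.5, use_sss=False)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = BackboneConfig.from_yaml(path)
        assert loaded == cfg
        assert loaded.config_hash() == cfg.config_hash()

    def test_hash_changes_with_fields(self):
        assert (tiny_config().config_hash()
                != tiny_config(drop_path=0.2).config_hash())

    def test_scaled_widths_round_to_group_multiples(self):
        cfg = BackboneConfig(width_multiplier=0.3)
        widths = cfg.scaled_widths()
        g = cfg.starma.groups
        for w in (*widths["stem"], *widths["stages"], widths["trunk"],
                  *widths["out"]):
            assert w % g == 0 and w >= g

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            BackboneConfig(num_classes=1)
        with pytest.raises(ConfigurationError):
            BackboneConfig(drop_path=1.0)
        with pytest.raises(ConfigurationError):
            BackboneConfig(width_multiplier=0.0)
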