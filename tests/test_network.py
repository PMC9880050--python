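"""Architecture contracts: shapes, concatenation bookkeeping, parameter
accounting, ablation isolation, and the shallow-decoder property."""

import numpy as np
import pytest

from fpmnet.config import ConfigurationError, NetworkConfig, default_config
from fpmnet.nn import (Conv2d, DepthwiseConv2d, FPMNet, ShapeError, build_fpb,
                       build_network, concat_eq1, concat_eq2,
                       count_parameters, depthwise_concat)
from fpmnet.nn.layers import ConvTranspose2d
from fpmnet.nn.network import FeaturePreservingBlock


class TestConfigValidation:
    def test_divisibility_error_names_dimension(self):
        cfg = NetworkConfig(input_height=100, input_width=96)
        with pytest.raises(ConfigurationError, match="input_height=100"):
            cfg.validate()

    def test_schedule_length_mismatch(self):
        cfg = NetworkConfig(fdb_blocks=3)
        with pytest.raises(ConfigurationError, match="fdb_channel_schedule"):
            cfg.validate()

    def test_two_classes_required(self):
        with pytest.raises(ConfigurationError, match="num_classes"):
            NetworkConfig(num_classes=3).validate()

    def test_default_yaml_roundtrip(self, tmp_path):
        cfg = default_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        assert NetworkConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestConcatenation:
    def test_channel_arithmetic_and_lossless_slices(self):
        rng = np.random.default_rng(0)
        a = rng.random((1, 3, 8, 8))
        b = rng.random((1, 5, 8, 8))
        k = concat_eq1(a, b)
        assert k.shape == (1, 8, 8, 8)
        # every input channel recoverable bit-exact by slicing
        assert np.array_equal(k[:, :3], a)
        assert np.array_equal(k[:, 3:], b)
        assert np.array_equal(k[:, 0], a[:, 0])
        assert np.array_equal(k[:, 3], b[:, 0])

    def test_concat_zero_map_keeps_existing_channels(self):
        rng = np.random.default_rng(1)
        a = rng.random((1, 4, 6, 6))
        z = np.zeros((1, 2, 6, 6))
        out = concat_eq1(a, z)
        assert np.array_equal(out[:, :4], a)

    def test_eq2_order_and_fpb_ablation(self):
        rng = np.random.default_rng(2)
        kp = rng.random((1, 4, 8, 8))
        fp = rng.random((1, 2, 8, 8))
        fi = rng.random((1, 3, 8, 8))
        m = concat_eq2(kp, fp, fi)
        assert m.shape[1] == 9
        assert np.array_equal(m[:, 4:6], fp)
        m2 = concat_eq2(kp, None, fi)
        assert m2.shape[1] == 7
        assert np.array_equal(m2[:, 4:], fi)

    def test_associativity(self):
        rng = np.random.default_rng(3)
        x, y, z = (rng.random((1, 2, 4, 4)) for _ in range(3))
        assert np.array_equal(depthwise_concat(depthwise_concat(x, y), z),
                              depthwise_concat(x, y, z))

    def test_spatial_mismatch_reports_both_sizes(self):
        with pytest.raises(ShapeError, match=r"\(8, 8\).*\(4, 4\)"):
            concat_eq1(np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 4, 4)))


class TestForwardContracts:
    def test_output_resolution_and_mask_codomain(self, tiny_config):
        net = build_network(tiny_config, seed=0)
        rng = np.random.default_rng(0)
        img = rng.random((32, 32, 3)).astype(np.float32)
        out = net.predict(img)
        assert out.prob_map.shape == (32, 32, 2)
        assert out.mask.shape == (32, 32)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert np.array_equal(out.mask, out.prob_map[:, :, 1] >= 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_probabilities_normalized_across_seeds(self, tiny_config, seed):
        net = build_network(tiny_config, seed=seed)
        rng = np.random.default_rng(seed + 100)
        out = net.predict(rng.random((32, 32, 3)).astype(np.float32))
        assert np.allclose(out.prob_map.sum(axis=2), 1.0, atol=1e-6)

    def test_inference_deterministic(self, tiny_config):
        net = build_network(tiny_config, seed=4)
        img = np.random.default_rng(5).random((32, 32, 3)).astype(np.float32)
        a = net.predict(img).prob_map
        b = net.predict(img).prob_map
        assert np.array_equal(a, b)

    def test_wrong_input_size_raises(self, tiny_config):
        net = build_network(tiny_config, seed=0)
        with pytest.raises(ShapeError):
            net.predict(np.zeros((16, 16, 3), dtype=np.float32))

    def test_minimal_single_block_config(self):
        cfg = NetworkConfig(
            input_height=16, input_width=16, fdb_blocks=1,
            fdb_channel_schedule=[4], convs_per_block=1, pooling_ops=0,
            fub_channel_schedule=[], fpb_channels=2, fif_channels=2,
            depthwise_separable_from_block=1)
        net = build_network(cfg, seed=0)
        out = net.predict(np.random.default_rng(0).random(
            (16, 16, 3)).astype(np.float32))
        assert out.prob_map.shape == (16, 16, 2)

    def test_feature_bundle_full_resolution_at_final_concat(self, tiny_config):
        net = build_network(tiny_config, seed=1)
        img = np.random.default_rng(1).random((32, 32, 3)).astype(np.float32)
        out = net.predict(img, return_features=True)
        fb = out.features
        for name in ("f_p", "f_ei", "k_prime", "f_if"):
            assert getattr(fb, name).shape[2:] == (32, 32), name
        assert fb.m_dense.shape[1] == (fb.k_prime.shape[1]
                                       + fb.f_p.shape[1] + fb.f_if.shape[1])


class TestParameterAccounting:
    def test_standard_conv_closed_form(self):
        conv = Conv2d(1, 8, 3, np.random.default_rng(0))
        assert conv.num_parameters() == 3 * 3 * 1 * 8 + 8  # == 80

    def test_depthwise_separable_closed_form_and_saving(self):
        rng = np.random.default_rng(0)
        dw = DepthwiseConv2d(8, 3, rng)
        pw = Conv2d(8, 16, 1, rng)
        assert dw.num_parameters() + pw.num_parameters() == 224
        assert Conv2d(8, 16, 3, rng).num_parameters() == 1168

    @pytest.mark.parametrize("c_in,c_out,k", [(2, 4, 3), (8, 8, 3), (16, 4, 5)])
    def test_separable_strictly_cheaper(self, c_in, c_out, k):
        rng = np.random.default_rng(0)
        sep = (DepthwiseConv2d(c_in, k, rng).num_parameters()
               + Conv2d(c_in, c_out, 1, rng).num_parameters())
        assert sep < Conv2d(c_in, c_out, k, rng).num_parameters()

    def test_default_budget_ledger(self):
        cfg = default_config()
        with_fpb = count_parameters(build_network(cfg, seed=0))
        without = count_parameters(
            build_network(cfg.with_updates(use_fpb=False), seed=0))
        assert 2.2e6 <= with_fpb <= 2.45e6
        assert 2.2e6 <= without <= 2.44e6
        assert 1 <= with_fpb - without <= 2e4

    def test_ablation_isolation(self, tiny_config):
        """All non-FPB blocks are bit-identical between the with/without-FPB
        builds; only the FPB branch and the classification head's f_p input
        channels differ."""
        net_a = build_network(tiny_config, seed=0)
        net_b = build_network(tiny_config.with_updates(use_fpb=False), seed=0)
        pa = dict(net_a.named_parameters())
        pb = dict(net_b.named_parameters())
        fpb_names = {n for n in pa if n.startswith(("fpb", "dilated_conv"))}
        assert fpb_names and not any(n in pb for n in fpb_names)
        for name in pb:
            if name.startswith("pcb"):
                continue
            assert np.array_equal(pa[name].value, pb[name].value), name
        # head shapes differ by exactly the f_p channel count
        assert (pa["pcb.weight"].value.shape[1]
                - pb["pcb.weight"].value.shape[1]) == tiny_config.fpb_channels

    def test_shallow_decoder_property(self, tiny_config):
        for cfg in (tiny_config, default_config()):
            net = build_network(cfg, seed=0)
            assert net.fub_conv_layer_count() < net.fdb_conv_layer_count()


class TestFeaturePreservingBlock:
    def test_layer_census(self, tiny_config):
        fpb = build_fpb(tiny_config)
        assert fpb.layer_census() == {"convolutions": 3,
                                      "transposed_convolutions": 1}
        n_tconv = sum(isinstance(m, ConvTranspose2d)
                      for m in fpb.body.modules)
        assert n_tconv == 1

    def test_restores_full_resolution(self, tiny_config):
        net = build_network(tiny_config, seed=0)
        half = np.random.default_rng(0).random(
            (1, tiny_config.fpb_channels, 16, 16)).astype(np.float32)
        out = net.fpb.forward(half)
        assert out.shape[2:] == (32, 32)

    def test_requires_fpb_enabled(self, tiny_config):
        with pytest.raises(ConfigurationError):
            build_fpb(tiny_config.with_updates(use_fpb=False))

    def test_parameter_count_closed_form(self):
        """FPB parameters equal the hand-summed per-layer formulas:
        3 x (conv k*k*c*c + c + BN 2c) + (tconv 2*2*c*c + c + BN 2c)."""
        cfg = NetworkConfig(fpb_channels=16)
        fpb = FeaturePreservingBlock(16, 3, np.random.default_rng(0))
        c = 16
        expected = 3 * (9 * c * c + c + 2 * c) + (4 * c * c + c + 2 * c)
        assert fpb.num_parameters() == expected
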