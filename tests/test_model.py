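"""Architecture fidelity: shapes, parameter counts, equivariance, identity."""

import numpy as np
import pytest

from pdeseray import (ConfigurationError, ModelConfig, build_model,
                      count_trainable_parameters, encoder_feature_shapes,
                      load_checkpoint, save_checkpoint)
from pdeseray.model import ConvNeXtBlock
from pdeseray.nn.tensor import Tensor

TINY = dict(input_size=64, embed_dim=8, stage_depths=(1, 1, 1, 1),
            stage_dims=(8, 16, 32, 64), decoder_channels=(8, 8, 8, 8, 8))


def closed_form_parameter_count(cfg: ModelConfig) -> int:
    """Independent layer-by-layer analytic parameter count."""
    k, p, e = cfg.embed_dim, cfg.patch_size, cfg.expansion_ratio
    dims, dec = cfg.stage_dims, cfg.decoder_channels

    def block(c):  # 7x7 dwconv(+b) + LN + pw1(+b) + pw2(+b) + gamma
        return (c * 49 + c) + 2 * c + (c * e * c + e * c) \
            + (e * c * c + c) + c

    total = cfg.input_channels * k * p * p + k + 2 * k  # stem conv + LN
    total += sum(cfg.stage_depths[i] * block(dims[i]) for i in range(4))
    for i in range(3):  # inter-stage downsampling: LN + 2x2 conv
        total += 2 * dims[i] + dims[i] * dims[i + 1] * 4 + dims[i + 1]
    # decoder: per stage two (bias-free conv + BN) blocks
    ins = (dims[3], dec[0], dec[1], dec[2], dec[3])
    skips = (dims[2], dims[1], dims[0], cfg.embed_dim, 0)
    for cin, skip, cout in zip(ins, skips, dec):
        if cfg.upsample_mode == "transposed_conv":
            total += cin * cin * 4 + cin
        total += (cin + skip) * cout * 9 + 2 * cout + cout * cout * 9 + 2 * cout
    total += dec[4] * 1 * 9 + 1  # head (biased)
    return total


class TestConfigValidation:
    def test_default_config_is_valid(self):
        cfg = ModelConfig()
        assert cfg.stage_depths == (3, 3, 9, 3)
        assert cfg.embed_dim == 96

    @pytest.mark.parametrize("kwargs,match", [
        (dict(input_size=100), "divisible by 32"),
        (dict(stage_depths=(1, 1, 1)), "length 4"),
        (dict(decoder_channels=(8, 8, 8)), "length 5"),
        (dict(stage_dims=(96, 192, 384, 700)), "double"),
        (dict(embed_dim=48), "embed_dim"),
        (dict(upsample_mode="bilinear"), "upsample_mode"),
    ])
    def test_invalid_configs_name_the_violated_invariant(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            ModelConfig(**kwargs)


class TestStructure:
    def test_default_stage_depths_and_stem_width(self):
        model = build_model(ModelConfig(input_size=64), seed=0)
        assert len(model.stages[2]) == 9
        assert model.stem_conv.weight.shape == (96, 3, 4, 4)
        assert [len(s) for s in model.stages] == [3, 3, 9, 3]

    def test_tiny_config_total_block_count(self):
        model = build_model(ModelConfig(**TINY), seed=0)
        assert sum(len(s) for s in model.stages) == 4

    def test_encoder_feature_shapes_table(self):
        shapes = encoder_feature_shapes(ModelConfig(input_size=512))
        assert shapes[0].as_tuple() == (96, 128, 128)  # stem
        assert shapes[1].as_tuple() == (96, 128, 128)  # stage 0
        assert shapes[2].as_tuple() == (192, 64, 64)
        assert shapes[3].as_tuple() == (384, 32, 32)
        assert shapes[4].as_tuple() == (768, 16, 16)

    def test_minimum_input_collapses_to_single_pixel(self):
        shapes = encoder_feature_shapes(ModelConfig(input_size=32))
        assert shapes[-1].as_tuple() == (768, 1, 1)

    def test_feature_shapes_match_forward_intermediates(self, rng):
        cfg = ModelConfig(**TINY)
        model = build_model(cfg, seed=0).eval()
        feats = model.forward_features(Tensor(rng.normal(size=(1, 3, 64, 64))))
        expected = encoder_feature_shapes(cfg)
        observed = [feats["stem"]] + [feats[f"stage{i}"] for i in range(4)]
        for exp, obs in zip(expected, observed):
            assert obs.shape[1:] == exp.as_tuple()


class TestForward:
    @pytest.mark.parametrize("n,d", [(1, 64), (2, 96)])
    def test_output_matches_input_resolution(self, rng, n, d):
        model = build_model(ModelConfig(**{**TINY, "input_size": d}), seed=0).eval()
        out = model(rng.normal(size=(n, 3, d, d)))
        assert out.shape == (n, 1, d, d)

    def test_zero_input_gives_finite_logits(self):
        model = build_model(ModelConfig(**TINY), seed=0).eval()
        out = model(np.zeros((1, 3, 64, 64)))
        assert np.isfinite(out.data).all()

    def test_wrong_channel_count_raises(self):
        model = build_model(ModelConfig(**TINY), seed=0)
        with pytest.raises(ValueError, match="channels"):
            model(np.zeros((1, 1, 64, 64)))

    def test_non_divisible_size_raises(self):
        model = build_model(ModelConfig(**TINY), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model(np.zeros((1, 3, 48, 48)))

    def test_patchification_shift_equivariance(self, rng):
        """Shifting the input by one patch shifts stem embeddings by one."""
        model = build_model(ModelConfig(**TINY), seed=0).eval()
        x = rng.normal(size=(1, 3, 64, 64))
        shifted = np.roll(x, model.config.patch_size, axis=3)
        stem = model.stem_norm(model.stem_conv(Tensor(x))).data
        stem_shifted = model.stem_norm(model.stem_conv(Tensor(shifted))).data
        np.testing.assert_allclose(stem_shifted[:, :, :, 1:],
                                   stem[:, :, :, :-1], atol=1e-10)

    def test_zeroed_block_is_identity(self, rng):
        block = ConvNeXtBlock(8, 4, 0.0, np.random.default_rng(0))
        for p in block.parameters():
            if p is not block.norm.weight:
                p.data[...] = 0.0
        x = rng.normal(size=(1, 8, 6, 6))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)


class TestParameterCount:
    def test_default_config_close_to_printed_total(self):
        model = build_model(ModelConfig(), seed=0)
        count = count_trainable_parameters(model)
        assert 31.9e6 <= count < 32.0e6

    def test_head_parameter_count(self):
        model = build_model(ModelConfig(**TINY), seed=0)
        head = sum(p.size for _, p in model.head.named_parameters())
        assert head == 8 * 1 * 3 * 3 + 1

    @pytest.mark.parametrize("mode", ["interpolate", "transposed_conv"])
    def test_count_matches_closed_form_oracle(self, mode):
        cfg = ModelConfig(**{**TINY, "upsample_mode": mode})
        model = build_model(cfg, seed=0)
        assert count_trainable_parameters(model) == closed_form_parameter_count(cfg)

    def test_default_count_matches_closed_form_oracle(self):
        cfg = ModelConfig()
        assert closed_form_parameter_count(cfg) == 31_956_401
        assert count_trainable_parameters(build_model(cfg, seed=0)) \
            == 31_956_401


class TestDeterminismAndCheckpoints:
    def test_same_seed_same_weights_and_outputs(self, rng):
        cfg = ModelConfig(**TINY)
        m1, m2 = build_model(cfg, seed=7), build_model(cfg, seed=7)
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(),
                                      m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)
        x = rng.normal(size=(1, 3, 64, 64))
        np.testing.assert_array_equal(m1.eval()(x).data, m2.eval()(x).data)

    def test_different_seed_different_weights(self):
        cfg = ModelConfig(**TINY)
        m1, m2 = build_model(cfg, seed=0), build_model(cfg, seed=1)
        assert not np.array_equal(m1.stem_conv.weight.data,
                                  m2.stem_conv.weight.data)

    def test_checkpoint_round_trip_bit_identical(self, rng, tmp_path):
        model = build_model(ModelConfig(**TINY), seed=3).eval()
        x = rng.normal(size=(1, 3, 64, 64))
        before = model(x).data
        path = save_checkpoint(model, tmp_path / "model.npz")
        reloaded = load_checkpoint(path)
        assert reloaded.config == model.config
        np.testing.assert_array_equal(reloaded(x).data, before)
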