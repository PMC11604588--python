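"""Architecture contracts: shapes, encoder state, decoders, fusion algebra,
prediction normalization, checkpoints."""

import numpy as np
import pytest

from fusionnet3d.model import (FusionNetConfig, build_fusionnet, fuse,
                               save_checkpoint, load_checkpoint)


def small_cfg(**kw):
    base = dict(in_channels=1, num_classes=4, base_width=2, num_blocks=3,
                fusion_mode="A", input_edge=32)
    base.update(kw)
    return FusionNetConfig(**base)


class TestConfig:
    def test_default_channel_progression_doubles_from_eight(self):
        cfg = FusionNetConfig(in_channels=4)
        assert cfg.block_widths == (8, 16, 32, 64, 128)
        assert sum(cfg.conv_counts) == 13  # VGG16 layout (2,2,3,3,3)

    def test_channel_cap_applies(self):
        cfg = FusionNetConfig(in_channels=1, base_width=32, max_width=64)
        assert cfg.block_widths == (32, 64, 64, 64, 64)

    def test_bottleneck_edge_from_pooling_count(self):
        cfg = small_cfg(num_blocks=3, input_edge=32)
        assert cfg.input_edge // 2 ** cfg.num_blocks == 4

    @pytest.mark.parametrize("kw", [
        dict(input_edge=100, num_blocks=5),
        dict(fusion_mode="X"),
        dict(in_channels=0),
        dict(num_classes=1),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestEncoder:
    def test_state_shapes_and_determinism(self, rng):
        cfg = small_cfg()
        m = build_fusionnet(cfg, seed=0)
        x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        s1 = m.encode(x, train=False)
        s2 = m.encode(x, train=False)
        assert len(s1.skip_features) == 3 and len(s1.pool_indices) == 3
        assert [f.shape[2] for f in s1.skip_features] == [32, 16, 8]
        assert s1.bottleneck.shape[2:] == (4, 4, 4)
        widths = cfg.block_widths
        assert [f.shape[1] for f in s1.skip_features] == list(widths)
        np.testing.assert_array_equal(s1.bottleneck, s2.bottleneck)

    def test_wrong_channel_count_raises(self, rng):
        m = build_fusionnet(small_cfg(), seed=0)
        x = rng.normal(size=(1, 2, 32, 32, 32)).astype(np.float32)
        with pytest.raises(ValueError, match="channel"):
            m.encode(x)

    def test_wrong_edge_names_offending_axis(self, rng):
        m = build_fusionnet(small_cfg(), seed=0)
        x = rng.normal(size=(1, 1, 32, 32, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="width"):
            m.encode(x)


class TestDecoders:
    def test_both_decoders_restore_full_resolution_at_base_width(self, rng):
        cfg = small_cfg()
        m = build_fusionnet(cfg, seed=0)
        x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        state = m.encode(x, train=False)
        a = m.decode_skip(state, train=False)
        b = m.decode_index(state, train=False)
        assert a.shape == b.shape == (1, cfg.base_width, 32, 32, 32)

    def test_zero_decoder_weights_give_zero_output(self, rng):
        m = build_fusionnet(small_cfg(), seed=0)
        x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        state = m.encode(x, train=False)
        for block in m.skip_blocks:
            for p in block.params():
                if p.name.endswith(("weight", "bias", "beta")):
                    p.value[...] = 0.0
        assert np.all(m.decode_skip(state, train=False) == 0.0)

    def test_decoding_same_state_twice_is_identical(self, rng):
        m = build_fusionnet(small_cfg(), seed=0)
        x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        state = m.encode(x, train=False)
        np.testing.assert_array_equal(m.decode_index(state, train=False),
                                      m.decode_index(state, train=False))

    def test_full_forward_composes_shared_encoder_and_decoders(self, rng):
        """One encoder pass feeds both decoders: composing encode ->
        decode_skip/decode_index -> fuse -> classifier reproduces
        forward_logits exactly."""
        cfg = small_cfg(fusion_mode="M")
        m = build_fusionnet(cfg, seed=1)
        x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        state = m.encode(x, train=False)
        manual = m.classifier.forward(
            fuse(m.decode_skip(state, train=False),
                 m.decode_index(state, train=False), "M"), train=False)
        np.testing.assert_array_equal(m.forward_logits(x, train=False), manual)


class TestFusion:
    def test_additive_doubles_identical_inputs(self, rng):
        x = rng.normal(size=(1, 4, 3, 3, 3))
        np.testing.assert_allclose(fuse(x, x, "A"), 2 * x)

    def test_multiplicative_annihilator_and_commutativity(self, rng):
        x = rng.normal(size=(2, 3, 4, 4, 4))
        y = rng.normal(size=(2, 3, 4, 4, 4))
        assert np.all(fuse(x, np.zeros_like(x), "M") == 0.0)
        np.testing.assert_array_equal(fuse(x, y, "M"), fuse(y, x, "M"))
        np.testing.assert_array_equal(fuse(x, y, "A"), fuse(y, x, "A"))

    def test_concatenation_adds_channel_counts(self, rng):
        a = rng.normal(size=(1, 8, 2, 2, 2))
        b = rng.normal(size=(1, 8, 2, 2, 2))
        assert fuse(a, b, "C").shape[1] == 16

    def test_shape_mismatch_rejected(self, rng):
        a = rng.normal(size=(1, 2, 4, 4, 4))
        b = rng.normal(size=(1, 2, 2, 2, 2))
        with pytest.raises(ValueError):
            fuse(a, b, "A")
        with pytest.raises(ValueError):
            fuse(a, rng.normal(size=(1, 3, 4, 4, 4)), "M")


class TestPredict:
    @pytest.mark.parametrize("mode", ["A", "M", "C"])
    @pytest.mark.parametrize("edge,blocks", [(16, 2), (32, 3)])
    def test_probability_volume_shape_and_normalization(self, rng, mode,
                                                        edge, blocks):
        cfg = small_cfg(fusion_mode=mode, input_edge=edge, num_blocks=blocks)
        m = build_fusionnet(cfg, seed=0)
        x = rng.normal(size=(1, edge, edge, edge)).astype(np.float32)
        probs, seg = m.predict(x)
        assert probs.shape == (4, edge, edge, edge)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert probs.min() >= 0.0
        np.testing.assert_array_equal(seg.data, np.argmax(probs, axis=0))
        assert set(np.unique(seg.data)) <= set(range(4))

    def test_prediction_on_phantom_uses_phantom_spacing(self, desk_phantom):
        m = build_fusionnet(small_cfg(in_channels=4), seed=0)
        _, seg = m.predict(desk_phantom.stack)
        assert seg.spacing == desk_phantom.labels.spacing


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, rng):
    cfg = small_cfg(num_blocks=2, input_edge=16, fusion_mode="C")
    m = build_fusionnet(cfg, seed=5)
    x = rng.normal(size=(1, 16, 16, 16)).astype(np.float32)
    probs, _ = m.predict(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path, extra={"note": "test"})
    m2, extra = load_checkpoint(path)
    assert extra == {"note": "test"}
    assert m2.config == cfg  # checkpoint is self-describing
    probs2, _ = m2.predict(x)
    np.testing.assert_array_equal(probs, probs2)
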