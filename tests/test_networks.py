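"""Architecture fidelity of the generators and PatchGAN discriminators."""

import numpy as np
import pytest

from fluorofill.autograd import Adam, Tensor
from fluorofill.networks import (DiscriminatorConfig, EdgeGenerator,
                                 GeneratorConfig, PatchDiscriminator,
                                 build_content_discriminator,
                                 build_content_generator,
                                 build_edge_discriminator,
                                 build_edge_generator, load_checkpoint,
                                 save_checkpoint)

# reference layer table: (op, kernel, channels, stride, norm, act)
G1_ROWS = [
    ("Conv", 7, 64, 1, "S/I", "relu"),
    ("Conv", 4, 128, 2, "S/I", "relu"),
    ("Conv", 4, 256, 2, "S/I", "relu"),
    ("Conv", 5, 32, 1, "", "elu"),
    ("Conv", 3, 32, 2, "", "elu"),
    ("Conv", 3, 64, 1, "", "elu"),
    ("Conv", 3, 128, 2, "", "elu"),
    ("Conv", 3, 128, 1, "", "elu"),
    ("Conv", 3, 128, 1, "", "relu"),
    ("ContextualAttention", 3, 128, 1, "", ""),
    ("Conv", 3, 128, 1, "", "elu"),
    ("Conv", 3, 128, 1, "", "elu"),
    ("Conv", 3, 384, 1, "S/I", "relu"),
    ("Conv", 3, 384, 1, "S/I", ""),
    ("ResNetBlocks", 3, 384, 1, "", ""),
    ("TransposeConv", 4, 128, 2, "S/I", "relu"),
    ("TransposeConv", 4, 64, 2, "S/I", "relu"),
    ("Conv", 7, 1, 1, "", "sigmoid"),
]

D_ROWS = [
    ("Conv", 4, 64, 2, "S", "lrelu"),
    ("Conv", 4, 128, 2, "S", "lrelu"),
    ("Conv", 4, 256, 2, "S", "lrelu"),
    ("Conv", 4, 512, 1, "S", "lrelu"),
    ("Conv", 4, 1, 1, "", "lrelu/sigmoid"),
]


def rows_of(summary):
    return [(r["op"], r["kernel"], r["channels"], r["stride"], r["norm"],
             r["act"]) for r in summary]


def desk_edge(seed=0, **kw):
    return EdgeGenerator(GeneratorConfig.edge(base_width=4, seed=seed, **kw))


def central_mask(size, frac=3):
    mask = np.zeros((size, size), dtype=np.uint8)
    q = size // 4
    mask[q:2 * q, q:2 * q] = 1
    return mask


class TestEdgeGeneratorArchitecture:
    def test_full_width_summary_matches_reference_table(self):
        g1 = build_edge_generator(GeneratorConfig.edge(paper_fidelity=True))
        assert rows_of(g1.summary()) == G1_ROWS
        blocks_row = [r for r in g1.summary() if r["op"] == "ResNetBlocks"][0]
        assert blocks_row["count"] == 8

    def test_full_width_forward_shape_and_range(self):
        g1 = build_edge_generator(GeneratorConfig.edge(paper_fidelity=True))
        x = np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32)
        y = g1(Tensor(x), central_mask(64))
        assert y.shape == (1, 1, 64, 64)
        assert 0.0 < y.data.min() and y.data.max() < 1.0

    def test_fully_convolutional_across_input_sizes(self):
        g1 = desk_edge()
        for size in (32, 64, 96):
            y = g1(Tensor(np.zeros((1, 3, size, size), np.float32)),
                   central_mask(size))
            assert y.shape == (1, 1, size, size)

    def test_attention_branch_ablation_shrinks_resnet(self):
        with_branch = desk_edge()
        without = EdgeGenerator(GeneratorConfig.edge(base_width=4,
                                                     attention_branch=False))
        assert without.res_channels == with_branch.res_channels - 2 * 4
        y = without(Tensor(np.zeros((1, 3, 32, 32), np.float32)))
        assert y.shape == (1, 1, 32, 32)
        assert all(r["op"] != "ContextualAttention"
                   for r in without.summary())

    def test_invalid_fidelity_config_raises(self):
        with pytest.raises(ValueError):
            EdgeGenerator(GeneratorConfig(base_width=64, n_resnet_blocks=5,
                                          paper_fidelity=True))
        with pytest.raises(ValueError):
            EdgeGenerator(GeneratorConfig(base_width=8, paper_fidelity=True))


class TestContentGeneratorArchitecture:
    def test_no_spectral_norm_anywhere(self):
        g2 = build_content_generator(GeneratorConfig.content(
            paper_fidelity=True))
        assert g2.spectral_layer_count() == 0
        assert all("S" not in r["norm"] for r in g2.summary())

    def test_four_resnet_blocks(self):
        g2 = build_content_generator(GeneratorConfig.content(
            paper_fidelity=True))
        assert len(g2.blocks) == 4

    def test_forward_shape_on_two_channel_input(self):
        g2 = EdgeGenerator(GeneratorConfig.content(base_width=4))
        y = g2(Tensor(np.zeros((1, 2, 64, 64), np.float32)), central_mask(64))
        assert y.shape == (1, 1, 64, 64)
        assert 0.0 < y.data.min() and y.data.max() < 1.0


class TestPatchDiscriminator:
    def test_summary_matches_reference_table(self):
        d = build_edge_discriminator(DiscriminatorConfig(in_channels=1))
        assert rows_of(d.summary()) == D_ROWS

    def test_score_map_is_32x32_for_256_input(self):
        d = PatchDiscriminator(DiscriminatorConfig(in_channels=1))
        y = d(Tensor(np.zeros((1, 1, 256, 256), np.float32)))
        assert y.shape == (1, 1, 32, 32)
        assert np.all((y.data > 0) & (y.data < 1))

    def test_receptive_field_is_70_pixels(self):
        assert PatchDiscriminator.receptive_field() == 70

    def test_constant_inputs_give_identical_score_maps(self):
        d = PatchDiscriminator(DiscriminatorConfig(in_channels=1,
                                                   base_width=4)).eval()
        a = d(Tensor(np.full((1, 1, 64, 64), 0.3, np.float32)))
        b = d(Tensor(np.full((1, 1, 64, 64), 0.3, np.float32)))
        np.testing.assert_array_equal(a.data, b.data)

    def test_feature_list_for_matching_loss(self):
        d = build_content_discriminator(DiscriminatorConfig(in_channels=2,
                                                            base_width=4))
        score, feats = d(Tensor(np.zeros((1, 2, 64, 64), np.float32)),
                         return_features=True)
        assert len(feats) == 5
        assert feats[-1] is score


class TestTrainingMechanics:
    def test_one_optimizer_step_moves_nearly_all_parameters(self):
        g1 = desk_edge(seed=3)
        opt = Adam(g1.parameters(), lr=1e-3)
        before = {k: v.data.copy() for k, v in g1.named_parameters()}
        x = np.random.default_rng(1).random((1, 3, 32, 32)).astype(np.float32)
        y = g1(Tensor(x, requires_grad=False), central_mask(32))
        ((y - 0.5) ** 2).mean().backward()
        opt.step()
        changed = [k for k, v in g1.named_parameters()
                   if not np.array_equal(before[k], v.data)]
        assert len(changed) >= 0.99 * len(before)

    def test_checkpoint_roundtrip_preserves_outputs(self, tmp_path):
        g1 = desk_edge(seed=5)
        path = tmp_path / "edge.npz"
        save_checkpoint(path, {"g1": g1}, {"g1": g1.cfg}, step=17)
        states, configs, step = load_checkpoint(path)
        assert step == 17
        clone = EdgeGenerator(GeneratorConfig(**configs["g1"]))
        clone.load_state_dict(states["g1"])
        x = Tensor(np.random.default_rng(2).random((1, 3, 32, 32))
                   .astype(np.float32))
        g1.eval()
        clone.eval()
        np.testing.assert_array_equal(g1(x, central_mask(32)).data,
                                      clone(x, central_mask(32)).data)
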