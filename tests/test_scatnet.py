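"""Tests for tiling, embeddings, scale fusion and diagnosis training."""

import numpy as np
import pytest

from melanopath import scatnet as sn
from melanopath.nn.tensor import Tensor
from melanopath.synthio.multiscale import MultiScaleCase


class TestTileImage:
    def test_2x3_grid_arithmetic(self):
        image = np.zeros((200, 300, 3), dtype=np.uint8)
        grid = sn.tile_image(image, 100)
        assert len(grid.patches) == 6
        assert grid.positions == [(0, 0), (0, 1), (0, 2),
                                  (1, 0), (1, 1), (1, 2)]

    def test_small_image_padded_to_one_patch(self):
        image = np.full((50, 50, 3), 10, dtype=np.uint8)
        grid = sn.tile_image(image, 100)
        assert len(grid.patches) == 1
        assert grid.patches[0].shape == (100, 100, 3)
        assert (grid.patches[0][:50, :50] == 10).all()
        assert (grid.patches[0][50:, :] == 255).all()  # white fill

    def test_reassembly_reproduces_padded_image(self):
        rng = np.random.default_rng(0)
        image = rng.integers(0, 256, size=(70, 90, 3), dtype=np.uint8)
        grid = sn.tile_image(image, 32)
        nh, nw = 3, 3
        rebuilt = np.zeros((96, 96, 3), dtype=np.uint8)
        for patch, (r, c) in zip(grid.patches, grid.positions):
            rebuilt[r * 32:(r + 1) * 32, c * 32:(c + 1) * 32] = patch
        np.testing.assert_array_equal(rebuilt[:70, :90], image)
        assert (rebuilt[70:, :] == 255).all()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sn.tile_image(np.zeros((0, 0, 3)), 32)


class TestSinusoidalEmbedding:
    def test_position_zero_pattern(self):
        emb = sn.sinusoidal_pos_embed([0], 8)[0]
        np.testing.assert_allclose(emb[0::2], 0.0)
        np.testing.assert_allclose(emb[1::2], 1.0)

    def test_values_bounded(self):
        emb = sn.sinusoidal_pos_embed(range(50), 16)
        assert (np.abs(emb) <= 1.0).all()

    def test_position_three_closed_form(self):
        emb = sn.sinusoidal_pos_embed([3], 8)[0]
        freqs = 1.0 / (10000.0 ** (np.arange(4) / 4))
        expected = np.empty(8)
        expected[0::2] = np.sin(3 * freqs)
        expected[1::2] = np.cos(3 * freqs)
        np.testing.assert_allclose(emb, expected)

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sn.sinusoidal_pos_embed([0], 7)


@pytest.fixture()
def tiny_model():
    cfg = sn.ScAtNetConfig(scales=("7.5x", "12.5x"), patch_size=16,
                           embed_dim=8, n_classes=3, seed=0)
    return sn.ScAtNet(cfg), cfg


def make_grid(rng, n=4, p=16):
    patches = rng.integers(0, 256, size=(n, p, p, 3), dtype=np.uint8)
    positions = [(i // 2, i % 2) for i in range(n)]
    return sn.PatchGrid(patches=patches, positions=positions, scale="7.5x")


class TestEmbedPatches:
    def test_identical_patches_get_identical_rows(self, tiny_model):
        model, _ = tiny_model
        rng = np.random.default_rng(1)
        grid = make_grid(rng)
        grid.patches[2] = grid.patches[0]
        emb = model.embed_patches(grid).data
        np.testing.assert_array_equal(emb[2], emb[0])

    def test_permutation_equivariance(self, tiny_model):
        model, _ = tiny_model
        rng = np.random.default_rng(2)
        grid = make_grid(rng)
        emb = model.embed_patches(grid).data
        perm = [3, 1, 0, 2]
        grid_p = sn.PatchGrid(patches=grid.patches[perm],
                              positions=[grid.positions[i] for i in perm],
                              scale=grid.scale)
        emb_p = model.embed_patches(grid_p).data
        np.testing.assert_array_equal(emb_p, emb[perm])

    def test_white_patch_equals_standalone_call(self, tiny_model):
        # independence oracle: embedding row = encoder on the single patch
        model, _ = tiny_model
        rng = np.random.default_rng(3)
        grid = make_grid(rng)
        grid.patches[1] = 255
        emb = model.embed_patches(grid).data
        single = sn.PatchGrid(patches=grid.patches[1:2], positions=[(0, 0)],
                              scale="7.5x")
        alone = model.embed_patches(single).data[0]
        np.testing.assert_allclose(emb[1], alone, atol=1e-12)


class TestContextualizeAndFuse:
    def test_permutation_invariance_without_positional(self):
        cfg = sn.ScAtNetConfig(scales=("7.5x",), patch_size=16, embed_dim=8,
                               n_classes=2, use_positional=False, seed=1)
        model = sn.ScAtNet(cfg)
        rng = np.random.default_rng(4)
        grid = make_grid(rng)
        emb = model.embed_patches(grid)
        out = model.contextualize_scale(emb, grid, "7.5x").data
        perm = [2, 0, 3, 1]
        grid_p = sn.PatchGrid(patches=grid.patches[perm],
                              positions=[grid.positions[i] for i in perm],
                              scale="7.5x")
        emb_p = model.embed_patches(grid_p)
        out_p = model.contextualize_scale(emb_p, grid_p, "7.5x").data
        np.testing.assert_allclose(out, out_p, atol=1e-10)

    def test_positional_embeddings_break_invariance(self):
        cfg = sn.ScAtNetConfig(scales=("7.5x",), patch_size=16, embed_dim=8,
                               n_classes=2, use_positional=True, seed=1)
        model = sn.ScAtNet(cfg)
        rng = np.random.default_rng(4)
        grid = make_grid(rng)
        out = model.contextualize_scale(
            model.embed_patches(grid), grid, "7.5x").data
        perm = [2, 0, 3, 1]
        grid_p = sn.PatchGrid(patches=grid.patches[perm],
                              positions=grid.positions, scale="7.5x")
        out_p = model.contextualize_scale(
            model.embed_patches(grid_p), grid_p, "7.5x").data
        assert not np.allclose(out, out_p, atol=1e-6)

    def test_output_length_is_embed_dim(self, tiny_model):
        model, cfg = tiny_model
        grid = make_grid(np.random.default_rng(5), p=16)
        out = model.contextualize_scale(model.embed_patches(grid), grid, "7.5x")
        assert out.shape == (cfg.embed_dim,)

    def test_single_scale_fusion_valid(self):
        cfg = sn.ScAtNetConfig(scales=("10x",), patch_size=16, embed_dim=8,
                               n_classes=2, seed=0)
        model = sn.ScAtNet(cfg)
        fused = model.scale_fuse([Tensor(np.ones(8))])
        assert fused.shape == (1, 8)

    def test_mismatched_dims_rejected(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError, match="mismatched"):
            model.scale_fuse([Tensor(np.ones(8)), Tensor(np.ones(6))])

    def test_scale_swap_changes_output_when_embeddings_differ(self, tiny_model):
        model, _ = tiny_model
        rng = np.random.default_rng(6)
        a, b = Tensor(rng.normal(size=8)), Tensor(rng.normal(size=8))
        out_ab = model.scale_fuse([a, b]).data
        out_ba = model.scale_fuse([b, a]).data
        assert not np.allclose(out_ab, out_ba, atol=1e-8)


class TestClassify:
    def test_flatten_length_and_normalization(self):
        cfg = sn.ScAtNetConfig(scales=("7.5x", "10x", "12.5x"), embed_dim=4,
                               n_classes=4, seed=0)
        model = sn.ScAtNet(cfg)
        assert model.classifier.w.shape == (12, 4)  # S*e = 3*4
        prob = model.classify(Tensor(np.random.default_rng(0).normal(size=(3, 4))))
        assert prob.shape == (4,)
        assert prob.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_weights_give_uniform(self):
        cfg = sn.ScAtNetConfig(scales=("10x",), embed_dim=4, n_classes=4, seed=0)
        model = sn.ScAtNet(cfg)
        model.classifier.w.data[:] = 0.0
        model.classifier.b.data[:] = 0.0
        prob = model.classify(Tensor(np.ones((1, 4))))
        np.testing.assert_allclose(prob.data, 0.25)


class TestTraining:
    def test_missing_scale_names_case(self):
        cfg = sn.ScAtNetConfig(n_classes=2, epochs=1, seed=0)
        case = MultiScaleCase(case_id="bad-case",
                              images={"7.5x": np.zeros((32, 32, 3), np.uint8)},
                              label=0)
        with pytest.raises(ValueError, match="bad-case"):
            sn.train_scatnet([case], cfg)

    def test_separable_cohort_recovery(self, scatnet_separable):
        assert scatnet_separable["log"].metrics[-1]["accuracy"] >= 0.9

    def test_multiscale_beats_best_single_scale(self, scatnet_crossscale):
        accs = scatnet_crossscale
        multi = accs[("7.5x", "10x", "12.5x")]
        singles = [v for k, v in accs.items() if len(k) == 1]
        assert multi > max(singles)

    def test_training_determinism(self):
        from melanopath.synthio import gen_multiscale_cohort

        cases = gen_multiscale_cohort(3, seed=5)
        cfg = sn.ScAtNetConfig(scales=("10x",), patch_size=32, embed_dim=8,
                               n_classes=3, epochs=2, seed=3)
        _, log_a = sn.train_scatnet(cases, cfg)
        _, log_b = sn.train_scatnet(cases, cfg)
        assert log_a.losses == log_b.losses
        assert log_a.metrics[-1] == log_b.metrics[-1]
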