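"""Patch embedding, scaled dot-product attention, MSA and encoder blocks."""

import numpy as np
import pytest

from pcgvit.autodiff import Tensor
from pcgvit.vit import (BranchConfig, ConfigurationError, ViTBranch,
                        embed_sequence, encoder_block, msa, patchify,
                        scaled_dot_attention, unpatchify)

S_CFG = BranchConfig(patch_size=4)
L_CFG = BranchConfig(patch_size=8)


class TestPatchify:
    @pytest.mark.parametrize("P,expected", [(4, (256, 48)), (8, (64, 192))])
    def test_patch_grid_arithmetic(self, rng, P, expected):
        assert patchify(rng.normal(size=(64, 64, 3)), P).shape == expected

    def test_single_patch_is_flattened_image(self):
        img = np.arange(4.0).reshape(2, 2, 1)
        np.testing.assert_array_equal(patchify(img, 2), img.reshape(1, 4))

    def test_row_order_is_left_to_right_top_to_bottom(self):
        # encode (row, col) in the pixel value; patch 1 must be the second
        # patch of the top row, not the first patch of the second row
        img = np.arange(64 * 64).reshape(64, 64, 1).astype(float)
        patches = patchify(img, 8)
        np.testing.assert_array_equal(patches[1], img[0:8, 8:16, 0].reshape(-1))
        np.testing.assert_array_equal(patches[8], img[8:16, 0:8, 0].reshape(-1))

    def test_roundtrip_identity(self, rng):
        for P in (4, 8, 16):
            img = rng.normal(size=(64, 64, 3))
            np.testing.assert_array_equal(unpatchify(patchify(img, P), P), img)

    def test_indivisible_dimensions_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            patchify(rng.normal(size=(64, 64, 3)), 6)


class TestEmbedSequence:
    @pytest.mark.parametrize("cfg,expected", [(S_CFG, (257, 64)), (L_CFG, (65, 64))])
    def test_token_sequence_dimensions(self, rng, cfg, expected):
        branch = ViTBranch(cfg, np.random.default_rng(0))
        z = branch.tokenize(rng.normal(size=(64, 64, 3)).astype(np.float32))
        assert z.shape == (1, *expected)

    def test_zero_patches_zero_embedding_reduces_to_token_plus_positions(self, rng):
        Np, pd, D = 6, 12, 8
        t = rng.normal(size=(1, 1, D))
        pos = rng.normal(size=(Np + 1, D))
        z = embed_sequence(np.zeros((Np, pd)), np.zeros((pd, D)), t, pos)
        expected = np.vstack([t[0], np.zeros((Np, D))]) + pos
        np.testing.assert_allclose(z.data[0], expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            embed_sequence(np.zeros((6, 12)), np.zeros((10, 8)),
                           np.zeros((1, 1, 8)), np.zeros((7, 8)))


class TestScaledDotAttention:
    def test_single_token_returns_value(self, rng):
        q, k, v = (rng.normal(size=(1, 4)) for _ in range(3))
        np.testing.assert_allclose(scaled_dot_attention(q, k, v).data, v, atol=1e-12)

    def test_identical_keys_give_uniform_average(self, rng):
        m = 7
        k = np.tile(rng.normal(size=(1, 4)), (m, 1))
        q, v = rng.normal(size=(m, 4)), rng.normal(size=(m, 4))
        out = scaled_dot_attention(q, k, v).data
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (m, 1)), atol=1e-9)

    def test_matches_per_query_loop_oracle(self):
        rng = np.random.default_rng(99)
        Q, K, V = (rng.normal(size=(5, 4)) for _ in range(3))
        out = scaled_dot_attention(Q, K, V).data
        for i in range(5):
            scores = np.array([Q[i] @ K[j] / np.sqrt(4) for j in range(5)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            expected = sum(w[j] * V[j] for j in range(5))
            np.testing.assert_allclose(out[i], expected, atol=1e-10)

    def test_output_is_convex_combination_of_values(self, rng):
        Q, K = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        V = rng.normal(size=(6, 3))
        out = scaled_dot_attention(Q, K, V).data
        assert np.all(out <= V.max(axis=0) + 1e-9)
        assert np.all(out >= V.min(axis=0) - 1e-9)

    def test_mismatched_query_key_dims_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            scaled_dot_attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)),
                                 rng.normal(size=(3, 5)))


def _random_msa_params(rng, D):
    return {
        "Wq": Tensor(rng.normal(size=(D, D)) * 0.2), "bq": Tensor(rng.normal(size=(D,)) * 0.1),
        "Wk": Tensor(rng.normal(size=(D, D)) * 0.2), "bk": Tensor(rng.normal(size=(D,)) * 0.1),
        "Wv": Tensor(rng.normal(size=(D, D)) * 0.2), "bv": Tensor(rng.normal(size=(D,)) * 0.1),
        "Umsa": Tensor(rng.normal(size=(D, D)) * 0.2), "b_msa": Tensor(np.zeros(D)),
    }


def _msa_oracle(Z, params, heads):
    """Independent per-head loop: project, attend, concatenate, project."""
    D = Z.shape[-1]
    ds = D // heads
    q = Z @ params["Wq"].data + params["bq"].data
    k = Z @ params["Wk"].data + params["bk"].data
    v = Z @ params["Wv"].data + params["bv"].data
    head_outs = []
    for h in range(heads):
        sl = slice(h * ds, (h + 1) * ds)
        scores = q[:, sl] @ k[:, sl].T / np.sqrt(ds)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        head_outs.append(w @ v[:, sl])
    return np.concatenate(head_outs, axis=1) @ params["Umsa"].data + params["b_msa"].data


class TestMSA:
    def test_single_head_identity_projection_equals_sda(self, rng):
        D = 8
        params = _random_msa_params(rng, D)
        params["Umsa"] = Tensor(np.eye(D))
        params["b_msa"] = Tensor(np.zeros(D))
        Z = rng.normal(size=(5, D))
        q = Z @ params["Wq"].data + params["bq"].data
        k = Z @ params["Wk"].data + params["bk"].data
        v = Z @ params["Wv"].data + params["bv"].data
        expected = scaled_dot_attention(q, k, v).data
        np.testing.assert_allclose(msa(Z, params, heads=1).data[0], expected, atol=1e-9)

    def test_four_heads_match_compositional_oracle(self):
        rng = np.random.default_rng(7)
        D = 16
        params = _random_msa_params(rng, D)
        Z = rng.normal(size=(6, D))
        np.testing.assert_allclose(msa(Z, params, heads=4).data[0],
                                   _msa_oracle(Z, params, 4), atol=1e-9)

    def test_permutation_equivariance(self, rng):
        D = 8
        params = _random_msa_params(rng, D)
        Z = rng.normal(size=(6, D))
        perm = rng.permutation(6)
        out = msa(Z, params, heads=2).data[0]
        out_perm = msa(Z[perm], params, heads=2).data[0]
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-9)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            msa(rng.normal(size=(4, 6)), _random_msa_params(rng, 6), heads=4)


class TestEncoderBlock:
    def test_zeroed_residual_branches_make_identity(self, rng):
        branch = ViTBranch(BranchConfig(patch_size=16, embed_dim=16, depth=2,
                                        heads=2, mlp_hidden=32),
                           np.random.default_rng(0))
        for blk in branch.blocks:
            blk["Umsa"].data[:] = 0
            blk["b_msa"].data[:] = 0
            blk["W2"].data[:] = 0
            blk["b2"].data[:] = 0
        Z = rng.normal(size=(1, 17, 16)).astype(np.float32)
        np.testing.assert_allclose(branch.encode(Z).data, Z, atol=1e-6)

    def test_shape_preserved_through_stack(self, rng):
        branch = ViTBranch(S_CFG, np.random.default_rng(0))
        Z = rng.normal(size=(2, 257, 64)).astype(np.float32)
        assert branch.encode(Z).shape == (2, 257, 64)

    def test_encode_equals_fold_of_blocks(self, rng):
        branch = ViTBranch(BranchConfig(patch_size=16, embed_dim=16, depth=3,
                                        heads=2, mlp_hidden=32),
                           np.random.default_rng(3))
        Z = rng.normal(size=(1, 17, 16)).astype(np.float32)
        z = Tensor(Z)
        for blk in branch.blocks:
            z = encoder_block(z, blk, branch.cfg.heads)
        np.testing.assert_allclose(branch.encode(Z).data, z.data, atol=1e-6)


class TestBranch:
    @pytest.mark.parametrize("cfg,n_tokens", [(S_CFG, 257), (L_CFG, 65)])
    def test_forward_dimensions(self, rng, cfg, n_tokens):
        branch = ViTBranch(cfg, np.random.default_rng(0))
        out = branch.forward(rng.normal(size=(2, 64, 64, 3)).astype(np.float32))
        assert out.shape == (2, n_tokens, 64)

    @pytest.mark.parametrize("cfg", [S_CFG, L_CFG])
    def test_parameter_shapes_follow_config_arithmetic(self, cfg):
        branch = ViTBranch(cfg, np.random.default_rng(0))
        assert branch.embed["E"].shape == (cfg.patch_dim, cfg.embed_dim)
        assert branch.embed["pos_embed"].shape == (cfg.n_patches + 1, cfg.embed_dim)
        for blk in branch.blocks:
            assert blk["Wq"].shape == (cfg.embed_dim, cfg.embed_dim)
            assert blk["W1"].shape == (cfg.embed_dim, cfg.mlp_hidden)

    def test_positional_embedding_breaks_permutation_invariance(self, rng):
        cfg = BranchConfig(patch_size=16, embed_dim=16, depth=1, heads=2, mlp_hidden=32)
        branch = ViTBranch(cfg, np.random.default_rng(0))
        img = rng.normal(size=(64, 64, 3)).astype(np.float32)
        perm = rng.permutation(cfg.n_patches)
        from pcgvit.vit import patchify as pf, unpatchify as upf
        img_perm = upf(pf(img, 16)[perm], 16)
        out = branch.forward(img[None]).data[0, 0]       # class-token row
        out_perm = branch.forward(img_perm[None]).data[0, 0]
        assert not np.allclose(out, out_perm, atol=1e-5)
        # zero positions: the class-token output must be permutation-invariant
        branch.embed["pos_embed"].data[:] = 0
        out = branch.forward(img[None]).data[0, 0]
        out_perm = branch.forward(img_perm[None]).data[0, 0]
        np.testing.assert_allclose(out, out_perm, atol=1e-4)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            BranchConfig(patch_size=6)
        with pytest.raises(ConfigurationError):
            BranchConfig(patch_size=4, embed_dim=30, heads=4)
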