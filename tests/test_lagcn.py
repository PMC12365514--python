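"""Layer-attention GCN: propagation, attention, decoder, loss, training."""

import numpy as np
import pytest

from ptmfusion.datatypes import AssociationMatrix, SimilarityMatrix
from ptmfusion.heterograph import build_hetero_network, sym_normalize
from ptmfusion.lagcn import (
    LagcnConfig,
    LayerAttentionGCN,
    bilinear_decode,
    gcn_layer,
    initial_attention,
    layer_attention,
    weighted_ce_loss,
)


def _model(assoc, sims, **cfg_kwargs):
    hg = build_hetero_network(assoc, *sims)
    defaults = dict(embed_dim=8, n_layers=3, epochs=60, lr=0.01,
                    dropout_node=0.0, dropout_edge=0.0)
    defaults.update(cfg_kwargs)
    return LayerAttentionGCN(hg, assoc, LagcnConfig(**defaults))


class TestGcnLayer:
    def test_identity_propagation(self):
        h = np.random.default_rng(0).normal(size=(4, 4))
        out = gcn_layer(h, np.eye(4), np.eye(4), activation=lambda x: x)
        assert np.allclose(out, h)

    def test_two_node_swap(self):
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = np.eye(2)
        out = gcn_layer(h, g, np.eye(2), activation=lambda x: x)
        assert np.allclose(out, [[0, 1], [1, 0]])

    def test_output_rows_stay_in_row_space_of_hw(self):
        # propagation mixes rows of H W, so every output row lies in their span
        rng = np.random.default_rng(1)
        g = rng.random((6, 6))
        g = 0.5 * (g + g.T)
        h = rng.normal(size=(6, 3))
        w = rng.normal(size=(3, 5))  # rank(HW) <= 3 < 5 makes this non-trivial
        out = gcn_layer(h, g, w, activation=lambda x: x)
        hw = h @ w
        coeffs, *_ = np.linalg.lstsq(hw.T, out.T, rcond=None)
        assert np.allclose(hw.T @ coeffs, out.T, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            gcn_layer(np.array([[np.nan]]), np.eye(1), np.eye(1))


class TestLayerAttention:
    def test_initialization_is_one_over_l_plus_one(self):
        assert np.allclose(initial_attention(3), [1 / 2, 1 / 3, 1 / 4])

    def test_equal_embeddings_scale_by_theta_sum(self):
        h = np.arange(12.0).reshape(6, 2)
        theta = np.array([0.5, 0.25, 0.125])
        h_p, h_d = layer_attention([h, h, h], theta, n_p=4)
        assert np.allclose(np.vstack([h_p, h_d]), theta.sum() * h)
        assert h_p.shape == (4, 2) and h_d.shape == (2, 2)

    def test_one_hot_selects_layer(self):
        rng = np.random.default_rng(2)
        hs = [rng.normal(size=(5, 3)) for _ in range(3)]
        h_p, h_d = layer_attention(hs, np.array([0.0, 1.0, 0.0]), n_p=5)
        assert np.allclose(h_p, hs[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="attention"):
            layer_attention([np.eye(2)], np.array([1.0, 1.0]), n_p=1)


class TestBilinearDecode:
    def test_zero_decoder_gives_half(self):
        scores = bilinear_decode(np.ones((3, 2)), np.ones((4, 2)), np.zeros((2, 2)))
        assert np.allclose(scores, 0.5)

    def test_scalar_example(self):
        h_p = np.array([[1.0, 0.0]])
        h_d = np.array([[0.0, 1.0]])
        w = np.array([[0.0, 2.0], [0.0, 0.0]])
        score = bilinear_decode(h_p, h_d, w)[0, 0]
        assert score == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-9)

    def test_monotone_in_positive_logit_scale(self):
        rng = np.random.default_rng(3)
        h_p = np.abs(rng.normal(size=(3, 4)))
        h_d = np.abs(rng.normal(size=(2, 4)))
        w = np.eye(4)
        s1 = bilinear_decode(h_p, h_d, w)
        s2 = bilinear_decode(2.0 * h_p, h_d, w)
        assert (s2 >= s1 - 1e-12).all()


class TestWeightedCeLoss:
    def test_balanced_half_scores_give_log_two(self):
        scores = np.array([[0.5, 0.5]])
        pos = np.array([[True, False]])
        loss = weighted_ce_loss(scores, pos, ~pos)
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_perfect_fit_limit(self):
        scores = np.array([[1.0 - 1e-9, 1e-9]])
        pos = np.array([[True, False]])
        assert weighted_ce_loss(scores, pos, ~pos) < 1e-6

    def test_balanced_sets_reduce_to_unweighted(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0.1, 0.9, size=(2, 4))
        pos = np.zeros((2, 4), dtype=bool)
        pos[0, :2] = True
        pos[1, :2] = True
        expected = -(
            np.log(scores[pos]).sum() + np.log(1 - scores[~pos]).sum()
        ) / scores.size
        assert weighted_ce_loss(scores, pos, ~pos) == pytest.approx(expected)

    def test_extreme_scores_clamped_finite(self):
        scores = np.array([[0.0, 1.0]])
        pos = np.array([[True, False]])
        assert np.isfinite(weighted_ce_loss(scores, pos, ~pos))

    def test_overlapping_masks_rejected(self):
        pos = np.array([[True, True]])
        with pytest.raises(ValueError, match="partition"):
            weighted_ce_loss(np.array([[0.5, 0.5]]), pos, pos)


class TestTraining:
    def test_gradients_match_finite_differences(self, tiny_assoc, tiny_similarities):
        model = _model(tiny_assoc, tiny_similarities, embed_dim=4, n_layers=2)
        params = model._init_params(np.random.default_rng(0))
        ghat = sym_normalize(model.hetero.g_pd)
        cache = model._forward(ghat, params, None)
        _, grads = model._loss_and_grads(ghat, params, cache, None)

        def loss_of():
            c = model._forward(ghat, params, None)
            return weighted_ce_loss(c["scores"], model.pos_mask, model.neg_mask)

        h = 1e-6
        for arr, grad in [
            (params["W"][0], grads["W"][0]),
            (params["Wp"], grads["Wp"]),
            (params["theta"], grads["theta"]),
        ]:
            flat = arr.reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss_of()
                flat[idx] = orig - h
                lm = loss_of()
                flat[idx] = orig
                assert (lp - lm) / (2 * h) == pytest.approx(
                    grad.reshape(-1)[idx], abs=1e-6
                )

    def test_loss_decreases_on_block_fixture(self):
        from ptmfusion.similarity import disease_gip, protein_gip
        from ptmfusion.synthetic import SyntheticSpec, simulate_associations

        window_drops = []
        for seed in range(3):
            spec = SyntheticSpec(
                n_proteins=20, n_diseases=10, n_blocks=2,
                within_block_density=0.6, noise_density=0.02,
                n_shared=10, n_shared_informative=5, seed=seed,
            )
            assoc = simulate_associations(spec)
            hg = build_hetero_network(assoc, protein_gip(assoc), disease_gip(assoc))
            res = LayerAttentionGCN(
                hg, assoc, LagcnConfig(embed_dim=8, epochs=120, lr=0.01)
            ).fit(seed=seed)
            first = res.loss_history[:50].mean()
            last = res.loss_history[-50:].mean()
            window_drops.append(first - last)
        assert np.mean(window_drops) > 0

    def test_reproducible_from_seed(self, tiny_assoc, tiny_similarities):
        r1 = _model(tiny_assoc, tiny_similarities, dropout_node=0.3,
                    dropout_edge=0.2).fit(seed=7)
        r2 = _model(tiny_assoc, tiny_similarities, dropout_node=0.3,
                    dropout_edge=0.2).fit(seed=7)
        assert np.array_equal(r1.scores.values, r2.scores.values)
        assert np.array_equal(r1.loss_history, r2.loss_history)

    def test_scores_strictly_inside_unit_interval(self, tiny_assoc, tiny_similarities):
        res = _model(tiny_assoc, tiny_similarities).fit(seed=0)
        v = res.scores.values
        assert ((v > 0) & (v < 1)).all()

    def test_summary_mentions_configuration(self, tiny_assoc, tiny_similarities):
        res = _model(tiny_assoc, tiny_similarities).fit(seed=0)
        text = res.summary()
        assert "L=3" in text and "theta_1" in text

    def test_preset_profiles(self):
        grid = LagcnConfig.preset("grid")
        text = LagcnConfig.preset("text")
        assert (grid.lr, grid.epochs) == (0.01, 800)
        assert (text.lr, text.epochs) == (0.001, 400)
        with pytest.raises(ValueError, match="preset"):
            LagcnConfig.preset("bogus")
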