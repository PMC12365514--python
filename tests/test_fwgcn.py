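"""Feature weighting, cosine sample graph, transductive GCN classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmfusion.datatypes import ExpressionDataset, ScoreMatrix
from ptmfusion.fwgcn import (
    DELTA_GRID,
    FeatureWeightedGCN,
    FwgcnConfig,
    cosine_adjacency,
    feature_weight,
    select_delta,
    train_fwgcn,
)


def cosine_graph_oracle(x, gamma):
    """Exhaustive threshold scan over all candidate epsilon values."""
    n = x.shape[0]
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    xn = x / safe[:, None]
    cos = np.clip(xn @ xn.T, -1, 1)
    np.fill_diagonal(cos, 0.0)
    zero = norms == 0
    cos[zero, :] = 0.0
    cos[:, zero] = 0.0
    off = cos[~np.eye(n, dtype=bool)]
    candidates = sorted(set(off[off >= 0].tolist()) | {0.0}, reverse=True)
    chosen = None
    for eps in candidates:
        mean_degree = (n + (off >= eps).sum()) / n
        if mean_degree >= gamma:
            chosen = eps
            break
    if chosen is None:
        chosen = 0.0
    g = np.where(cos >= chosen, cos, 0.0)
    np.fill_diagonal(g, 1.0)
    return chosen, g


def _expr(values, labels, shared, disease_key="D0"):
    n, f = values.shape
    return ExpressionDataset(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        protein_ids=[f"p{j}" for j in range(f)],
        labels=labels,
        shared_index=np.asarray(shared, dtype=int),
        disease_key=disease_key,
    )


def _scores(n_proteins, values_by_protein, disease="D0"):
    vals = np.full((n_proteins, 1), 0.5)
    for j, v in values_by_protein.items():
        vals[j, 0] = v
    return ScoreMatrix(vals, [f"p{j}" for j in range(n_proteins)], [disease])


class TestFeatureWeight:
    def test_identity_at_neutral_score(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 3))
        expr = _expr(values, np.array([0, 1, 0, 1, 0]), shared=[0, 2])
        scores = _scores(3, {0: 0.5, 2: 0.5})
        out = feature_weight(expr, scores, delta=0.0)
        assert np.allclose(out.values, values)

    def test_scalar_example(self):
        values = np.array([[1.0, 5.0]])
        expr = _expr(values, np.array([0]), shared=[0])
        scores = _scores(2, {0: 0.8})
        out = feature_weight(expr, scores, delta=0.0)
        assert out.values[0, 0] == pytest.approx(1.6)
        assert out.values[0, 1] == pytest.approx(5.0)  # non-shared untouched

    def test_zero_expression_stays_zero(self):
        expr = _expr(np.zeros((3, 2)), np.array([0, 1, 0]), shared=[0, 1])
        scores = _scores(2, {0: 0.9, 1: 0.2})
        out = feature_weight(expr, scores, delta=1.0)
        assert np.allclose(out.values, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        p=st.floats(0.01, 5.0),
        a1=st.floats(0.01, 0.99),
        a2=st.floats(0.01, 0.99),
        delta=st.floats(0.0, 1.0),
    )
    def test_strictly_monotone_in_score_for_positive_p(self, p, a1, a2, delta):
        lo, hi = sorted([a1, a2])
        if hi - lo < 1e-9:
            return
        def weighted(a):
            expr = _expr(np.array([[p]]), np.array([0]), shared=[0])
            return feature_weight(expr, _scores(1, {0: a}), delta).values[0, 0]
        assert weighted(hi) > weighted(lo)

    def test_shrink_mode_flips_exponent(self):
        expr = _expr(np.array([[2.0]]), np.array([0]), shared=[0])
        scores = _scores(1, {0: 0.5})
        lit = feature_weight(expr, scores, delta=0.5, mode="literal").values[0, 0]
        shr = feature_weight(expr, scores, delta=0.5, mode="shrink").values[0, 0]
        assert lit == pytest.approx(2.0 * np.exp(1.0))
        assert shr == pytest.approx(2.0 * np.exp(-1.0))

    def test_missing_disease_key_rejected(self):
        expr = _expr(np.ones((2, 1)), np.array([0, 1]), shared=[0], disease_key="D9")
        with pytest.raises(KeyError, match="D9"):
            feature_weight(expr, _scores(1, {}), delta=0.0)

    def test_negative_delta_rejected(self):
        expr = _expr(np.ones((2, 1)), np.array([0, 1]), shared=[0])
        with pytest.raises(ValueError, match="delta"):
            feature_weight(expr, _scores(1, {}), delta=-0.1)


class TestCosineAdjacency:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(size=(n, int(rng.integers(2, 6))))
        gamma = int(rng.integers(1, n + 1))
        graph = cosine_adjacency(x, gamma)
        eps_oracle, g_oracle = cosine_graph_oracle(x, gamma)
        assert graph.epsilon == pytest.approx(eps_oracle, abs=1e-12)
        assert np.allclose(graph.g_pp, g_oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_achieved_degree_is_minimal_admissible(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = np.abs(rng.normal(size=(10, 4)))
        gamma = 3
        graph = cosine_adjacency(x, gamma)
        assert graph.achieved_degree >= gamma
        # any strictly larger candidate threshold must fall below gamma
        norms = np.linalg.norm(x, axis=1)
        xn = x / norms[:, None]
        cos = np.clip(xn @ xn.T, -1, 1)
        np.fill_diagonal(cos, 0.0)
        off = cos[~np.eye(10, dtype=bool)]
        larger = np.unique(off[off > graph.epsilon])
        n = 10
        for eps in larger:
            assert (n + (off >= eps).sum()) / n < gamma

    def test_orthogonal_samples_self_loops_only(self):
        graph = cosine_adjacency(np.eye(4), gamma=1)
        assert np.allclose(graph.g_pp, np.eye(4))

    def test_identical_samples_complete_graph(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        graph = cosine_adjacency(x, gamma=4)
        assert np.allclose(graph.g_pp, 1.0)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            cosine_adjacency(np.eye(3), gamma=0)
        with pytest.raises(ValueError, match="gamma"):
            cosine_adjacency(np.eye(3), gamma=5)

    def test_zero_rows_get_self_loop_only(self):
        x = np.vstack([np.zeros(3), np.ones((3, 3))])
        with pytest.warns(UserWarning, match="all-zero"):
            graph = cosine_adjacency(x, gamma=2)
        assert graph.g_pp[0, 0] == 1.0
        assert np.allclose(graph.g_pp[0, 1:], 0.0)


def _separable_data(n=40, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(scale=0.3, size=(n, n_features))
    x[y == 0, 0] += 2.0
    x[y == 1, 0] -= 2.0
    return x, y


class TestClassifier:
    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            FeatureWeightedGCN(x, np.zeros(10, dtype=int))

    def test_initial_loss_near_log_c(self):
        x, y = _separable_data(seed=1)
        res = train_fwgcn(x, y, config=FwgcnConfig(epochs=1, gamma=2), seed=0)
        assert res.loss_history[0] == pytest.approx(np.log(2.0), rel=0.2)

    def test_separable_data_reaches_full_training_accuracy(self):
        x, y = _separable_data(seed=2)
        res = train_fwgcn(x, y, config=FwgcnConfig(epochs=200, gamma=2), seed=0)
        pred = res.predict_proba_train().argmax(axis=1)
        assert np.mean(pred == y) == 1.0

    def test_probabilities_sum_to_one(self):
        x, y = _separable_data(seed=3)
        res = train_fwgcn(x[:30], y[:30], config=FwgcnConfig(epochs=50, gamma=2), seed=0)
        probs = res.predict_transductive(x[30:])
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_duplicate_test_sample_inherits_probabilities(self):
        # a test node with identical features is exchangeable with its
        # training twin inside the extended graph
        x, y = _separable_data(seed=4)
        res = train_fwgcn(x, y, config=FwgcnConfig(epochs=100, gamma=2), seed=0)
        x_all = np.vstack([x, x[5]])
        graph = cosine_adjacency(x_all, res.config.gamma)
        from ptmfusion.heterograph import sym_normalize

        probs_all = res._forward(x_all, sym_normalize(graph.g_pp))
        assert np.abs(probs_all[-1] - probs_all[5]).max() < 1e-3

    def test_batch_and_single_extension_agree_on_separable_data(self):
        x, y = _separable_data(n=60, seed=5)
        tr, te = np.arange(40), np.arange(40, 60)
        res = train_fwgcn(x[tr], y[tr], config=FwgcnConfig(epochs=150, gamma=2), seed=0)
        batch = res.predict(x[te], mode="batch")
        single = res.predict(x[te], mode="single")
        assert np.mean(batch == single) >= 0.95

    def test_feature_dim_mismatch_rejected(self):
        x, y = _separable_data(seed=6)
        res = train_fwgcn(x, y, config=FwgcnConfig(epochs=5, gamma=2), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            res.predict_transductive(np.ones((2, 99)))

    def test_training_reproducible_from_seed(self):
        x, y = _separable_data(seed=7)
        r1 = train_fwgcn(x, y, config=FwgcnConfig(epochs=40, gamma=2), seed=3)
        r2 = train_fwgcn(x, y, config=FwgcnConfig(epochs=40, gamma=2), seed=3)
        assert np.array_equal(r1.loss_history, r2.loss_history)
        for w1, w2 in zip(r1.weights, r2.weights):
            assert np.array_equal(w1, w2)


class TestSelectDelta:
    def test_singleton_grid_returned(self):
        expr = _expr(np.random.default_rng(0).normal(size=(20, 3)),
                     np.tile([0, 1], 10), shared=[0])
        assert select_delta(expr, _scores(3, {0: 0.7}), grid=(0.01,)) == 0.01

    def test_default_grid_is_canonical(self):
        assert DELTA_GRID == (
            0.0001, 0.0003, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0
        )

    def test_large_delta_rejected_when_it_amplifies_noise(self):
        # shared columns carry pure noise with a high score: a large delta
        # blows them up and drowns the (unweighted) signal column
        rng = np.random.default_rng(1)
        n = 60
        y = np.tile([0, 1], n // 2)
        x = rng.normal(size=(n, 8))
        x[:, 0] += np.where(y == 0, 2.0, -2.0)
        expr = _expr(x, y, shared=[1, 2, 3])
        scores = _scores(8, {1: 0.9, 2: 0.9, 3: 0.9})
        cfg = FwgcnConfig(epochs=60, gamma=2, hidden_dim=16)
        chosen = select_delta(expr, scores, grid=(0.0001, 0.01, 3.0),
                              seed=0, config=cfg)
        assert chosen < 3.0
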