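import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from prosim.edge_features import EdgeFeatures
from prosim.reliability import (
    ReliabilityModel,
    load_model,
    predict_reliability,
    save_model,
    train_reliability,
    weight_network,
)
from prosim.synthetic_data import generate_planted_logistic


@pytest.fixture(scope="module")
def planted():
    beta = np.array([0.0, 3.0, 2.0, -1.0])
    pos, neg, X, y = generate_planted_logistic(4000, beta, seed=42)
    return beta, pos, neg, X, y


class TestTrainReliability:
    def test_recovers_planted_signs_and_discriminates(self, planted):
        beta, pos, neg, X, y = planted
        # train on the first half, score the untouched second half
        half_pos = EdgeFeatures(pos.edges[: len(pos.edges) // 2], pos.X[: len(pos.edges) // 2])
        half_neg = EdgeFeatures(neg.edges[: len(neg.edges) // 2], neg.X[: len(neg.edges) // 2])
        model = train_reliability(half_pos, half_neg, seed=0)
        assert np.all(np.sign(model.beta[1:]) == np.sign(beta[1:]))
        n_half = len(X) // 2
        p = predict_reliability(model, X[n_half:])
        assert roc_auc_score(y[n_half:], p) > 0.9

    def test_beta_is_exact_mean_of_ten_folds(self, planted):
        _, pos, neg, _, _ = planted
        model = train_reliability(pos, neg, folds=10, seed=1)
        assert model.fold_betas.shape == (10, 4)
        assert np.abs(model.beta - model.fold_betas.mean(axis=0)).max() <= 1e-12

    def test_median_option(self, planted):
        _, pos, neg, _, _ = planted
        model = train_reliability(pos, neg, seed=1, average="median")
        assert np.allclose(model.beta, np.median(model.fold_betas, axis=0))

    def test_deterministic_given_seed(self, planted):
        _, pos, neg, _, _ = planted
        m1 = train_reliability(pos, neg, seed=3)
        m2 = train_reliability(pos, neg, seed=3)
        assert np.array_equal(m1.beta, m2.beta)
        assert np.array_equal(m1.fold_betas, m2.fold_betas)

    def test_null_features_do_not_discriminate(self):
        # labels independent of features: held-out discrimination is chance
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, size=(3000, 3))
        y = rng.random(3000) < 0.5
        pos = EdgeFeatures(tuple(("a", f"p{i}") for i in range(y.sum())), X[y])
        neg = EdgeFeatures(tuple(("a", f"n{i}") for i in range((~y).sum())), X[~y])
        model = train_reliability(pos, neg, seed=0)
        X_test = rng.uniform(-1, 1, size=(2000, 3))
        y_test = rng.random(2000) < 0.5
        auc = roc_auc_score(y_test, predict_reliability(model, X_test))
        assert abs(auc - 0.5) < 0.1

    def test_too_few_examples_rejected(self):
        X = np.zeros((5, 3))
        tiny = EdgeFeatures(tuple(("a", f"b{i}") for i in range(5)), X)
        with pytest.raises(ValueError, match="examples per class"):
            train_reliability(tiny, tiny)

    def test_balance_truncates_positive_set(self, planted):
        # with many more positives than negatives, balancing must use only
        # the first |neg| positive rows: corrupting the tail has no effect
        _, pos, neg, _, _ = planted
        n_neg = len(neg.edges) // 2
        neg_small = EdgeFeatures(neg.edges[:n_neg], neg.X[:n_neg])
        assert len(pos.edges) > n_neg
        corrupted_X = pos.X.copy()
        corrupted_X[n_neg:] = 1e3  # junk beyond the balanced block
        corrupted = EdgeFeatures(pos.edges, corrupted_X)
        m1 = train_reliability(pos, neg_small, seed=5)
        m2 = train_reliability(corrupted, neg_small, seed=5)
        assert np.array_equal(m1.beta, m2.beta)


class TestPredictReliability:
    def test_null_model_gives_half(self):
        model = ReliabilityModel(np.zeros(4), np.zeros((1, 4)))
        assert predict_reliability(model, np.array([5.0, -3.0, 2.0])) == 0.5

    def test_hand_arithmetic(self):
        model = ReliabilityModel(np.array([1.0, 2.0, 0.0, -1.0]), np.zeros((1, 4)))
        got = predict_reliability(model, np.array([0.5, 0.3, 0.2]))
        assert got == pytest.approx(1 / (1 + np.exp(-1.8)), abs=1e-9)
        assert got == pytest.approx(0.858149, abs=1e-6)

    def test_saturation(self):
        model = ReliabilityModel(np.array([100.0, 0, 0, 0]), np.zeros((1, 4)))
        assert predict_reliability(model, np.zeros(3)) == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_each_feature(self):
        model = ReliabilityModel(np.array([0.0, 2.0, -1.5, 0.7]), np.zeros((1, 4)))
        x = np.array([0.1, 0.2, 0.3])
        for i, coef in enumerate(model.beta[1:]):
            dx = np.zeros(3)
            dx[i] = 1e-4
            diff = predict_reliability(model, x + dx) - predict_reliability(model, x)
            assert np.sign(diff) == np.sign(coef)

    def test_non_finite_rejected(self):
        model = ReliabilityModel(np.zeros(4), np.zeros((1, 4)))
        with pytest.raises(ValueError):
            predict_reliability(model, np.array([np.nan, 0, 0]))


class TestWeightNetwork:
    def test_weights_in_unit_interval(self, small_bundle, small_prio):
        w = np.array(list(small_prio.net.edges.values()))
        assert np.all((w > 0) & (w < 1))
        assert set(small_prio.net.nodes) == set(small_bundle.net.nodes)

    def test_true_edges_outweigh_planted_negatives(self, small_bundle, small_prio):
        from prosim.edge_features import build_edge_features
        from prosim.reliability import train_reliability

        pos_feat = build_edge_features(small_bundle.net, small_bundle.expr, small_bundle.locs)
        neg_feat = build_edge_features(small_bundle.neg_net, small_bundle.expr, small_bundle.locs)
        model = train_reliability(pos_feat, neg_feat, seed=0)
        pos_w = predict_reliability(model, pos_feat.X)
        neg_w = predict_reliability(model, neg_feat.X)
        assert pos_w.mean() > neg_w.mean()

    def test_missing_feature_row_names_edge(self, small_bundle):
        from prosim.edge_features import build_edge_features
        from prosim.reliability import train_reliability

        pos_feat = build_edge_features(small_bundle.net, small_bundle.expr, small_bundle.locs)
        neg_feat = build_edge_features(small_bundle.neg_net, small_bundle.expr, small_bundle.locs)
        model = train_reliability(pos_feat, neg_feat, seed=0)
        truncated = EdgeFeatures(pos_feat.edges[:-1], pos_feat.X[:-1])
        with pytest.raises(KeyError):
            weight_network(small_bundle.net, model, truncated)


def test_model_serialization_round_trip(tmp_path):
    model = ReliabilityModel(
        np.array([0.25, -1.5, 3.125, 0.0]),
        np.arange(40, dtype=float).reshape(10, 4),
    )
    path = tmp_path / "model.tsv"
    save_model(model, path)
    back = load_model(path)
    assert np.array_equal(back.beta, model.beta)
    assert np.array_equal(back.fold_betas, model.fold_betas)
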