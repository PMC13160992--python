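"""Feature-selection strategies: oracles, conventions, planted recovery."""

import math
import warnings

import numpy as np
import pytest
from sklearn.feature_selection import f_classif

from ssrtrace.extract import FeatureKey, FeatureMatrix, GroupLabels
from ssrtrace.select import (
    LassoModel,
    anova_f_scores,
    gc_ssr_select,
    hybrid_select,
    lasso_fit,
    lasso_loss,
    lasso_select,
    predict_proba,
    select_k_best,
)
from ssrtrace.simulate import SimulationConfig, simulate_feature_table

from conftest import make_matrix, random_matrix


def gc_oracle(matrix, labels):
    """Exhaustive double loop over (feature, group)."""
    retained = {}
    for j, key in enumerate(matrix.feature_keys):
        for g in labels.groups:
            rows = [matrix.sample_ids.index(s) for s in labels.samples_of(g)]
            if all(matrix.values[i, j] == 1 for i in rows):
                retained.setdefault(key, set()).add(g)
    return retained


class TestGcSsr:
    def test_all_groups_feature_retained_and_attributed_everywhere(self):
        m, labels = make_matrix(np.ones((6, 2)), ["A"] * 3 + ["B"] * 3)
        res = gc_ssr_select(m, labels)
        assert len(res.features) == 2
        assert all(res.group_attribution[k] == {"A", "B"} for k in res.features)

    def test_feature_missing_somewhere_in_every_group_dropped(self):
        vals = np.ones((4, 1))
        vals[0, 0] = 0  # missing in A
        vals[3, 0] = 0  # missing in B
        m, labels = make_matrix(vals, ["A", "A", "B", "B"])
        assert gc_ssr_select(m, labels).features == []

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m, labels = random_matrix(rng, int(rng.integers(6, 13)), 50, 3)
            res = gc_ssr_select(m, labels)
            oracle = gc_oracle(m, labels)
            assert set(res.features) == set(oracle)
            assert res.group_attribution == oracle

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        m, labels = random_matrix(rng, 10, 30, 3)
        res1 = gc_ssr_select(m, labels)
        perm = rng.permutation(m.n_samples)
        m2 = FeatureMatrix(
            [m.sample_ids[i] for i in perm], m.feature_keys, m.values[perm]
        )
        res2 = gc_ssr_select(m2, labels)
        assert res1.features == res2.features
        sub = m.restrict(res1.features)
        assert gc_ssr_select(sub, labels).features == res1.features

    def test_empty_group_rejected(self):
        m, _ = make_matrix(np.ones((2, 2)), ["A", "A"])
        labels = GroupLabels({"s00": "A", "s01": "A"}, groups=["A", "B"])
        with pytest.raises(ValueError, match="B"):
            gc_ssr_select(m, labels)


def anova_oracle(X, y):
    """Textbook two-loop sum-of-squares computation."""
    n, K = len(y), len(set(y))
    scores = []
    for j in range(X.shape[1]):
        col = X[:, j].astype(float)
        grand = col.mean()
        ssb = ssw = 0.0
        for g in sorted(set(y)):
            vals = col[[i for i in range(n) if y[i] == g]]
            ssb += len(vals) * (vals.mean() - grand) ** 2
            ssw += ((vals - vals.mean()) ** 2).sum()
        if ssw == 0:
            scores.append(math.inf if ssb > 0 else 0.0)
        else:
            scores.append((ssb / (K - 1)) / (ssw / (n - K)))
    return np.array(scores)


class TestAnovaF:
    def test_group_indicator_scores_infinite(self):
        vals = np.array([[1], [1], [0], [0], [0], [0]])
        m, labels = make_matrix(vals, ["A", "A", "B", "B", "C", "C"])
        assert anova_f_scores(m, labels)[0] == np.inf

    def test_constant_feature_scores_zero(self):
        m, labels = make_matrix(np.ones((4, 1)), ["A", "A", "B", "B"])
        assert anova_f_scores(m, labels)[0] == 0.0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m, labels = random_matrix(rng, 10, 8, 3)
            y = labels.vector(m.sample_ids)
            got = anova_f_scores(m, labels)
            want = anova_oracle(m.values, list(y))
            finite = np.isfinite(want)
            assert np.allclose(got[finite], want[finite], atol=1e-10)
            assert (got[~finite] == want[~finite]).all()

    def test_agrees_with_sklearn_on_nondegenerate_features(self):
        rng = np.random.default_rng(2)
        m, labels = random_matrix(rng, 12, 20, 3)
        y = labels.vector(m.sample_ids)
        got = anova_f_scores(m, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            want, _ = f_classif(m.values.astype(float), y)
        ok = np.isfinite(got) & np.isfinite(want)
        assert np.allclose(got[ok], want[ok], atol=1e-8)

    def test_single_group_rejected(self):
        m, labels = make_matrix(np.ones((3, 2)), ["A", "A", "A"])
        with pytest.raises(ValueError):
            anova_f_scores(m, labels)


class TestSelectKBest:
    def test_k_equals_m_returns_all_sorted(self):
        rng = np.random.default_rng(5)
        m, labels = random_matrix(rng, 10, 12, 2)
        res = select_k_best(m, labels, k=12)
        assert len(res.features) == 12
        assert all(res.scores[i] >= res.scores[i + 1] for i in range(11))

    def test_k1_returns_unique_infinite_feature(self):
        vals = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        m, labels = make_matrix(vals, ["A", "A", "B", "B"])
        res = select_k_best(m, labels, k=1)
        assert res.features == [m.feature_keys[0]]
        assert res.scores[0] == np.inf

    def test_nesting_property(self):
        rng = np.random.default_rng(9)
        m, labels = random_matrix(rng, 12, 25, 3)
        for k in range(1, 25):
            assert set(select_k_best(m, labels, k=k).features) <= set(
                select_k_best(m, labels, k=k + 1).features
            )

    def test_matches_full_sort_of_oracle_scores(self):
        rng = np.random.default_rng(13)
        m, labels = random_matrix(rng, 10, 30, 3)
        res = select_k_best(m, labels, k=5)
        want = anova_oracle(m.values, list(labels.vector(m.sample_ids)))
        order = sorted(range(30), key=lambda j: (-want[j], m.feature_keys[j]))
        assert res.features == [m.feature_keys[j] for j in order[:5]]


HYBRID_FAST = dict(
    search_iterations=5,
    search_space={"n_estimators": [100], "max_depth": [5], "min_samples_leaf": [1, 2]},
)


class TestHybrid:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimulationConfig(
            group_names=("A", "B"),
            samples_per_group=(10, 10),
            n_conserved_per_group=(5, 0),
            n_noise_features=50,
            noise_presence_prob=0.3,
            heterogeneous_groups=frozenset({"B"}),
            seed=21,
        )
        return simulate_feature_table(cfg)

    def test_recovers_planted_discriminative_features(self, planted):
        m, labels, truth = planted
        res = hybrid_select(m, labels, k1=m.n_features, k2=5, seed=0, **HYBRID_FAST)
        assert set(res.features) == truth.planted_conserved["A"]

    def test_stage1_identity_when_k1_geq_m(self, planted):
        m, labels, _ = planted
        res = hybrid_select(m, labels, k1=10_000, k2=5, seed=0, **HYBRID_FAST)
        assert len(res.features) == 5

    def test_deterministic_given_seed(self, planted):
        m, labels, _ = planted
        a = hybrid_select(m, labels, k1=m.n_features, k2=5, seed=3, **HYBRID_FAST)
        b = hybrid_select(m, labels, k1=m.n_features, k2=5, seed=3, **HYBRID_FAST)
        assert a.features == b.features and a.scores == b.scores

    def test_too_few_samples_for_folds_rejected(self):
        m, labels = make_matrix(np.eye(4), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="stratify"):
            hybrid_select(m, labels, k1=4, k2=2, cv_folds=4)


def lasso_loss_oracle(W, b, lam, X, y, classes):
    """Explicit double-sum with scalar sigmoids."""
    n, K = X.shape[0], len(classes)
    total = 0.0
    for i in range(n):
        scores = [
            1.0 / (1.0 + math.exp(-(np.dot(W[k], X[i]) + b[k]))) for k in range(K)
        ]
        Z = sum(scores)
        for k in range(K):
            if classes[k] == y[i]:
                total -= math.log(max(scores[k] / Z, 1e-15))
    penalty = lam * sum(abs(W[k][j]) for k in range(K) for j in range(W.shape[1]))
    return total / n + penalty


def _model(W, b, lam, classes, m):
    keys = [FeatureKey(f"L{j}", "A", 10) for j in range(m)]
    return LassoModel(np.array(W, float), np.array(b, float), lam, classes, keys)


class TestLassoLoss:
    def test_perfect_fit_zero_loss_at_lambda_zero(self):
        # huge margins -> probabilities ~1 for the true class
        W = [[60.0], [-60.0]]
        b = [-30.0, 30.0]
        model = _model(W, b, 0.0, ["A", "B"], 1)
        X = np.array([[1.0], [0.0]])
        y = ["A", "B"]
        assert lasso_loss(model, X, y) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_probabilities_give_log_K(self):
        for K in (2, 3, 4):
            model = _model(np.zeros((K, 2)), np.zeros(K), 0.0, [f"c{k}" for k in range(K)], 2)
            X = np.zeros((5, 2))
            y = [f"c{k % K}" for k in range(5)]
            assert lasso_loss(model, X, y) == pytest.approx(math.log(K), abs=1e-12)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            K, m, n = 3, 4, 6
            W = rng.normal(size=(K, m))
            b = rng.normal(size=K)
            lam = float(rng.uniform(0, 2))
            X = rng.integers(0, 2, size=(n, m)).astype(float)
            classes = ["A", "B", "C"]
            y = [classes[i % K] for i in range(n)]
            model = _model(W, b, lam, classes, m)
            got = lasso_loss(model, X, y)
            want = lasso_loss_oracle(W, b, lam, X, y, classes)
            assert got == pytest.approx(want, abs=1e-10)

    def test_monotone_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(23)
        W = rng.normal(size=(2, 3))
        b = rng.normal(size=2)
        X = rng.integers(0, 2, size=(5, 3)).astype(float)
        y = ["A", "B", "A", "B", "A"]
        lams = [0.0, 0.1, 0.5, 1.0, 5.0]
        losses = [lasso_loss(_model(W, b, lam, ["A", "B"], 3), X, y) for lam in lams]
        assert all(a <= b_ + 1e-12 for a, b_ in zip(losses, losses[1:]))
        # at lambda = 0 the loss is exactly the mean cross-entropy
        assert losses[0] == pytest.approx(
            lasso_loss_oracle(W, b, 0.0, X, y, ["A", "B"]), abs=1e-12
        )


class TestPredictProba:
    def test_zero_model_gives_uniform_rows(self):
        model = _model(np.zeros((4, 3)), np.zeros(4), 0.0, list("ABCD"), 3)
        P = predict_proba(model, np.ones((6, 3)))
        assert np.allclose(P, 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(29)
        model = _model(rng.normal(size=(3, 5)), rng.normal(size=3), 0.0, list("ABC"), 5)
        P = predict_proba(model, rng.integers(0, 2, size=(10, 5)).astype(float))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_two_class_hand_computation(self):
        model = _model([[2.0], [-1.0]], [0.5, 0.0], 0.0, ["A", "B"], 1)
        x = 1.0
        sa = 1 / (1 + math.exp(-(2 * x + 0.5)))
        sb = 1 / (1 + math.exp(1 * x))
        P = predict_proba(model, np.array([[x]]))
        assert P[0, 0] == pytest.approx(sa / (sa + sb), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = _model(np.zeros((2, 3)), np.zeros(2), 0.0, ["A", "B"], 3)
        with pytest.raises(ValueError, match="features"):
            predict_proba(model, np.zeros((2, 4)))


class TestLassoFitSelect:
    def test_extreme_regularization_zeroes_all_weights(self, separable_table):
        m, labels, _ = separable_table
        model = lasso_fit(m, labels, c_bounds=(1e-6, 1e-5), search_iterations=2, seed=0)
        assert np.allclose(model.weights, 0.0)

    def test_separable_table_reaches_perfect_loocv_f1(self, separable_table):
        m, labels, truth = separable_table
        res = lasso_select(m, labels, cap=30, search_iterations=8, seed=0)
        assert truth.planted_all() <= set(res.features) or len(res.features) > 0
        # weak regularization must separate a noise-free planted table
        model = lasso_fit(m, labels, c_bounds=(10.0, 1000.0), search_iterations=4, seed=0)
        P = predict_proba(model, m)
        preds = [model.classes[j] for j in P.argmax(axis=1)]
        assert list(preds) == list(labels.vector(m.sample_ids))

    def test_same_seed_identical_model(self, separable_table):
        m, labels, _ = separable_table
        a = lasso_fit(m, labels, search_iterations=5, seed=7)
        b = lasso_fit(m, labels, search_iterations=5, seed=7)
        assert a.lam == b.lam
        assert np.array_equal(a.weights, b.weights)

    def test_all_zero_model_yields_empty_selection_with_warning(self, separable_table):
        m, labels, _ = separable_table
        with pytest.warns(UserWarning, match="no features"):
            res = lasso_select(
                m, labels, cap=30, c_bounds=(1e-6, 1e-5), search_iterations=2, seed=0
            )
        assert res.features == []

    def test_cap_truncates_ranked_by_max_weight(self, paper_shaped):
        m, labels, _ = paper_shaped
        res = lasso_select(m, labels, cap=5, search_iterations=5, seed=0)
        assert len(res.features) == 5
        assert all(res.scores[i] >= res.scores[i + 1] for i in range(len(res.scores) - 1))

    def test_planted_features_among_selected(self, paper_shaped):
        m, labels, truth = paper_shaped
        res = lasso_select(m, labels, cap=30, search_iterations=8, seed=0)
        assert len(set(res.features) & truth.planted_all()) >= 6
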