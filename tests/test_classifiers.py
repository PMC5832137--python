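"""The four multilabel classifiers against hand and brute-force oracles."""

import numpy as np
import pytest

from emrdx.classifiers import (
    bpmll_fit, bpmll_loss, bpmll_objective_grad, bpmll_predict, bpmll_score,
    cc_fit, cc_predict, cc_score,
    mlknn_fit, mlknn_predict, mlknn_score,
    rakel_fit, rakel_predict, rakel_score,
    rank_labels, sum_squares_loss,
)
from emrdx.classifiers.bpmll import _pack


class TestRanking:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.9, 0.1, 0.5], [1, 3, 2]),
            ([0.3, 0.3, 0.3], [1, 2, 3]),
            ([0.5, 0.9, 0.5], [2, 1, 3]),
        ],
    )
    def test_rank_labels(self, scores, expected):
        assert rank_labels(np.array(scores)).tolist() == expected

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_labels(np.array([0.1, np.nan]))


class TestBPMLLLoss:
    def test_equal_outputs_give_unit_loss(self):
        assert bpmll_loss(np.array([0.3, 0.3]), np.array([1, 0])) == pytest.approx(1.0)

    def test_margin_two_gives_exp_minus_two(self):
        got = bpmll_loss(np.array([2.0, 0.0]), np.array([1, 0]))
        assert got == pytest.approx(np.exp(-2), abs=1e-12)
        assert got == pytest.approx(0.1353, abs=1e-4)

    def test_monotone_decreasing_in_margin(self):
        margins = [0.0, 0.5, 1.0, 3.0, 10.0]
        losses = [bpmll_loss(np.array([m, 0.0]), np.array([1, 0])) for m in margins]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-4

    def test_degenerate_rows_rejected(self):
        with pytest.raises(ValueError):
            bpmll_loss(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_loss_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = rng.integers(2, 6)
            c = rng.normal(size=Q)
            y = np.zeros(Q, dtype=int)
            y[rng.choice(Q, size=rng.integers(1, Q), replace=False)] = 1
            if y.all() or not y.any():
                continue
            pairs = [
                np.exp(-(c[k] - c[l]))
                for k in range(Q) if y[k]
                for l in range(Q) if not y[l]
            ]
            expected = np.mean(pairs)
            assert bpmll_loss(c, y) == pytest.approx(expected, rel=1e-12)

    def test_legacy_sum_of_squares(self):
        assert sum_squares_loss(np.array([1.0, -1.0]), np.array([1.0, 1.0])) == 4.0


class TestBPMLLFit:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.X = rng.normal(size=(60, 5))
        W = rng.normal(size=(5, 3))
        self.Y = (self.X @ W > 0).astype(int)
        self.Y[self.Y.sum(axis=1) == 0, 0] = 1
        self.Y[self.Y.sum(axis=1) == 3, 2] = 0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 4))
        Y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
        d, h, Q = 4, 3, 3
        flat = rng.normal(size=d * h + h + h * Q + Q) * 0.3
        _, grad = bpmll_objective_grad(flat, X, Y, h, 1e-4)
        eps = 1e-6
        for i in range(0, flat.size, 5):
            plus, minus = flat.copy(), flat.copy()
            plus[i] += eps
            minus[i] -= eps
            num = (
                bpmll_objective_grad(plus, X, Y, h, 1e-4)[0]
                - bpmll_objective_grad(minus, X, Y, h, 1e-4)[0]
            ) / (2 * eps)
            assert abs(num - grad[i]) / max(abs(num), 1e-8) < 1e-5

    def test_loss_non_increasing_with_small_learning_rate(self):
        d, Q = 5, 3
        h = 3
        rng = np.random.default_rng(3)
        flat = _pack(
            rng.uniform(-0.05, 0.05, (d, h)), rng.uniform(-0.05, 0.05, h),
            rng.uniform(-0.05, 0.05, (h, Q)), rng.uniform(-0.05, 0.05, Q),
        )
        losses = []
        for _ in range(30):
            obj, grad = bpmll_objective_grad(flat, self.X, self.Y, h, 1e-5)
            losses.append(obj)
            flat = flat - 0.01 * grad
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_learns_linearly_separable_signal(self):
        from emrdx.metrics import average_precision
        model = bpmll_fit(self.X, self.Y, epochs=400, seed=4)
        ap = average_precision(bpmll_score(model, self.X), self.Y)
        assert ap >= 0.95

    def test_degenerate_rows_skipped_with_warning(self):
        Y = self.Y.copy()
        Y[0] = 1  # all-positive row
        with pytest.warns(UserWarning, match="skipped"):
            model = bpmll_fit(self.X, Y, epochs=5, seed=0)
        assert model.skipped_rows.tolist() == [0]

    def test_all_degenerate_raises(self):
        Y = np.ones((4, 2), dtype=int)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                bpmll_fit(np.eye(4), Y, epochs=2)

    def test_bipartition_consistent_with_scores_and_threshold(self):
        model = bpmll_fit(self.X, self.Y, epochs=50, seed=5)
        scores = bpmll_score(model, self.X)
        A = np.hstack([scores, np.ones((scores.shape[0], 1))])
        t = A @ model.threshold_coef
        np.testing.assert_array_equal(
            bpmll_predict(model, self.X), (scores > t[:, None]).astype(np.int8)
        )

    def test_fit_reproducible_given_seed(self):
        m1 = bpmll_fit(self.X, self.Y, epochs=20, seed=6)
        m2 = bpmll_fit(self.X, self.Y, epochs=20, seed=6)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.threshold_coef, m2.threshold_coef)


def brute_force_mlknn_scores(X, Y, k, s, queries):
    """Independent MLkNN posterior computation by direct enumeration."""
    p, Q = Y.shape
    scores = np.zeros((len(queries), Q))
    def knn(point, exclude=None):
        dists = np.linalg.norm(X - point, axis=1)
        order = [i for i in np.argsort(dists, kind="stable") if i != exclude]
        return order[:k]
    for j in range(Q):
        prior = (s + sum(Y[i, j] for i in range(p))) / (2 * s + p)
        kj = [0] * (k + 1)
        knj = [0] * (k + 1)
        for i in range(p):
            c = sum(Y[n, j] for n in knn(X[i], exclude=i))
            if Y[i, j]:
                kj[c] += 1
            else:
                knj[c] += 1
        for qi, q in enumerate(queries):
            c = sum(Y[n, j] for n in knn(q))
            pe_h = (s + kj[c]) / (s * (k + 1) + sum(kj))
            pe_nh = (s + knj[c]) / (s * (k + 1) + sum(knj))
            scores[qi, j] = prior * pe_h / (prior * pe_h + (1 - prior) * pe_nh)
    return scores


class TestMLkNN:
    def test_prior_formula(self):
        X = np.arange(8).reshape(4, 2).astype(float)
        Y = np.array([[1], [1], [1], [1]])
        model = mlknn_fit(X, Y, k=2, s=1.0)
        assert model.priors[0] == pytest.approx(5 / 6)

    def test_unanimous_neighbours_push_posterior_past_half(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        Y = np.array([[1, 0]] * 10 + [[0, 1]] * 10)
        model = mlknn_fit(X, Y, k=3, s=1.0)
        post = mlknn_score(model, np.array([[0.0, 0.0]]))
        assert post[0, 0] > 0.5 and post[0, 1] < 0.5
        np.testing.assert_array_equal(mlknn_predict(model, np.array([[0.0, 0.0]])),
                                      [[1, 0]])

    def test_five_instance_toy_matches_brute_force(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        Y = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1]])
        model = mlknn_fit(X, Y, k=2, s=1.0)
        queries = np.array([[0.5], [10.5], [5.0]])
        expected = brute_force_mlknn_scores(X, Y, 2, 1.0, queries)
        np.testing.assert_allclose(mlknn_score(model, queries), expected, atol=1e-12)

    def test_conditionals_normalised(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        Y = (rng.random((12, 4)) < 0.4).astype(int)
        model = mlknn_fit(X, Y, k=3, s=1.0)
        np.testing.assert_allclose(model.cond_pos.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.cond_neg.sum(axis=1), 1.0, atol=1e-12)

    def test_k_not_smaller_than_p_raises(self):
        with pytest.raises(ValueError):
            mlknn_fit(np.eye(3), np.ones((3, 1), dtype=int), k=3)


class TestRAkEL:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.X = rng.normal(size=(24, 3))
        W = rng.normal(size=(3, 4))
        self.Y = (self.X @ W > 0).astype(int)

    def test_full_labelset_reduces_to_label_powerset(self):
        model = rakel_fit(self.X, self.Y, k_r=4, m=1, seed=0)
        assert len(model.members) == 1
        assert model.members[0].labelset == (0, 1, 2, 3)
        scores = rakel_score(model, self.X)
        assert set(np.unique(scores)) <= {0.0, 1.0}

    def test_uncovered_label_scores_zero_with_warning(self):
        Y = np.hstack([self.Y, np.zeros((24, 1), dtype=int)])
        Y[:, 4] = (self.X[:, 0] > 0).astype(int)
        rng_hit = False
        # force coverage gap: k_r=1, m=2 distinct singletons out of 5
        with pytest.warns(UserWarning, match="no labelset"):
            model = rakel_fit(self.X, Y, k_r=1, m=2, seed=1)
        uncovered = np.flatnonzero(model.coverage() == 0)
        assert uncovered.size >= 1
        scores = rakel_score(model, self.X)
        assert np.all(scores[:, uncovered] == 0.0)

    def test_vote_fractions_match_hand_tally(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        Y = np.array([
            [1, 0, 0, 1], [1, 0, 0, 1], [1, 1, 0, 0],
            [0, 1, 1, 0], [0, 1, 1, 0], [0, 0, 1, 1],
        ])
        model = rakel_fit(X, Y, k_r=3, m=4, seed=3)
        scores = rakel_score(model, X)
        # tally votes by replaying every member classifier
        votes = np.zeros((6, 4))
        appear = np.zeros(4)
        for mem in model.members:
            for j in mem.labelset:
                appear[j] += 1
            if mem.clf is None:
                bits = np.tile(mem.classes[mem.constant_class], (6, 1))
            else:
                bits = mem.classes[mem.clf.predict(X)]
            for col, j in enumerate(mem.labelset):
                votes[:, j] += bits[:, col]
        np.testing.assert_allclose(scores, votes / np.maximum(appear, 1))

    def test_too_many_labelsets_requested(self):
        with pytest.raises(ValueError):
            rakel_fit(self.X, self.Y, k_r=4, m=2)

    def test_bipartition_is_majority_vote(self):
        model = rakel_fit(self.X, self.Y, k_r=2, m=5, seed=4)
        scores = rakel_score(model, self.X)
        np.testing.assert_array_equal(
            rakel_predict(model, self.X), (scores > 0.5).astype(np.int8)
        )

    def test_reproducible_given_seed(self):
        m1 = rakel_fit(self.X, self.Y, k_r=2, m=4, seed=5)
        m2 = rakel_fit(self.X, self.Y, k_r=2, m=4, seed=5)
        assert [m.labelset for m in m1.members] == [m.labelset for m in m2.members]
        np.testing.assert_array_equal(rakel_score(m1, self.X), rakel_score(m2, self.X))


class TestClassifierChains:
    def test_single_label_chain_equals_binary_classifier(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        model = cc_fit(X, y[:, None])
        ref = LogisticRegression(max_iter=1000, C=10.0).fit(X, y)
        np.testing.assert_allclose(
            cc_score(model, X)[:, 0], ref.predict_proba(X)[:, 1], atol=1e-9
        )

    def test_copied_label_perfectly_predicted_downstream(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y0 = (X[:, 0] + 0.2 * rng.normal(size=40) > 0).astype(int)
        Y = np.stack([y0, y0], axis=1)  # label 1 copies label 0
        model = cc_fit(X, Y)
        pred = cc_predict(model, X)
        np.testing.assert_array_equal(pred[:, 1], pred[:, 0])

    def test_constant_column_predicted_constant_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        Y = np.zeros((10, 2), dtype=int)
        Y[:, 0] = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            model = cc_fit(X, Y)
        assert np.all(cc_score(model, X)[:, 1] == 0.0)
        assert np.all(cc_predict(model, X)[:, 1] == 0)

    def test_invalid_chain_order_rejected(self):
        with pytest.raises(ValueError):
            cc_fit(np.eye(4), np.eye(4, 2, dtype=int), chain_order=[0, 0])

    def test_scores_reported_in_original_label_order(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        Y = (rng.random((30, 3)) < 0.5).astype(int)
        m_fwd = cc_fit(X, Y, chain_order=[0, 1, 2])
        m_rev = cc_fit(X, Y, chain_order=[2, 1, 0])
        # first classifier of the reversed chain sees only X for label 2
        m_single = cc_fit(X, Y[:, 2][:, None])
        np.testing.assert_allclose(cc_score(m_rev, X)[:, 2], cc_score(m_single, X)[:, 0])
        assert cc_score(m_fwd, X).shape == (30, 3)
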