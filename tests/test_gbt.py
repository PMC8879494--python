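"""Second-order boosting: closed forms, tree growth, ensemble behavior."""

import math

import numpy as np
import pytest

from prip import gbt
from prip.gbt import (
    BoostedModel,
    GBTParams,
    GradHess,
    fit,
    grow_tree,
    leaf_objective,
    leaf_weight,
    logistic_grad_hess,
    split_gain,
)


class TestGradHess:
    def test_closed_forms_at_zero_margin(self):
        gh = logistic_grad_hess(np.array([1.0]), np.array([0.0]))
        assert gh.g[0] == pytest.approx(-0.5) and gh.h[0] == pytest.approx(0.25)
        gh = logistic_grad_hess(np.array([0.0]), np.array([0.0]))
        assert gh.g[0] == pytest.approx(0.5) and gh.h[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("y,w", [(1.0, 1.0), (0.0, 1.0), (1.0, 3.5)])
    def test_finite_difference_check(self, y, w):
        margin, eps = 0.3, 1e-5

        def loss(m):
            p = 1 / (1 + math.exp(-m))
            return -w * math.log(p) if y == 1 else -math.log(1 - p)

        gh = logistic_grad_hess(np.array([y]), np.array([margin]), w)
        g_num = (loss(margin + eps) - loss(margin - eps)) / (2 * eps)
        h_num = (loss(margin + eps) - 2 * loss(margin) + loss(margin - eps)) / eps**2
        assert gh.g[0] == pytest.approx(g_num, abs=1e-6)
        assert gh.h[0] == pytest.approx(h_num, abs=1e-4)

    def test_hessian_nonnegative(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100).astype(float)
        gh = logistic_grad_hess(y, rng.normal(size=100), 2.0)
        assert (gh.h >= 0).all()


class TestClosedForms:
    def test_leaf_weight(self):
        assert leaf_weight(0.0, 5.0, 1.0) == 0.0
        assert leaf_weight(2.0, 3.0, 1.0) == -0.5

    def test_leaf_weight_minimizes_objective(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            G = rng.normal() * 5
            H = rng.uniform(0.1, 5)
            lam = rng.uniform(0, 3)
            w_star = leaf_weight(G, H, lam)
            obj = lambda w: G * w + 0.5 * (H + lam) * w * w
            best = obj(w_star)
            probes = rng.normal(scale=3, size=1000)
            assert (obj(probes) >= best - 1e-12).all()

    def test_leaf_objective_closed_form(self):
        assert leaf_objective([(2.0, 3.0)], 1.0, 1.0) == pytest.approx(0.5)
        assert leaf_objective([(0.0, 1.0), (0.0, 2.0)], 0.5, 0.0) == 0.0

    def test_leaf_objective_equals_substituted_optimum(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            leaves = [(rng.normal() * 4, rng.uniform(0.1, 4)) for _ in range(rng.integers(1, 6))]
            lam, gamma = rng.uniform(0, 2), rng.uniform(0, 2)
            direct = leaf_objective(leaves, lam, gamma)
            manual = sum(
                G * leaf_weight(G, H, lam) + 0.5 * (H + lam) * leaf_weight(G, H, lam) ** 2
                for G, H in leaves
            ) + gamma * len(leaves)
            assert direct == pytest.approx(manual, rel=1e-12)

    def test_split_gain(self):
        assert split_gain(1.0, 1.0, 1.0, 1.0, 0.0, 0.0) == pytest.approx(0.0)
        assert split_gain(-2.0, 2.0, 2.0, 2.0, 0.0, 0.0) == pytest.approx(2.0)

    def test_gain_linear_in_gamma(self):
        base = split_gain(-1.0, 2.0, 3.0, 1.5, 0.7, 0.0)
        for gamma in (0.3, 1.0, 5.0):
            assert split_gain(-1.0, 2.0, 3.0, 1.5, 0.7, gamma) == pytest.approx(base - gamma)


def _brute_force_best_split(X, g, h, lam, gamma):
    """Exhaustive (feature, midpoint-threshold) enumeration; ties broken by
    lowest feature then lowest threshold.  Independent of the tree code."""
    best = (0.0, None, None)  # gain, feature, threshold
    Gt, Ht = g.sum(), h.sum()
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            left = X[:, f] < thr
            GL, HL = g[left].sum(), h[left].sum()
            gain = 0.5 * (
                GL**2 / (HL + lam)
                + (Gt - GL) ** 2 / (Ht - HL + lam)
                - Gt**2 / (Ht + lam)
            ) - gamma
            if gain > best[0] + 1e-12:
                best = (gain, f, thr)
    return best


class TestGrowTree:
    def test_hand_case_depth_one(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        gh = GradHess(np.array([-1.0, -1.0, 1.0, 1.0]), np.ones(4))
        params = GBTParams(max_depth=1, reg_lambda=0.0, reg_gamma=0.0, min_child_hessian=0.0)
        node = grow_tree(X, gh, params)
        assert node.feature_index == 0 and node.threshold == pytest.approx(1.5)
        assert node.left.weight == pytest.approx(1.0)
        assert node.right.weight == pytest.approx(-1.0)

    def test_homogeneous_gradients_give_single_leaf(self):
        X = np.ones((6, 2))
        gh = GradHess(np.full(6, 0.7), np.ones(6))
        node = grow_tree(X, gh, GBTParams(max_depth=3, min_child_hessian=0.0))
        assert node.is_leaf

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            X = rng.normal(size=(8, 3))
            g = rng.normal(size=8)
            h = rng.uniform(0.1, 2.0, size=8)
            lam = rng.uniform(0, 2)
            gamma = rng.uniform(0, 0.2)
            params = GBTParams(
                max_depth=1, reg_lambda=lam, reg_gamma=gamma, min_child_hessian=0.0
            )
            node = grow_tree(X, GradHess(g, h), params)
            gain, f, thr = _brute_force_best_split(X, g, h, lam, gamma)
            if f is None:
                assert node.is_leaf
            else:
                assert node.feature_index == f
                assert node.threshold == pytest.approx(thr)

    def test_split_gain_decomposition(self):
        """Gain of the chosen split equals parent objective minus children
        objective sum (with the per-leaf gamma accounting)."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        g = rng.normal(size=30)
        h = rng.uniform(0.2, 1.5, size=30)
        lam, gamma = 1.0, 0.05
        params = GBTParams(max_depth=1, reg_lambda=lam, reg_gamma=gamma, min_child_hessian=0.0)
        node = grow_tree(X, GradHess(g, h), params)
        assert not node.is_leaf
        left = X[:, node.feature_index] < node.threshold
        GL, HL = g[left].sum(), h[left].sum()
        GR, HR = g[~left].sum(), h[~left].sum()
        gain = split_gain(GL, HL, GR, HR, lam, gamma)
        parent_obj = leaf_objective([(GL + GR, HL + HR)], lam, gamma)
        children_obj = leaf_objective([(GL, HL), (GR, HR)], lam, gamma)
        assert parent_obj - children_obj == pytest.approx(gain)


def _tree_complexity(node):
    leaves = node.leaves()
    return len(leaves), sum(l.weight**2 for l in leaves)


def _regularized_objective(model, X, y):
    margins = model.predict_margin(X)
    p = 1 / (1 + np.exp(-margins))
    w = np.where(y == 1, model.params.scale_pos_weight, 1.0)
    loss = -(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum()
    reg = 0.0
    for t in model.trees:
        T, w2 = _tree_complexity(t)
        reg += model.params.reg_gamma * T + 0.5 * model.params.reg_lambda * w2
    return loss + reg


class TestFit:
    def test_separable_toy_converges(self):
        X = np.array([[0.0]] * 5 + [[1.0]] * 5)
        y = np.array([0] * 5 + [1] * 5)
        model = fit(X, y, GBTParams(n_rounds=20, max_depth=1, scale_pos_weight=1.0))
        pred = (model.predict_proba(X) >= 0.5).astype(int)
        assert (pred == y).all()

    def test_zero_rounds_predicts_base_score(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        model = fit(X, y, GBTParams(n_rounds=0, base_score=0.3))
        assert np.allclose(model.predict_proba(X), 0.3)

    def test_objective_non_increasing_across_rounds(self):
        """The regularized training objective decreases monotonically for
        moderate learning rates on 20 random small datasets."""
        rng = np.random.default_rng(5)
        for trial in range(20):
            X = rng.normal(size=(40, 3))
            y = (X[:, 0] + rng.normal(scale=1.0, size=40) > 0).astype(int)
            if y.min() == y.max():
                continue
            params = GBTParams(
                n_rounds=1, max_depth=2, learning_rate=0.3, scale_pos_weight=1.0
            )
            prev = None
            trees = []
            for rounds in range(1, 9):
                model = fit(X, y, GBTParams(n_rounds=rounds, max_depth=2,
                                            learning_rate=0.3, scale_pos_weight=1.0))
                obj = _regularized_objective(model, X, y)
                if prev is not None:
                    assert obj <= prev + 1e-9
                prev = obj

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))  # continuous features: all values distinct
        y = (X[:, 1] > 0).astype(int)
        perm = rng.permutation(60)
        m1 = fit(X, y, GBTParams(n_rounds=5, max_depth=3))
        m2 = fit(X[perm], y[perm], GBTParams(n_rounds=5, max_depth=3))
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_duplicated_feature_changes_nothing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] - X[:, 2] > 0).astype(int)
        m1 = fit(X, y, GBTParams(n_rounds=5, max_depth=3))
        m2 = fit(np.hstack([X, X[:, [0]]]), y, GBTParams(n_rounds=5, max_depth=3))
        assert np.array_equal(
            m1.predict_proba(X), m2.predict_proba(np.hstack([X, X[:, [0]]]))
        )

    def test_matches_reference_boosting_implementation(self):
        """Cross-implementation check against xgboost's exact greedy trees
        on an identical configuration."""
        xgb = pytest.importorskip("xgboost")
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 5))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.5, size=300) > 0).astype(int)
        params = GBTParams(
            n_rounds=10, max_depth=2, learning_rate=0.3, reg_lambda=1.0,
            reg_gamma=0.0, min_child_hessian=1.0, scale_pos_weight=1.0,
        )
        mine = fit(X, y, params).predict_proba(X)
        ref = (
            xgb.XGBClassifier(
                n_estimators=10, max_depth=2, learning_rate=0.3, reg_lambda=1.0,
                gamma=0.0, min_child_weight=1.0, base_score=0.5,
                tree_method="exact", objective="binary:logistic",
            )
            .fit(X, y)
            .predict_proba(X)[:, 1]
        )
        assert np.abs(mine - ref).mean() < 0.05

    def test_auto_scale_pos_weight(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        y = np.array([1] * 4 + [0] * 16)
        model = fit(X, y, GBTParams(n_rounds=1, max_depth=1))
        assert model.params.scale_pos_weight == pytest.approx(4.0)

    def test_probabilities_strictly_inside_unit_interval(self, small_chains, tiny_dictionary):
        from prip import encode

        X, y = encode.encode_chains(small_chains[:10], 3, tiny_dictionary)
        model = fit(X, y, GBTParams(n_rounds=5, max_depth=3))
        p = model.predict_proba(X)
        assert ((p > 0) & (p < 1)).all()

    def test_feature_dim_checked(self):
        X = np.zeros((4, 3))
        y = np.array([0, 1, 0, 1])
        model = fit(X, y, GBTParams(n_rounds=1, max_depth=1))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 5)))


class TestSerialization:
    def test_round_trip_exact(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit(X, y, GBTParams(n_rounds=4, max_depth=3))
        back = BoostedModel.from_dict(model.to_dict())
        assert np.array_equal(back.predict_proba(X), model.predict_proba(X))

    def test_squared_loss_mode(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = fit(X, y, GBTParams(n_rounds=10, max_depth=1, loss="squared",
                                    scale_pos_weight=1.0))
        m = model.predict_margin(X)
        assert m[0] < 0.5 < m[-1]
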