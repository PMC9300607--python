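"""Threshold, tree and forest classifiers on the three diameters."""

import numpy as np
import pytest

from nodesphere.classifiers import (
    ForestParams,
    ThresholdClassifier,
    TreeParams,
    fit_forest,
    fit_threshold,
    fit_tree,
    model_from_json,
    model_to_json,
    predict_nodes,
)
from nodesphere.morphometry import score_nodes
from nodesphere.simulate import CohortConfig, cohort_to_node_frame, generate_cohort
from tests.conftest import two_class_scores


def brute_force_youden(scores, labels, grid=2000):
    """Independent fine-grid maximizer of J for the >= rule."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    ts = np.linspace(s.min() - 1e-6, s.max() + 1e-6, grid)
    best_j, best_t = -2.0, None
    for t in ts:
        pred = s >= t
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        if sens + spec - 1 > best_j:
            best_j, best_t = sens + spec - 1, t
    return best_t, best_j


class TestThreshold:
    def test_perfectly_separable_midpoint(self):
        clf = fit_threshold([0.9, 0.8, 0.2, 0.3], [1, 1, 0, 0])
        assert clf.cutoff == pytest.approx(0.55)
        assert clf.youden_j == pytest.approx(1.0)
        assert clf.informative

    def test_degenerate_identical_scores(self):
        clf = fit_threshold([0.5, 0.5, 0.5], [1, 0, 1])
        assert clf.cutoff == 0.5
        assert clf.youden_j == 0.0
        assert not clf.informative

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_threshold([0.1, 0.2], [1, 1])

    def test_matches_grid_search_oracle(self, rng):
        scores, labels = two_class_scores(rng, 60, 140)
        clf = fit_threshold(scores, labels)
        t_star, j_star = brute_force_youden(scores, labels)
        assert abs(clf.cutoff - t_star) < 0.05
        assert clf.youden_j == pytest.approx(j_star, abs=1e-9)

    def test_matches_sklearn_roc_youden(self, rng):
        """Cross-check J* against sklearn's ROC thresholds."""
        from sklearn.metrics import roc_curve

        scores, labels = two_class_scores(rng, 50, 120)
        clf = fit_threshold(scores, labels)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert clf.youden_j == pytest.approx((tpr - fpr).max(), abs=1e-12)

    def test_monotone_in_score(self, rng):
        scores, labels = two_class_scores(rng, 40, 80)
        clf = fit_threshold(scores, labels)
        s = np.sort(rng.random(100))
        preds = clf.predict_scores(s)
        assert (np.diff(preds) >= 0).all()  # raising score never flips to 0

    def test_predict_from_axes(self):
        clf = ThresholdClassifier("sphericity", 0.7)
        assert predict_nodes(clf, [(10, 10, 10)]).tolist() == [1]
        # sphericity(3,7,12) = cbrt(252)/12 ~ 0.526 < 0.7
        assert predict_nodes(clf, [(3, 7, 12)]).tolist() == [0]


def _axis_data(rng):
    cfg = CohortConfig(n_patients=60, seed=int(rng.integers(2**31)))
    df = score_nodes(cohort_to_node_frame(generate_cohort(cfg)))
    X = df[["a_mm", "b_mm", "c_mm"]].to_numpy()
    y = df["node_label"].to_numpy(int)
    return X, y


def exhaustive_depth2_accuracy(X, y):
    """Best training accuracy of any depth-2 axis-threshold tree.

    For the accuracy objective the two subtrees are independent given
    the root split, so exhaustive root x best-leaf-rule per side is the
    global optimum.
    """

    def best_leaf_rule_correct(Xs, ys):
        # best of: constant leaf, or one split with constant leaves
        n = len(ys)
        best = max((ys == 0).sum(), (ys == 1).sum())
        for f in range(3):
            v = Xs[:, f]
            order = np.argsort(v)
            vs, yo = v[order], ys[order]
            cuts = np.nonzero(np.diff(vs) > 0)[0]
            if cuts.size == 0:
                continue
            cum1 = np.cumsum(yo)
            left_n = cuts + 1
            left1 = cum1[cuts]
            left0 = left_n - left1
            right1 = cum1[-1] - left1
            right0 = (n - left_n) - right1
            correct = np.maximum(left0, left1) + np.maximum(right0, right1)
            best = max(best, int(correct.max()))
        return best

    n = len(y)
    best = best_leaf_rule_correct(X, y)
    for f in range(3):
        v = X[:, f]
        for t in np.unique(v)[:-1]:
            left = v <= t
            c = best_leaf_rule_correct(X[left], y[left]) + best_leaf_rule_correct(
                X[~left], y[~left]
            )
            best = max(best, c)
    return best / n


class TestTree:
    def test_separable_single_feature_depth1(self):
        X = np.array([[3, 5, 20], [4, 6, 22], [3, 6, 8], [4, 5, 9]], float)
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y, TreeParams(max_depth=3, min_leaf=1))
        assert tree.root.feature == 2  # splits on c
        assert (tree.predict(X) == y).all()
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    def test_training_accuracy_beats_majority(self, rng):
        X, y = _axis_data(rng)
        tree = fit_tree(X, y)
        acc = (tree.predict(X) == y).mean()
        assert acc >= max(y.mean(), 1 - y.mean())

    def test_depth2_bracketed_by_exhaustive_oracle(self, rng):
        X, y = _axis_data(rng)
        n = 137
        X, y = X[:n], y[:n]
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        a_star = exhaustive_depth2_accuracy(X, y)
        greedy2 = fit_tree(X, y, TreeParams(max_depth=2, min_leaf=1))
        acc2 = (greedy2.predict(X) == y).mean()
        full = fit_tree(X, y, TreeParams(max_depth=None, min_leaf=1))
        acc_full = (full.predict(X) == y).mean()
        assert acc2 <= a_star + 1e-12
        assert acc_full >= a_star - 1e-12

    def test_matches_sklearn_training_accuracy(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X, y = _axis_data(rng)
        ours = fit_tree(X, y, TreeParams(max_depth=4, min_leaf=5))
        sk = DecisionTreeClassifier(
            max_depth=4, min_samples_leaf=5, random_state=0
        ).fit(X, y)
        ours_acc = (ours.predict(X) == y).mean()
        sk_acc = sk.score(X, y)
        assert ours_acc == pytest.approx(sk_acc, abs=1e-9)

    def test_leaf_counts_sum_to_training_size(self, rng):
        X, y = _axis_data(rng)
        tree = fit_tree(X, y)
        totals = []

        def visit(node):
            if node.is_leaf:
                totals.append(sum(node.counts))
            else:
                visit(node.left)
                visit(node.right)

        visit(tree.root)
        assert sum(totals) == len(y)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            fit_tree([(1, 2, 3)] * 4, [0, 1, 0, 1], TreeParams(min_leaf=0))
        with pytest.raises(ValueError):
            fit_tree([(1, 2, 3)] * 4, [0, 0, 0, 0])

    def test_json_roundtrip(self, rng):
        X, y = _axis_data(rng)
        tree = fit_tree(X, y)
        back = model_from_json(model_to_json(tree))
        assert (back.predict(X) == tree.predict(X)).all()


class TestForest:
    def test_single_tree_no_bootstrap_equals_tree(self, rng):
        X, y = _axis_data(rng)
        params = ForestParams(
            n_trees=1, features_per_split=3, min_leaf=5, max_depth=4,
            bootstrap=False, seed=0,
        )
        forest = fit_forest(X, y, params)
        tree = fit_tree(X, y, TreeParams(max_depth=4, min_leaf=5))
        assert (forest.predict(X) == tree.predict(X)).all()

    def test_seeded_determinism(self, rng):
        X, y = _axis_data(rng)
        p = ForestParams(n_trees=20, seed=5)
        f1, f2 = fit_forest(X, y, p), fit_forest(X, y, p)
        assert (f1.predict(X) == f2.predict(X)).all()
        assert f1.oob_error == f2.oob_error
        assert f1.importances == f2.importances

    def test_adding_trees_preserves_early_trees(self, rng):
        """Counter-based seeding: tree k is independent of n_trees."""
        X, y = _axis_data(rng)
        f10 = fit_forest(X, y, ForestParams(n_trees=10, seed=3))
        f25 = fit_forest(X, y, ForestParams(n_trees=25, seed=3))
        for t_small, t_big in zip(f10.trees, f25.trees):
            assert t_small.to_dict() == t_big.to_dict()

    def test_high_accuracy_on_separable_classes(self, separated_params):
        cfg = CohortConfig(
            n_patients=80, class_params=separated_params, seed=21
        )
        df = cohort_to_node_frame(generate_cohort(cfg))
        X = df[["a_mm", "b_mm", "c_mm"]].to_numpy()
        y = df["node_label"].to_numpy(int)
        forest = fit_forest(X, y, ForestParams(n_trees=100, seed=1))
        assert (forest.predict(X) == y).mean() >= 0.95

    def test_oob_close_to_holdout(self, separated_params):
        """OOB error estimates holdout error on an independent draw."""
        train_cfg = CohortConfig(
            n_patients=120, class_params=separated_params, seed=31
        )
        test_cfg = CohortConfig(
            n_patients=120, class_params=separated_params, seed=32
        )
        df_tr = cohort_to_node_frame(generate_cohort(train_cfg))
        df_te = cohort_to_node_frame(generate_cohort(test_cfg))
        Xtr = df_tr[["a_mm", "b_mm", "c_mm"]].to_numpy()
        ytr = df_tr["node_label"].to_numpy(int)
        forest = fit_forest(Xtr, ytr, ForestParams(n_trees=100, seed=2))
        Xte = df_te[["a_mm", "b_mm", "c_mm"]].to_numpy()
        yte = df_te["node_label"].to_numpy(int)
        holdout = (forest.predict(Xte) != yte).mean()
        assert abs(forest.oob_error - holdout) < 0.03

    def test_tie_vote_is_non_metastatic(self, rng):
        X, y = _axis_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=2, seed=4))
        # force an exact 50/50 vote by replacing the trees' predictions
        votes = np.array([t.predict(X[:1])[0] for t in forest.trees])
        if votes.sum() == 1:  # genuine tie occurred
            assert forest.predict(X[:1])[0] == 0

    def test_importances_nonneg_and_validation(self, rng):
        X, y = _axis_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=30, seed=6))
        assert all(v >= 0 for v in forest.importances.values())
        with pytest.raises(ValueError):
            fit_forest(X, y, ForestParams(features_per_split=4))

    def test_json_roundtrip(self, rng):
        X, y = _axis_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=5, seed=8))
        back = model_from_json(model_to_json(forest))
        assert (back.predict(X) == forest.predict(X)).all()
        assert back.oob_error == forest.oob_error


def test_threshold_convergence_to_density_crossing():
    """Fitted Youden cutoff and rates converge to the analytic values
    implied by the two truncated-normal generating score laws."""
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    mu0, mu1, sd = 0.60, 0.85, 0.08

    def tn(mu):
        return truncnorm((0 - mu) / sd, (1 - mu) / sd, loc=mu, scale=sd)

    d0, d1 = tn(mu0), tn(mu1)
    t_star = brentq(lambda x: d0.pdf(x) - d1.pdf(x), mu0, mu1)
    sens_star = 1 - d1.cdf(t_star)
    spec_star = d0.cdf(t_star)

    cfg = CohortConfig(n_patients=2000, nodes_per_patient=(5, 10), seed=41)
    df = score_nodes(cohort_to_node_frame(generate_cohort(cfg)))
    y = df["node_label"].to_numpy(int)
    s = df["sphericity"].to_numpy()
    clf = fit_threshold(s, y)
    assert abs(clf.cutoff - t_star) < 0.02
    pred = clf.predict_scores(s)
    assert abs(pred[y == 1].mean() - sens_star) < 0.02
    assert abs(1 - pred[y == 0].mean() - spec_star) < 0.02
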