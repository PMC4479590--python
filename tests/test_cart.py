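"""CART growth, pruning, cross-validation and rule export.

Oracle strategy: best_split is checked against a brute-force enumeration of
every (feature, midpoint) candidate written independently here; the
cost-complexity ladder is checked against a naive re-implementation of
weakest-link pruning; root splits are cross-checked against scikit-learn's
CART on datasets with a unique optimum.
"""

import itertools
import re

import numpy as np
import pytest

from steptree.cart import (
    DecisionTree,
    best_split,
    cost_complexity_path,
    cv_risk,
    export_rules,
    gini_impurity,
    grow_tree,
    predict,
    prune_to_size,
    select_size,
    stratified_folds,
)


def brute_force_best_split(X, y, min_leaf=1, feature_names=("distance_m", "angle_deg")):
    """Independent exhaustive search over every (feature, midpoint) candidate."""
    n = len(y)
    counts = {c: np.sum(y == c) for c in set(y.tolist())}
    parent = 1.0 - sum((v / n) ** 2 for v in counts.values())
    best = None
    for j, name in enumerate(feature_names[: X.shape[1]]):
        for threshold in sorted(
            {
                0.5 * (a + b)
                for a, b in itertools.pairwise(sorted(set(X[:, j].tolist())))
            }
        ):
            left = y[X[:, j] <= threshold]
            right = y[X[:, j] > threshold]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gl = 1.0 - sum(
                (np.sum(left == c) / len(left)) ** 2 for c in set(left.tolist())
            )
            gr = 1.0 - sum(
                (np.sum(right == c) / len(right)) ** 2 for c in set(right.tolist())
            )
            gain = parent - len(left) / n * gl - len(right) / n * gr
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (name, threshold, gain)
    return best


class TestGini:
    def test_pure_node(self):
        assert gini_impurity({"A": 4}) == 0.0

    def test_even_two_class(self):
        assert gini_impurity({"A": 2, "B": 2}) == 0.5

    def test_four_even_classes(self):
        assert gini_impurity({"A": 1, "B": 1, "C": 1, "D": 1}) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity({"A": 0})


class TestBestSplit:
    def test_hand_worked_example(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array(["F", "F", "W", "W"], dtype=object)
        feature, threshold, gain = best_split(X, y, min_leaf=1)
        assert feature == "distance_m"
        assert threshold == 6.0
        assert gain == pytest.approx(0.5)

    def test_single_class_returns_none(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        y = np.array(["F"] * 8, dtype=object)
        assert best_split(X, y) is None

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            X = rng.integers(0, 6, size=(n, 2)).astype(float)
            y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=n)
            ours = best_split(X, y, min_leaf=1)
            oracle = brute_force_best_split(X, y, min_leaf=1)
            if oracle is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours[2] == pytest.approx(oracle[2], abs=1e-12)

    def test_matches_sklearn_root_split(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        checked = 0
        for _ in range(120):
            n = int(rng.integers(8, 25))
            X = rng.normal(size=(n, 2))
            y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=n)
            ours = best_split(X, y, min_leaf=1)
            if ours is None:
                continue
            # skip near-ties, where implementations may differ legitimately
            second = brute_force_second_best(X, y)
            if second is not None and ours[2] - second < 1e-6:
                continue
            clf = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0)
            clf.fit(X, y)
            j = {"distance_m": 0, "angle_deg": 1}[ours[0]]
            assert clf.tree_.feature[0] == j
            # sklearn stores features as float32, so thresholds match only
            # to single precision
            assert clf.tree_.threshold[0] == pytest.approx(ours[1], rel=1e-6, abs=1e-5)
            checked += 1
        assert checked >= 30


def brute_force_second_best(X, y, feature_names=("distance_m", "angle_deg")):
    """Gain of the runner-up candidate split (for tie detection)."""
    n = len(y)
    counts = {c: np.sum(y == c) for c in set(y.tolist())}
    parent = 1.0 - sum((v / n) ** 2 for v in counts.values())
    gains = []
    for j in range(X.shape[1]):
        for threshold in {
            0.5 * (a + b) for a, b in itertools.pairwise(sorted(set(X[:, j].tolist())))
        }:
            left, right = y[X[:, j] <= threshold], y[X[:, j] > threshold]
            gl = 1.0 - sum((np.sum(left == c) / len(left)) ** 2 for c in set(left.tolist()))
            gr = 1.0 - sum((np.sum(right == c) / len(right)) ** 2 for c in set(right.tolist()))
            gains.append((parent - len(left) / n * gl - len(right) / n * gr, j, threshold))
    gains.sort(reverse=True)
    return gains[1][0] if len(gains) > 1 else None


class TestGrowTree:
    def test_linearly_separable_depth_one(self):
        X = np.column_stack([np.r_[np.zeros(10), np.ones(10) * 50], np.zeros(20)])
        y = np.array(["Resting"] * 10 + ["Walking"] * 10, dtype=object)
        tree = grow_tree(X, y, ["Resting", "Walking"], min_leaf=5)
        assert tree.n_terminal == 2
        assert tree.root.threshold == pytest.approx(25.0)
        assert np.all(tree.predict(X) == y)

    def test_pure_input_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        y = np.array(["Foraging"] * 12, dtype=object)
        tree = grow_tree(X, y, ["Foraging"])
        assert tree.n_terminal == 1

    def test_training_accuracy_beats_majority_baseline(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=80, p=[0.5, 0.3, 0.2])
        tree = grow_tree(X, y, ["F", "L", "W"], min_leaf=5)
        acc = np.mean(tree.predict(X) == y)
        baseline = max(np.mean(y == c) for c in "FLW")
        assert acc >= baseline

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(np.empty((0, 2)), np.array([], dtype=object), ["F"])

    def test_children_counts_sum_to_parent(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.choice(np.array(["F", "L"], dtype=object), size=60)
        tree = grow_tree(X, y, ["F", "L"], min_leaf=5)
        for node in tree.nodes.values():
            if not node.is_leaf:
                left, right = tree.nodes[node.left], tree.nodes[node.right]
                for c in tree.classes:
                    assert node.class_counts[c] == (
                        left.class_counts[c] + right.class_counts[c]
                    )


def _subtree_ids(tree, root_id):
    ids, stack = [], [root_id]
    while stack:
        i = stack.pop()
        ids.append(i)
        node = tree.nodes[i]
        if not node.is_leaf:
            stack.extend([node.left, node.right])
    return ids


def naive_weakest_link(tree):
    """Independent re-implementation of weakest-link pruning."""
    n_total = sum(tree.root.class_counts.values())

    def err(node):
        return (
            sum(node.class_counts.values()) - max(node.class_counts.values())
        ) / n_total

    ladder = [tree.copy()]
    current = tree.copy()
    while current.n_terminal > 1:
        g = {}
        for i, node in current.nodes.items():
            if node.is_leaf:
                continue
            leaves = [
                j for j in _subtree_ids(current, i) if current.nodes[j].is_leaf
            ]
            g[i] = (err(node) - sum(err(current.nodes[j]) for j in leaves)) / (
                len(leaves) - 1
            )
        g_min = min(g.values())
        for i in sorted(k for k, v in g.items() if v <= g_min + 1e-12):
            if i in current.nodes and not current.nodes[i].is_leaf:
                node = current.nodes[i]
                for k in _subtree_ids(current, i):
                    if k != i:
                        del current.nodes[k]
                node.split_feature = node.threshold = node.left = node.right = None
        ladder.append(current.copy())
    return ladder


class TestCostComplexityPath:
    def test_single_leaf_tree(self):
        X = np.zeros((6, 2))
        y = np.array(["F"] * 6, dtype=object)
        tree = grow_tree(X, y, ["F"])
        path = cost_complexity_path(tree)
        assert len(path) == 1 and path[0][0] == 0.0

    def test_nested_subtrees_and_monotone_alpha(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=50)
        tree = grow_tree(X, y, ["F", "L", "W"], min_leaf=3)
        path = cost_complexity_path(tree)
        alphas = [a for a, _ in path]
        assert alphas == sorted(alphas)
        for (_, bigger), (_, smaller) in itertools.pairwise(path):
            assert set(smaller.nodes) < set(bigger.nodes)
        assert path[-1][1].n_terminal == 1

    def test_matches_naive_weakest_link(self, rng):
        for _ in range(10):
            X = rng.integers(0, 5, size=(20, 2)).astype(float)
            y = rng.choice(np.array(["F", "L"], dtype=object), size=20)
            tree = grow_tree(X, y, ["F", "L"], min_leaf=2)
            ladder = cost_complexity_path(tree)
            naive = naive_weakest_link(tree)
            assert [set(t.nodes) for _, t in ladder] == [set(t.nodes) for t in naive]

    def test_training_accuracy_nondecreasing_in_size(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=60)
        tree = grow_tree(X, y, ["F", "L", "W"], min_leaf=4)
        path = cost_complexity_path(tree)
        accs = [
            (t.n_terminal, np.mean(t.predict(X) == y))
            for _, t in sorted(path, key=lambda e: e[1].n_terminal)
        ]
        for (s1, a1), (s2, a2) in itertools.pairwise(accs):
            assert a2 >= a1 - 1e-12


class TestCVRisk:
    def _separable(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [
                np.column_stack([rng.normal(3, 0.3, 30), rng.normal(120, 20, 30)]),
                np.column_stack([rng.normal(55, 2, 30), rng.normal(30, 10, 30)]),
            ]
        )
        y = np.array(["Resting"] * 30 + ["Walking"] * 30, dtype=object)
        return X, y

    def test_zero_risk_at_separating_size(self):
        X, y = self._separable()
        curve = cv_risk(X, y, ["Resting", "Walking"], k=5, repeats=2, min_leaf=5, seed=1)
        assert curve.risk(2) == 0.0

    def test_root_risk_equals_minority_fraction(self):
        X, y = self._separable()
        curve = cv_risk(X, y, ["Resting", "Walking"], k=5, repeats=2, min_leaf=5, seed=1)
        assert curve.risk(1) == pytest.approx(0.5, abs=0.05)

    def test_single_class_zero_risk(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array(["F"] * 20, dtype=object)
        curve = cv_risk(X, y, ["F"], k=5, repeats=1, seed=0)
        assert curve.entries == [(1, 0.0, 0.0)]

    def test_deterministic_given_seed(self):
        X, y = self._separable()
        c1 = cv_risk(X, y, ["Resting", "Walking"], k=5, repeats=3, seed=42)
        c2 = cv_risk(X, y, ["Resting", "Walking"], k=5, repeats=3, seed=42)
        assert c1.entries == c2.entries

    def test_stratified_folds_cover_all_and_balance(self, rng):
        y = np.array(["F"] * 25 + ["W"] * 8 + ["S"] * 3, dtype=object)
        with pytest.warns(UserWarning, match="folds will lack"):
            folds = stratified_folds(y, 10, rng)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(36))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 3


class TestSelectAndPrune:
    def _toy_trees(self):
        from steptree.cart import TreeNode

        def leaf_tree(classes_at_leaves):
            """Right-leaning chain tree whose leaves predict the given classes."""
            nodes = {}
            next_id = 0
            remaining = list(classes_at_leaves)
            while remaining:
                i = next_id
                c = remaining[0]
                if len(remaining) == 1:
                    nodes[i] = TreeNode(i, {c: 1}, c)
                    remaining = []
                else:
                    nodes[i] = TreeNode(
                        i, {c: 1}, c, "distance_m", float(i + 1), i + 1, i + 2
                    )
                    nodes[i + 1] = TreeNode(i + 1, {c: 1}, c)
                    next_id = i + 2
                    remaining = remaining[1:]
            return DecisionTree(nodes, sorted(set(classes_at_leaves)))

        return leaf_tree

    def test_lowest_risk_covering_size(self):
        leaf_tree = self._toy_trees()
        from steptree.cart import RiskCurve

        trees = {
            1: leaf_tree(["F"]),
            3: leaf_tree(["F", "L", "W"]),
            27: leaf_tree(["F", "L", "W"]),
        }
        curve = RiskCurve([(1, 0.4, 0.0), (3, 0.1, 0.0), (27, 0.12, 0.0)])
        assert select_size(curve, trees, ["F", "L", "W"]) == 3

    def test_larger_size_when_small_one_misses_a_class(self):
        leaf_tree = self._toy_trees()
        from steptree.cart import RiskCurve

        trees = {3: leaf_tree(["F", "L", "L"]), 27: leaf_tree(["F", "L", "S", "W"])}
        curve = RiskCurve([(3, 0.1, 0.0), (27, 0.12, 0.0)])
        assert select_size(curve, trees, ["F", "L", "S", "W"]) == 27

    def test_equal_risk_prefers_smallest_covering(self):
        leaf_tree = self._toy_trees()
        from steptree.cart import RiskCurve

        trees = {
            2: leaf_tree(["F", "W"]),
            5: leaf_tree(["F", "W"]),
            9: leaf_tree(["F", "W"]),
        }
        curve = RiskCurve([(2, 0.2, 0.0), (5, 0.2, 0.0), (9, 0.2, 0.0)])
        assert select_size(curve, trees, ["F", "W"]) == 2

    def test_prune_to_size_rules(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=60)
        tree = grow_tree(X, y, ["F", "L", "W"], min_leaf=4)
        path = cost_complexity_path(tree)
        sizes = sorted({t.n_terminal for _, t in path})
        assert prune_to_size(path, tree.n_terminal).n_terminal == tree.n_terminal
        assert prune_to_size(path, 1).n_terminal == 1
        if len(sizes) >= 2:
            lo, hi = sizes[0], sizes[1]
            target = (lo + hi) // 2
            got = prune_to_size(path, target).n_terminal
            best = min(sizes, key=lambda s: (abs(s - target), s))
            assert got == best


class TestPredictAndRules:
    def test_root_only_tree_predicts_majority(self):
        X = np.random.default_rng(1).normal(size=(10, 2))
        y = np.array(["F"] * 7 + ["W"] * 3, dtype=object)
        tree = grow_tree(np.zeros((10, 2)), y, ["F", "W"])
        assert predict(tree, [123.0, 45.0]) == "F"

    def test_sample_at_threshold_goes_left(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        y = np.array(["F", "F", "W", "W"], dtype=object)
        tree = grow_tree(X, y, ["F", "W"], min_leaf=1)
        assert tree.root.threshold == 6.0
        assert predict(tree, [6.0, 0.0]) == "F"

    def test_nan_feature_refused(self):
        tree = grow_tree(
            np.array([[0.0, 0.0], [1.0, 1.0]]),
            np.array(["F", "F"], dtype=object),
            ["F"],
        )
        with pytest.raises(ValueError, match="NaN|undefined"):
            tree.predict(np.array([[np.nan, 1.0]]))

    def _rule_trace(self, rules_text, row):
        """Independent evaluation of exported rules on one sample."""
        matches = []
        for line in rules_text.strip().splitlines():
            cond_text, rest = line[3:].split(" THEN ")
            label = rest.split(" (")[0]
            ok = True
            if cond_text != "TRUE":
                for clause in cond_text.split(" AND "):
                    m = re.match(r"(\w+) (<=|>) (.+)", clause)
                    feat, op, value = m.group(1), m.group(2), float(m.group(3))
                    v = row[{"distance_m": 0, "angle_deg": 1}[feat]]
                    ok &= (v <= value) if op == "<=" else (v > value)
            if ok:
                matches.append(label)
        return matches

    def test_rules_partition_space_and_match_predict(self, rng):
        X = rng.normal(size=(70, 2)) * np.array([20.0, 60.0]) + np.array([20.0, 90.0])
        y = rng.choice(np.array(["F", "L", "W"], dtype=object), size=70)
        tree = grow_tree(X, y, ["F", "L", "W"], min_leaf=5)
        rules = export_rules(tree)
        assert len(rules.strip().splitlines()) == tree.n_terminal
        for _ in range(10):
            row = rng.normal(size=2) * np.array([20.0, 60.0]) + np.array([20.0, 90.0])
            matches = self._rule_trace(rules, row)
            assert len(matches) == 1  # rules partition the plane
            assert matches[0] == predict(tree, row)

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.choice(np.array(["F", "W"], dtype=object), size=40)
        tree = grow_tree(X, y, ["F", "W"], min_leaf=4)
        back = DecisionTree.from_json(tree.to_json())
        probe = rng.normal(size=(25, 2))
        assert np.all(back.predict(probe) == tree.predict(probe))
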