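"""From-scratch CART for two-feature behaviour classification.

Binary classification trees over (step distance, turning angle): Gini-impurity
growth with exhaustive midpoint threshold search, minimal cost-complexity
("weakest link") pruning into a nested subtree ladder, repeated stratified
k-fold cross-validated misclassification risk per candidate tree size, and a
size-selection rule that prefers the lowest-risk size still able to predict
every required class. All tie-breaks are fixed (first feature, then smaller
threshold; first class in class order at leaves; "<= goes left" routing) so
that identical inputs and seeds reproduce identical trees bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

FEATURE_NAMES = ("distance_m", "angle_deg")

_EPS = 1e-12


def gini_impurity(class_counts: Mapping[str, float] | Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_i^2) of a node's class counts."""
    counts = np.asarray(
        list(class_counts.values())
        if isinstance(class_counts, Mapping)
        else class_counts,
        dtype=float,
    )
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    node_id: int
    class_counts: dict[str, int]
    predicted_class: str
    split_feature: str | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclass
class DecisionTree:
    """A binary CART tree; node 0 is the root."""

    nodes: dict[int, TreeNode]
    classes: list[str]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def n_terminal(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def leaves(self) -> list[TreeNode]:
        return [self.nodes[i] for i in self._preorder() if self.nodes[i].is_leaf]

    def leaf_classes(self) -> set[str]:
        return {leaf.predicted_class for leaf in self.leaves()}

    def _preorder(self) -> list[int]:
        order, stack = [], [0]
        while stack:
            i = stack.pop()
            order.append(i)
            node = self.nodes[i]
            if not node.is_leaf:
                stack.extend([node.right, node.left])
        return order

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict class labels for an (n, n_features) array."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if np.isnan(X).any():
            raise ValueError(
                "undefined feature value (NaN); drop undefined-angle samples first"
            )
        findex = {name: j for j, name in enumerate(self.feature_names)}
        out = np.empty(len(X), dtype=object)
        idx = np.arange(len(X))
        stack = [(0, idx)]
        while stack:
            node_id, rows = stack.pop()
            node = self.nodes[node_id]
            if node.is_leaf:
                out[rows] = node.predicted_class
                continue
            go_left = X[rows, findex[node.split_feature]] <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def copy(self) -> "DecisionTree":
        nodes = {
            i: TreeNode(
                n.node_id,
                dict(n.class_counts),
                n.predicted_class,
                n.split_feature,
                n.threshold,
                n.left,
                n.right,
            )
            for i, n in self.nodes.items()
        }
        return DecisionTree(nodes, list(self.classes), tuple(self.feature_names))

    def to_json(self) -> str:
        payload = {
            "classes": self.classes,
            "feature_names": list(self.feature_names),
            "nodes": [
                {
                    "node_id": n.node_id,
                    "class_counts": n.class_counts,
                    "predicted_class": n.predicted_class,
                    "split_feature": n.split_feature,
                    "threshold": n.threshold,
                    "left": n.left,
                    "right": n.right,
                }
                for _, n in sorted(self.nodes.items())
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        payload = json.loads(text)
        nodes = {
            d["node_id"]: TreeNode(
                d["node_id"],
                {k: int(v) for k, v in d["class_counts"].items()},
                d["predicted_class"],
                d["split_feature"],
                d["threshold"],
                d["left"],
                d["right"],
            )
            for d in payload["nodes"]
        }
        return cls(nodes, list(payload["classes"]), tuple(payload["feature_names"]))


def _majority(counts: Mapping[str, int], classes: Sequence[str]) -> str:
    best = max(counts.values())
    for c in classes:  # tie -> first in class order
        if counts.get(c, 0) == best:
            return c
    raise AssertionError("unreachable")


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int = 1,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> tuple[str, float, float] | None:
    """Exhaustive best Gini split: (feature, threshold, impurity_decrease).

    Candidate thresholds are the midpoints between consecutive distinct sorted
    values of each feature; both children must hold >= ``min_leaf`` samples.
    Ties are broken by feature order, then by smaller threshold. Returns None
    when no split yields a positive impurity decrease.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2 * min_leaf:
        return None
    labels, codes = np.unique(y, return_inverse=True)
    if len(labels) == 1:
        return None
    onehot = np.eye(len(labels))[codes]
    parent_counts = onehot.sum(axis=0)
    parent_gini = 1.0 - np.sum((parent_counts / n) ** 2)

    best: tuple[str, float, float] | None = None
    for j, name in enumerate(feature_names[: X.shape[1]]):
        order = np.argsort(X[:, j], kind="stable")
        vals = X[order, j]
        cum = np.cumsum(onehot[order], axis=0)  # cum[i] = counts of first i+1
        # left child = first i samples, i in [1, n-1]
        i = np.arange(1, n)
        valid = (vals[1:] > vals[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        i = i[valid]
        left = cum[i - 1]
        right = parent_counts - left
        nl = i.astype(float)
        nr = n - nl
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        gain = parent_gini - (nl / n) * gini_l - (nr / n) * gini_r
        k = int(np.argmax(gain))  # first max -> smallest threshold
        if gain[k] > _EPS and (best is None or gain[k] > best[2] + _EPS):
            threshold = 0.5 * (vals[i[k] - 1] + vals[i[k]])
            best = (name, float(threshold), float(gain[k]))
    return best


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    classes: Sequence[str],
    min_leaf: int = 5,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> DecisionTree:
    """Grow an unrestricted-depth CART tree by recursive Gini splitting.

    Splitting stops only when no candidate split has positive gain or would
    violate ``min_leaf``. Deterministic given the dataset and tie rules.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(y) == 0:
        raise ValueError("cannot grow a tree on an empty dataset")
    classes = list(classes)
    nodes: dict[int, TreeNode] = {}
    next_id = [0]

    def build(rows: np.ndarray) -> int:
        node_id = next_id[0]
        next_id[0] += 1
        counts = {c: int(np.sum(y[rows] == c)) for c in classes}
        node = TreeNode(node_id, counts, _majority(counts, classes))
        nodes[node_id] = node
        split = best_split(X[rows], y[rows], min_leaf, feature_names)
        if split is not None:
            name, threshold, _ = split
            j = list(feature_names).index(name)
            go_left = X[rows, j] <= threshold
            node.split_feature = name
            node.threshold = threshold
            node.left = build(rows[go_left])
            node.right = build(rows[~go_left])
        return node_id

    build(np.arange(len(y)))
    return DecisionTree(nodes, classes, tuple(feature_names))


def _node_error(node: TreeNode) -> int:
    return sum(node.class_counts.values()) - max(node.class_counts.values())


def _collapse(tree: DecisionTree, node_id: int) -> DecisionTree:
    """Return a copy with ``node_id`` turned into a leaf."""
    out = tree.copy()
    drop: list[int] = []
    stack = [out.nodes[node_id].left, out.nodes[node_id].right]
    while stack:
        i = stack.pop()
        if i is None:
            continue
        drop.append(i)
        stack.extend([out.nodes[i].left, out.nodes[i].right])
    for i in drop:
        del out.nodes[i]
    node = out.nodes[node_id]
    node.split_feature = node.threshold = node.left = node.right = None
    return out


def cost_complexity_path(tree: DecisionTree) -> list[tuple[float, DecisionTree]]:
    """Minimal cost-complexity (weakest-link) subtree ladder.

    Repeatedly collapses the internal node(s) with the smallest per-leaf
    increase in training misclassification error until only the root remains.
    Returns [(alpha, subtree), ...] with non-decreasing alphas, starting at
    (0, full tree) and ending at the root-only tree; each subtree's node set
    is contained in its predecessor's.
    """
    n_total = sum(tree.root.class_counts.values())
    path: list[tuple[float, DecisionTree]] = [(0.0, tree.copy())]
    current = tree.copy()
    alpha_prev = 0.0
    while current.n_terminal > 1:
        # g(t) = (R(t) - R(subtree_t)) / (leaves_t - 1), in error-fraction units
        stats: dict[int, tuple[float, int]] = {}  # id -> (subtree error, leaves)

        def visit(i: int) -> tuple[float, int]:
            node = current.nodes[i]
            if node.is_leaf:
                return _node_error(node) / n_total, 1
            el, ll = visit(node.left)
            er, lr = visit(node.right)
            stats[i] = (el + er, ll + lr)
            return el + er, ll + lr

        visit(0)
        g = {
            i: (_node_error(current.nodes[i]) / n_total - err) / (leaves - 1)
            for i, (err, leaves) in stats.items()
        }
        g_min = min(g.values())
        weakest = sorted(i for i, v in g.items() if v <= g_min + _EPS)
        # Collapse top-most weakest links only (descendants vanish with them).
        for i in weakest:
            if i in current.nodes and not current.nodes[i].is_leaf:
                current = _collapse(current, i)
        alpha_prev = max(alpha_prev, g_min)
        path.append((alpha_prev, current.copy()))
    return path


@dataclass
class RiskCurve:
    """Cross-validated misclassification risk per candidate tree size."""

    entries: list[tuple[int, float, float]]  # (n_terminal, risk_mean, risk_sd)

    def sizes(self) -> list[int]:
        return [e[0] for e in self.entries]

    def risk(self, n_terminal: int) -> float:
        for size, mean, _ in self.entries:
            if size == n_terminal:
                return mean
        raise KeyError(n_terminal)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.entries, columns=["n_terminal", "risk_mean", "risk_sd"]
        ).to_csv(path, index=False)


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled per-class round-robin assignment of sample indices to k folds.

    Classes with fewer than k samples simply appear in a subset of folds
    (still at most one sample difference between folds).
    """
    y = np.asarray(y, dtype=object)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            warnings.warn(
                f"class {c!r} has {len(idx)} samples (< k={k}); "
                "some folds will lack it",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for offset, i in enumerate(idx):
            folds[(start + offset) % k].append(int(i))
        start += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds]


def prune_to_size(
    path: Sequence[tuple[float, DecisionTree]], n_target: int
) -> DecisionTree:
    """Subtree of the ladder whose leaf count is closest to ``n_target``.

    Equidistant candidates resolve to the smaller subtree.
    """
    best = None
    for _, subtree in path:
        key = (abs(subtree.n_terminal - n_target), subtree.n_terminal)
        if best is None or key < best[0]:
            best = (key, subtree)
    return best[1].copy()


def cv_risk(
    X: np.ndarray,
    y: np.ndarray,
    classes: Sequence[str],
    k: int = 10,
    repeats: int = 10,
    min_leaf: int = 5,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
) -> RiskCurve:
    """Repeated stratified k-fold misclassification risk per tree size.

    Candidate sizes default to those realised by the cost-complexity path of
    the tree grown on the full data (other sizes are unreachable by pruning).
    Each repeat reshuffles the folds with the seeded generator; within a fold,
    a tree is grown on the k-1 training folds, its own cost-complexity ladder
    is pruned to each candidate size, and the held-out fold is scored. Risk is
    averaged over folds and repeats; the sd is across repeat means.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if sizes is None:
        reference = grow_tree(X, y, classes, min_leaf)
        sizes = sorted({t.n_terminal for _, t in cost_complexity_path(reference)})
    sizes = list(sizes)
    rng = np.random.default_rng(seed)
    per_repeat = np.zeros((repeats, len(sizes)))
    for r in range(repeats):
        folds = stratified_folds(y, k, rng)
        errors = np.zeros(len(sizes))
        weights = np.zeros(len(sizes))
        for fold in folds:
            if len(fold) == 0:
                continue
            train = np.setdiff1d(np.arange(len(y)), fold)
            fitted = grow_tree(X[train], y[train], classes, min_leaf)
            path = cost_complexity_path(fitted)
            for s, size in enumerate(sizes):
                pruned = prune_to_size(path, size)
                miss = np.mean(pruned.predict(X[fold]) != y[fold])
                errors[s] += miss * len(fold)
                weights[s] += len(fold)
        per_repeat[r] = errors / weights
    means = per_repeat.mean(axis=0)
    sds = per_repeat.std(axis=0, ddof=1) if repeats > 1 else np.zeros(len(sizes))
    return RiskCurve(
        [(int(s), float(m), float(sd)) for s, m, sd in zip(sizes, means, sds)]
    )


def select_size(
    curve: RiskCurve,
    trees_by_size: Mapping[int, DecisionTree],
    required_classes: Sequence[str],
) -> int:
    """Smallest-risk size whose pruned tree still predicts every required class.

    Ties on risk prefer fewer leaves. If no candidate covers all classes, the
    smallest-risk size among those with maximal class coverage is returned
    with a warning.
    """
    if not curve.entries:
        raise ValueError("risk curve is empty")
    required = set(required_classes)
    ranked = sorted(curve.entries, key=lambda e: (e[1], e[0]))
    for size, _, _ in ranked:
        tree = trees_by_size.get(size)
        if tree is not None and required <= tree.leaf_classes():
            return size
    coverage = {
        size: len(required & trees_by_size[size].leaf_classes())
        for size, _, _ in curve.entries
        if size in trees_by_size
    }
    best_cov = max(coverage.values())
    warnings.warn(
        "no candidate size predicts every required class; "
        "falling back to largest coverage",
        stacklevel=2,
    )
    for size, _, _ in ranked:
        if coverage.get(size) == best_cov:
            return size
    raise AssertionError("unreachable")


def predict(tree: DecisionTree, sample: Sequence[float] | Mapping[str, float]):
    """Classify one feature row by routing comparisons (``<=`` goes left)."""
    if isinstance(sample, Mapping):
        row = [sample[name] for name in tree.feature_names]
    else:
        row = list(sample)
    return tree.predict(np.asarray(row, dtype=float).reshape(1, -1))[0]


def export_rules(tree: DecisionTree) -> str:
    """One decision rule per leaf: threshold conjunction -> class (counts).

    The rules partition the feature space: any defined feature row satisfies
    exactly one of them.
    """
    lines: list[str] = []

    def walk(node_id: int, conditions: list[str]) -> None:
        node = tree.nodes[node_id]
        if node.is_leaf:
            counts = ", ".join(f"{c}={node.class_counts.get(c, 0)}" for c in tree.classes)
            cond = " AND ".join(conditions) if conditions else "TRUE"
            lines.append(f"IF {cond} THEN {node.predicted_class} ({counts})")
            return
        walk(node.left, conditions + [f"{node.split_feature} <= {node.threshold!r}"])
        walk(node.right, conditions + [f"{node.split_feature} > {node.threshold!r}"])

    walk(0, [])
    return "\n".join(lines) + "\n"
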