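"""Model/Results objects wrapping the CART machinery.

`BehaviourTreeModel` is built from a labelled interval dataset (or a plain
DataFrame of distance/angle/behaviour columns); `fit()` grows the unrestricted
reference tree, computes its cost-complexity ladder and repeated
cross-validated risk curve, selects the tree size (lowest risk that still
predicts every required class) and prunes — returning a
`BehaviourTreeResults` carrying the fitted tree, the risk curve and the usual
prediction/diagnostic methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cart
from .coupling import LabelledDataset


class BehaviourTreeModel:
    """CART behaviour classifier over (step distance, turning angle).

    Parameters
    ----------
    X : (n, 2) array of distance_m, angle_deg (no NaNs).
    y : length-n behaviour labels.
    classes : ordered class vocabulary; defaults to the sorted labels present.
    min_leaf : minimum samples per leaf during growth (guards degenerate
        leaves; depth itself is unrestricted).
    """

    def __init__(
        self,
        X,
        y,
        classes: Sequence[str] | None = None,
        min_leaf: int = 5,
        feature_names: Sequence[str] = cart.FEATURE_NAMES,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, n_features) aligned with y")
        if np.isnan(self.X).any():
            raise ValueError("X contains NaN; drop undefined-angle samples first")
        self.classes = list(classes) if classes is not None else sorted(set(self.y))
        self.min_leaf = int(min_leaf)
        self.feature_names = tuple(feature_names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: Sequence[str] = cart.FEATURE_NAMES,
        label_col: str = "behaviour",
        **kwargs,
    ) -> "BehaviourTreeModel":
        sub = df.dropna(subset=list(feature_cols))
        return cls(
            sub[list(feature_cols)].to_numpy(dtype=float),
            sub[label_col].to_numpy(dtype=object),
            feature_names=feature_cols,
            **kwargs,
        )

    @classmethod
    def from_dataset(cls, dataset: LabelledDataset, **kwargs) -> "BehaviourTreeModel":
        return cls(
            dataset.features(), dataset.labels(), classes=dataset.classes, **kwargs
        )

    def fit(
        self,
        k: int = 10,
        repeats: int = 10,
        seed: int = 0,
        required_classes: Sequence[str] | None = None,
    ) -> "BehaviourTreeResults":
        """Grow, cross-validate, select size and prune.

        ``k``-fold cross-validation (stratified by class) repeated ``repeats``
        times estimates the misclassification risk of every tree size on the
        reference tree's pruning ladder; the chosen size is the lowest-risk
        one whose pruned tree still predicts every class in
        ``required_classes`` (default: all classes present in the data).
        """
        reference = cart.grow_tree(
            self.X, self.y, self.classes, self.min_leaf, self.feature_names
        )
        path = cart.cost_complexity_path(reference)
        trees_by_size = {}
        for _, subtree in path:
            trees_by_size.setdefault(subtree.n_terminal, subtree)
        curve = cart.cv_risk(
            self.X,
            self.y,
            self.classes,
            k=k,
            repeats=repeats,
            min_leaf=self.min_leaf,
            seed=seed,
            sizes=sorted(trees_by_size),
        )
        required = (
            sorted(set(self.y)) if required_classes is None else list(required_classes)
        )
        n_selected = cart.select_size(curve, trees_by_size, required)
        pruned = cart.prune_to_size(path, n_selected)
        return BehaviourTreeResults(
            model=self,
            tree=pruned,
            reference_tree=reference,
            path=path,
            risk_curve=curve,
            n_terminal_selected=n_selected,
            cv_settings={"k": k, "repeats": repeats, "seed": seed},
        )


@dataclass
class BehaviourTreeResults:
    """Fitted, pruned behaviour tree plus its selection diagnostics."""

    model: BehaviourTreeModel
    tree: cart.DecisionTree
    reference_tree: cart.DecisionTree
    path: list
    risk_curve: cart.RiskCurve
    n_terminal_selected: int
    cv_settings: Mapping[str, int]

    def predict(self, X) -> np.ndarray:
        """Predict behaviour labels for feature rows or a DataFrame."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.tree.feature_names)].to_numpy(dtype=float)
        return self.tree.predict(np.asarray(X, dtype=float))

    def confusion(self, X, y_true):
        """Confusion matrix of observed vs predicted labels."""
        from .stats import confusion_matrix

        if isinstance(X, LabelledDataset):
            y_true = X.labels()
            X = X.features()
        return confusion_matrix(
            np.asarray(y_true, dtype=object), self.predict(X), self.model.classes
        )

    @property
    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.X) == self.model.y))

    def rules(self) -> str:
        return cart.export_rules(self.tree)

    def summary(self) -> str:
        """Plain-text account of the fit, selection and training performance."""
        lines = [
            "Behaviour classification tree (CART)",
            "=" * 44,
            f"samples:            {len(self.model.y)}",
            f"classes:            {', '.join(self.model.classes)}",
            f"features:           {', '.join(self.tree.feature_names)}",
            f"min samples/leaf:   {self.model.min_leaf}",
            (
                f"cross-validation:   {self.cv_settings['k']}-fold x "
                f"{self.cv_settings['repeats']} repeats (seed "
                f"{self.cv_settings['seed']})"
            ),
            f"reference tree:     {self.reference_tree.n_terminal} terminal nodes",
            f"selected size:      {self.n_terminal_selected} terminal nodes",
            f"pruned tree size:   {self.tree.n_terminal} terminal nodes",
            f"training accuracy:  {100 * self.training_accuracy:.1f}%",
            "",
            "risk curve (cross-validated misclassification):",
            "  n_terminal  risk_mean  risk_sd",
        ]
        for size, mean, sd in self.risk_curve.entries:
            marker = "  <- selected" if size == self.n_terminal_selected else ""
            lines.append(f"  {size:10d}  {mean:9.4f}  {sd:7.4f}{marker}")
        return "\n".join(lines) + "\n"
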