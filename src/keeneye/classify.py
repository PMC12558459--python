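"""Diagnostic classification: published threshold rules, a from-scratch
Gini/CART inducer with rpart-style complexity control, stratified
cross-validation and confusion-matrix metrics.

Two single-feature decision criteria are built in as published rules:

* ``LSB14`` — neglect iff LSB >= 14 (missed left circles under bilateral
  presentation);
* ``KA017`` — neglect iff KA_all >= 0.17 (overall asymmetry coefficient).

The tree inducer is greedy binary recursive partitioning on Gini impurity.
Hyperparameters follow the rpart vocabulary so fits can be cross-checked
against an independent implementation: ``minsplit`` (minimum node size to
attempt a split, default 20), ``minbucket`` (minimum leaf size, default 7),
and ``cp`` (a split must reduce the resubstitution misclassification risk by
at least ``cp`` times the root risk, default 0.01).

The model-fitting surface follows the statsmodels convention:
``NeglectTreeModel(data, features, label_col).fit()`` returns a
:class:`NeglectTreeResults` with the fitted tree, resubstitution metrics, a
``summary()`` table and ``predict()``/``cross_validate()`` methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

NEGLECT = "neglect"
NO_NEGLECT = "no_neglect"

#: predictor sets used by the published models
RAW_COUNT_FEATURES = ["RSU", "LSU", "RSB", "LSB", "RH", "LH"]
COEFFICIENT_FEATURES = [
    "KA_bilateral", "KPrR_bilateral", "KPrL_bilateral",
    "KA_all", "KEf_all", "KPrR_all", "KPrL_all",
]


class ClassificationError(ValueError):
    """Raised when a rule's required feature is undefined or missing."""


def classify_rule(sheet, rule: Literal["LSB14", "KA017"]) -> str:
    """Apply a published single-threshold diagnostic rule to a score sheet.

    Accepts a ScoreSheet or any mapping exposing the needed feature.
    """
    def get(name):
        if isinstance(sheet, Mapping):
            return sheet.get(name)
        return getattr(sheet, name, None)

    if rule == "LSB14":
        lsb = get("LSB")
        if lsb is None:
            raise ClassificationError("LSB is missing")
        return NEGLECT if lsb >= 14 else NO_NEGLECT
    if rule == "KA017":
        ka = get("KA_all")
        if ka is None:
            raise ClassificationError("KA_all is undefined; rule KA017 cannot be applied")
        return NEGLECT if ka >= 0.17 else NO_NEGLECT
    raise ValueError(f"unknown rule {rule!r}")


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity 1 - sum p_k^2; 0 for a pure node, 0.5 at a 50/50 binary split."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty node has no impurity")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


@dataclass(frozen=True)
class FitParams:
    """Tree-growing controls (rpart vocabulary)."""

    minsplit: int = 20
    minbucket: int = 7
    cp: float = 0.01
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if not 0 <= self.cp <= 1:
            raise ValueError("cp must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class TreeNode:
    """A node of the fitted binary tree; leaves have feature=None."""

    n: int
    n_neglect: int
    prediction: str
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_neglect": self.n_neglect, "prediction": self.prediction}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n=d["n"], n_neglect=d["n_neglect"], prediction=d["prediction"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class DecisionTreeModel:
    """A fitted CART: node tree plus the root misclassification risk."""

    root: TreeNode
    features: list[str]
    params: FitParams
    root_risk: int

    def n_leaves(self) -> int:
        def count(node):
            return 1 if node.is_leaf else count(node.left) + count(node.right)
        return count(self.root)

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def to_json(self) -> str:
        return json.dumps({
            "features": self.features,
            "params": vars(self.params),
            "root_risk": self.root_risk,
            "tree": self.root.to_dict(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        d = json.loads(text)
        return cls(root=TreeNode.from_dict(d["tree"]), features=d["features"],
                   params=FitParams(**d["params"]), root_risk=d["root_risk"])


def _node_majority(n_neglect: int, n_total: int) -> str:
    # ties resolve to no_neglect, favoring specificity
    return NEGLECT if n_neglect > n_total - n_neglect else NO_NEGLECT


def _node_risk(n_neglect: int, n_total: int) -> int:
    return min(n_neglect, n_total - n_neglect)


def _best_split(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str],
                minbucket: int) -> tuple[int, float, float] | None:
    """Best (feature index, threshold, weighted-child impurity).

    Candidate thresholds are midpoints between consecutive sorted unique
    values. Ties in impurity break toward the lexicographically lower feature
    name then the lower threshold.
    """
    n = len(y)
    best: tuple[float, str, float, int] | None = None  # (impurity, fname, thr, j)
    order_by_name = sorted(range(X.shape[1]), key=lambda j: feature_names[j])
    for j in order_by_name:
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        xs, ys = col[order], y[order]
        uniq = np.unique(xs)
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2.0
            left = xs < thr
            nl = int(left.sum())
            nr = n - nl
            if nl < minbucket or nr < minbucket:
                continue
            pl = int(ys[left].sum())
            pr = int(ys.sum()) - pl
            imp = (nl * gini_impurity((pl, nl - pl))
                   + nr * gini_impurity((pr, nr - pr))) / n
            key = (imp, feature_names[j], thr)
            if best is None or key < (best[0], best[1], best[2]):
                best = (imp, feature_names[j], thr, j)
    if best is None:
        return None
    return best[3], best[2], best[0]


def fit_cart(data: pd.DataFrame, params: FitParams = FitParams(),
             features: Sequence[str] | None = None,
             label_col: str = "label") -> DecisionTreeModel:
    """Grow a CART by greedy Gini partitioning under rpart-style controls.

    A split is accepted only if the parent holds >= minsplit samples, both
    children hold >= minbucket, and the drop in resubstitution
    misclassification count is >= cp * root_risk.
    """
    if features is None:
        features = [c for c in data.columns if c != label_col]
    features = list(features)
    X = data[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in splitting features")
    labels = data[label_col].to_numpy()
    y = (labels == NEGLECT).astype(int)
    if len(y) < 2:
        raise ValueError("need at least 2 labelled samples")
    root_risk = _node_risk(int(y.sum()), len(y))
    if root_risk == 0:
        warnings.warn("single-class data: returning a single-leaf tree")

    min_gain = params.cp * root_risk

    def grow(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        n, pos = len(yi), int(yi.sum())
        node = TreeNode(n=n, n_neglect=pos, prediction=_node_majority(pos, n))
        if n < params.minsplit or pos == 0 or pos == n:
            return node
        found = _best_split(X[idx], yi, features, params.minbucket)
        if found is None:
            return node
        j, thr, _ = found
        left_mask = X[idx, j] < thr
        li, ri = idx[left_mask], idx[~left_mask]
        lpos, rpos = int(y[li].sum()), int(y[ri].sum())
        gain = (_node_risk(pos, n)
                - _node_risk(lpos, len(li)) - _node_risk(rpos, len(ri)))
        if gain < min_gain or gain <= 0:
            return node
        node.feature = features[j]
        node.threshold = thr
        node.left = grow(li)
        node.right = grow(ri)
        return node

    root = grow(np.arange(len(y)))
    return DecisionTreeModel(root=root, features=features, params=params,
                             root_risk=root_risk)


def predict(tree: DecisionTreeModel, fv: Mapping[str, float]) -> str:
    """Route a feature vector root-to-leaf; value < threshold goes left."""
    node = tree.root
    while not node.is_leaf:
        if node.feature not in fv:
            raise ClassificationError(f"missing feature {node.feature!r}")
        value = fv[node.feature]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ClassificationError(f"feature {node.feature!r} is undefined")
        node = node.left if value < node.threshold else node.right
    return node.prediction


def predict_frame(tree: DecisionTreeModel, data: pd.DataFrame) -> np.ndarray:
    return np.array([predict(tree, row) for row in data[tree.features].to_dict("records")])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with ``neglect`` as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)

    @classmethod
    def from_labels(cls, true: Iterable[str], predicted: Iterable[str]) -> "ConfusionMatrix":
        tp = fp = fn = tn = 0
        for t, p in zip(true, predicted):
            if t == NEGLECT and p == NEGLECT:
                tp += 1
            elif t == NO_NEGLECT and p == NEGLECT:
                fp += 1
            elif t == NEGLECT:
                fn += 1
            else:
                tn += 1
        return cls(tp, fp, fn, tn)


def _ratio(num: int, denom: int) -> float | None:
    return num / denom if denom else None


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1, sensitivity, specificity.

    A zero-denominator ratio is reported as None, never silently as 0.
    """
    total = cm.TP + cm.FP + cm.FN + cm.TN
    if total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.TP, cm.TP + cm.FP)
    recall = _ratio(cm.TP, cm.TP + cm.FN)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (cm.TP + cm.TN) / total,
        "precision": precision,
        "recall": recall,
        "F1": f1,
        "sensitivity": recall,
        "specificity": _ratio(cm.TN, cm.TN + cm.FP),
    }


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded class-stratified fold assignment (0..folds-1 per sample)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for k, i in enumerate(idx):
            assignment[i] = k % folds
    return assignment


def cross_validate(data: pd.DataFrame, params: FitParams = FitParams(),
                   features: Sequence[str] | None = None,
                   label_col: str = "label") -> dict:
    """Stratified k-fold CV of the tree inducer.

    Returns per-fold confusion matrices and pooled metrics over all held-out
    predictions; folds that lose a class entirely are flagged.
    """
    labels = data[label_col].to_numpy()
    if len(labels) < params.folds:
        raise ValueError("fewer samples than folds")
    assignment = stratified_folds(labels, params.folds, params.seed)
    per_fold = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for k in range(params.folds):
        test_mask = assignment == k
        train = data.loc[~test_mask]
        test = data.loc[test_mask]
        flagged = len(set(train[label_col])) < 2 or len(test) == 0
        if len(set(train[label_col])) < 2:
            warnings.warn(f"fold {k}: training data lost a class")
        tree = fit_cart(train, params, features, label_col)
        pred = predict_frame(tree, test) if len(test) else np.array([])
        cm = ConfusionMatrix.from_labels(test[label_col], pred)
        per_fold.append({"fold": k, "confusion": cm, "flagged": flagged})
        pooled = pooled + cm
    return {
        "folds": per_fold,
        "pooled_confusion": pooled,
        "pooled_metrics": confusion_metrics(pooled),
    }


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair

class NeglectTreeModel:
    """Diagnostic decision-tree model over a cohort score table.

    Parameters
    ----------
    data : DataFrame with one row per subject: feature columns plus a label
        column holding ``"neglect"`` / ``"no_neglect"``.
    features : predictor subset; defaults to every non-label column. The
        published raw-count and coefficient predictor sets are available as
        ``RAW_COUNT_FEATURES`` and ``COEFFICIENT_FEATURES``.
    """

    def __init__(self, data: pd.DataFrame, features: Sequence[str] | None = None,
                 label_col: str = "label"):
        self.data = data.reset_index(drop=True)
        self.label_col = label_col
        self.features = list(features) if features is not None else \
            [c for c in data.columns if c != label_col]

    @classmethod
    def from_scoresheets(cls, sheets: Iterable, labels: Iterable[str],
                         features: Sequence[str] | None = None) -> "NeglectTreeModel":
        rows = []
        for sheet, label in zip(sheets, labels):
            row = sheet.as_row()
            row["label"] = label
            rows.append(row)
        return cls(pd.DataFrame(rows), features=features)

    def fit(self, params: FitParams = FitParams()) -> "NeglectTreeResults":
        tree = fit_cart(self.data, params, self.features, self.label_col)
        return NeglectTreeResults(self, tree, params)


class NeglectTreeResults:
    """Results of a tree fit: the tree, resubstitution metrics, CV access."""

    def __init__(self, model: NeglectTreeModel, tree: DecisionTreeModel,
                 params: FitParams):
        self.model = model
        self.tree = tree
        self.params = params
        pred = predict_frame(tree, model.data)
        self.resubstitution_confusion = ConfusionMatrix.from_labels(
            model.data[model.label_col], pred)
        self.resubstitution_metrics = confusion_metrics(self.resubstitution_confusion)

    def predict(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray | str:
        if isinstance(data, pd.DataFrame):
            return predict_frame(self.tree, data)
        return predict(self.tree, data)

    def cross_validate(self, seed: int | None = None) -> dict:
        params = self.params if seed is None else FitParams(
            **{**vars(self.params), "seed": seed})
        return cross_validate(self.model.data, params, self.model.features,
                              self.model.label_col)

    def summary(self) -> str:
        lines = ["Neglect decision-tree fit",
                 "=" * 40,
                 f"n = {len(self.model.data)}  features = {len(self.model.features)}",
                 f"minsplit={self.params.minsplit} minbucket={self.params.minbucket} "
                 f"cp={self.params.cp}",
                 f"leaves = {self.tree.n_leaves()}  depth = {self.tree.depth()}",
                 "-" * 40]

        def render(node: TreeNode, indent: str):
            if node.is_leaf:
                lines.append(f"{indent}-> {node.prediction} "
                             f"({node.n_neglect}/{node.n} neglect)")
            else:
                lines.append(f"{indent}{node.feature} < {node.threshold:g}?")
                render(node.left, indent + "  ")
                lines.append(f"{indent}{node.feature} >= {node.threshold:g}?")
                render(node.right, indent + "  ")

        render(self.tree.root, "")
        lines.append("-" * 40)
        lines.append("resubstitution metrics:")
        for k, v in self.resubstitution_metrics.items():
            lines.append(f"  {k:12s} {'NA' if v is None else f'{v:.3f}'}")
        return "\n".join(lines)
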