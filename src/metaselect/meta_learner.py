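"""Re-induce applicability knowledge from (metafeature, label) metadata.

Two meta-level learners mirror the knowledge-extraction procedure the
package supports:

* **stepwise regression** — a correlation pre-filter (keep features whose
  marginal |Pearson r| with the target exceeds 0.3) followed by
  bidirectional stepwise least squares: at each round the candidate with the
  smallest partial-F p-value enters if below ``p_enter``, then any included
  feature whose p-value exceeds ``p_remove`` leaves; iterate to a fixed
  point.  For a single added regressor the partial F statistic is the square
  of its t statistic, so the candidate's coefficient t-test supplies the
  p-value.  A binary recommend-or-not target is fit as a linear probability
  model by default (a logistic mode is available).

* **a C4.5-style decision tree** — recursive partitioning on the gain
  ratio (information gain over split information), binary threshold splits
  at midpoints for numeric features and multiway splits for categorical
  ones, followed by pessimistic error-based pruning at confidence ``cf``.

Both learners are deterministic given (data, parameters, seed); ties are
broken by feature order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MetaDataset",
    "StepwiseResult",
    "TreeNode",
    "DecisionTree",
    "correlation_prefilter",
    "stepwise_select",
    "build_c45_tree",
    "predict_tree",
    "cross_validate",
    "tree_to_text",
]


@dataclass
class MetaDataset:
    """Rows of metafeature vectors with a per-row target.

    ``features`` is an n × p DataFrame (numeric columns plus optional
    categorical columns such as the domain field label); ``target`` is a
    length-n Series — a recommendation label (categorical / 0-1) or a real
    magnitude such as a predicted log10 time.
    """

    features: pd.DataFrame
    target: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.target):
            raise ValueError("features and target length mismatch")
        if self.target.isna().any():
            raise ValueError("target contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n(self) -> int:
        return len(self.features)


@dataclass
class StepwiseResult:
    """Outcome of a bidirectional stepwise search."""

    selected_features: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    # trace entries: (action "add"/"remove", feature, p-value)


def _numeric_design(features: pd.DataFrame) -> pd.DataFrame:
    """One-hot any categorical columns so every learner sees numbers."""
    return pd.get_dummies(features, drop_first=True, dtype=float)


def correlation_prefilter(
    meta: MetaDataset, threshold: float = 0.3
) -> list[str]:
    """Features whose |Pearson r| with a real-valued target exceeds threshold.

    Constant features have undefined correlation; they are treated as r = 0
    and excluded.  The filter is marginal: duplicated informative features
    are all kept.
    """
    y = pd.to_numeric(meta.target)
    X = _numeric_design(meta.features)
    kept = []
    for col in X.columns:
        x = X[col]
        if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) > threshold:
            kept.append(col)
    return kept


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    return sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0)


def stepwise_select(
    meta: MetaDataset,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    *,
    candidates: Sequence[str] | None = None,
    logistic: bool = False,
) -> StepwiseResult:
    """Bidirectional stepwise selection over the (pre-filtered) candidates.

    Deterministic: candidates are scanned in lexicographic order and the
    smallest p-value wins ties by that order.  A candidate whose addition
    makes the design rank-deficient is skipped with a warning entry in the
    trace.
    """
    import warnings

    y = pd.to_numeric(meta.target).to_numpy(dtype=float)
    X_full = _numeric_design(meta.features)
    pool = sorted(candidates) if candidates is not None else sorted(X_full.columns)
    fit = _fit_logit if logistic else _fit_ols

    included: list[str] = []
    trace: list[tuple[str, str, float]] = []
    while True:
        changed = False
        # forward: best candidate by partial-F (== squared-t) p-value
        best_p, best_feat = None, None
        for feat in pool:
            if feat in included:
                continue
            cols = included + [feat]
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(y)), X_full[cols].to_numpy()])
            ) < len(cols) + 1:
                warnings.warn(f"skipping rank-deficient candidate {feat!r}")
                continue
            try:
                model = fit(y, X_full[cols])
            except (np.linalg.LinAlgError, ValueError):
                warnings.warn(f"skipping candidate {feat!r}: fit failed")
                continue
            p = float(model.pvalues[feat])
            if math.isnan(p):
                continue
            if best_p is None or p < best_p:
                best_p, best_feat = p, feat
        if best_feat is not None and best_p < p_enter:
            included.append(best_feat)
            trace.append(("add", best_feat, best_p))
            changed = True
        # backward: drop the worst included feature above p_remove
        while included:
            model = fit(y, X_full[included])
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > p_remove:
                included.remove(worst)
                trace.append(("remove", worst, float(pvals[worst])))
                changed = True
            else:
                break
        if not changed:
            break

    if included:
        model = fit(y, X_full[included])
        coefs = {"intercept": float(model.params["const"])}
        coefs.update({f: float(model.params[f]) for f in included})
    else:
        coefs = {"intercept": float(np.mean(y))}
    return StepwiseResult(selected_features=included, coefficients=coefs,
                          trace=trace)


# ---------------------------------------------------------------------------
# C4.5-style decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Internal split node or leaf of the gain-ratio tree."""

    # leaf fields
    label: object = None
    counts: dict = field(default_factory=dict)
    # split fields
    feature: str | None = None
    threshold: float | None = None  # numeric split: <= threshold left
    children: dict = field(default_factory=dict)
    # numeric split children keyed "le"/"gt"; categorical keyed by level

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def majority(self):
        return max(sorted(self.counts, key=str), key=lambda k: self.counts[k])


@dataclass
class DecisionTree:
    root: TreeNode
    feature_names: list[str]

    @property
    def depth(self) -> int:
        def d(node):
            if node.is_leaf:
                return 0
            return 1 + max(d(c) for c in node.children.values())
        return d(self.root)

    @property
    def leaf_count(self) -> int:
        def c(node):
            if node.is_leaf:
                return 1
            return sum(c(ch) for ch in node.children.values())
        return c(self.root)


def _entropy_of(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _split_candidates_numeric(x: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted distinct values."""
    v = np.unique(x)
    return (v[:-1] + v[1:]) / 2.0 if len(v) > 1 else np.empty(0)


def _gain_ratio(y: np.ndarray, parts: list[np.ndarray]) -> float:
    """Information gain over split information for a candidate partition."""
    n = len(y)
    parent = _entropy_of(y)
    child = sum(len(p) / n * _entropy_of(p) for p in parts)
    gain = parent - child
    weights = np.array([len(p) / n for p in parts])
    split_info = float(-(weights * np.log2(weights)).sum())
    if split_info <= 0:
        return 0.0
    return gain / split_info


def _best_numeric_split(x: np.ndarray, y_codes: np.ndarray, n_classes: int,
                        min_leaf: int) -> tuple[float | None, float]:
    """Best threshold and gain ratio for one numeric feature.

    Single sorted sweep with cumulative class counts: O(n log n + n·k)
    instead of re-partitioning per candidate threshold.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    # one-hot cumulative class counts along the sorted order
    onehot = np.zeros((len(x), n_classes))
    onehot[np.arange(len(x)), y_codes[order]] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    n = len(x)

    # candidate boundaries: positions where the sorted value changes
    boundary = np.nonzero(xs[:-1] < xs[1:])[0]  # split after index i
    if boundary.size == 0:
        return None, 0.0
    n_left = boundary + 1
    valid = (n_left >= min_leaf) & (n - n_left >= min_leaf)
    boundary = boundary[valid]
    if boundary.size == 0:
        return None, 0.0
    n_left = boundary + 1

    left = cum[boundary]
    right = total - left

    def ent(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    n_right = n - n_left
    child = (n_left * ent(left, n_left) + n_right * ent(right, n_right)) / n
    parent_counts = total / n
    parent = -np.sum(np.where(parent_counts > 0,
                              parent_counts * np.log2(parent_counts), 0.0))
    gain = parent - child
    w_l, w_r = n_left / n, n_right / n
    split_info = -(w_l * np.log2(w_l) + w_r * np.log2(w_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        gr = np.where(split_info > 0, gain / split_info, 0.0)
    i = int(np.argmax(gr))
    if gr[i] <= 0:
        return None, 0.0
    thr = (xs[boundary[i]] + xs[boundary[i] + 1]) / 2.0
    return float(thr), float(gr[i])


def _best_split(X: pd.DataFrame, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold-or-None, gain ratio) over all candidates.

    Numeric columns get binary threshold splits; non-numeric columns get one
    multiway split over their levels.  Ties break by feature order, then by
    lower threshold.
    """
    classes, y_codes = np.unique(y, return_inverse=True)
    best = (None, None, 0.0)
    for feat in X.columns:
        col = X[feat]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            thr, gr = _best_numeric_split(x, y_codes, len(classes), min_leaf)
            if thr is not None and gr > best[2] + 1e-12:
                best = (feat, thr, gr)
        else:
            levels = col.unique()
            if len(levels) < 2:
                continue
            parts = [y[(col == lv).to_numpy()] for lv in levels]
            if min(len(p) for p in parts) < min_leaf:
                continue
            gr = _gain_ratio(y, parts)
            if gr > best[2] + 1e-12:
                best = (feat, None, gr)
    return best


def _leaf(y: np.ndarray) -> TreeNode:
    values, counts = np.unique(y, return_counts=True)
    d = {(v.item() if hasattr(v, "item") else v): int(c)
         for v, c in zip(values, counts)}
    label = max(sorted(d, key=str), key=lambda k: d[k])
    return TreeNode(label=label, counts=d)


def _grow(X: pd.DataFrame, y: np.ndarray, min_leaf: int) -> TreeNode:
    if len(np.unique(y)) == 1 or len(y) < 2 * min_leaf:
        return _leaf(y)
    feat, thr, gr = _best_split(X, y, min_leaf)
    if feat is None or gr <= 0:
        return _leaf(y)
    node = _leaf(y)  # keep counts for pruning
    node.label = None
    node.feature, node.threshold = feat, thr
    if thr is not None:
        x = X[feat].to_numpy(dtype=float)
        node.children = {
            "le": _grow(X[x <= thr], y[x <= thr], min_leaf),
            "gt": _grow(X[x > thr], y[x > thr], min_leaf),
        }
    else:
        col = X[feat]
        node.children = {
            lv: _grow(X[(col == lv).to_numpy()], y[(col == lv).to_numpy()],
                      min_leaf)
            for lv in col.unique()
        }
    node.label = None
    return node


def _pessimistic_errors(counts: dict, cf: float) -> float:
    """Upper confidence bound on the error count at a (virtual) leaf.

    Standard C4.5 estimate: the observed error rate f = e/n is replaced by
    the upper limit of a one-sided confidence interval at level ``cf``
    (normal approximation to the binomial), and scaled back to a count.
    """
    n = sum(counts.values())
    if n == 0:
        return 0.0
    e = n - max(counts.values())
    f = e / n
    z = stats.norm.ppf(1 - cf)
    num = f + z * z / (2 * n) + z * math.sqrt(f * (1 - f) / n + z * z / (4 * n * n))
    return n * num / (1 + z * z / n)


def _prune(node: TreeNode, cf: float) -> TreeNode:
    if node.is_leaf:
        return node
    node.children = {k: _prune(ch, cf) for k, ch in node.children.items()}
    subtree_err = _subtree_pessimistic(node, cf)
    leaf_err = _pessimistic_errors(node.counts, cf)
    if leaf_err <= subtree_err + 0.1:  # C4.5's tolerance for replacement
        return TreeNode(label=max(sorted(node.counts, key=str),
                                  key=lambda k: node.counts[k]),
                        counts=node.counts)
    return node


def _subtree_pessimistic(node: TreeNode, cf: float) -> float:
    if node.is_leaf:
        return _pessimistic_errors(node.counts, cf)
    return sum(_subtree_pessimistic(ch, cf) for ch in node.children.values())


def build_c45_tree(
    meta: MetaDataset, min_leaf: int = 2, cf: float = 0.25
) -> DecisionTree:
    """Grow and prune a gain-ratio tree on a categorical target.

    A single-class input yields a single-leaf tree.  ``cf`` is the pruning
    confidence; smaller values prune harder.
    """
    y = meta.target.to_numpy()
    X = meta.features
    root = _grow(X, y, min_leaf)
    root = _prune(root, cf)
    return DecisionTree(root=root, feature_names=list(X.columns))


def predict_tree(tree: DecisionTree, row: pd.Series | dict):
    """Deterministic root-to-leaf descent; returns the leaf majority label.

    An unseen categorical level falls back to the node's majority label.
    """
    if isinstance(row, dict):
        row = pd.Series(row)
    node = tree.root
    while not node.is_leaf:
        if node.feature not in row.index:
            raise KeyError(
                f"metafeature {node.feature!r} required by the tree is missing"
            )
        value = row[node.feature]
        if node.threshold is not None:
            node = node.children["le" if value <= node.threshold else "gt"]
        else:
            if value not in node.children:
                return node.majority()
            node = node.children[value]
    return node.label


def tree_predict_frame(tree: DecisionTree, X: pd.DataFrame) -> np.ndarray:
    return np.array([predict_tree(tree, X.iloc[i]) for i in range(len(X))])


def cross_validate(
    meta: MetaDataset,
    learner: str = "tree",
    k: int = 10,
    seed: int = 0,
    **learner_kwargs,
) -> float:
    """Stratified k-fold mean held-out accuracy of a meta-learner.

    ``learner`` is ``"tree"`` (gain-ratio decision tree) or ``"stepwise"``
    (stepwise linear probability model thresholded at 0.5; requires a binary
    0/1 target).  Folds missing a training class are skipped with a warning.
    """
    import warnings

    from sklearn.model_selection import KFold, StratifiedKFold

    if meta.n < k:
        raise ValueError(f"n={meta.n} rows < k={k} folds")
    y = meta.target.to_numpy()
    _, class_counts = np.unique(y, return_counts=True)
    if k <= class_counts.min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # stratification impossible (e.g. leave-one-out); plain shuffled folds
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(meta.features, y):
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            warnings.warn("fold skipped: a class is absent from training data")
            continue
        train = MetaDataset(meta.features.iloc[train_idx].reset_index(drop=True),
                            pd.Series(y_train))
        X_test = meta.features.iloc[test_idx].reset_index(drop=True)
        y_test = y[test_idx]
        if learner == "tree":
            tree = build_c45_tree(train, **learner_kwargs)
            pred = tree_predict_frame(tree, X_test)
        elif learner == "stepwise":
            res = stepwise_select(train, **learner_kwargs)
            X_num = _numeric_design(X_test)
            yhat = np.full(len(X_test), res.coefficients["intercept"])
            for f in res.selected_features:
                yhat = yhat + res.coefficients[f] * X_num[f].to_numpy(dtype=float)
            pred = (yhat >= 0.5).astype(int)
        else:
            raise ValueError(f"unknown learner {learner!r}")
        accs.append(float((pred == y_test).mean()))
    if not accs:
        raise ValueError("every fold was skipped")
    return float(np.mean(accs))


def tree_to_text(tree: DecisionTree) -> str:
    """Indented-rule rendering of a decision tree."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, indent: int):
        pad = "  " * indent
        if node.is_leaf:
            lines.append(f"{pad}{prefix}-> {node.label}  {node.counts}")
            return
        if node.threshold is not None:
            lines.append(f"{pad}{prefix}{node.feature} <= {node.threshold:g}:")
            walk(node.children["le"], "", indent + 1)
            lines.append(f"{pad}{prefix}{node.feature} > {node.threshold:g}:")
            walk(node.children["gt"], "", indent + 1)
        else:
            for lv, child in node.children.items():
                lines.append(f"{pad}{prefix}{node.feature} = {lv}:")
                walk(child, "", indent + 1)

    walk(tree.root, "", 0)
    return "\n".join(lines)
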