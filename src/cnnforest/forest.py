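"""From-scratch decision trees and random forest over the CNN feature matrix.

Split candidates follow the (random row, random column) scheme: a node draws
``candidates_per_node`` (column, threshold) pairs, where the column is
uniform over features and the threshold is the feature value of a row drawn
uniformly from the rows reaching the node; the candidate minimising the
child-size-weighted mean Gini impurity wins.  ``candidates_per_node``
defaults to ceil(sqrt(n_features)); setting it to 1 recovers the fully
random single-draw variant, and ``exhaustive=True`` scores every
(row, column) pair instead (used by the oracle-equivalence tests).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

NEGATIVE_CLASS = 0  # deterministic tie-break target


@dataclass
class ClassDistribution:
    """Per-class sample counts at a node (binary by default)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a 1-D non-negative integer vector")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def majority_class(self) -> int:
        # argmax breaks ties toward the lower (negative) class index
        return int(np.argmax(self.counts))


def gini_impurity(dist: ClassDistribution | Sequence[int]) -> float:
    """1 - sum p(i)^2 over the class probabilities of the node."""
    if not isinstance(dist, ClassDistribution):
        dist = ClassDistribution(np.asarray(dist))
    total = dist.total
    if total == 0:
        raise ValueError("Gini impurity is undefined for an empty distribution")
    p = dist.counts / total
    return float(1.0 - np.sum(p * p))


def max_candidate_features(n_features: int) -> int:
    """ceil(sqrt(n_features)), capped at n_features."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return min(math.ceil(math.sqrt(n_features)), n_features)


def bootstrap_rows(n_rows: int, rng: np.random.Generator) -> np.ndarray:
    """n_rows row indices drawn uniformly with replacement."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    return rng.integers(0, n_rows, size=n_rows)


@dataclass
class ForestParams:
    n_trees: int = 15
    candidates_per_node: int | None = None  # None -> ceil(sqrt(n_features))
    bootstrap: bool = True
    max_depth: int = 16
    min_samples_leaf: int = 1
    rng_seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.candidates_per_node is not None and self.candidates_per_node < 1:
            raise ValueError("candidates_per_node must be >= 1")
        if self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("max_depth and min_samples_leaf must be >= 1")

    def resolve_candidates(self, n_features: int) -> int:
        if self.candidates_per_node is None:
            return max_candidate_features(n_features)
        return min(self.candidates_per_node, n_features)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForestParams":
        return cls(**d)


@dataclass
class TreeNode:
    """Internal node (feature_col, threshold, children) or leaf (class, counts)."""

    feature_col: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    predicted_class: int | None = None
    counts: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.predicted_class is not None


@dataclass
class DecisionTree:
    root: TreeNode
    n_features: int


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    n_features: int
    params: ForestParams = field(default_factory=ForestParams)


def _node_counts(labels: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.bincount(labels[rows], minlength=2).astype(np.int64)


def draw_split_candidate(
    P: np.ndarray, node_rows: np.ndarray, rng: np.random.Generator
) -> tuple[int, float]:
    """A (feature column, threshold) pair: uniform column, threshold = the
    chosen column's value at a row drawn uniformly from ``node_rows``."""
    if len(node_rows) == 0:
        raise ValueError("node_rows must be non-empty")
    col = int(rng.integers(P.shape[1]))
    row = node_rows[int(rng.integers(len(node_rows)))]
    return col, float(P[row, col])


def _weighted_child_gini(
    P: np.ndarray, labels: np.ndarray, rows: np.ndarray, col: int, thr: float
) -> float | None:
    """Child-size-weighted mean Gini of the (<= thr, > thr) partition.

    None when one side is empty (the candidate cannot split).
    """
    go_left = P[rows, col] <= thr
    n_left = int(go_left.sum())
    n_right = len(rows) - n_left
    if n_left == 0 or n_right == 0:
        return None
    left_counts = _node_counts(labels, rows[go_left])
    right_counts = _node_counts(labels, rows[~go_left])
    g_left = gini_impurity(ClassDistribution(left_counts))
    g_right = gini_impurity(ClassDistribution(right_counts))
    return (n_left * g_left + n_right * g_right) / len(rows)


def best_split(
    P: np.ndarray,
    labels: np.ndarray,
    node_rows: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
) -> tuple[int, float] | None:
    """The Gini-minimising candidate among the node's drawn candidates.

    Returns None ("no split") when every candidate leaves a child empty.
    With ``params.exhaustive`` every (row, column) pair is scored instead of
    a random draw.
    """
    node_rows = np.asarray(node_rows)
    if params.exhaustive:
        candidates = [
            (col, float(P[row, col])) for col in range(P.shape[1]) for row in node_rows
        ]
    else:
        m = params.resolve_candidates(P.shape[1])
        candidates = [draw_split_candidate(P, node_rows, rng) for _ in range(m)]

    best_score, best_candidate = np.inf, None
    for col, thr in candidates:
        score = _weighted_child_gini(P, labels, node_rows, col, thr)
        if score is not None and score < best_score:
            best_score, best_candidate = score, (col, thr)
    return best_candidate


def grow_tree(
    P: np.ndarray,
    labels: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
    rows: np.ndarray | None = None,
) -> DecisionTree:
    """Grow one tree on (a bootstrap of) the feature-matrix rows.

    Recursion stops at zero Gini, ``max_depth``, fewer than
    ``min_samples_leaf`` rows, or when no candidate can split the node.
    """
    P = np.asarray(P, dtype=np.float64)
    labels = np.asarray(labels)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("P must be a non-empty 2-D matrix")
    if len(labels) != P.shape[0]:
        raise ValueError("labels must align with the rows of P")
    if rows is None:
        rows = bootstrap_rows(P.shape[0], rng) if params.bootstrap else np.arange(P.shape[0])

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        counts = _node_counts(labels, rows)
        dist = ClassDistribution(counts)
        if (
            gini_impurity(dist) == 0.0
            or depth >= params.max_depth
            or len(rows) < params.min_samples_leaf
        ):
            return TreeNode(predicted_class=dist.majority_class(), counts=counts)
        split = best_split(P, labels, rows, params, rng)
        if split is None:
            return TreeNode(predicted_class=dist.majority_class(), counts=counts)
        col, thr = split
        go_left = P[rows, col] <= thr
        return TreeNode(
            feature_col=col,
            threshold=thr,
            left=build(rows[go_left], depth + 1),
            right=build(rows[~go_left], depth + 1),
        )

    return DecisionTree(root=build(np.asarray(rows), 0), n_features=P.shape[1])


def predict_tree(tree: DecisionTree, x: Sequence[float]) -> int:
    """Route ``x`` down the tree (value <= threshold goes left); return the leaf class."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (tree.n_features,):
        raise ValueError(f"expected a feature vector of length {tree.n_features}, got {x.shape}")
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.feature_col] <= node.threshold else node.right
    return int(node.predicted_class)


def build_forest(
    P: np.ndarray, labels: np.ndarray, params: ForestParams | None = None
) -> ForestModel:
    """Grow ``params.n_trees`` trees, each with an independent seeded rng stream."""
    params = params or ForestParams()
    P = np.asarray(P, dtype=np.float64)
    trees = []
    for t in range(params.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, t]))
        trees.append(grow_tree(P, labels, params, rng))
    return ForestModel(trees=trees, n_features=P.shape[1], params=params)


def predict_forest(model: ForestModel, x: Sequence[float]) -> tuple[int, float]:
    """Majority vote over trees; returns (class, fraction of positive votes).

    An exact tie predicts the negative class (impossible with an odd forest).
    """
    if not model.trees:
        raise ValueError("forest has no trees")
    votes = np.array([predict_tree(t, x) for t in model.trees])
    vote_fraction = float(np.mean(votes == 1))
    predicted = 1 if vote_fraction > 0.5 else NEGATIVE_CLASS
    return predicted, vote_fraction


def predict_forest_matrix(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised predict_forest over the rows of X."""
    X = np.asarray(X, dtype=np.float64)
    preds, fracs = [], []
    for row in X:
        c, f = predict_forest(model, row)
        preds.append(c)
        fracs.append(f)
    return np.array(preds), np.array(fracs)


# -- persistence ----------------------------------------------------------


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"leaf": True, "class": int(node.predicted_class),
                "counts": [int(c) for c in node.counts]}
    return {
        "leaf": False,
        "feature_col": int(node.feature_col),
        "threshold": float(node.threshold),
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if d["leaf"]:
        return TreeNode(predicted_class=d["class"], counts=np.asarray(d["counts"]))
    return TreeNode(
        feature_col=d["feature_col"],
        threshold=d["threshold"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def save_forest(model: ForestModel, out: str | Path) -> Path:
    out = Path(out)
    payload = {
        "n_features": model.n_features,
        "params": model.params.to_dict(),
        "trees": [
            {"n_features": t.n_features, "root": _node_to_dict(t.root)} for t in model.trees
        ],
    }
    out.write_text(json.dumps(payload, indent=1))
    return out


def load_forest(path: str | Path) -> ForestModel:
    payload = json.loads(Path(path).read_text())
    trees = [
        DecisionTree(root=_node_from_dict(t["root"]), n_features=t["n_features"])
        for t in payload["trees"]
    ]
    return ForestModel(
        trees=trees,
        n_features=payload["n_features"],
        params=ForestParams.from_dict(payload["params"]),
    )
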