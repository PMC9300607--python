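"""Node-level classifiers on the three principal diameters.

Four prediction methods, mirroring the study design:

* two formula-threshold classifiers (``ratio_2d`` or ``sphericity``
  score against a Youden-optimal cutoff, higher score = metastatic);
* a CART decision tree splitting on the raw diameters (a, b, c) by
  Gini impurity;
* a bagged random forest of such trees (default 100 trees) with
  out-of-bag error and mean-decrease-in-impurity variable importances.

Deterministic conventions, applied everywhere:

* class ties resolve to non-metastatic (the clinically conservative
  "needs pathological confirmation" class);
* threshold ties resolve toward the smaller cutoff, split ties toward
  the lower feature index (a, b, c) then the smaller threshold;
* the forest expands its single integer seed through a counter-based
  scheme (one child stream per tree index), so tree k's bootstrap is
  unchanged when n_trees grows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from nodesphere import morphometry
from nodesphere.types import AxisTriple

logger = logging.getLogger(__name__)

FEATURES = ("a", "b", "c")

ArrayLike = Union[np.ndarray, Sequence[Sequence[float]]]


class NotFittedError(RuntimeError):
    pass


def _as_feature_matrix(axes: ArrayLike) -> np.ndarray:
    """Coerce a list of axis triples / (n, 3) array to a float matrix."""
    if isinstance(axes, np.ndarray) and axes.ndim == 2 and axes.shape[1] == 3:
        return axes.astype(float, copy=False)
    rows = []
    for item in axes:
        if isinstance(item, AxisTriple):
            rows.append(item.as_tuple())
        else:
            rows.append(tuple(float(v) for v in item))
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) axis matrix, got shape {X.shape}")
    return X


def _check_labels(y: Sequence[int]) -> np.ndarray:
    arr = np.asarray(y, dtype=int)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return arr


# ---------------------------------------------------------------------------
# Youden-threshold classifier
# ---------------------------------------------------------------------------

@dataclass
class ThresholdClassifier:
    """Score-threshold rule: score >= cutoff => metastatic."""

    score_name: str
    cutoff: float
    youden_j: float = float("nan")
    informative: bool = True

    def predict_scores(self, scores: Sequence[float]) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return (s >= self.cutoff).astype(int)

    def predict(self, axes: ArrayLike) -> np.ndarray:
        X = _as_feature_matrix(axes)
        if self.score_name == "ratio_2d":
            scores = X[:, 0] / X[:, 2]
        elif self.score_name == "sphericity":
            scores = np.cbrt(X[:, 0] * X[:, 1] * X[:, 2]) / X[:, 2]
        else:
            raise ValueError(f"unknown score {self.score_name!r}")
        return self.predict_scores(scores)

    def to_dict(self) -> dict:
        return {
            "method": self.score_name,
            "kind": "threshold",
            "score_name": self.score_name,
            "cutoff": self.cutoff,
            "youden_j": self.youden_j,
            "informative": self.informative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdClassifier":
        return cls(
            score_name=d["score_name"],
            cutoff=float(d["cutoff"]),
            youden_j=float(d["youden_j"]),
            informative=bool(d["informative"]),
        )


def fit_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    score_name: str = "sphericity",
) -> ThresholdClassifier:
    """Youden-optimal cutoff for a "higher score = metastatic" rule.

    Candidate cutoffs are the midpoints between consecutive distinct
    score values; the cutoff maximizing J = sensitivity + specificity - 1
    is returned, ties broken toward the smaller cutoff. With a single
    distinct score the rule is non-informative (J = 0) and flagged.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a cutoff")

    order = np.argsort(s, kind="mergesort")
    ss, ys = s[order], y[order]
    distinct = np.nonzero(np.diff(ss) > 0)[0]  # split after these indices
    if distinct.size == 0:
        logger.warning("all scores identical; threshold is non-informative")
        return ThresholdClassifier(score_name, float(ss[0]), 0.0, informative=False)
    cutoffs = (ss[distinct] + ss[distinct + 1]) / 2.0
    cum_pos = np.cumsum(ys)
    left_pos = cum_pos[distinct]            # positives strictly below cutoff
    left_n = distinct + 1
    sens = (n_pos - left_pos) / n_pos
    spec = (left_n - left_pos) / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = smallest cutoff
    return ThresholdClassifier(score_name, float(cutoffs[best]), float(j[best]))


# ---------------------------------------------------------------------------
# CART decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a fitted tree; leaves have ``feature`` None."""

    counts: tuple[int, int]                 # (n non-metastatic, n metastatic)
    prediction: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    impurity_decrease: float = 0.0          # weighted by n_node / n_train

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d: dict = {"counts": list(self.counts), "prediction": self.prediction}
        if not self.is_leaf:
            d.update(
                feature=FEATURES[self.feature],
                threshold=self.threshold,
                impurity_decrease=self.impurity_decrease,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=tuple(d["counts"]), prediction=int(d["prediction"]))
        if "feature" in d:
            node.feature = FEATURES.index(d["feature"])
            node.threshold = float(d["threshold"])
            node.impurity_decrease = float(d.get("impurity_decrease", 0.0))
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeParams:
    """CART hyperparameters; defaults suit a ~137-node training set."""

    max_depth: Optional[int] = 4
    min_leaf: int = 5
    min_impurity_decrease: float = 0.0

    def validate(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.min_impurity_decrease < 0:
            raise ValueError("min_impurity_decrease must be >= 0")


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: Sequence[int],
    min_leaf: int,
) -> Optional[tuple[int, float, float]]:
    """Best (feature, threshold, weighted impurity decrease) or None.

    The decrease is per parent sample. Ties resolve to the lower feature
    index, then the smaller threshold.
    """
    n = y.size
    n_pos = int(y.sum())
    parent = _gini(n_pos, n)
    best: Optional[tuple[int, float, float]] = None
    for f in feature_indices:
        v = X[:, f]
        order = np.argsort(v, kind="mergesort")
        vs, ys = v[order], y[order]
        cut = np.nonzero(np.diff(vs) > 0)[0]
        if cut.size:
            left_n = cut + 1
            ok = (left_n >= min_leaf) & (n - left_n >= min_leaf)
            cut, left_n = cut[ok], left_n[ok]
        if cut.size == 0:
            continue
        left_pos = np.cumsum(ys)[cut]
        right_n = n - left_n
        right_pos = n_pos - left_pos
        child = (
            left_n * (2 * (left_pos / left_n) * (1 - left_pos / left_n))
            + right_n * (2 * (right_pos / right_n) * (1 - right_pos / right_n))
        ) / n
        decrease = parent - child
        k = int(np.argmax(decrease))  # first max = smallest threshold
        if best is None or decrease[k] > best[2]:
            thr = (vs[cut[k]] + vs[cut[k] + 1]) / 2.0
            best = (f, float(thr), float(decrease[k]))
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    params: TreeParams,
    n_train: int,
    rng: Optional[np.random.Generator],
    features_per_split: int,
) -> TreeNode:
    n = y.size
    n_pos = int(y.sum())
    counts = (n - n_pos, n_pos)
    prediction = int(n_pos > n - n_pos)  # tie -> non-metastatic
    node = TreeNode(counts=counts, prediction=prediction)
    if (
        n_pos in (0, n)
        or n < 2 * params.min_leaf
        or (params.max_depth is not None and depth >= params.max_depth)
    ):
        return node
    if rng is None or features_per_split >= len(FEATURES):
        feats: Sequence[int] = range(len(FEATURES))
    else:
        feats = np.sort(
            rng.choice(len(FEATURES), size=features_per_split, replace=False)
        )
    split = _best_split(X, y, feats, params.min_leaf)
    if split is None:
        return node
    f, thr, decrease = split
    if decrease * n / n_train < params.min_impurity_decrease or decrease <= 0:
        return node
    go_left = X[:, f] <= thr
    node.feature = f
    node.threshold = thr
    node.impurity_decrease = decrease * n / n_train
    node.left = _grow(
        X[go_left], y[go_left], depth + 1, params, n_train, rng, features_per_split
    )
    node.right = _grow(
        X[~go_left], y[~go_left], depth + 1, params, n_train, rng, features_per_split
    )
    return node


@dataclass
class DecisionTree:
    """A fitted CART tree over the (a, b, c) diameters."""

    root: TreeNode
    params: TreeParams
    n_train: int

    def predict(self, axes: ArrayLike) -> np.ndarray:
        X = _as_feature_matrix(axes)
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    @property
    def feature_importances_(self) -> dict[str, float]:
        """Normalized total Gini decrease attributed to each diameter."""
        totals = np.zeros(len(FEATURES))

        def visit(node: TreeNode) -> None:
            if not node.is_leaf:
                totals[node.feature] += node.impurity_decrease
                visit(node.left)
                visit(node.right)

        visit(self.root)
        total = totals.sum()
        if total > 0:
            totals = totals / total
        return dict(zip(FEATURES, totals.tolist()))

    def to_dict(self) -> dict:
        return {
            "method": "tree",
            "kind": "tree",
            "params": {
                "max_depth": self.params.max_depth,
                "min_leaf": self.params.min_leaf,
                "min_impurity_decrease": self.params.min_impurity_decrease,
            },
            "n_train": self.n_train,
            "root": self.root.to_dict(),
            "importances": self.feature_importances_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        p = d["params"]
        return cls(
            root=TreeNode.from_dict(d["root"]),
            params=TreeParams(
                max_depth=p["max_depth"],
                min_leaf=int(p["min_leaf"]),
                min_impurity_decrease=float(p["min_impurity_decrease"]),
            ),
            n_train=int(d["n_train"]),
        )


def fit_tree(
    axes: ArrayLike,
    labels: Sequence[int],
    params: Optional[TreeParams] = None,
) -> DecisionTree:
    """Fit a Gini CART tree on the three diameters.

    Greedy recursive binary splitting; candidate thresholds are the
    midpoints between consecutive distinct feature values. Deterministic
    given data and params.
    """
    params = params or TreeParams()
    params.validate()
    X = _as_feature_matrix(axes)
    y = _check_labels(labels)
    if X.shape[0] != y.size:
        raise ValueError("axes and labels must align")
    if y.size < 2 * params.min_leaf:
        raise ValueError(
            f"need at least 2*min_leaf={2 * params.min_leaf} samples, got {y.size}"
        )
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit a tree")
    root = _grow(X, y, 0, params, y.size, rng=None, features_per_split=len(FEATURES))
    return DecisionTree(root=root, params=params, n_train=y.size)


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

@dataclass
class ForestParams:
    """Bagging hyperparameters; n_trees=100 is the study's operating point."""

    n_trees: int = 100
    features_per_split: int = 2     # ceil(sqrt(3))
    min_leaf: int = 1
    max_depth: Optional[int] = None
    bootstrap: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.features_per_split <= len(FEATURES)):
            raise ValueError(
                f"features_per_split must be in [1, {len(FEATURES)}]"
            )
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class RandomForest:
    """Bagged ensemble of CART trees with OOB error and importances."""

    trees: list[DecisionTree]
    params: ForestParams
    importances: dict[str, float]
    oob_error: Optional[float]
    n_train: int
    bootstrap_seeds: list[int] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, axes: ArrayLike) -> np.ndarray:
        X = _as_feature_matrix(axes)
        votes = np.zeros(X.shape[0], dtype=int)
        for tree in self.trees:
            votes += tree.predict(X)
        # strict majority for metastatic; ties -> non-metastatic
        return (2 * votes > self.n_trees).astype(int)

    def to_dict(self) -> dict:
        return {
            "method": "forest",
            "kind": "forest",
            "params": {
                "n_trees": self.params.n_trees,
                "features_per_split": self.params.features_per_split,
                "min_leaf": self.params.min_leaf,
                "max_depth": self.params.max_depth,
                "bootstrap": self.params.bootstrap,
                "seed": self.params.seed,
            },
            "n_train": self.n_train,
            "importances": self.importances,
            "oob_error": self.oob_error,
            "bootstrap_seeds": self.bootstrap_seeds,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RandomForest":
        p = d["params"]
        return cls(
            trees=[DecisionTree.from_dict(t) for t in d["trees"]],
            params=ForestParams(
                n_trees=int(p["n_trees"]),
                features_per_split=int(p["features_per_split"]),
                min_leaf=int(p["min_leaf"]),
                max_depth=p["max_depth"],
                bootstrap=bool(p["bootstrap"]),
                seed=int(p["seed"]),
            ),
            importances={k: float(v) for k, v in d["importances"].items()},
            oob_error=None if d["oob_error"] is None else float(d["oob_error"]),
            n_train=int(d["n_train"]),
            bootstrap_seeds=[int(s) for s in d.get("bootstrap_seeds", [])],
        )


def fit_forest(
    axes: ArrayLike,
    labels: Sequence[int],
    params: Optional[ForestParams] = None,
) -> RandomForest:
    """Fit a bagged forest of Gini CART trees on the three diameters.

    Each tree trains on a size-n bootstrap resample and samples
    ``features_per_split`` of the three diameters at every split. The
    out-of-bag vote over trees not containing a sample estimates the
    generalization error; importances are the per-tree-normalized mean
    decrease in Gini impurity, averaged over trees.
    """
    params = params or ForestParams()
    params.validate()
    X = _as_feature_matrix(axes)
    y = _check_labels(labels)
    if X.shape[0] != y.size:
        raise ValueError("axes and labels must align")
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit a forest")
    n = y.size
    tree_params = TreeParams(
        max_depth=params.max_depth,
        min_leaf=params.min_leaf,
        min_impurity_decrease=0.0,
    )
    tree_params.validate()

    trees: list[DecisionTree] = []
    seeds: list[int] = []
    oob_votes_pos = np.zeros(n, dtype=int)
    oob_counts = np.zeros(n, dtype=int)
    importance_sum = np.zeros(len(FEATURES))

    for k in range(params.n_trees):
        # counter-based stream: tree k is independent of n_trees
        rng = np.random.default_rng([params.seed, k])
        seeds.append(k)
        if params.bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        yb = y[idx]
        if yb.min() == yb.max():
            # single-class resample: a stump predicting that class
            root = TreeNode(
                counts=(int((yb == 0).sum()), int(yb.sum())),
                prediction=int(yb[0]),
            )
        else:
            root = _grow(
                X[idx], yb, 0, tree_params, n, rng, params.features_per_split
            )
        tree = DecisionTree(root=root, params=tree_params, n_train=n)
        trees.append(tree)

        imp = np.array([tree.feature_importances_[f] for f in FEATURES])
        importance_sum += imp

        if params.bootstrap:
            oob = np.ones(n, dtype=bool)
            oob[np.unique(idx)] = False
            if oob.any():
                preds = tree.predict(X[oob])
                oob_votes_pos[oob] += preds
                oob_counts[oob] += 1

    importances = dict(zip(FEATURES, (importance_sum / params.n_trees).tolist()))

    oob_error: Optional[float] = None
    if params.bootstrap:
        covered = oob_counts > 0
        if covered.any():
            oob_pred = (2 * oob_votes_pos[covered] > oob_counts[covered]).astype(int)
            oob_error = float(np.mean(oob_pred != y[covered]))
            if not covered.all():
                logger.warning(
                    "%d/%d samples had no out-of-bag vote", int((~covered).sum()), n
                )

    return RandomForest(
        trees=trees,
        params=params,
        importances=importances,
        oob_error=oob_error,
        n_train=n,
        bootstrap_seeds=seeds,
    )


# ---------------------------------------------------------------------------
# Shared prediction / serialization helpers
# ---------------------------------------------------------------------------

Model = Union[ThresholdClassifier, DecisionTree, RandomForest]


def predict_nodes(model: Model, axes: ArrayLike) -> np.ndarray:
    """One binary metastasis call per node, for any fitted model."""
    if not isinstance(model, (ThresholdClassifier, DecisionTree, RandomForest)):
        raise NotFittedError(f"not a fitted model: {model!r}")
    return model.predict(axes)


def model_to_json(model: Model) -> str:
    return json.dumps(model.to_dict(), indent=2)


def model_from_json(text: str) -> Model:
    d = json.loads(text)
    kind = d.get("kind")
    if kind == "threshold":
        return ThresholdClassifier.from_dict(d)
    if kind == "tree":
        return DecisionTree.from_dict(d)
    if kind == "forest":
        return RandomForest.from_dict(d)
    raise ValueError(f"unknown model kind {kind!r}")
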