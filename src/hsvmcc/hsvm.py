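"""Hierarchical SVM tree built by k-means-guided binary splits.

An N-class problem is solved by a binary tree of N−1 linear SVM nodes.  The
tree is grown top-down: at each node, candidate feature subsets (cheapest
sensors first) are clustered with 2-means; each candidate split is scored by
*purity* (fraction of windows landing in their class's majority cluster) and
*equilibrium* (how evenly the classes divide between the two clusters).  The
best candidate's class partition is then separated with a linear soft-margin
SVM trained on a stratified 80/20 split, and the procedure recurses into each
side until every leaf holds a single class.

Classification is a root-to-leaf traversal, so a prediction evaluates at most
``depth`` binary rules and only extracts the features those rules need — the
reason this classifier is cheap enough for always-on, low-sampling-rate use.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``get_params``); module-level helpers (`train_tree`, `classify`, ...) are
thin wrappers around it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateSplitError, ParameterError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "FeatureCost",
    "DEFAULT_FEATURE_COSTS",
    "SplitCandidate",
    "HsvmNode",
    "HierarchicalSVMClassifier",
    "rank_features",
    "kmeans_split",
    "select_split",
    "train_node",
    "train_tree",
    "classify",
    "tree_to_json",
    "tree_from_json",
]

MODEL_FORMAT = "hsvm-tree"
MODEL_VERSION = 1


@dataclass(frozen=True)
class FeatureCost:
    """Extraction cost of one feature: (sensor rank, compute rank).

    Lower sensor rank = cheaper sensor kept powered (the barometer draws less
    than the accelerometer); lower compute rank = cheaper arithmetic given
    the sensor is already on.  The pair induces the feature priority order.
    """

    name: str
    sensor_rank: int
    compute_rank: int


# Barometer features first (cheaper sensor); within the accelerometer the
# vertical-axis mean is the most informative cheap feature, then the motion
# feature Twave, then the remaining axis means.
DEFAULT_FEATURE_COSTS = (
    FeatureCost("Pd", 0, 0),
    FeatureCost("Pdabs", 0, 1),
    FeatureCost("Ymeans", 1, 0),
    FeatureCost("Twave", 1, 1),
    FeatureCost("Xmeans", 1, 2),
    FeatureCost("Zmeans", 1, 3),
)


def rank_features(costs) -> list[str]:
    """Sort feature names by (sensor rank, compute rank), stable for ties."""
    names = [c.name for c in costs]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate feature ids in cost table: {names}")
    return [c.name for c in sorted(costs, key=lambda c: (c.sensor_rank, c.compute_rank))]


@dataclass
class SplitCandidate:
    """A scored 2-means split of the training windows at one node."""

    features: tuple[str, ...]
    assignment: np.ndarray  # 0 = cluster A (smaller centroid), 1 = cluster B
    purity: float
    balance: float
    classes_a: tuple
    classes_b: tuple


def kmeans_split(values, labels, seed=None) -> SplitCandidate:
    """Cluster per-window feature values into two groups and score the split.

    ``values`` is (n,) or (n, d); columns are standardised before clustering
    so multi-feature candidates are not dominated by units.  Cluster A is the
    one with the lexicographically smaller centroid (original units).  Purity
    is the fraction of windows whose cluster agrees with their class's
    majority cluster; balance is ``min(|classes in A|, |classes in B|) /
    n_classes`` with every class assigned to its majority cluster.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ParameterError("values and labels lengths differ")
    if X.shape[0] < 2 or len(set(y)) < 2:
        raise ParameterError("kmeans_split needs >= 2 windows of >= 2 classes")
    if np.allclose(X, X[0], atol=1e-12):
        raise DegenerateSplitError(
            f"all values identical for features {tuple(X.shape)}; cannot split"
        )
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=2, n_init=10, tol=1e-6, random_state=seed)
    raw = km.fit_predict((X - mu) / sd)
    centroids = np.vstack([X[raw == c].mean(axis=0) for c in (0, 1)])
    # canonical order: A has the smaller centroid (lexicographic)
    order = sorted((0, 1), key=lambda c: tuple(centroids[c]))
    assign = np.where(raw == order[0], 0, 1)

    classes = sorted(set(y))
    majority = {}
    for cls in classes:
        in_a = int((assign[y == cls] == 0).sum())
        n_cls = int((y == cls).sum())
        majority[cls] = 0 if in_a * 2 >= n_cls else 1
    purity = float(np.mean([assign[i] == majority[y[i]] for i in range(len(y))]))
    classes_a = tuple(c for c in classes if majority[c] == 0)
    classes_b = tuple(c for c in classes if majority[c] == 1)
    balance = min(len(classes_a), len(classes_b)) / len(classes)
    return SplitCandidate(
        features=tuple(),  # filled by the caller that knows the subset
        assignment=assign,
        purity=purity,
        balance=balance,
        classes_a=classes_a,
        classes_b=classes_b,
    )


def select_split(candidates, purity_threshold: float) -> SplitCandidate:
    """Pick the split with maximal class balance among sufficiently pure ones.

    Candidates must be supplied in feature-priority order; ties keep the
    earlier (cheaper) candidate.  If no candidate reaches the purity
    threshold the purest one is returned with a warning.
    """
    if not candidates:
        raise ParameterError("select_split received no candidates")
    pure = [c for c in candidates if c.purity >= purity_threshold]
    if pure:
        return max(pure, key=lambda c: c.balance)  # max() keeps the first tie
    warnings.warn(
        f"no split candidate reaches purity {purity_threshold}; "
        "falling back to the purest candidate",
        UserWarning,
        stacklevel=2,
    )
    return max(candidates, key=lambda c: c.purity)


@dataclass
class HsvmNode:
    """One binary decision: a linear rule over a feature subset.

    The rule is ``w . (x - mean) / scale + b``; non-positive values route to
    side A, positive to side B.  Each side is either a leaf class or a child
    node, and ``classes_a`` / ``classes_b`` partition the node's class set.
    """

    features: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    classes_a: tuple
    classes_b: tuple
    holdout_accuracy: float
    n_train: int
    child_a: "HsvmNode | None" = None
    child_b: "HsvmNode | None" = None
    leaf_a: str | None = None
    leaf_b: str | None = None
    split_purity: float = field(default=float("nan"))
    split_balance: float = field(default=float("nan"))

    def decision_value(self, x: np.ndarray) -> float:
        z = (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_scale
        return float(self.coef @ z + self.intercept)

    def side(self, x: np.ndarray) -> int:
        """0 -> A, 1 -> B."""
        return 1 if self.decision_value(x) > 0 else 0

    def count_nodes(self) -> int:
        n = 1
        for child in (self.child_a, self.child_b):
            if child is not None:
                n += child.count_nodes()
        return n

    def leaves(self) -> list[str]:
        out = []
        for child, leaf in ((self.child_a, self.leaf_a), (self.child_b, self.leaf_b)):
            out.extend(child.leaves() if child is not None else [leaf])
        return out


def _node_features_frame(X: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    missing = set(features) - set(X.columns)
    if missing:
        raise ParameterError(f"feature columns missing from input: {sorted(missing)}")
    return X.loc[:, list(features)].to_numpy(dtype=float)


def train_node(
    X: pd.DataFrame,
    y,
    classes_a,
    classes_b,
    features,
    C: float = 1.0,
    seed=None,
    test_size: float = 0.2,
) -> HsvmNode:
    """Fit one linear binary SVM separating class group A from group B.

    Features are standardised with training-split statistics; the held-out
    stratified ``test_size`` fraction only reports the node's accuracy.
    """
    y = np.asarray(y, dtype=object)
    classes_a, classes_b = tuple(classes_a), tuple(classes_b)
    if not classes_a or not classes_b:
        raise ParameterError("both class groups must be non-empty")
    unknown = set(y) - set(classes_a) - set(classes_b)
    if unknown:
        raise ParameterError(f"windows with classes outside A u B: {sorted(unknown)}")
    Xf = _node_features_frame(X, tuple(features))
    target = np.isin(y, classes_b).astype(int)  # 0 = A, 1 = B
    stratify = y if min(np.unique(y, return_counts=True)[1]) >= 2 else None
    X_tr, X_te, t_tr, t_te = train_test_split(
        Xf, target, test_size=test_size, random_state=seed, stratify=stratify
    )
    mean = X_tr.mean(axis=0)
    scale = X_tr.std(axis=0)
    scale[scale == 0] = 1.0
    svm = SVC(kernel="linear", C=C)
    svm.fit((X_tr - mean) / scale, t_tr)
    holdout = float(accuracy_score(t_te, svm.predict((X_te - mean) / scale)))
    return HsvmNode(
        features=tuple(features),
        scaler_mean=mean,
        scaler_scale=scale,
        coef=svm.coef_.ravel().astype(float),
        intercept=float(svm.intercept_[0]),
        classes_a=classes_a,
        classes_b=classes_b,
        holdout_accuracy=holdout,
        n_train=int(len(t_tr)),
    )


class HierarchicalSVMClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass classifier as a binary tree of k-means-guided linear SVMs.

    Parameters
    ----------
    feature_costs : sequence of FeatureCost, optional
        Priority table; defaults to barometer features before accelerometer
        features (`DEFAULT_FEATURE_COSTS`).
    purity_threshold : float, default 0.95
        Minimum split purity for a candidate to compete on balance.
    C : float, default 1.0
        Soft-margin cost of each node's linear SVM.
    top_m : int, default 4
        Number of highest-priority features whose singletons (and pairs, when
        ``include_pairs``) form the candidate subset pool.
    include_pairs : bool, default True
        Also try unordered feature pairs from the top-m features.
    full_power_set : bool, default False
        Search every non-empty subset of the top-m features (exponential;
        exposed for completeness — single features suffice in practice).
    test_size : float, default 0.2
        Held-out fraction of each node's stratified train/test split.
    random_state : int or RandomState, optional
        Seeds k-means restarts and the per-node train/test splits.

    Attributes
    ----------
    tree_ : HsvmNode
        Root of the fitted decision tree (N−1 nodes for N classes).
    classes_ : ndarray
        Sorted class labels.
    n_nodes_ : int
        Number of internal (SVM) nodes.
    """

    def __init__(
        self,
        feature_costs=None,
        purity_threshold: float = 0.95,
        C: float = 1.0,
        top_m: int = 4,
        include_pairs: bool = True,
        full_power_set: bool = False,
        test_size: float = 0.2,
        random_state=None,
    ):
        self.feature_costs = feature_costs
        self.purity_threshold = purity_threshold
        self.C = C
        self.top_m = top_m
        self.include_pairs = include_pairs
        self.full_power_set = full_power_set
        self.test_size = test_size
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if hasattr(self, "feature_names_in_"):
            return pd.DataFrame(X, columns=list(self.feature_names_in_))
        return pd.DataFrame(X, columns=list(FEATURE_NAMES[: X.shape[1]]))

    def _candidate_subsets(self, available: list[str]) -> list[tuple[str, ...]]:
        costs = self.feature_costs or DEFAULT_FEATURE_COSTS
        ranked = [f for f in rank_features(costs) if f in available]
        ranked += [f for f in available if f not in ranked]
        top = ranked[: self.top_m]
        if self.full_power_set:
            subsets = []
            for r in range(1, len(top) + 1):
                subsets.extend(combinations(top, r))
            return subsets
        subsets = [(f,) for f in top]
        if self.include_pairs:
            subsets.extend(combinations(top, 2))
        return subsets

    def fit(self, X, y):
        X = self._as_frame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ParameterError("X and y lengths differ")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ParameterError("need at least 2 classes")
        if counts.min() < 2:
            thin = classes[counts < 2].tolist()
            raise ParameterError(f"every class needs >= 2 windows; too few: {thin}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.classes_ = classes
        rng = check_random_state(self.random_state)
        subsets = self._candidate_subsets(list(X.columns))
        idx = np.arange(len(y))
        self.tree_ = self._build(X, y, idx, tuple(classes), subsets, rng, depth=0)
        self.n_nodes_ = self.tree_.count_nodes()
        return self

    def _build(self, X, y, idx, classes, subsets, rng, depth) -> HsvmNode:
        if depth > len(self.classes_):
            raise RuntimeError(
                f"tree construction exceeded max depth {len(self.classes_)} at "
                f"classes {classes}: splits are not separating the class set"
            )
        ysub = y[idx]
        candidates = []
        for subset in subsets:
            vals = X.loc[idx, list(subset)].to_numpy(dtype=float)
            try:
                cand = kmeans_split(vals, ysub, seed=rng.randint(2**31))
            except DegenerateSplitError:
                continue
            if cand.balance == 0:  # all classes on one side: unusable partition
                continue
            cand.features = subset
            candidates.append(cand)
        if not candidates:
            raise ParameterError(
                f"no usable split candidate for class set {classes}"
            )
        best = select_split(candidates, self.purity_threshold)
        node = train_node(
            X.loc[idx],
            ysub,
            best.classes_a,
            best.classes_b,
            best.features,
            C=self.C,
            seed=rng.randint(2**31),
            test_size=self.test_size,
        )
        node.split_purity = best.purity
        node.split_balance = best.balance
        for side, cls_group in (("a", best.classes_a), ("b", best.classes_b)):
            child_idx = idx[np.isin(ysub, cls_group)]
            if len(cls_group) == 1:
                setattr(node, f"leaf_{side}", cls_group[0])
            else:
                child = self._build(
                    X, y, child_idx, cls_group, subsets, rng, depth + 1
                )
                setattr(node, f"child_{side}", child)
        return node

    # -- prediction --------------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = self._as_frame(X)
        out = np.empty(len(X), dtype=object)
        for i, (_, row) in enumerate(X.iterrows()):
            out[i] = self._classify_row(row)
        return out

    def _classify_row(self, row) -> str:
        node = self.tree_
        while True:
            x = np.array([row[f] for f in node.features], dtype=float)
            if node.side(x) == 0:
                if node.leaf_a is not None:
                    return node.leaf_a
                node = node.child_a
            else:
                if node.leaf_b is not None:
                    return node.leaf_b
                node = node.child_b

    # -- persistence -------------------------------------------------------

    def to_json(self, indent=2) -> str:
        check_is_fitted(self, "tree_")
        return tree_to_json(self, indent=indent)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "HierarchicalSVMClassifier":
        with open(path, encoding="utf-8") as fh:
            return tree_from_json(fh.read())


# -- serialization ---------------------------------------------------------


def _node_to_dict(node: HsvmNode) -> dict:
    d = {
        "features": list(node.features),
        "scaler_mean": node.scaler_mean.tolist(),
        "scaler_scale": node.scaler_scale.tolist(),
        "coef": node.coef.tolist(),
        "intercept": node.intercept,
        "classes_a": list(node.classes_a),
        "classes_b": list(node.classes_b),
        "holdout_accuracy": node.holdout_accuracy,
        "n_train": node.n_train,
        "split_purity": node.split_purity,
        "split_balance": node.split_balance,
    }
    d["a"] = {"leaf": node.leaf_a} if node.child_a is None else _node_to_dict(node.child_a)
    d["b"] = {"leaf": node.leaf_b} if node.child_b is None else _node_to_dict(node.child_b)
    return d


def _node_from_dict(d: dict) -> HsvmNode:
    node = HsvmNode(
        features=tuple(d["features"]),
        scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
        coef=np.asarray(d["coef"], dtype=float),
        intercept=float(d["intercept"]),
        classes_a=tuple(d["classes_a"]),
        classes_b=tuple(d["classes_b"]),
        holdout_accuracy=float(d["holdout_accuracy"]),
        n_train=int(d["n_train"]),
        split_purity=float(d["split_purity"]),
        split_balance=float(d["split_balance"]),
    )
    for side in ("a", "b"):
        sub = d[side]
        if "leaf" in sub:
            setattr(node, f"leaf_{side}", sub["leaf"])
        else:
            setattr(node, f"child_{side}", _node_from_dict(sub))
    return node


def tree_to_json(model: HierarchicalSVMClassifier, indent=2) -> str:
    """Serialize a fitted classifier to the documented JSON schema."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "classes": model.classes_.tolist(),
        "feature_names": model.feature_names_in_.tolist(),
        "params": model.get_params(deep=False) | {"feature_costs": None},
        "root": _node_to_dict(model.tree_),
    }
    params = payload["params"]
    if isinstance(params.get("random_state"), np.random.RandomState):
        params["random_state"] = None
    return json.dumps(payload, indent=indent, sort_keys=True)


def tree_from_json(text: str) -> HierarchicalSVMClassifier:
    payload = json.loads(text)
    if payload.get("format") != MODEL_FORMAT:
        raise ParameterError(f"not a {MODEL_FORMAT} file")
    params = {k: v for k, v in payload["params"].items() if k != "feature_costs"}
    model = HierarchicalSVMClassifier(**params)
    model.classes_ = np.asarray(payload["classes"], dtype=object)
    model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    model.n_features_in_ = len(model.feature_names_in_)
    model.tree_ = _node_from_dict(payload["root"])
    model.n_nodes_ = model.tree_.count_nodes()
    return model


# -- functional wrappers ---------------------------------------------------


def train_tree(
    X,
    y,
    costs=None,
    seed=None,
    purity_threshold: float = 0.95,
    **kwargs,
) -> HierarchicalSVMClassifier:
    """Fit a `HierarchicalSVMClassifier` on a feature table + labels."""
    model = HierarchicalSVMClassifier(
        feature_costs=costs,
        purity_threshold=purity_threshold,
        random_state=seed,
        **kwargs,
    )
    return model.fit(X, y)


def classify(model: HierarchicalSVMClassifier, fv) -> str:
    """Classify one feature vector (FeatureVector, mapping, or array)."""
    if isinstance(fv, FeatureVector):
        row = fv.as_dict()
    elif isinstance(fv, dict):
        row = fv
    else:
        row = dict(zip(model.feature_names_in_, np.asarray(fv, dtype=float)))
    return model.predict(pd.DataFrame([row]))[0]
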