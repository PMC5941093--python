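"""CART-style regression tree exposing per-leaf training-label variance.

All risk predictors in this package are regression trees over binary labels,
so a leaf's mean is a risk score in [0, 1] and the (population) variance of
the training labels in that leaf quantifies how mixed the leaf is. The
question-selection stage consumes both, hence
:meth:`VarianceRegressionTree.predict_with_variance`.

Splitting is greedy variance reduction with deterministic tie-breaking:
among equal-gain splits, the lowest feature index wins, then the lowest
threshold. Growth stops at ``max_depth``, at ``min_samples_leaf``, or when
no split reduces the node's sum of squared errors by more than
``min_variance_reduction`` per sample.
"""

from __future__ import annotations

import json

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["VarianceRegressionTree"]

_LEAF = -1


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold, sse_gain) or None.

    Vectorized over features: each column is sorted once, child SSEs are
    computed from prefix sums at every admissible split position.
    """
    n, d = X.shape
    if n < 2 * min_leaf or n < 2:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    cs = np.cumsum(ys, axis=0)
    cs2 = np.cumsum(ys * ys, axis=0)
    tot = y.sum()
    tot2 = (y * y).sum()

    nl = np.arange(1, n, dtype=np.float64)[:, None]
    nr = n - nl
    sl, s2l = cs[:-1], cs2[:-1]
    sse = (s2l - sl * sl / nl) + ((tot2 - s2l) - (tot - sl) ** 2 / nr)
    valid = (xs[:-1] < xs[1:]) & (nl >= min_leaf) & (nr >= min_leaf)
    sse = np.where(valid, sse, np.inf)

    # argmin returns the first minimum: lowest threshold within a feature,
    # then lowest feature index across features — the documented tie-break.
    pos = np.argmin(sse, axis=0)
    per_feature = sse[pos, np.arange(d)]
    j = int(np.argmin(per_feature))
    if not np.isfinite(per_feature[j]):
        return None
    p = int(pos[j])
    threshold = (xs[p, j] + xs[p + 1, j]) / 2.0
    # midpoint can round up onto the right value when the two are adjacent
    # floats; fall back to the left value so neither child is empty
    if not (xs[p, j] <= threshold < xs[p + 1, j]):
        threshold = xs[p, j]
    parent_sse = tot2 - tot * tot / n
    return j, threshold, parent_sse - per_feature[j]


class VarianceRegressionTree(RegressorMixin, BaseEstimator):
    """Greedy variance-reduction regression tree with leaf variances.

    Parameters
    ----------
    max_depth : int, default 4
        Maximum number of splits on any root-to-leaf path (>= 1).
    min_samples_leaf : int, default 5
        Minimum training samples per leaf.
    min_variance_reduction : float, default 0.0
        Minimum per-sample SSE reduction a split must achieve; splits with
        zero gain never happen.
    random_state : int or None
        Accepted for interface symmetry; fitting is fully deterministic.

    Attributes
    ----------
    feature_, threshold_, children_left_, children_right_ : ndarray
        Flat node arrays (``feature_ == -1`` marks a leaf). A sample goes
        left when ``x[feature] <= threshold``.
    value_, variance_, n_node_samples_ : ndarray
        Training-label mean, population variance and count per node.
    """

    def __init__(
        self,
        max_depth: int = 4,
        min_samples_leaf: int = 5,
        min_variance_reduction: float = 0.0,
        random_state: int | None = None,
    ):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_variance_reduction = min_variance_reduction
        self.random_state = random_state

    def fit(self, X, y) -> "VarianceRegressionTree":
        X = _dense(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        value: list[float] = []
        variance: list[float] = []
        counts: list[int] = []

        def new_node(idx: np.ndarray) -> int:
            node = len(feature)
            yi = y[idx]
            feature.append(_LEAF)
            threshold.append(np.nan)
            left.append(_LEAF)
            right.append(_LEAF)
            value.append(float(yi.mean()))
            variance.append(float(yi.var()))  # population variance
            counts.append(len(idx))
            return node

        root_idx = np.arange(X.shape[0])
        stack = [(new_node(root_idx), root_idx, 0)]
        while stack:
            node, idx, depth = stack.pop()
            if depth >= self.max_depth or variance[node] <= 0.0:
                continue
            split = _best_split(X[idx], y[idx], self.min_samples_leaf)
            if split is None:
                continue
            j, thr, gain = split
            if gain <= self.min_variance_reduction * len(idx) or gain <= 1e-12:
                continue
            go_left = X[idx, j] <= thr
            feature[node] = j
            threshold[node] = thr
            li = new_node(idx[go_left])
            ri = new_node(idx[~go_left])
            left[node], right[node] = li, ri
            stack.append((li, idx[go_left], depth + 1))
            stack.append((ri, idx[~go_left], depth + 1))

        self.feature_ = np.asarray(feature, dtype=np.int64)
        self.threshold_ = np.asarray(threshold, dtype=np.float64)
        self.children_left_ = np.asarray(left, dtype=np.int64)
        self.children_right_ = np.asarray(right, dtype=np.int64)
        self.value_ = np.asarray(value, dtype=np.float64)
        self.variance_ = np.asarray(variance, dtype=np.float64)
        self.n_node_samples_ = np.asarray(counts, dtype=np.int64)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------

    def apply(self, X) -> np.ndarray:
        """Leaf node index for each sample."""
        check_is_fitted(self, "feature_")
        X = _dense(X)
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            f = self.feature_[node]
            active = np.where(f >= 0)[0]
            if active.size == 0:
                return node
            xa = X[active, f[active]]
            thr = self.threshold_[node[active]]
            nxt = np.where(
                xa <= thr,
                self.children_left_[node[active]],
                self.children_right_[node[active]],
            )
            node[active] = nxt

    def predict(self, X) -> np.ndarray:
        return self.value_[self.apply(X)]

    def predict_with_variance(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(leaf mean, leaf training-label population variance) per sample."""
        leaves = self.apply(X)
        return self.value_[leaves], self.variance_[leaves]

    def training_mse(self, X, y) -> float:
        y = np.asarray(y, dtype=np.float64).ravel()
        return float(np.mean((self.predict(X) - y) ** 2))

    # -- serialization -----------------------------------------------------

    def _node_dict(self, node: int) -> dict:
        base = {
            "n": int(self.n_node_samples_[node]),
            "value": float(self.value_[node]),
            "variance": float(self.variance_[node]),
        }
        if self.feature_[node] == _LEAF:
            base["leaf"] = True
            return base
        base["leaf"] = False
        base["feature"] = int(self.feature_[node])
        base["threshold"] = float(self.threshold_[node])
        base["left"] = self._node_dict(int(self.children_left_[node]))
        base["right"] = self._node_dict(int(self.children_right_[node]))
        return base

    def to_dict(self) -> dict:
        check_is_fitted(self, "feature_")
        return {
            "params": self.get_params(),
            "n_features": int(self.n_features_in_),
            "root": self._node_dict(0),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "VarianceRegressionTree":
        model = cls(**payload["params"])
        feature, threshold, left, right = [], [], [], []
        value, variance, counts = [], [], []

        def add(nd: dict) -> int:
            i = len(feature)
            feature.append(_LEAF)
            threshold.append(np.nan)
            left.append(_LEAF)
            right.append(_LEAF)
            value.append(nd["value"])
            variance.append(nd["variance"])
            counts.append(nd["n"])
            if not nd["leaf"]:
                feature[i] = nd["feature"]
                threshold[i] = nd["threshold"]
                left[i] = add(nd["left"])
                right[i] = add(nd["right"])
            return i

        add(payload["root"])
        model.feature_ = np.asarray(feature, dtype=np.int64)
        model.threshold_ = np.asarray(threshold, dtype=np.float64)
        model.children_left_ = np.asarray(left, dtype=np.int64)
        model.children_right_ = np.asarray(right, dtype=np.int64)
        model.value_ = np.asarray(value, dtype=np.float64)
        model.variance_ = np.asarray(variance, dtype=np.float64)
        model.n_node_samples_ = np.asarray(counts, dtype=np.int64)
        model.n_features_in_ = payload["n_features"]
        return model

    @classmethod
    def from_json(cls, path) -> "VarianceRegressionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
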