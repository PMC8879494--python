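"""Regularized second-order gradient-boosted decision trees.

An additive ensemble of regression trees fitted to the first/second
derivatives (g, h) of a logistic loss.  With G and H the sums of g and h
over the samples in a leaf, the optimal leaf weight is

    w* = -G / (H + lambda),

the minimized structure objective is

    obj* = -1/2 * sum_j G_j^2 / (H_j + lambda) + gamma * T,

and a candidate split of a node into L and R children scores

    Gain = 1/2 * [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                   - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma.

Trees are grown greedily, level by level, by exhaustive scan over all
features and midpoint thresholds between consecutive distinct sorted
values; a split is applied only when the best gain is strictly positive and
both children carry at least ``min_child_hessian`` of hessian.  Ties in
gain are broken toward the lowest feature index, then the lowest
threshold.  Shrinkage ``learning_rate`` scales every leaf weight.

The split scan and tree traversal are numba-compiled; all results are
deterministic functions of the inputs and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit


@dataclass(frozen=True)
class GBTParams:
    n_rounds: int = 100
    max_depth: int = 6
    learning_rate: float = 0.3
    reg_lambda: float = 1.0
    reg_gamma: float = 0.0
    min_child_hessian: float = 1.0
    scale_pos_weight: Optional[float] = None  # None -> N_neg / N_pos at fit time
    base_score: float = 0.5
    loss: str = "logistic"  # or "squared" (oracle mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.reg_lambda < 0 or self.reg_gamma < 0 or self.min_child_hessian < 0:
            raise ValueError("regularization parameters must be >= 0")
        if not (0 < self.base_score < 1):
            raise ValueError("base_score must be in (0, 1)")
        if self.scale_pos_weight is not None and self.scale_pos_weight <= 0:
            raise ValueError("scale_pos_weight must be > 0")
        if self.loss not in ("logistic", "squared"):
            raise ValueError("loss must be 'logistic' or 'squared'")


@dataclass
class GradHess:
    """Per-sample first (g) and second (h) derivatives of the loss."""

    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.g.shape != self.h.shape:
            raise ValueError("g and h must have equal length")


@dataclass
class TreeNode:
    """Either a split node (feature_index, threshold, left, right) or a leaf
    (weight).  Samples with ``x[feature] < threshold`` route left."""

    feature_index: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    weight: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def predict_row(self, x: np.ndarray) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature_index] < node.threshold else node.right
        return node.weight

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"weight": self.weight}
        return {
            "feature_index": self.feature_index,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TreeNode":
        if "weight" in doc:
            return cls(weight=doc["weight"])
        return cls(
            feature_index=doc["feature_index"],
            threshold=doc["threshold"],
            left=cls.from_dict(doc["left"]),
            right=cls.from_dict(doc["right"]),
        )


# ---------------------------------------------------------------------------
# Closed forms

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logistic_grad_hess(y, margin, scale_pos_weight: float = 1.0) -> GradHess:
    """g = w (p - y), h = w p (1 - p) with p = sigmoid(margin) and
    w = scale_pos_weight for positives, 1 for negatives."""
    y = np.asarray(y, dtype=float)
    p = sigmoid(margin)
    w = np.where(y == 1, scale_pos_weight, 1.0)
    return GradHess(w * (p - y), w * p * (1.0 - p))


def squared_grad_hess(y, margin) -> GradHess:
    y = np.asarray(y, dtype=float)
    margin = np.asarray(margin, dtype=float)
    return GradHess(margin - y, np.ones_like(margin))


def leaf_weight(G: float, H: float, reg_lambda: float) -> float:
    """Optimal leaf weight w* = -G / (H + lambda)."""
    if H + reg_lambda <= 0:
        raise ValueError("H + lambda must be positive")
    return -G / (H + reg_lambda)


def leaf_objective(leaves: Sequence[tuple[float, float]], reg_lambda: float,
                   reg_gamma: float) -> float:
    """Minimized objective -1/2 sum_j G_j^2/(H_j+lambda) + gamma T."""
    obj = 0.0
    for G, H in leaves:
        if H + reg_lambda <= 0:
            raise ValueError("H + lambda must be positive")
        obj -= 0.5 * G * G / (H + reg_lambda)
    return obj + reg_gamma * len(leaves)


def split_gain(GL: float, HL: float, GR: float, HR: float, reg_lambda: float,
               reg_gamma: float) -> float:
    """Objective reduction of splitting a node into (L, R) children."""
    lam = reg_lambda
    return 0.5 * (
        GL * GL / (HL + lam) + GR * GR / (HR + lam)
        - (GL + GR) ** 2 / (HL + HR + lam)
    ) - reg_gamma


# ---------------------------------------------------------------------------
# Exact greedy growth (level-wise scan over presorted features)

@njit(cache=True)
def _scan_level(sorted_vals, sorted_idx, node_of, node_slot, g, h,
                Gtot, Htot, lam, gamma, min_h, best_gain, best_feat, best_thr):
    D, N = sorted_vals.shape
    S = Gtot.shape[0]
    GL = np.zeros(S)
    HL = np.zeros(S)
    last = np.zeros(S)
    started = np.zeros(S, np.uint8)
    for f in range(D):
        for s in range(S):
            GL[s] = 0.0
            HL[s] = 0.0
            started[s] = 0
        for ii in range(N):
            i = sorted_idx[f, ii]
            slot = node_slot[node_of[i]]
            if slot < 0:
                continue
            v = sorted_vals[f, ii]
            if started[slot] == 1 and v > last[slot]:
                HR = Htot[slot] - HL[slot]
                if HL[slot] >= min_h and HR >= min_h:
                    GRv = Gtot[slot] - GL[slot]
                    gain = 0.5 * (
                        GL[slot] * GL[slot] / (HL[slot] + lam)
                        + GRv * GRv / (HR + lam)
                        - Gtot[slot] * Gtot[slot] / (Htot[slot] + lam)
                    ) - gamma
                    if gain > best_gain[slot]:
                        best_gain[slot] = gain
                        best_feat[slot] = f
                        best_thr[slot] = 0.5 * (v + last[slot])
            GL[slot] += g[i]
            HL[slot] += h[i]
            last[slot] = v
            started[slot] = 1


@njit(cache=True)
def _traverse(X, feat, thr, left, right, weight, roots, base, out):
    N = X.shape[0]
    for i in range(N):
        acc = base
        for t in range(roots.shape[0]):
            node = roots[t]
            while feat[node] >= 0:
                if X[i, feat[node]] < thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            acc += weight[node]
        out[i] = acc


class _FlatTree:
    """Array-of-nodes tree used during growth and fast prediction."""

    __slots__ = ("feature", "threshold", "left", "right", "weight")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.weight: list[float] = []

    def add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.weight.append(0.0)
        return len(self.feature) - 1

    def to_node(self, i: int = 0) -> TreeNode:
        if self.feature[i] < 0:
            return TreeNode(weight=self.weight[i])
        return TreeNode(
            feature_index=self.feature[i],
            threshold=self.threshold[i],
            left=self.to_node(self.left[i]),
            right=self.to_node(self.right[i]),
        )


def _grow_flat(X, g, h, params: GBTParams, sorted_vals=None, sorted_idx=None) -> _FlatTree:
    N, D = X.shape
    if sorted_idx is None:
        sorted_idx = np.argsort(X, axis=0, kind="stable").T.astype(np.int64)
        sorted_vals = np.take_along_axis(X.T, sorted_idx, axis=1)
    tree = _FlatTree()
    root = tree.add_node()
    node_of = np.zeros(N, dtype=np.int64)
    node_depth = {root: 0}
    lam, gam, minh = params.reg_lambda, params.reg_gamma, params.min_child_hessian
    for depth in range(params.max_depth + 1):
        active = [n for n, d in node_depth.items() if d == depth and tree.feature[n] == -1]
        if not active:
            break
        Gtot = np.zeros(len(active))
        Htot = np.zeros(len(active))
        node_slot = np.full(len(tree.feature), -1, dtype=np.int64)
        for s, n in enumerate(active):
            node_slot[n] = s
        slot_of_sample = node_slot[node_of]
        mask = slot_of_sample >= 0
        np.add.at(Gtot, slot_of_sample[mask], g[mask])
        np.add.at(Htot, slot_of_sample[mask], h[mask])

        if depth == params.max_depth:
            for s, n in enumerate(active):
                tree.weight[n] = leaf_weight(Gtot[s], Htot[s], lam)
            break

        best_gain = np.full(len(active), 0.0)
        best_feat = np.full(len(active), -1, dtype=np.int64)
        best_thr = np.zeros(len(active))
        _scan_level(sorted_vals, sorted_idx, node_of, node_slot, g, h,
                    Gtot, Htot, lam, gam, minh, best_gain, best_feat, best_thr)

        for s, n in enumerate(active):
            if best_feat[s] >= 0 and best_gain[s] > 0.0:
                lc = tree.add_node()
                rc = tree.add_node()
                tree.feature[n] = int(best_feat[s])
                tree.threshold[n] = float(best_thr[s])
                tree.left[n], tree.right[n] = lc, rc
                node_depth[lc] = node_depth[rc] = depth + 1
                members = np.flatnonzero(node_of == n)
                goes_left = X[members, best_feat[s]] < best_thr[s]
                node_of[members[goes_left]] = lc
                node_of[members[~goes_left]] = rc
            else:
                tree.weight[n] = leaf_weight(Gtot[s], Htot[s], lam)
    return tree


def grow_tree(X, gh: GradHess, params: GBTParams) -> TreeNode:
    """Grow one tree on the given gradients; leaf weights are the raw
    optima -G/(H+lambda) (shrinkage is applied by :func:`fit`)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D array")
    return _grow_flat(X, gh.g, gh.h, params).to_node()


@dataclass
class BoostedModel:
    """Additive tree ensemble; prediction is sigmoid of summed margins."""

    trees: list[TreeNode]
    params: GBTParams
    feature_dim: int

    def __post_init__(self) -> None:
        self._flat = None

    @property
    def base_margin(self) -> float:
        return math.log(self.params.base_score / (1 - self.params.base_score))

    def _flatten(self):
        if self._flat is not None:
            return self._flat
        feat, thr, left, right, weight, roots = [], [], [], [], [], []

        def emit(node: TreeNode) -> int:
            i = len(feat)
            feat.append(-1 if node.is_leaf else node.feature_index)
            thr.append(0.0 if node.is_leaf else node.threshold)
            left.append(-1)
            right.append(-1)
            weight.append(node.weight if node.is_leaf else 0.0)
            if not node.is_leaf:
                left[i] = emit(node.left)
                right[i] = emit(node.right)
            return i

        for t in self.trees:
            roots.append(emit(t))
        self._flat = (
            np.array(feat, dtype=np.int64), np.array(thr), np.array(left, dtype=np.int64),
            np.array(right, dtype=np.int64), np.array(weight), np.array(roots, dtype=np.int64),
        )
        return self._flat

    def predict_margin(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.shape[1] != self.feature_dim:
            raise ValueError(f"expected {self.feature_dim} features, got {X.shape[1]}")
        base = self.base_margin if self.params.loss == "logistic" else 0.0
        out = np.empty(X.shape[0])
        if not self.trees:
            out[:] = base
            return out
        feat, thr, left, right, weight, roots = self._flatten()
        _traverse(X, feat, thr, left, right, weight, roots, base, out)
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample probability of the positive class, strictly in (0, 1)."""
        if self.params.loss != "logistic":
            raise ValueError("probabilities are defined for the logistic loss only")
        return sigmoid(self.predict_margin(X))

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "feature_dim": self.feature_dim,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BoostedModel":
        return cls(
            trees=[TreeNode.from_dict(t) for t in doc["trees"]],
            params=GBTParams(**doc["params"]),
            feature_dim=doc["feature_dim"],
        )


def _scale_leaves(node: TreeNode, eta: float) -> None:
    if node.is_leaf:
        node.weight *= eta
    else:
        _scale_leaves(node.left, eta)
        _scale_leaves(node.right, eta)


def fit(X, y, params: GBTParams = GBTParams()) -> BoostedModel:
    """Boost ``n_rounds`` trees on binary labels.

    Margins start at logit(base_score); each round fits a tree to the
    current (g, h), scales its leaves by the learning rate, and updates the
    margins.  ``scale_pos_weight=None`` resolves to N_neg / N_pos of the
    training data (imbalance-compensating operating point).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching first dimension")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")

    spw = params.scale_pos_weight
    if spw is None:
        n_pos = int((y == 1).sum())
        spw = float((y == 0).sum()) / n_pos if n_pos > 0 else 1.0
    resolved = GBTParams(**{**asdict(params), "scale_pos_weight": spw})

    sorted_idx = np.argsort(X, axis=0, kind="stable").T.astype(np.int64)
    sorted_vals = np.take_along_axis(X.T, sorted_idx, axis=1)
    sorted_vals = np.ascontiguousarray(sorted_vals)
    sorted_idx = np.ascontiguousarray(sorted_idx)

    if resolved.loss == "logistic":
        margins = np.full(X.shape[0], math.log(resolved.base_score / (1 - resolved.base_score)))
    else:
        margins = np.zeros(X.shape[0])
    trees: list[TreeNode] = []
    flats: list[_FlatTree] = []
    out = np.empty(X.shape[0])
    for _ in range(resolved.n_rounds):
        if resolved.loss == "logistic":
            gh = logistic_grad_hess(y, margins, spw)
        else:
            gh = squared_grad_hess(y, margins)
        flat = _grow_flat(X, gh.g, gh.h, resolved, sorted_vals, sorted_idx)
        node = flat.to_node()
        _scale_leaves(node, resolved.learning_rate)
        trees.append(node)
        single = BoostedModel([node], resolved, X.shape[1])
        _traverse(X, *single._flatten(), 0.0, out)
        margins = margins + out
    return BoostedModel(trees, resolved, X.shape[1])
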