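"""Exact path-dependent TreeSHAP for gradient-boosted tree ensembles.

Computes Shapley attributions of a tree ensemble's margin prediction in
float64. Features absent from a conditioning subset are marginalized with
training cover weights (the path-dependent convention), and the recursion
tracks, for every subset size, the proportion of feature-permutation
"paths" that reach each node — giving every feature's exact Shapley value
in one pass per tree instead of an exponential subset enumeration.

Local accuracy holds by construction: the per-row attributions plus the
ensemble's cover-weighted expected value sum to the float64 margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import xgboost as xgb
from numba import njit

__all__ = ["TreeEnsemble", "parse_xgboost", "shap_values",
           "margin_predictions"]


@dataclass
class TreeEnsemble:
    """Flattened ensemble: concatenated per-node arrays plus tree offsets."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray      # -1 at leaves
    threshold: np.ndarray
    value: np.ndarray        # leaf value; 0 elsewhere
    cover: np.ndarray
    tree_offset: np.ndarray  # root index of each tree
    base_score: float
    n_features: int
    max_depth: int = 0

    def __post_init__(self) -> None:
        if self.max_depth == 0:
            self.max_depth = _ensemble_depth(
                self.children_left, self.children_right, self.tree_offset)

    def expected_value(self) -> float:
        """Cover-weighted mean margin of the ensemble."""
        total = self.base_score
        for t in range(len(self.tree_offset) - 1):
            lo, hi = self.tree_offset[t], self.tree_offset[t + 1]
            leaves = self.feature[lo:hi] < 0
            cov = self.cover[lo:hi][leaves]
            total += float(np.sum(self.value[lo:hi][leaves] * cov) / cov.sum())
        return total


def _ensemble_depth(cl, cr, offsets) -> int:
    def depth(node: int) -> int:
        if cl[node] < 0:
            return 0
        return 1 + max(depth(cl[node]), depth(cr[node]))

    return max(depth(int(offsets[t])) for t in range(len(offsets) - 1))


def parse_xgboost(model) -> TreeEnsemble:
    """Flatten an xgboost regressor/booster into plain node arrays."""
    booster = model if isinstance(model, xgb.Booster) else model.get_booster()
    df = booster.trees_to_dataframe()
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    try:
        feat_index = {name: i for i, name in enumerate(booster.feature_names)}
    except (TypeError, AttributeError):
        feat_index = None

    df = df.sort_values(["Tree", "Node"], kind="stable").reset_index(drop=True)
    tree_ids = df["Tree"].to_numpy()
    nodes = df["Node"].to_numpy()
    is_leaf = (df["Feature"] == "Leaf").to_numpy()
    pos_of = {}  # (tree, node id) -> flat position
    for k, (t, nid) in enumerate(zip(tree_ids, nodes)):
        pos_of[(int(t), int(nid))] = k

    n = len(df)
    cl = np.full(n, -1, dtype=np.int64)
    cr = np.full(n, -1, dtype=np.int64)
    feat = np.full(n, -1, dtype=np.int64)
    thr = np.zeros(n, dtype=np.float64)
    val = np.zeros(n, dtype=np.float64)
    cov = df["Cover"].to_numpy(dtype=np.float64)
    gains = df["Gain"].to_numpy(dtype=np.float64)
    # dumps print float32 thresholds as 9-digit decimals; cast back
    # through float32 to recover the exact stored bits
    splits = df["Split"].to_numpy(dtype=np.float32).astype(np.float64)
    feats = df["Feature"].to_numpy()
    yes = df["Yes"].to_numpy()
    no = df["No"].to_numpy()

    val[is_leaf] = gains[is_leaf]
    for k in np.flatnonzero(~is_leaf):
        t = int(tree_ids[k])
        cl[k] = pos_of[(t, int(str(yes[k]).split("-")[1]))]
        cr[k] = pos_of[(t, int(str(no[k]).split("-")[1]))]
        name = feats[k]
        if feat_index is not None and name in feat_index:
            feat[k] = feat_index[name]
        else:
            feat[k] = int(str(name).lstrip("f"))
        thr[k] = splits[k]

    boundaries = np.flatnonzero(np.diff(tree_ids)) + 1
    offsets = np.concatenate([[0], boundaries, [n]]).astype(np.int64)

    return TreeEnsemble(
        children_left=cl, children_right=cr, feature=feat, threshold=thr,
        value=val, cover=cov, tree_offset=offsets, base_score=base_score,
        n_features=int(booster.num_features()),
    )


@njit(inline="always")
def _extend(fi, zf, of, pw, off, depth, zero_fraction, one_fraction,
            feature_index):
    fi[off + depth] = feature_index
    zf[off + depth] = zero_fraction
    of[off + depth] = one_fraction
    pw[off + depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[off + i + 1] += one_fraction * pw[off + i] * (i + 1.0) / (depth + 1.0)
        pw[off + i] = zero_fraction * pw[off + i] * (depth - i) / (depth + 1.0)


@njit(inline="always")
def _unwind(fi, zf, of, pw, off, depth, path_index):
    one_fraction = of[off + path_index]
    zero_fraction = zf[off + path_index]
    nxt = pw[off + depth]
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[off + i]
            pw[off + i] = nxt * (depth + 1.0) / ((i + 1.0) * one_fraction)
            nxt = tmp - pw[off + i] * zero_fraction * (depth - i) / (depth + 1.0)
        else:
            pw[off + i] = pw[off + i] * (depth + 1.0) / (zero_fraction * (depth - i))
    for i in range(path_index, depth):
        fi[off + i] = fi[off + i + 1]
        zf[off + i] = zf[off + i + 1]
        of[off + i] = of[off + i + 1]


@njit(inline="always")
def _unwound_sum(zf, of, pw, off, depth, path_index):
    one_fraction = of[off + path_index]
    zero_fraction = zf[off + path_index]
    nxt = pw[off + depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = nxt * (depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            nxt = pw[off + i] - tmp * zero_fraction * ((depth - i) / (depth + 1.0))
        else:
            total += pw[off + i] / (zero_fraction * ((depth - i) / (depth + 1.0)))
    return total


@njit
def _shap_all(cl, cr, feat, thr, val, cov, offsets, max_depth, X, phi):
    # one path workspace reused across rows and trees; the frame at
    # unique depth L occupies at most (max_depth + 3) slots after its
    # parent's segment
    size = (max_depth + 3) * (max_depth + 4)
    fi = np.zeros(size, dtype=np.int64)
    zf = np.zeros(size, dtype=np.float64)
    of = np.zeros(size, dtype=np.float64)
    pw = np.zeros(size, dtype=np.float64)

    # explicit DFS stack: (node, depth, parent offset, parent zero/one
    # fractions, parent feature); LIFO order finishes a subtree before its
    # sibling reuses the same path segment
    cap = 4 * (max_depth + 4)
    s_node = np.empty(cap, dtype=np.int64)
    s_depth = np.empty(cap, dtype=np.int64)
    s_poff = np.empty(cap, dtype=np.int64)
    s_pzf = np.empty(cap, dtype=np.float64)
    s_pof = np.empty(cap, dtype=np.float64)
    s_pfeat = np.empty(cap, dtype=np.int64)

    for r in range(X.shape[0]):
        x = X[r]
        prow = phi[r]
        for t in range(len(offsets) - 1):
            top = 0
            s_node[0] = offsets[t]
            s_depth[0] = 0
            s_poff[0] = 0
            s_pzf[0] = 1.0
            s_pof[0] = 1.0
            s_pfeat[0] = -1
            while top >= 0:
                node = s_node[top]
                depth = s_depth[top]
                p_off = s_poff[top]
                pzf = s_pzf[top]
                pof = s_pof[top]
                pfeat = s_pfeat[top]
                top -= 1

                off = p_off + depth
                for i in range(depth):
                    fi[off + i] = fi[p_off + i]
                    zf[off + i] = zf[p_off + i]
                    of[off + i] = of[p_off + i]
                    pw[off + i] = pw[p_off + i]
                _extend(fi, zf, of, pw, off, depth, pzf, pof, pfeat)

                if feat[node] < 0:  # leaf
                    for i in range(1, depth + 1):
                        w = _unwound_sum(zf, of, pw, off, depth, i)
                        prow[fi[off + i]] += (w * (of[off + i] - zf[off + i])
                                              * val[node])
                    continue

                if x[feat[node]] < thr[node]:
                    hot, cold = cl[node], cr[node]
                else:
                    hot, cold = cr[node], cl[node]
                incoming_zero = 1.0
                incoming_one = 1.0
                path_index = 0
                while path_index <= depth:
                    if fi[off + path_index] == feat[node]:
                        break
                    path_index += 1
                if path_index != depth + 1:
                    incoming_zero = zf[off + path_index]
                    incoming_one = of[off + path_index]
                    _unwind(fi, zf, of, pw, off, depth, path_index)
                    depth -= 1

                # push cold first so the hot subtree is finished first
                top += 1
                s_node[top] = cold
                s_depth[top] = depth + 1
                s_poff[top] = off
                s_pzf[top] = cov[cold] / cov[node] * incoming_zero
                s_pof[top] = 0.0
                s_pfeat[top] = feat[node]
                top += 1
                s_node[top] = hot
                s_depth[top] = depth + 1
                s_poff[top] = off
                s_pzf[top] = cov[hot] / cov[node] * incoming_zero
                s_pof[top] = incoming_one
                s_pfeat[top] = feat[node]


@njit
def _margins(cl, cr, feat, thr, val, offsets, X, out):
    for r in range(X.shape[0]):
        total = 0.0
        for t in range(len(offsets) - 1):
            node = offsets[t]
            while feat[node] >= 0:
                node = cl[node] if X[r, feat[node]] < thr[node] else cr[node]
            total += val[node]
        out[r] = total


def margin_predictions(ensemble: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Float64 ensemble margin (base score + summed leaf values) per row."""
    X = _as_model_precision(X)
    out = np.empty(X.shape[0], dtype=np.float64)
    _margins(ensemble.children_left, ensemble.children_right,
             ensemble.feature, ensemble.threshold, ensemble.value,
             ensemble.tree_offset, X, out)
    return out + ensemble.base_score


def _as_model_precision(X: np.ndarray) -> np.ndarray:
    # xgboost evaluates splits in float32; rounding inputs through float32
    # reproduces its branch decisions exactly at threshold boundaries
    return np.ascontiguousarray(
        np.asarray(X, dtype=np.float32).astype(np.float64))


def shap_values(ensemble: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Float64 Shapley attribution matrix (rows x features)."""
    X = _as_model_precision(X)
    phi = np.zeros((X.shape[0], ensemble.n_features), dtype=np.float64)
    _shap_all(ensemble.children_left, ensemble.children_right,
              ensemble.feature, ensemble.threshold, ensemble.value,
              ensemble.cover, ensemble.tree_offset, ensemble.max_depth,
              X, phi)
    return phi
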