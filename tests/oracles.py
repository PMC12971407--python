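"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities directly from their definitions with
plain Python loops — no shared code with the package implementation — so
agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations, permutations

import numpy as np


def bf_patches(codes: np.ndarray, valid: np.ndarray, connectivity: int = 8):
    """Connected components per class via BFS; returns list of patch dicts."""
    rows, cols = codes.shape
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(valid, dtype=bool)
    patches = []
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c] or seen[r, c]:
                continue
            cls = codes[r, c]
            cells = []
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                y, x = queue.popleft()
                cells.append((y, x))
                for dy, dx in offs:
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < rows and 0 <= nx < cols and valid[ny, nx]
                            and not seen[ny, nx] and codes[ny, nx] == cls):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            cellset = set(cells)
            perim = 0
            for y, x in cells:
                for dy, dx in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    ny, nx = y + dy, x + dx
                    inside = (0 <= ny < rows and 0 <= nx < cols
                              and valid[ny, nx] and (ny, nx) in cellset)
                    if not inside:
                        perim += 1
            patches.append({"code": int(cls), "area": len(cells),
                            "perimeter": perim})
    return patches


def bf_metrics(codes: np.ndarray, valid: np.ndarray | None = None,
               connectivity: int = 8) -> dict:
    """All six landscape metrics straight from their definitions."""
    codes = np.asarray(codes)
    if valid is None:
        valid = np.ones_like(codes, dtype=bool)
    total = int(valid.sum())
    classes = sorted({int(codes[r, c]) for r in range(codes.shape[0])
                      for c in range(codes.shape[1]) if valid[r, c]})
    m = len(classes)
    counts = {k: 0 for k in classes}
    for r in range(codes.shape[0]):
        for c in range(codes.shape[1]):
            if valid[r, c]:
                counts[int(codes[r, c])] += 1
    p = {k: counts[k] / total for k in classes}

    shdi = -sum(v * math.log(v) for v in p.values() if v > 0)
    shei = 0.0 if m <= 1 else shdi / math.log(m)

    patches = bf_patches(codes, valid, connectivity)
    division = 1.0 - sum((pt["area"] / total) ** 2 for pt in patches)

    num = den = 0.0
    for pt in patches:
        frac = 1.0 if pt["area"] <= 1 else \
            2.0 * math.log(0.25 * pt["perimeter"]) / math.log(pt["area"])
        num += frac * pt["area"]
        den += pt["area"]
    frac_am = num / den

    # inter-class edges (single count) and double-count adjacency matrix
    e = {}
    g = {(i, k): 0 for i in classes for k in classes}
    rows, cols = codes.shape
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and valid[nr, nc]:
                    a, b = int(codes[r, c]), int(codes[nr, nc])
                    g[(a, b)] += 1
                    g[(b, a)] += 1
                    if a != b:
                        key = (min(a, b), max(a, b))
                        e[key] = e.get(key, 0) + 1

    total_e = sum(e.values())
    if m < 3 or total_e == 0:
        iji = float("nan")
    else:
        h = -sum((v / total_e) * math.log(v / total_e) for v in e.values())
        iji = 100.0 * h / math.log(0.5 * m * (m - 1))

    if m <= 1:
        contag = 100.0
    else:
        s = 0.0
        for i in classes:
            gi = sum(g[(i, k)] for k in classes)
            if gi == 0:
                continue
            for k in classes:
                q = p[i] * g[(i, k)] / gi
                if q > 0:
                    s += q * math.log(q)
        contag = 100.0 * (1.0 + s / (2.0 * math.log(m)))
        contag = min(max(contag, 0.0), 100.0)

    return {"shdi": shdi, "shei": shei, "division": division,
            "frac_am": frac_am, "iji": iji, "contag": contag, "m": m}


def bf_morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Dense double-loop Moran's I."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    return n * num / (s0 * np.sum((x - xbar) ** 2))


def bf_entropy_weights(X: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Step-by-step entropy weighting from the textbook recipe."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    w = np.zeros(k)
    es = np.zeros(k)
    for j in range(k):
        col = X[:, j] + eps
        pj = col / col.sum()
        es[j] = -sum(pi * math.log(pi) for pi in pj) / math.log(n)
    d = 1.0 - es
    return d / d.sum()


# ---------------------------------------------------------------------------
# Exhaustive Shapley enumeration on small xgboost tree ensembles
# ---------------------------------------------------------------------------

def _tree_value(tree: dict, node: int, x: np.ndarray, subset: set[int]) -> float:
    """Expected leaf value conditioning only on features in ``subset``.

    Features outside the subset are marginalized with cover weights — the
    same conditional-expectation convention the tree-path algorithm uses.
    """
    nd = tree[node]
    if nd["leaf"] is not None:
        return nd["leaf"]
    f = nd["feature"]
    if f in subset:
        nxt = nd["yes"] if x[f] < nd["split"] else nd["no"]
        return _tree_value(tree, nxt, x, subset)
    cy = tree[nd["yes"]]["cover"]
    cn = tree[nd["no"]]["cover"]
    return (cy * _tree_value(tree, nd["yes"], x, subset)
            + cn * _tree_value(tree, nd["no"], x, subset)) / (cy + cn)


def parse_booster(model) -> list[dict]:
    """xgboost booster -> list of {node_id: node dict} trees."""
    df = model.get_booster().trees_to_dataframe()
    trees = []
    for tid, tdf in df.groupby("Tree"):
        tree = {}
        for _, row in tdf.iterrows():
            nid = int(row["Node"])
            if row["Feature"] == "Leaf":
                tree[nid] = {"leaf": float(row["Gain"]), "cover": row["Cover"]}
            else:
                tree[nid] = {
                    "leaf": None,
                    "feature": int(row["Feature"].lstrip("f"))
                    if row["Feature"].startswith("f") else row["Feature"],
                    # recover the exact float32 threshold bits from the
                    # 9-digit decimal the dump prints
                    "split": float(np.float32(row["Split"])),
                    "yes": int(row["Yes"].split("-")[1]),
                    "no": int(row["No"].split("-")[1]),
                    "cover": row["Cover"],
                }
        trees.append(tree)
    return trees


def bf_shapley(model, x: np.ndarray, n_features: int,
               base_score: float) -> np.ndarray:
    """Exact Shapley values by enumeration over all feature subsets."""
    trees = parse_booster(model)
    # the model compares features in float32; mirror that
    x = np.asarray(x, dtype=np.float32).astype(np.float64)

    def v(subset: set[int]) -> float:
        return base_score + sum(_tree_value(t, 0, x, subset) for t in trees)

    phi = np.zeros(n_features)
    all_feats = set(range(n_features))
    for i in range(n_features):
        others = sorted(all_feats - {i})
        for r in range(len(others) + 1):
            for S in combinations(others, r):
                S = set(S)
                weight = (math.factorial(len(S))
                          * math.factorial(n_features - len(S) - 1)
                          / math.factorial(n_features))
                phi[i] += weight * (v(S | {i}) - v(S))
    return phi
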