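"""Landscape pattern metrics and the organization index EO.

Six FRAGSTATS-style metrics are computed per analysis unit, each unit's
sub-raster treated as its own landscape:

* SHDI — Shannon diversity of class proportions, ``-sum P_i ln P_i``
* SHEI — Shannon evenness, ``SHDI / ln m`` (0 for a single class)
* DIVISION — landscape division, ``1 - sum (a_ij / A)^2`` over patches
* IJI — interspersion/juxtaposition of inter-class edges, [0, 100],
  defined only for m >= 3 classes
* CONTAG — contagion from cell adjacencies, [0, 100]
* FRAC_AM — area-weighted mean patch fractal dimension,
  ``2 ln(0.25 p_ij) / ln(a_ij)``

Patches are connected components per class (8-connectivity by default, the
FRAGSTATS convention); perimeters are always counted on the 4-neighbourhood,
as is the adjacency matrix for CONTAG (double-count method, like-class
adjacencies included, landscape boundary excluded).

The organization index EO combines min-max-normalized metrics with fixed
weights. The flat weight vector (default) applies the six published
sub-weights directly; the nested mode applies the published group form
(connectivity / heterogeneity / shape groups re-weighted), which
double-applies the group coefficients and is kept only for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CategoricalGrid

__all__ = [
    "PatchSet",
    "OrganizationWeights",
    "EmptyLandscapeError",
    "label_patches",
    "shdi",
    "shei",
    "division",
    "frac_am",
    "iji",
    "contag",
    "adjacency_counts",
    "interclass_edges",
    "unit_metrics",
    "organization_index",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["shdi", "shei", "division", "iji", "contag", "frac_am"]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT8 = np.ones((3, 3), bool)


class EmptyLandscapeError(ValueError):
    """Raised when a landscape has no unmasked cells."""


@dataclass
class PatchSet:
    """Connected-component patches of a categorical landscape.

    ``labels`` holds a positive patch id per cell (0 = background/nodata);
    ``patches`` records (patch_id, class code, area in cells, perimeter in
    cell edges). Perimeter counts every 4-neighbour cell edge bordering a
    different patch label, a masked cell, or the raster boundary.
    """

    labels: np.ndarray
    patches: pd.DataFrame = field(repr=False)

    @property
    def areas(self) -> np.ndarray:
        return self.patches["area"].to_numpy()

    @property
    def perimeters(self) -> np.ndarray:
        return self.patches["perimeter"].to_numpy()


def label_patches(cat: CategoricalGrid, connectivity: int = 8) -> PatchSet:
    """Delineate per-class connected components.

    ``connectivity`` (4 or 8) controls which cells join a patch; perimeters
    are counted on the 4-neighbourhood regardless. Label order is
    deterministic (scanline, class code ascending).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    valid = ~cat.nodata_mask
    if not valid.any():
        raise EmptyLandscapeError("landscape is fully masked")

    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels = np.zeros(cat.shape, dtype=int)
    records = []
    next_id = 1
    for code in sorted(int(c) for c in np.unique(cat.codes[valid])):
        class_mask = (cat.codes == code) & valid
        lab, n = ndimage.label(class_mask, structure=struct)
        if n == 0:
            continue
        labels[class_mask] = lab[class_mask] + (next_id - 1)
        areas = np.bincount(lab[class_mask], minlength=n + 1)[1:]
        for k in range(n):
            records.append((next_id + k, code, int(areas[k]), 0))
        next_id += n

    patches = pd.DataFrame(records,
                           columns=["patch_id", "code", "area", "perimeter"])
    patches["perimeter"] = _patch_perimeters(labels, len(patches))
    return PatchSet(labels=labels, patches=patches)


def _patch_perimeters(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """4-neighbour perimeter (in cell edges) per patch label."""
    perim = np.zeros(n_patches + 1, dtype=int)
    padded = np.pad(labels, 1, constant_values=0)
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nbr = padded[1 + dr:padded.shape[0] - 1 + dr,
                     1 + dc:padded.shape[1] - 1 + dc]
        edge = (labels > 0) & (labels != nbr)
        perim += np.bincount(labels[edge], minlength=n_patches + 1)
    return perim[1:]


# ---------------------------------------------------------------------------
# Scalar metric formulas
# ---------------------------------------------------------------------------

def shdi(proportions) -> float:
    """Shannon diversity index of class proportions."""
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict)
                   else proportions, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shei(proportions) -> float:
    """Shannon evenness: SHDI / ln m; 0 for a single-class landscape."""
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict)
                   else proportions, dtype=float)
    m = int(np.sum(p > 0))
    if m <= 1:
        return 0.0
    return shdi(p) / np.log(m)


def division(patches: PatchSet, total_area: float) -> float:
    """Landscape division: probability two random cells lie in different patches."""
    if not total_area > 0:
        raise ValueError("total_area must be positive")
    a = patches.areas / total_area
    return float(1.0 - np.sum(a * a))


def frac_am(patches: PatchSet, cell_size: float = 1.0) -> float:
    """Area-weighted mean fractal dimension.

    Per patch: ``2 ln(0.25 p) / ln(a)`` with perimeter and area in linear /
    squared map units. Single-cell (unit-area) patches take the limit value 1.
    """
    a = patches.areas * cell_size * cell_size
    p = patches.perimeters * cell_size
    frac = np.ones(len(a))
    big = a > cell_size * cell_size  # ln(area) == 0 at one cell -> convention 1
    frac[big] = 2.0 * np.log(0.25 * p[big]) / np.log(a[big])
    return float(np.sum(frac * a) / np.sum(a))


def interclass_edges(cat: CategoricalGrid) -> dict[tuple[int, int], int]:
    """Inter-class 4-adjacency edge lengths e_ik (single count, i < k)."""
    edges: dict[tuple[int, int], int] = {}
    codes = cat.codes
    valid = ~cat.nodata_mask
    for axis in (0, 1):
        a = codes.take(range(codes.shape[axis] - 1), axis=axis)
        b = codes.take(range(1, codes.shape[axis]), axis=axis)
        va = valid.take(range(codes.shape[axis] - 1), axis=axis)
        vb = valid.take(range(1, codes.shape[axis]), axis=axis)
        sel = va & vb & (a != b)
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        for i, k in zip(lo.ravel(), hi.ravel()):
            edges[(int(i), int(k))] = edges.get((int(i), int(k)), 0) + 1
    return edges


def adjacency_counts(cat: CategoricalGrid) -> tuple[np.ndarray, list[int]]:
    """Double-count 4-adjacency matrix g_ik over unmasked cells.

    Returns (matrix, class codes); like-class adjacencies included,
    landscape-boundary and masked-neighbour edges excluded.
    """
    valid = ~cat.nodata_mask
    codes = sorted(int(c) for c in np.unique(cat.codes[valid]))
    index = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m), dtype=int)
    arr = cat.codes
    for axis in (0, 1):
        a = arr.take(range(arr.shape[axis] - 1), axis=axis)
        b = arr.take(range(1, arr.shape[axis]), axis=axis)
        va = valid.take(range(arr.shape[axis] - 1), axis=axis)
        vb = valid.take(range(1, arr.shape[axis]), axis=axis)
        sel = va & vb
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            i, j = index[int(x)], index[int(y)]
            g[i, j] += 1  # each shared edge counted from both sides
            g[j, i] += 1
    return g, codes


def iji(edges: dict[tuple[int, int], int], m: int) -> float:
    """Interspersion & juxtaposition index on [0, 100]; undefined for m < 3."""
    total = sum(edges.values())
    if m < 3 or total <= 0:
        return float("nan")
    e = np.array([v for v in edges.values() if v > 0], dtype=float) / total
    h = -np.sum(e * np.log(e))
    return float(100.0 * h / np.log(0.5 * m * (m - 1)))


def contag(proportions, g: np.ndarray, m: int) -> float:
    """Contagion index on [0, 100]; 100 for a single-class landscape."""
    if m <= 1:
        return 100.0
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict)
                   else proportions, dtype=float)
    row_sums = g.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = p[:, None] * np.where(row_sums > 0, g / np.where(row_sums == 0, 1, row_sums), 0.0)
    q = q[q > 0]
    s = float(np.sum(q * np.log(q)))
    val = 100.0 * (1.0 + s / (2.0 * np.log(m)))
    return float(min(max(val, 0.0), 100.0))


# ---------------------------------------------------------------------------
# Per-unit evaluation and EO
# ---------------------------------------------------------------------------

def landscape_metrics(cat: CategoricalGrid, connectivity: int = 8) -> dict:
    """All six metrics for one landscape (one unit's sub-raster)."""
    valid = ~cat.nodata_mask
    if not valid.any():
        raise EmptyLandscapeError("landscape is fully masked")
    props = cat.class_proportions()
    p = np.array([props[c] for c in sorted(props)])
    m = len(p)
    patches = label_patches(cat, connectivity=connectivity)
    g, _ = adjacency_counts(cat)
    total = float(valid.sum())
    return {
        "shdi": shdi(p),
        "shei": shei(p),
        "division": division(patches, total),
        "iji": iji(interclass_edges(cat), m),
        "contag": contag(p, g, m),
        "frac_am": frac_am(patches, cell_size=cat.cell_size),
        "m": m,
    }


def unit_metrics(cat: CategoricalGrid, unit_cells: int,
                 connectivity: int = 8) -> pd.DataFrame:
    """Evaluate the six metrics per analysis unit (block).

    Each block is treated as an independent landscape. Metrics undefined on
    a block (IJI with < 3 classes) are recorded as NaN, never as zero.
    Mask-dominated blocks (valid cells < half the nominal block) are dropped,
    mirroring the zonal-aggregation rule.
    """
    from .grid import _iter_blocks, unit_id_for  # shared lattice convention

    nominal = unit_cells * unit_cells
    n_bcol = int(np.ceil(cat.shape[1] / unit_cells))
    rows = []
    n_single = 0
    for br, bc, sl in _iter_blocks(cat.shape, unit_cells):
        sub = CategoricalGrid(
            codes=cat.codes[sl], legend=cat.legend, cell_size=cat.cell_size,
            nodata_mask=cat.nodata_mask[sl],
        )
        if int((~sub.nodata_mask).sum()) * 2 < nominal:
            continue
        met = landscape_metrics(sub, connectivity=connectivity)
        if met["m"] < 2:
            n_single += 1
        rows.append({"unit_id": unit_id_for(br, bc, n_bcol),
                     "block_row": br, "block_col": bc, **met})
    if n_single:
        logger.info("unit_metrics: %d unit(s) contain a single class", n_single)
    return pd.DataFrame(rows)


@dataclass
class OrganizationWeights:
    """Published EO weights; flat mode sums the six sub-weights directly."""

    w_shdi: float = 0.1499
    w_shei: float = 0.1502
    w_division: float = 0.1002
    w_iji: float = 0.2173
    w_contag: float = 0.1191
    w_frac: float = 0.2633
    # group coefficients of the nested (grouped) form
    w_connectivity: float = 0.3001
    w_heterogeneity: float = 0.4366
    w_shape: float = 0.2633
    mode: str = "flat"

    def flat_vector(self) -> np.ndarray:
        return np.array([self.w_shdi, self.w_shei, self.w_division,
                         self.w_iji, self.w_contag, self.w_frac])


def _minmax_normalize(col: pd.Series) -> tuple[pd.Series, bool]:
    lo, hi = col.min(), col.max()
    if not np.isfinite(lo) or hi - lo == 0:
        return pd.Series(0.5, index=col.index), True
    return (col - lo) / (hi - lo), False


def organization_index(records: pd.DataFrame,
                       weights: OrganizationWeights | None = None) -> pd.DataFrame:
    """Combine per-unit metrics into the organization index EO in [0, 1].

    Each metric is min-max normalized across *all* rows (pool units and
    years before calling to keep EO temporally comparable). Missing metrics
    are imputed with the cross-unit median of the normalized column; a
    metric constant across units normalizes to 0.5 and is flagged.
    """
    weights = weights or OrganizationWeights()
    out = records.copy()
    normed = {}
    for col in METRIC_COLUMNS:
        norm, degenerate = _minmax_normalize(out[col])
        if degenerate:
            logger.warning("organization_index: metric %s is constant; "
                           "normalized to 0.5", col)
        n_missing = int(norm.isna().sum())
        if n_missing:
            logger.info("organization_index: imputing %d missing %s values "
                        "with the median", n_missing, col)
            norm = norm.fillna(norm.median())
        normed[col] = norm
        out[col + "_norm"] = norm

    if weights.mode == "nested":
        lc = weights.w_shdi * normed["shdi"] + weights.w_shei * normed["shei"]
        lh = (weights.w_division * normed["division"]
              + weights.w_iji * normed["iji"]
              + weights.w_contag * normed["contag"])
        ic = weights.w_frac * normed["frac_am"]
        eo = (weights.w_connectivity * lc + weights.w_heterogeneity * lh
              + weights.w_shape * ic)
    else:
        w = weights.flat_vector()
        eo = sum(w[i] * normed[c] for i, c in enumerate(METRIC_COLUMNS))
    out["eo"] = eo.clip(0.0, 1.0)
    return out
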