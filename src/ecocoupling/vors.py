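"""VORS ecosystem health: vitality, organization, resilience, services, EHI.

The ecosystem health index is the geometric mean of four [0, 1] components,

    EHI = (EV * EO * ER * ESI) ** (1/4)

where EV is min-max-normalized unit-mean net primary productivity, EO is the
landscape organization index (see :mod:`ecocoupling.landmetrics`), ER is an
area-weighted resilience score from per-class resistance/recovery
coefficients, and ESI is an entropy-weighted composite of five ecosystem
service indicators (carbon storage, food production, environmental quality,
soil retention, water yield).

Normalization is pooled across all years passed in, so levels are
comparable through time. Area weights A_i in ER are within-unit class
proportions, keeping ER scale-free on [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResilienceCoefficients",
    "NormalizationDegenerateError",
    "minmax",
    "vitality",
    "resilience",
    "entropy_weights",
    "service_index",
    "ehi",
    "classify_levels",
    "LEVEL_LABELS",
]

logger = logging.getLogger(__name__)

LEVEL_LABELS = ["very poor", "poor", "moderate", "good", "excellent"]


class NormalizationDegenerateError(ValueError):
    """Min-max normalization attempted on a constant column."""


@dataclass
class ResilienceCoefficients:
    """Per-class resistance and recovery coefficients, keyed by class name.

    Defaults follow the published table for the six-class legend:
    ER of a pure-forest unit is 0.4*1 + 0.6*0.9 = 0.94, of pure desert
    0.4*0.2 + 0.6*0.1 = 0.14.
    """

    resistant: dict[str, float] = field(default_factory=lambda: {
        "farmland": 0.6, "forest": 1.0, "grassland": 0.6,
        "water": 0.8, "construction": 0.3, "desert": 0.2,
    })
    resilient: dict[str, float] = field(default_factory=lambda: {
        "farmland": 0.4, "forest": 0.9, "grassland": 0.7,
        "water": 0.8, "construction": 0.2, "desert": 0.1,
    })

    def __post_init__(self) -> None:
        for table in (self.resistant, self.resilient):
            for cls, c in table.items():
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"coefficient for {cls} outside [0, 1]")

    def score(self, cls: str) -> float:
        """Combined 0.4*resistance + 0.6*recovery score for one class."""
        if cls not in self.resistant or cls not in self.resilient:
            raise KeyError(f"no resilience coefficients for class {cls!r}")
        return 0.4 * self.resistant[cls] + 0.6 * self.resilient[cls]


def minmax(x: pd.Series | np.ndarray, allow_degenerate: bool = False):
    """Min-max normalize to [0, 1]; constant input -> error or 0.5 fill."""
    arr = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi - lo == 0:
        if not allow_degenerate:
            raise NormalizationDegenerateError("constant column cannot be normalized")
        warnings.warn("constant column normalized to 0.5", stacklevel=2)
        out = np.full(arr.shape, 0.5)
    else:
        out = (arr - lo) / (hi - lo)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


def vitality(unit_npp: pd.DataFrame, column: str = "npp") -> pd.DataFrame:
    """EV: pooled min-max normalization of unit-mean NPP.

    ``unit_npp`` must hold one row per unit (and per year if several years
    are pooled); the ``column`` values are normalized across all rows.
    """
    out = unit_npp.copy()
    out["ev"] = minmax(out[column])
    return out


def resilience(class_proportions: pd.DataFrame,
               coeffs: ResilienceCoefficients | None = None) -> pd.DataFrame:
    """ER per unit from within-unit land-cover proportions.

    ``class_proportions`` columns: ``unit_id`` plus one proportion column per
    class name present in the landscape (rows sum to 1 over those columns).
    """
    coeffs = coeffs or ResilienceCoefficients()
    cls_cols = [c for c in class_proportions.columns
                if c not in ("unit_id", "block_row", "block_col", "year")]
    er = np.zeros(len(class_proportions))
    for cls in cls_cols:
        er += class_proportions[cls].to_numpy() * coeffs.score(cls)
    out = class_proportions[[c for c in ("unit_id", "block_row", "block_col", "year")
                             if c in class_proportions.columns]].copy()
    out["er"] = er
    return out


def entropy_weights(X: pd.DataFrame | np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Entropy-method indicator weights for a units x indicators matrix.

    Indicators are expected min-max normalized to [0, 1]. Zeros are shifted
    by ``eps`` before the share computation (the p ln p term is undefined at
    zero). A constant (zero-information) indicator receives near-zero
    weight; if *all* indicators are constant, weights fall back to equal
    with a warning.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 units")
    n, k = arr.shape
    shifted = arr + eps
    p = shifted / shifted.sum(axis=0, keepdims=True)
    e = -(p * np.log(p)).sum(axis=0) / np.log(n)
    d = 1.0 - e
    if np.allclose(d, 0.0):
        warnings.warn("all indicators constant; falling back to equal weights",
                      stacklevel=2)
        return np.full(k, 1.0 / k)
    return d / d.sum()


def service_index(services: pd.DataFrame, weights: np.ndarray | None = None,
                  service_cols: list[str] | None = None) -> pd.DataFrame:
    """ESI: weighted sum of normalized service indicators.

    Columns are pooled-min-max normalized here; weights default to the
    entropy method on the normalized matrix.
    """
    cols = service_cols or [c for c in services.columns
                            if c not in ("unit_id", "block_row", "block_col", "year")]
    normed = np.column_stack([
        minmax(services[c], allow_degenerate=True) for c in cols])
    if weights is None:
        weights = entropy_weights(normed)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("service weights must sum to 1")
    out = services[[c for c in ("unit_id", "block_row", "block_col", "year")
                    if c in services.columns]].copy()
    for c, w, col in zip(cols, weights, normed.T):
        out[c + "_norm"] = col
        out[c + "_w"] = w
    out["esi"] = normed @ weights
    return out


def ehi(components: pd.DataFrame) -> pd.DataFrame:
    """EHI = (EV * EO * ER * ESI)^(1/4), the geometric mean of the components.

    All four columns (``ev``, ``eo``, ``er``, ``esi``) must lie in [0, 1];
    any zero component forces EHI = 0.
    """
    comp = components[["ev", "eo", "er", "esi"]].to_numpy(dtype=float)
    if np.any((comp < 0) | (comp > 1)):
        raise ValueError("EHI components must lie in [0, 1]")
    out = components.copy()
    out["ehi"] = np.prod(comp, axis=1) ** 0.25
    return out


def classify_levels(values: pd.Series | np.ndarray, scheme: str = "equal_interval",
                    k: int = 5, labels: list[str] | None = None,
                    bounds: tuple[float, float] = (0.0, 1.0)):
    """Grade an index layer into k ordered levels and report area shares.

    ``equal_interval`` splits ``bounds`` (default [0, 1], the natural range
    of the indices here) into k equal bins; ``quantile`` uses data
    quantiles. Returns (labels per unit, {level: share in percent}).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    arr = np.asarray(values, dtype=float)
    labels = labels or (LEVEL_LABELS if k == 5 else [f"L{i+1}" for i in range(k)])
    if len(labels) != k:
        raise ValueError("need one label per class")
    if scheme == "equal_interval":
        edges = np.linspace(bounds[0], bounds[1], k + 1)
    elif scheme == "quantile":
        edges = np.quantile(arr, np.linspace(0, 1, k + 1))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(np.unique(arr)) < k:
        warnings.warn("fewer distinct values than classes; classification "
                      "is degenerate", stacklevel=2)
    idx = np.clip(np.searchsorted(edges[1:-1], arr, side="right"), 0, k - 1)
    assigned = np.asarray(labels, dtype=object)[idx]
    shares = {lab: 100.0 * float(np.mean(assigned == lab)) for lab in labels}
    if isinstance(values, pd.Series):
        assigned = pd.Series(assigned, index=values.index)
    return assigned, shares
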