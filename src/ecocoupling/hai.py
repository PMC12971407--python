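"""Composite human-activity-intensity index (HAI).

HAI combines three pressure indicators per analysis unit:

* SLUCC — land-use disturbance score, the area-proportion-weighted mean of
  ordinal class weights (construction 10, farmland 7, grassland 3, all
  other classes 0), range [0, 10];
* PD — population density;
* NTL — nighttime-light intensity.

Each indicator is range-normalized (pooled across units and years, matching
the EHI treatment) and the three are summed. The raw sum lives on [0, 3];
it is divided by 3 so that HAI is commensurate with EHI in [0, 1] for the
coupling model. The rescale is monotone and order-preserving, so level
classifications are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vors import classify_levels, minmax  # noqa: F401  (classify_levels re-exported)

__all__ = ["LuccWeights", "slucc", "hai_index", "classify_levels"]


@dataclass
class LuccWeights:
    """Ordinal land-use disturbance weights per class name."""

    weights: dict[str, float] = field(default_factory=lambda: {
        "construction": 10.0, "farmland": 7.0, "grassland": 3.0,
        "forest": 0.0, "water": 0.0, "desert": 0.0,
    })

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("disturbance weights must be non-negative")


def slucc(class_proportions: pd.DataFrame,
          weights: LuccWeights | None = None) -> pd.DataFrame:
    """Per-unit land-use disturbance score on [0, 10].

    ``class_proportions`` columns: ``unit_id`` (plus optional lattice/year
    columns) and one within-unit proportion column per class name.
    """
    weights = weights or LuccWeights()
    cls_cols = [c for c in class_proportions.columns
                if c not in ("unit_id", "block_row", "block_col", "year")]
    unknown = [c for c in cls_cols if c not in weights.weights]
    if unknown:
        raise KeyError(f"no disturbance weight for class(es) {unknown}")
    score = np.zeros(len(class_proportions))
    for cls in cls_cols:
        score += class_proportions[cls].to_numpy() * weights.weights[cls]
    out = class_proportions[[c for c in ("unit_id", "block_row", "block_col", "year")
                             if c in class_proportions.columns]].copy()
    out["slucc_raw"] = score
    return out


def hai_index(components: pd.DataFrame, slucc_col: str = "slucc_raw",
              pd_col: str = "pop_density", ntl_col: str = "ntl") -> pd.DataFrame:
    """HAI per unit: range-normalize SLUCC, PD and NTL, sum, divide by 3.

    Normalization pools all rows passed in (units x years). A component
    constant across all units normalizes to 0.5 with a warning.
    """
    out = components.copy()
    out["slucc_n"] = minmax(out[slucc_col], allow_degenerate=True)
    out["pd_n"] = minmax(out[pd_col], allow_degenerate=True)
    out["ntl_n"] = minmax(out[ntl_col], allow_degenerate=True)
    out["hai"] = (out["slucc_n"] + out["pd_n"] + out["ntl_n"]) / 3.0
    return out
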