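"""Coupling coordination degree and four-quadrant zoning of EHI vs HAI.

The coupling degree C = 2 sqrt(ab) / (a + b) measures how balanced the two
subsystem indices are (1 iff equal and positive); the coordination index T
mixes their levels with weights alpha + beta = 1; the coupling coordination
degree D = sqrt(C * T) is graded into five bands from severe dissonance
[0, 0.2) to high coordination [0.8, 1].

T defaults to the additive convention alpha*EHI + beta*HAI. The literal
product form alpha*EHI * beta*HAI is also available (mode="multiplicative")
for comparison; with alpha = beta = 0.5 it caps T at 0.25*EHI*HAI, which is
incompatible with coordination degrees above 0.8, so it is not the default.

The four-quadrant model z-scores both indices and splits space at the
standardized means: quadrant I (high EHI, high HAI) coordinated
development, II (low, high) ecological management, III (low, low) risk
prevention, IV (high, low) potential conservation. Values exactly at a
threshold count as high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "coupling_degree",
    "coordination_index",
    "ccd",
    "classify_ccd",
    "CCD_LEVELS",
    "QUADRANT_MEANINGS",
    "quadrant_assign",
    "zone_summary",
]

CCD_LEVELS = ["severe dissonance", "mild dissonance", "near-dissonance",
              "mild coordination", "high coordination"]

QUADRANT_MEANINGS = {
    "I": "coordinated development",
    "II": "ecological management",
    "III": "risk prevention",
    "IV": "potential conservation",
}


def coupling_degree(ehi, hai):
    """C = 2 sqrt(EHI*HAI) / (EHI + HAI); defined as 0 when both are 0."""
    a = np.asarray(ehi, dtype=float)
    b = np.asarray(hai, dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("coupling inputs must lie in [0, 1]")
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(s > 0, 2.0 * np.sqrt(a * b) / np.where(s == 0, 1, s), 0.0)
    return c if c.ndim else float(c)


def coordination_index(ehi, hai, alpha: float = 0.5, beta: float = 0.5,
                       mode: str = "additive"):
    """Coordination index T of the two subsystem levels.

    additive (default): T = alpha*EHI + beta*HAI.
    multiplicative: T = (alpha*EHI) * (beta*HAI), the literal product form.
    """
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha + beta must equal 1")
    a = np.asarray(ehi, dtype=float)
    b = np.asarray(hai, dtype=float)
    if mode == "additive":
        t = alpha * a + beta * b
    elif mode == "multiplicative":
        t = (alpha * a) * (beta * b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return t if t.ndim else float(t)


def ccd(c, t):
    """Coupling coordination degree D = sqrt(C * T)."""
    d = np.sqrt(np.asarray(c, dtype=float) * np.asarray(t, dtype=float))
    return d if d.ndim else float(d)


def classify_ccd(d):
    """Five-level grading of D with half-open bands, top band closed at 1.

    [0, 0.2) severe dissonance, [0.2, 0.4) mild dissonance, [0.4, 0.6)
    near-dissonance, [0.6, 0.8) mild coordination, [0.8, 1.0] high
    coordination.
    """
    arr = np.asarray(d, dtype=float)
    idx = np.clip(np.searchsorted([0.2, 0.4, 0.6, 0.8], arr, side="right"), 0, 4)
    if arr.ndim == 0:
        return CCD_LEVELS[int(idx)]
    return np.asarray(CCD_LEVELS, dtype=object)[idx]


def quadrant_assign(ehi, hai, threshold: str = "zscore_zero") -> pd.DataFrame:
    """Assign each unit to one of four quadrants of z-scored (EHI, HAI).

    ``zscore_zero`` (equivalent to ``mean``): both variables standardized,
    split at 0. Quadrant I: ehi_z >= 0 and hai_z >= 0; II: ehi_z < 0,
    hai_z >= 0; III: both < 0; IV: ehi_z >= 0, hai_z < 0. Exactly-at-mean
    values count as high.
    """
    if threshold not in ("zscore_zero", "mean"):
        raise ValueError(f"unknown threshold {threshold!r}")
    a = np.asarray(ehi, dtype=float)
    b = np.asarray(hai, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("quadrant assignment undefined for constant input")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    quad = np.where(az >= 0, np.where(bz >= 0, "I", "IV"),
                    np.where(bz >= 0, "II", "III"))
    return pd.DataFrame({"ehi_z": az, "hai_z": bz, "quadrant": quad})


def zone_summary(quadrants: pd.DataFrame, d: np.ndarray | pd.Series,
                 years: np.ndarray | pd.Series | None = None) -> pd.DataFrame:
    """Per-year quadrant area shares (percent) and mean D per quadrant.

    Returns one row per (year, quadrant) with columns ``share_pct`` and
    ``mean_d``; when several years are present a ``share_change_pct``
    column reports last-minus-first-year share per quadrant.
    """
    df = quadrants.copy()
    df["d"] = np.asarray(d, dtype=float)
    df["year"] = 0 if years is None else np.asarray(years)

    rows = []
    for year, grp in df.groupby("year"):
        n = len(grp)
        for q in ("I", "II", "III", "IV"):
            sel = grp[grp["quadrant"] == q]
            rows.append({
                "year": year, "quadrant": q,
                "share_pct": 100.0 * len(sel) / n,
                "mean_d": float(sel["d"].mean()) if len(sel) else np.nan,
            })
    out = pd.DataFrame(rows)
    yrs = sorted(out["year"].unique())
    first, last = yrs[0], yrs[-1]
    change = (out[out["year"] == last].set_index("quadrant")["share_pct"]
              - out[out["year"] == first].set_index("quadrant")["share_pct"])
    out["share_change_pct"] = out["quadrant"].map(change)
    return out
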