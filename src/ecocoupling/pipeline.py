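"""End-to-end orchestration: layers -> indices -> spatial stats -> coupling -> drivers.

The pipeline runs the analysis stages in their methodological order on one
configuration: (1) per-unit EHI and HAI, with all min-max normalizations
pooled across years; (2) global and bivariate Moran's I plus Gi* hot/cold
spots per year; (3) coupling coordination degrees, five-level grading,
four-quadrant zoning and per-zone summaries; (4) gradient-boosted-tree
driver models with TreeSHAP attribution and dependence thresholds.

Inputs come either from the synthetic-scenario generator (``mode:
synthetic``) or from user-supplied rasters (``mode: rasters``). Every
random draw derives from the global seed plus a stage tag, so each stage
is a pure function of (inputs, config, seed) and a re-run from persisted
intermediates reproduces the monolithic run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import drivers as drv
from . import hai as hai_mod
from . import landmetrics, spatial, vors
from .grid import CategoricalGrid, aggregate_to_units, load_grid, unit_table_to_csv
from .synth import ScenarioConfig, DriverResponse, SyntheticDataset, make_scenario

__all__ = ["PipelineConfig", "run", "assess_units", "report_hash"]

logger = logging.getLogger(__name__)

_SCENARIO_KEYS = set(ScenarioConfig.__dataclass_fields__)


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic"
    scenario: dict = field(default_factory=dict)  # ScenarioConfig overrides
    rasters: dict = field(default_factory=dict)   # year -> {layer: path}
    unit_cells: int = 4
    seed: int = 0
    weights_scheme: str = "queen"
    n_perm: int = 999
    eo_mode: str = "flat"
    connectivity: int = 8
    level_scheme: str = "equal_interval"
    coordination_mode: str = "additive"
    driver_features: list = field(default_factory=lambda: [
        "temperature", "precipitation", "pet", "plant_available_water",
        "rainfall_erosivity", "gdp", "pop_density", "ntl", "elevation",
        "slope"])
    driver_targets: list = field(default_factory=lambda: ["ehi", "hai", "d"])
    param_grid: dict | None = None
    cv_folds: int = 5
    test_fraction: float = 0.3
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mode not in ("synthetic", "rasters"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        bad = set(cfg.scenario) - _SCENARIO_KEYS
        if bad:
            raise ValueError(f"unknown scenario keys: {sorted(bad)}")
        if cfg.mode == "rasters":
            for year, layers in cfg.rasters.items():
                if "landcover" not in layers:
                    raise ValueError(f"raster mode: year {year} lacks a "
                                     "landcover layer")
        if cfg.unit_cells < 1:
            raise ValueError("unit_cells must be >= 1")
        return cfg

    def scenario_config(self) -> ScenarioConfig:
        raw = dict(self.scenario)
        raw.setdefault("seed", _stage_seed(self.seed, "synth"))
        if "driver_spec" in raw:
            raw["driver_spec"] = [
                s if isinstance(s, DriverResponse) else DriverResponse(**s)
                for s in raw["driver_spec"]]
        if "class_proportions" in raw and raw["class_proportions"] is None:
            raw.pop("class_proportions")
        return ScenarioConfig(**raw)

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")
        return d


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# Stage 1: layers -> per-unit index table
# ---------------------------------------------------------------------------

def _unit_class_proportions(cat: CategoricalGrid, unit_cells: int) -> pd.DataFrame:
    """Within-unit land-cover proportions, one column per class name."""
    out = None
    for code, name in cat.legend.items():
        tab = aggregate_to_units(cat, unit_cells, "proportion_of", code=code,
                                 column=name)
        out = tab if out is None else out.merge(
            tab, on=["unit_id", "block_row", "block_col"])
    return out


def _load_layers(config: PipelineConfig) -> SyntheticDataset | dict:
    if config.mode == "synthetic":
        return make_scenario(config.scenario_config())
    layers = {}
    for year, paths in sorted(config.rasters.items()):
        yr = {}
        for name, path in paths.items():
            kind = "categorical" if name == "landcover" else "continuous"
            yr[name] = load_grid(path, kind=kind)
        layers[int(year)] = yr
    return layers


def _year_layer_tables(config: PipelineConfig) -> pd.DataFrame:
    """One row per (unit, year) with every aggregated layer column."""
    uc = config.unit_cells
    data = _load_layers(config)
    frames = []
    if isinstance(data, SyntheticDataset):
        for y in data.years:
            tab = _unit_class_proportions(data.landcover[y], uc)
            met = landmetrics.unit_metrics(data.landcover[y], uc,
                                           connectivity=config.connectivity)
            tab = tab.merge(met.drop(columns=["block_row", "block_col"]),
                            on="unit_id")
            for name, grid in [("npp", data.npp[y]),
                               ("pop_density", data.pop_density[y]),
                               ("ntl", data.ntl[y]), ("gdp", data.gdp[y]),
                               ("elevation", data.elevation),
                               ("slope", data.slope),
                               *data.services[y].items(),
                               *data.drivers[y].items()]:
                agg = aggregate_to_units(grid, uc, "mean", column=name)
                tab = tab.merge(agg.drop(columns=["block_row", "block_col"]),
                                on="unit_id")
            tab["year"] = y
            frames.append(tab)
    else:
        for y, layers in data.items():
            cat = layers["landcover"]
            tab = _unit_class_proportions(cat, uc)
            met = landmetrics.unit_metrics(cat, uc,
                                           connectivity=config.connectivity)
            tab = tab.merge(met.drop(columns=["block_row", "block_col"]),
                            on="unit_id")
            for name, grid in layers.items():
                if name == "landcover":
                    continue
                agg = aggregate_to_units(grid, uc, "mean", column=name)
                tab = tab.merge(agg.drop(columns=["block_row", "block_col"]),
                                on="unit_id")
            tab["year"] = y
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def assess_units(config: PipelineConfig) -> pd.DataFrame:
    """Stage 1: per-(unit, year) table with EV, EO, ER, ESI, EHI and HAI."""
    pooled = _year_layer_tables(config)
    legend_names = ["farmland", "forest", "grassland", "water",
                    "construction", "desert"]
    cls_cols = [c for c in legend_names if c in pooled.columns]

    # EO: pooled normalization of the landscape metrics
    eo = landmetrics.organization_index(
        pooled[["unit_id", "year"] + landmetrics.METRIC_COLUMNS],
        landmetrics.OrganizationWeights(mode=config.eo_mode))
    pooled["eo"] = eo["eo"]

    pooled["ev"] = vors.minmax(pooled["npp"], allow_degenerate=True)

    er = vors.resilience(pooled[["unit_id"] + cls_cols])
    pooled["er"] = er["er"].to_numpy()

    service_cols = [c for c in ("carbon", "food", "quality", "soil",
                                "water_yield") if c in pooled.columns]
    esi = vors.service_index(pooled[["unit_id"] + service_cols],
                             service_cols=service_cols)
    pooled["esi"] = esi["esi"].to_numpy()

    pooled = vors.ehi(pooled)

    sl = hai_mod.slucc(pooled[["unit_id"] + cls_cols])
    pooled["slucc_raw"] = sl["slucc_raw"].to_numpy()
    pooled = hai_mod.hai_index(pooled)
    return pooled


# ---------------------------------------------------------------------------
# Stages 2-4
# ---------------------------------------------------------------------------

def spatial_stage(units: pd.DataFrame, config: PipelineConfig) -> dict:
    """Per-year Moran's I for EHI and HAI, bivariate I, Gi* class counts."""
    out = {}
    seed = _stage_seed(config.seed, "spatial")
    for year, grp in units.groupby("year"):
        w = spatial.build_weights(grp, scheme=config.weights_scheme)
        entry = {}
        for var in ("ehi", "hai"):
            res = spatial.morans_i(grp[var].to_numpy(), w,
                                   n_perm=config.n_perm, seed=seed)
            entry[f"moran_{var}"] = {"I": res.I, "p_one_sided": res.p_one_sided,
                                     "p_two_sided": res.p_two_sided,
                                     "z": res.z_score}
            gi = spatial.getis_ord_gstar(grp[var].to_numpy(), w)
            entry[f"gistar_{var}_counts"] = gi.counts()
        biv = spatial.bivariate_morans_i(grp["hai"].to_numpy(),
                                         grp["ehi"].to_numpy(), w,
                                         n_perm=config.n_perm, seed=seed)
        entry["bivariate_moran_hai_ehi"] = {
            "I": biv.I, "p_one_sided": biv.p_one_sided,
            "p_two_sided": biv.p_two_sided, "z": biv.z_score}
        out[int(year)] = entry
    return out


def coupling_stage(units: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Coupling coordination + quadrants per (unit, year); summary dict."""
    df = units.copy()
    df["c"] = cpl.coupling_degree(df["ehi"], df["hai"])
    df["t"] = cpl.coordination_index(df["ehi"], df["hai"],
                                     mode=config.coordination_mode)
    df["d"] = cpl.ccd(df["c"], df["t"])
    df["ccd_level"] = cpl.classify_ccd(df["d"].to_numpy())

    quad_frames = []
    for year, grp in df.groupby("year"):
        q = cpl.quadrant_assign(grp["ehi"].to_numpy(), grp["hai"].to_numpy())
        q.index = grp.index
        quad_frames.append(q)
    quads = pd.concat(quad_frames).sort_index()
    df[["ehi_z", "hai_z", "quadrant"]] = quads[["ehi_z", "hai_z", "quadrant"]]

    zones = cpl.zone_summary(df[["quadrant"]], df["d"], years=df["year"])
    level_shares = {}
    for year, grp in df.groupby("year"):
        _, shares = vors.classify_levels(grp["d"], scheme=config.level_scheme,
                                         labels=cpl.CCD_LEVELS)
        level_shares[int(year)] = shares
    summary = {
        "zone_summary": zones.to_dict(orient="records"),
        "ccd_level_shares": level_shares,
    }
    return df, summary


def drivers_stage(units: pd.DataFrame, config: PipelineConfig) -> dict:
    """Fit GBT + TreeSHAP per target on the latest year's cross-section."""
    year = units["year"].max()
    cross = units[units["year"] == year].reset_index(drop=True)
    features = [f for f in config.driver_features if f in cross.columns]
    seed = _stage_seed(config.seed, "drivers")
    out = {}
    for target in config.driver_targets:
        dm = drv.assemble_design(cross, features, target,
                                 test_fraction=config.test_fraction, seed=seed)
        model, report = drv.fit_gbt(dm, param_grid=config.param_grid,
                                    cv_folds=config.cv_folds, seed=seed)
        shap = drv.shap_attribution(model, dm.X)
        thresholds = {}
        for feat in features:
            if cross[feat].nunique() < 50:
                continue
            th = drv.dependence_threshold(shap, feat, seed=seed)
            if th.has_threshold:
                thresholds[feat] = {
                    "breakpoint": th.breakpoint, "direction": th.direction,
                    "ci": [th.ci_low, th.ci_high]}
        out[target] = {
            "fit": report.as_dict(),
            "importance_share": shap.importance_share().round(6).to_dict(),
            "thresholds": thresholds,
        }
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def report_hash(report: dict) -> str:
    payload = json.dumps(report, sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


def run(config: PipelineConfig, run_drivers: bool = True) -> dict:
    """Execute the full pipeline and return the machine-readable report."""
    stages = {}
    try:
        units = assess_units(config)
    except Exception as exc:
        raise RuntimeError(f"[assess] {exc}") from exc

    level_shares = {}
    for year, grp in units.groupby("year"):
        shares = {}
        for var in ("ehi", "hai"):
            _, s = vors.classify_levels(grp[var], scheme=config.level_scheme)
            shares[var] = s
        level_shares[int(year)] = shares
    stages["level_shares"] = level_shares

    try:
        stages["spatial"] = spatial_stage(units, config)
    except Exception as exc:
        raise RuntimeError(f"[spatial] {exc}") from exc

    try:
        units, coupling_summary = coupling_stage(units, config)
    except Exception as exc:
        raise RuntimeError(f"[coupling] {exc}") from exc
    stages["coupling"] = coupling_summary

    if run_drivers:
        try:
            stages["drivers"] = drivers_stage(units, config)
        except Exception as exc:
            raise RuntimeError(f"[drivers] {exc}") from exc

    from . import __version__

    report = {
        "software_version": __version__,
        "config": config.canonical(),
        "n_units": int(units.groupby("year")["unit_id"].count().iloc[0]),
        "years": sorted(int(y) for y in units["year"].unique()),
        **stages,
    }
    report["config_hash"] = hashlib.sha256(
        json.dumps(config.canonical(), sort_keys=True, default=str).encode()
    ).hexdigest()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        unit_table_to_csv(units, out / "units.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
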