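"""End-to-end orchestration: layers -> grid -> presence -> hotspots ->
overlap -> peripherality -> protection -> models -> outputs.

Every stage is a pure function of (config, seed); a failed model is logged
and the run continues, but the run is marked errored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import betareg, geoio, gridding, hotspots, peripherality, protection
from .synthetic_data import SyntheticScenario, generate

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Exactly one of ``input_paths`` (a mapping of layer files) or
    ``scenario`` (synthetic generation) must be set."""

    out_dir: str = "riskgrid_out"
    seed: int = 0
    input_paths: dict[str, str] | None = None
    scenario: SyntheticScenario | None = None
    grid: gridding.GridConfig = field(default_factory=gridding.GridConfig)
    models: tuple[str, ...] = betareg.MODEL_IDS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.scenario is None):
            raise ConfigError("exactly one of input_paths / scenario must be given")
        bad = [m for m in self.models if m not in betareg.MODEL_IDS]
        if bad:
            raise ConfigError(f"unknown model ids in config: models -> {bad}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    kwargs: dict[str, Any] = {}
    for key in ("out_dir", "seed", "input_paths", "log_level"):
        if key in doc:
            kwargs[key] = doc[key]
    if "models" in doc:
        kwargs["models"] = tuple(doc["models"])
    if "grid" in doc:
        try:
            kwargs["grid"] = gridding.GridConfig(**doc["grid"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"grid: {exc}") from exc
    if "scenario" in doc:
        try:
            kwargs["scenario"] = SyntheticScenario(**doc["scenario"])
        except TypeError as exc:
            raise ConfigError(f"scenario: {exc}") from exc
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    layers: geoio.StudyLayers
    grid: gridding.RegionGrid
    presence: gridding.PresenceMatrix
    hotspot_sets: dict[str, hotspots.HotspotSet]
    overlap: hotspots.OverlapMatrix
    metrics: pd.DataFrame
    periph_summary: pd.DataFrame
    cell_protection: protection.CellProtectionSummary
    models: dict[str, betareg.ModelResult]
    model_errors: dict[str, str]
    ground_truth: Any = None
    ok: bool = True


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    if config.scenario is not None:
        scenario = replace(config.scenario, seed=config.seed)
        layers, gt = generate(scenario)
    else:
        layers = geoio.load_layers(config.input_paths)
        gt = None

    grid = gridding.build_grid(layers.focal_region, layers.protected_areas, config.grid)
    pm = gridding.presence_matrix(grid, layers.taxa, layers.focal_region)
    logger.info("grid: %d cells; taxa: %d", grid.n_cells, len(layers.taxa))

    national_ids = [t.taxon_id for t in layers.taxa if t.nationally_at_risk]
    global_ids = [t.taxon_id for t in layers.taxa if t.globally_at_risk]
    cap = config.grid.cap_fraction

    sets: dict[str, hotspots.HotspotSet] = {}
    for group in geoio.GROUPS:
        ids = [
            t.taxon_id
            for t in layers.taxa
            if t.group == group and t.nationally_at_risk
        ]
        if not ids:
            continue
        sets[group] = hotspots.select_hotspots(
            pm.richness(ids), cap, cell_ids=pm.cell_ids, label=group
        )
    sets["national_all"] = hotspots.select_hotspots(
        pm.richness(national_ids), cap, cell_ids=pm.cell_ids, label="national_all"
    )
    sets["global_all"] = hotspots.select_hotspots(
        pm.richness(global_ids), cap, cell_ids=pm.cell_ids, label="global_all"
    )
    overlap = hotspots.overlap_matrix(list(sets.values()))

    metrics = peripherality.compute_metrics(layers)
    metrics = protection.add_protection_metrics(metrics, layers)
    nat_metrics = metrics[metrics["national_status"] != "none"]
    periph_summary = peripherality.peripherality_summary(
        metrics, by=None
    ) if nat_metrics.empty else pd.concat(
        [
            peripherality.peripherality_summary(nat_metrics).assign(set="national"),
            peripherality.peripherality_summary(
                metrics[metrics["global_status"] != "none"]
            ).assign(set="global"),
        ],
        ignore_index=True,
    )

    cell_prot = protection.cell_protection_table(
        grid, pm, sets["national_all"], sets["global_all"], national_ids, global_ids
    )

    model_results: dict[str, betareg.ModelResult] = {}
    model_errors: dict[str, str] = {}
    for mid in config.models:
        try:
            model_results[mid] = betareg.run_model(mid, metrics)
        except Exception as exc:  # partial failure: log and continue
            logger.error("model %s failed: %s", mid, exc)
            model_errors[mid] = str(exc)

    result = RunResult(
        layers=layers,
        grid=grid,
        presence=pm,
        hotspot_sets=sets,
        overlap=overlap,
        metrics=metrics,
        periph_summary=periph_summary,
        cell_protection=cell_prot,
        models=model_results,
        model_errors=model_errors,
        ground_truth=gt,
        ok=not model_errors,
    )
    if write:
        geoio.write_outputs(result, config.out_dir, seed=config.seed)
    return result
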