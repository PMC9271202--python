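"""Pipeline configuration and orchestration.

A validated YAML config drives the stages: ``simulate`` (synthetic
landscape + site table), ``rates`` (transition accounting), ``effects``
(mixed-model contrasts) and ``link`` (risk classification).  Each run
writes a manifest recording the config hash, seeds and stage outputs so
deterministic stages are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import synthetic
from .effects import QMCSettings, run_effects
from .io import (
    read_degradation_series,
    read_raster_series,
    read_site_table,
    write_degradation_series,
    write_raster_series,
    write_site_table,
    write_table,
    SCHEMA_VERSION,
)
from .risk import DEFAULT_COMPONENTS, ranked_report, risk_summary
from .transitions import (
    AgePolicy,
    AllocationRatio,
    CONTRAST_TRANSITIONS,
    STANDARD_TRANSITIONS,
    classify_forest_age,
    contrast_rate_table,
    overlay_degradation,
    tabulate_rates,
)

logger = logging.getLogger(__name__)


class PathsConfig(BaseModel):
    rasters: str = "landcover.tif"
    degradation: str = "degradation.tif"
    sites: str = "sites.csv"
    out_dir: str = "results"


class ModelConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    covariates: list[str] = ["clay", "elevation", "slope"]
    reference: str = "UF"
    qmc_n: int = 2**13
    qmc_reps: int = 8
    qmc_tol: float = 2.5e-4


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (see ``PipelineConfig.model_json_schema()``
    for the published schema)."""

    paths: PathsConfig = PathsConfig()
    model: ModelConfig = ModelConfig()
    seed: int = 0
    simulate: bool = True
    grid_shape: tuple[int, int] = (120, 120)
    years: tuple[int, int] = (1985, 2019)
    window: tuple[int, int] = (2006, 2019)
    age_threshold: int = Field(20, ge=1)
    allocation_ratio: tuple[float, float] = (0.985, 0.015)
    fire_on_unlogged: str = "LBF"
    tie_rule: str = "gt"
    log_rates: bool = True
    correlation_method: str = "auto"
    component_map: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_COMPONENTS))

    @model_validator(mode="after")
    def _check(self):
        AllocationRatio(*self.allocation_ratio)  # validates
        if self.window[0] < self.years[0] or self.window[1] > self.years[1]:
            raise ValueError("window must lie within years")
        if self.tie_rule not in ("gt", "ge"):
            raise ValueError("tie_rule must be 'gt' or 'ge'")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _manifest(config: PipelineConfig, stage: str, outputs: dict) -> dict:
    from . import __version__

    return {
        "schema_version": SCHEMA_VERSION,
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "outputs": outputs,
    }


def _write_manifest(config: PipelineConfig, stage: str, outputs: dict, out_dir: Path):
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(_manifest(config, stage, outputs), indent=1, sort_keys=True))
    return path


def stage_simulate(config: PipelineConfig) -> dict:
    out_dir = Path(config.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = synthetic.substreams(config.seed)
    logger.info("stage simulate: grid %s years %s", config.grid_shape, config.years)
    truth = synthetic.default_landcover_truth(
        seed=seeds["landcover"], grid_shape=tuple(config.grid_shape), years=tuple(config.years)
    )
    sim = synthetic.simulate_landcover_series(truth, age_threshold=config.age_threshold)
    write_raster_series(sim.base_series, out_dir / config.paths.rasters)
    write_degradation_series(sim.degradation, out_dir / config.paths.degradation)
    eco = synthetic.default_eco_truth(seed=seeds["eco"])
    sites = synthetic.simulate_ecological_sites(eco)
    write_site_table(sites, out_dir / config.paths.sites)
    outputs = {
        "rasters": config.paths.rasters,
        "degradation": config.paths.degradation,
        "sites": config.paths.sites,
    }
    _write_manifest(config, "simulate", outputs, out_dir)
    return outputs


def stage_rates(config: PipelineConfig) -> pd.DataFrame:
    out_dir = Path(config.paths.out_dir)
    raster_path = out_dir / config.paths.rasters
    if not raster_path.exists():
        raise FileNotFoundError(f"stage rates: missing input raster {raster_path}")
    logger.info("stage rates: window %s", config.window)
    series = read_raster_series(raster_path)
    classified = classify_forest_age(series, AgePolicy(config.age_threshold))
    deg_path = out_dir / config.paths.degradation
    if deg_path.exists():
        classified = overlay_degradation(
            classified, read_degradation_series(deg_path), config.fire_on_unlogged
        )
    rates = tabulate_rates(classified, tuple(config.window), STANDARD_TRANSITIONS)
    write_table(rates, out_dir / "rates.csv", window=list(config.window), stage="rates")
    _write_manifest(config, "rates", {"rates": "rates.csv"}, out_dir)
    return rates


def stage_effects(config: PipelineConfig) -> pd.DataFrame:
    out_dir = Path(config.paths.out_dir)
    sites_path = out_dir / config.paths.sites
    if not sites_path.exists():
        raise FileNotFoundError(f"stage effects: missing input site table {sites_path}")
    sites = read_site_table(sites_path)
    variables = [v for v in config.component_map if v in sites.columns]
    if not variables:
        raise ValueError("stage effects: no modeled variables found in the site table")
    logger.info("stage effects: %d variables", len(variables))
    m = config.model
    effects, meta = run_effects(
        sites,
        variables,
        covariates=tuple(m.covariates),
        alpha=m.alpha,
        reference=m.reference,
        qmc_settings=QMCSettings(n=m.qmc_n, reps=m.qmc_reps, tol=m.qmc_tol),
    )
    write_table(effects, out_dir / "effects.csv", stage="effects")
    (out_dir / "effects_meta.json").write_text(json.dumps(meta, indent=1, default=str))
    _write_manifest(config, "effects", {"effects": "effects.csv"}, out_dir)
    return effects


def stage_link(config: PipelineConfig) -> pd.DataFrame:
    out_dir = Path(config.paths.out_dir)
    rates_path = out_dir / "rates.csv"
    effects_path = out_dir / "effects.csv"
    for p, stage in ((rates_path, "rates"), (effects_path, "effects")):
        if not p.exists():
            raise FileNotFoundError(
                f"stage link: missing input {p} (run the {stage} stage first)"
            )
    rates = pd.read_csv(rates_path)
    effects = pd.read_csv(effects_path)
    rate_series = contrast_rate_table(rates, CONTRAST_TRANSITIONS)
    summary = risk_summary(
        effects,
        rate_series,
        component_map=config.component_map,
        method=config.correlation_method,
        log_rates=config.log_rates,
        tie_rule=config.tie_rule,
    )
    write_table(summary, out_dir / "risk.csv", stage="link")
    (out_dir / "risk_report.txt").write_text(ranked_report(summary) + "\n")
    _write_manifest(config, "link", {"risk": "risk.csv", "report": "risk_report.txt"}, out_dir)
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; any stage failure halts with the stage
    named.  Returns the result bundle (tables keyed by stage)."""
    bundle: dict = {}
    stages = (["simulate"] if config.simulate else []) + ["rates", "effects", "link"]
    for stage in stages:
        fn = {
            "simulate": stage_simulate,
            "rates": stage_rates,
            "effects": stage_effects,
            "link": stage_link,
        }[stage]
        try:
            bundle[stage] = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
        logger.info("stage %s done", stage)
    return bundle
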