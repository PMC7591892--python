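"""Configured, seed-reproducible orchestration of the full analysis.

Stage order: simulate (optional) -> validate -> age QC (optional) ->
back-calculation (species and species-by-location) -> growth modelling
(hierarchical on back-calculated data, raw on capture data, curve
comparison).  A failure in one group halts downstream work for that group
only; the JSON manifest is written even on partial failure and is identical
across runs with the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .age_qc import qc_table, read_pairs_csv
from .backcalc import (
    ConvergenceError,
    ProportionalityPriors,
    run_backcalculation,
)
from .data_model import (
    read_growth_csv,
    report_as_tsv,
    validate_dataset,
    write_growth_csv,
)
from .growth import (
    VBPriors,
    compare_growth_curves,
    convergence_protocol,
    filter_for_hierarchical_fit,
    fit_vb_raw,
)
from .mcmc import MCMCSettings
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger("otogrow.pipeline")


class StageToggles(BaseModel):
    simulate: bool = False
    validate_data: bool = True
    qc: bool = False
    backcalc: bool = True
    growth: bool = True
    compare: bool = True


class FilterConfig(BaseModel):
    """Eligibility thresholds; defaults are the published protocol."""

    min_known_r0p: int = 2
    excluded_capture_ages: list[int] = Field(default_factory=lambda: [0, 1])
    min_individuals_hierarchical: int = 5
    min_age_cpt_hierarchical_exclusive: int = 2
    min_individuals_raw_exclusive: int = 10
    cv_threshold_percent: float = 5.0


class MCMCConfig(BaseModel):
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    rhat_threshold: float = 1.01
    seed: int = 20201027

    def settings(self) -> MCMCSettings:
        return MCMCSettings(
            chains=self.chains, iterations=self.iterations, warmup=self.warmup,
            rhat_threshold=self.rhat_threshold, seed=self.seed,
        )


class SpeciesPriorConfig(BaseModel):
    linf_mean: float = 400.0
    linf_sd: float = 100.0
    k_mean: float = 0.5
    k_sd: float = 0.25
    t0_mean: float = 0.0
    t0_sd: float = 1.0

    def vb_priors(self) -> VBPriors:
        return VBPriors(
            linf_mean=self.linf_mean, linf_sd=self.linf_sd,
            k_mean=self.k_mean, k_sd=self.k_sd,
            t0_mean=self.t0_mean, t0_sd=self.t0_sd,
        )


class PriorConfig(BaseModel):
    b_mean: float = 200.0
    b_sd: float = 200.0
    c_mean: float = 1.0
    c_sd: float = 1.0
    sigma_scale: float = 50.0
    vb_default: SpeciesPriorConfig = Field(default_factory=SpeciesPriorConfig)
    vb_by_species: dict[str, SpeciesPriorConfig] = Field(default_factory=dict)

    def proportionality(self) -> ProportionalityPriors:
        return ProportionalityPriors(
            b_mean=self.b_mean, b_sd=self.b_sd, c_mean=self.c_mean,
            c_sd=self.c_sd, sigma_scale=self.sigma_scale,
        )

    def vb_for(self, species_key: str) -> VBPriors:
        cfg = self.vb_by_species.get(species_key, self.vb_default)
        return cfg.vb_priors()


class PipelineConfig(BaseModel):
    stages: StageToggles = Field(default_factory=StageToggles)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    priors: PriorConfig = Field(default_factory=PriorConfig)
    mcmc: MCMCConfig = Field(default_factory=MCMCConfig)
    simulation: Optional[SimulationConfig] = None
    input_csv: Optional[str] = None
    reads_csv: Optional[str] = None
    output_dir: str = "otogrow_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    if not logger.handlers:
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.mcmc.seed,
        "stages": {},
    }
    settings = cfg.mcmc.settings()
    ok = True

    # ------------------------------------------------------------------ data
    if cfg.stages.simulate:
        sim_cfg = cfg.simulation or SimulationConfig(seed=cfg.mcmc.seed)
        ds, truth = simulate_dataset(sim_cfg)
        write_growth_csv(ds, out_dir / "simulated.csv")
        truth.frame().to_csv(out_dir / "simulated_truth.csv", index=False)
        manifest["stages"]["simulate"] = {
            "status": "ok",
            "n_individuals": ds.n_individuals,
            "n_increments": ds.n_increments,
        }
        logger.info("simulate: %d individuals", ds.n_individuals)
    elif cfg.input_csv:
        ds = read_growth_csv(cfg.input_csv)
        manifest["stages"]["load"] = {
            "status": "ok",
            "n_individuals": ds.n_individuals,
            "n_increments": ds.n_increments,
        }
    else:
        raise ValueError("config must enable the simulate stage or set input_csv")

    # -------------------------------------------------------------- validate
    if cfg.stages.validate_data:
        violations = validate_dataset(ds)
        (out_dir / "validation.tsv").write_text(report_as_tsv(violations))
        manifest["stages"]["validate"] = {
            "status": "ok" if not violations else "violations",
            "n_violations": len(violations),
        }
        logger.info("validate: %d violations", len(violations))
        if violations:
            ok = False

    # -------------------------------------------------------------------- qc
    if cfg.stages.qc and cfg.reads_csv:
        pairs = read_pairs_csv(cfg.reads_csv)
        table = qc_table(pairs, cfg.filters.cv_threshold_percent)
        table.to_csv(out_dir / "age_qc.csv", index=False)
        manifest["stages"]["qc"] = {
            "status": "ok",
            "n_pairs": len(table),
            "n_flagged": int(table["reread"].sum()),
        }

    # -------------------------------------------------------------- backcalc
    posteriors_by_species = {}
    annotated = ds
    if cfg.stages.backcalc:
        bc_stage: dict = {}
        for grouping in ("species", "species_by_location"):
            annotated, report, posts = run_backcalculation(
                annotated, grouping,
                cfg.priors.proportionality(), settings,
            )
            if grouping == "species":
                posteriors_by_species = posts
            bc_stage[grouping] = report.as_dict()
            logger.info(
                "backcalc %s: %d groups fitted, %d dropped",
                grouping, len(report.fitted_groups), len(report.dropped_groups),
            )
        write_growth_csv(annotated, out_dir / "backcalculated.csv")
        manifest["stages"]["backcalc"] = {"status": "ok", **bc_stage}

    # ---------------------------------------------------------------- growth
    if cfg.stages.growth and cfg.stages.backcalc:
        growth_stage: dict = {}
        key = (
            annotated.individuals["Genus"].astype(str)
            + " "
            + annotated.individuals["Species"].astype(str)
        )
        for species_key in sorted(key.unique()):
            entry: dict = {}
            ids = annotated.individuals.index[key == species_key]
            sub_inc = annotated.increments[annotated.increments["ID"].isin(ids)]
            est = sub_inc.rename(
                columns={"Li_sp_m": "length_mean", "Li_sp_sd": "length_sd"}
            )[["ID", "Age_i", "length_mean", "length_sd"]].dropna(
                subset=["length_mean"]
            )
            data = filter_for_hierarchical_fit(
                est, annotated.individuals.loc[ids],
                min_individuals=cfg.filters.min_individuals_hierarchical,
                min_age_cpt_exclusive=cfg.filters.min_age_cpt_hierarchical_exclusive,
            )
            vb_priors = cfg.priors.vb_for(species_key)
            post_bc = post_raw = None
            if data.empty:
                entry["hierarchical"] = {"status": "skipped", "reason": "filters"}
            else:
                try:
                    post_bc, actions = convergence_protocol(
                        data, vb_priors, settings, group_label=species_key,
                    )
                    entry["hierarchical"] = {
                        "status": "ok",
                        "actions": [a.__dict__ for a in actions],
                        "summary": post_bc.summary().to_dict("records"),
                    }
                except ConvergenceError as err:
                    ok = False
                    entry["hierarchical"] = {"status": "error", "reason": str(err)}
            n_raw = len(ids)
            if n_raw > cfg.filters.min_individuals_raw_exclusive:
                try:
                    post_raw = fit_vb_raw(
                        annotated.individuals.loc[ids], vb_priors, settings,
                        group_label=species_key,
                        min_individuals_exclusive=cfg.filters.min_individuals_raw_exclusive,
                    )
                    entry["raw"] = {
                        "status": "ok",
                        "summary": post_raw.summary().to_dict("records"),
                    }
                except ConvergenceError as err:  # pragma: no cover - rare
                    ok = False
                    entry["raw"] = {"status": "error", "reason": str(err)}
            else:
                entry["raw"] = {"status": "skipped", "reason": "n_too_small"}
            if cfg.stages.compare and post_bc is not None and post_raw is not None:
                max_age = int(annotated.individuals.loc[ids, "Age_cpt"].max())
                ages = np.arange(1, max_age + 1)
                comp = compare_growth_curves(post_bc, post_raw, ages)
                entry["compare"] = {
                    "status": "ok",
                    "all_overlap": comp.all_overlap,
                    "bc_below_raw": comp.bc_below_raw,
                }
                comp.frame().to_csv(
                    out_dir / f"compare_{species_key.replace(' ', '_')}.csv",
                    index=False,
                )
            growth_stage[species_key] = entry
            logger.info("growth %s: %s", species_key,
                        entry.get("hierarchical", {}).get("status"))
        manifest["stages"]["growth"] = {"status": "ok", "groups": growth_stage}

    manifest["status"] = "ok" if ok else "partial"
    manifest = _round_floats(manifest)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
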