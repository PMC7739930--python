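"""End-to-end orchestration: simulate -> allocate -> popularity -> traits -> fit -> report.

Each stage reads and writes plain CSV/JSON under one output directory,
so stages can be re-run individually from cached intermediates. A run
manifest records the config hash, seeds, input digests, per-stage
timings and output paths; re-running with the same manifest inputs
reproduces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from conservebias import countmodel, funding, popcal, synthio, traits as traits_mod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "allocate", "popularity", "traits", "fit", "report")


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    synth: synthio.SynthConfig = Field(default_factory=synthio.SynthConfig)
    batch_size: int = 5
    r2_threshold: float = 0.95
    trends_noise_sdlog: float = 0.0
    skew_threshold: float = 1.0
    collinearity_threshold: float = 0.7
    top_k: int = 30
    #: class labels counted as vertebrates in the bias metrics; all
    #: other classes count as invertebrates
    vertebrate_classes: list[str] = Field(default_factory=lambda: ["class_0", "class_1"])
    #: known species richness per group; empty -> use generated counts
    richness: dict[str, int] = Field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list[str]
    timings: dict[str, float]
    outputs: dict[str, str]
    digests: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: pathlib.Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def stage_simulate(config: PipelineConfig, outdir: pathlib.Path) -> synthio.SyntheticData:
    data = synthio.generate_dataset(config.synth)
    synthio.write_dataset(data, outdir)
    return data


def stage_allocate(outdir: pathlib.Path) -> pd.DataFrame:
    projects_path = outdir / "projects.csv"
    if not projects_path.exists():
        raise FileNotFoundError(f"missing input: {projects_path}")
    projects = funding.projects_from_frame(pd.read_csv(projects_path))
    allocs = funding.allocate_budget(projects)
    allocs.to_csv(outdir / "allocations.csv", index=False)
    return allocs


def stage_popularity(
    config: PipelineConfig, outdir: pathlib.Path, data: synthio.SyntheticData | None
) -> pd.DataFrame:
    """Calibrate popularity via anchor chaining over simulated batch queries.

    Species are queried in descending order of latent interest so
    adjacent batches are close in magnitude, which keeps the anchor's
    reported values away from the integer-rounding floor.
    """
    if data is None:
        raise FileNotFoundError("popularity stage needs simulated latent series (run simulate)")
    order = sorted(data.latent, key=lambda sp: -data.latent[sp].true_mean)
    counter = {"i": 0}

    def query(batch_species):
        counter["i"] += 1
        resp = synthio.simulate_trends_api(
            data.latent,
            batch_species,
            seed=config.synth.seed * 100003 + counter["i"],
            noise_sdlog=config.trends_noise_sdlog,
        )
        return {s.species: s.values for s in resp}

    calibrated, factors = popcal.calibrate(
        query, order, config.batch_size, config.r2_threshold
    )
    pop = popcal.popularity_frame(calibrated, factors)
    pop.to_csv(outdir / "popularity.csv", index=False)
    return pop


def stage_traits(config: PipelineConfig, outdir: pathlib.Path) -> pd.DataFrame:
    species = pd.read_csv(outdir / "species.csv")
    pop = pd.read_csv(outdir / "popularity.csv")
    allocs = pd.read_csv(outdir / "allocations.csv")
    table = traits_mod.build_analysis_table(species, pop, allocs)

    report = traits_mod.decide_transforms(
        table, ("popularity", "body_size"), config.skew_threshold
    )
    table = traits_mod.apply_transforms(table, report)
    # guarantee the model's predictor columns regardless of the skew decision
    for col, offset in (("popularity", 1.0), ("body_size", 0.0)):
        if f"log_{col}" not in table.columns:
            table[f"log_{col}"] = np.log10(table[col].to_numpy(float) + offset)

    predictors = ["log_popularity", "log_body_size", "n_projects", "total_budget"]
    screen = traits_mod.collinearity_screen(
        table, predictors, config.collinearity_threshold
    )
    _write_json(
        {
            "transforms": report.transforms,
            "skewness": report.skewness,
            "flagged_pairs": [list(p) for p in screen.flagged_pairs],
            "dropped": screen.dropped,
            "zero_variance": screen.zero_variance,
            "notes": screen.notes,
        },
        outdir / "exploration_report.json",
    )
    table.to_csv(outdir / "analysis_table.csv", index=False)
    return table


def stage_fit(outdir: pathlib.Path) -> countmodel.FamilySelection:
    table = pd.read_csv(outdir / "analysis_table.csv")
    sel = countmodel.select_family(table, countmodel.ModelSpec())
    fit = sel.final
    _write_json(
        {
            "family": fit.family,
            "fixed": [dataclasses.asdict(fe) for fe in fit.fixed],
            "random_sd": fit.random_sd,
            "theta": fit.theta,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "dispersion": dataclasses.asdict(sel.dispersion),
            "switched_to_nb": sel.switched,
            "diagnostics": fit.diagnostics,
        },
        outdir / "fit.json",
    )
    countmodel.significance_table(fit).to_csv(outdir / "fit_table.csv", index=False)
    return sel


def report_breakdowns(
    allocs: pd.DataFrame,
    table: pd.DataFrame,
    vertebrate_classes: list[str],
    richness: Mapping[str, int] | None = None,
    top_k: int = 30,
) -> dict:
    """Summary surfaces: group shares, top-k species, IUCN breakdown, r.

    All numbers are views over the funding/traits module outputs (class
    and vertebrate/invertebrate summaries via ``summarize_groups``,
    ratios via ``bias_metrics``, the budget-projects correlation via
    ``attention_correlation``); nothing is recomputed independently.
    """
    class_of = dict(zip(table["species"], table["class"]))
    group_of = {
        sp: ("vertebrate" if cls in vertebrate_classes else "invertebrate")
        for sp, cls in class_of.items()
    }
    by_class = funding.summarize_groups(allocs, class_of)
    by_group = funding.summarize_groups(allocs, group_of)

    metrics = None
    if {"vertebrate", "invertebrate"} <= set(by_group["group"]):
        if not richness:
            counts = table.assign(g=[group_of[sp] for sp in table["species"]])
            richness = counts.groupby("g")["species"].nunique().to_dict()
        metrics = funding.bias_metrics(by_group, richness)

    top_budget = allocs.nlargest(min(top_k, len(allocs)), "total_budget")
    top_projects = allocs.nlargest(min(top_k, len(allocs)), "n_projects")
    iucn_counts = (
        table.groupby("iucn")["n_projects"].sum().sort_values(ascending=False).to_dict()
    )
    return {
        "by_class": by_class.to_dict(orient="records"),
        "by_group": by_group.to_dict(orient="records"),
        "bias_metrics": metrics,
        "top_species_by_budget": top_budget.to_dict(orient="records"),
        "top_species_by_projects": top_projects.to_dict(orient="records"),
        "iucn_project_counts": iucn_counts,
        "budget_projects_correlation": funding.attention_correlation(allocs),
    }


def stage_report(config: PipelineConfig, outdir: pathlib.Path) -> dict:
    allocs = pd.read_csv(outdir / "allocations.csv")
    table = pd.read_csv(outdir / "analysis_table.csv")
    report = report_breakdowns(
        allocs, table, config.vertebrate_classes, config.richness or None, config.top_k
    )
    _write_json(report, outdir / "report.json")
    return report


def run_pipeline(
    config: PipelineConfig,
    outdir,
    simulate: bool = True,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full pipeline; each stage's failure halts the run.

    Partial outputs from completed stages are preserved on failure, and
    the failing stage is named in the raised error.
    """
    from conservebias import __version__

    if seed is not None:
        config = config.model_copy(update={"synth": config.synth.model_copy(update={"seed": seed})})
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_json = config.model_dump_json()
    config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    timings: dict[str, float] = {}
    data: synthio.SyntheticData | None = None
    stages_run: list[str] = []

    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                if not simulate:
                    for fname in ("projects.csv", "species.csv"):
                        if not (outdir / fname).exists():
                            raise FileNotFoundError(
                                f"missing input {outdir / fname} and --simulate not set"
                            )
                    continue
                data = stage_simulate(config, outdir)
            elif stage == "allocate":
                stage_allocate(outdir)
            elif stage == "popularity":
                stage_popularity(config, outdir, data)
            elif stage == "traits":
                stage_traits(config, outdir)
            elif stage == "fit":
                stage_fit(outdir)
            elif stage == "report":
                stage_report(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        stages_run.append(stage)
        logger.info("stage %-10s done in %.2fs (seed=%d, config=%s)",
                    stage, timings[stage], config.synth.seed, config_hash)

    outputs = {
        p.name: str(p)
        for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    digests = {name: _digest(pathlib.Path(path)) for name, path in outputs.items()}
    manifest = RunManifest(
        config_hash=config_hash,
        seed=config.synth.seed,
        package_version=__version__,
        stages=stages_run,
        timings=timings,
        outputs=outputs,
        digests=digests,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
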