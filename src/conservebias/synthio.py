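"""Synthetic generator for the funding-bias analysis.

Emulates the three data sources of the analysis — a funded-projects
database, a species trait table, and a Trends-style relative
search-volume API — from a single generative model with known ground
truth:

* a nested taxonomy (classes > orders > families > species);
* latent per-species online interest (log-normal), correlated with log
  body size;
* per-species project counts drawn from a negative-binomial mixed model
  with log link: ``log mu = X beta + b_class + b_order + b_family``;
* log-normal project budgets, with a configurable fraction of projects
  targeting several species;
* a search-volume simulator that max-normalizes each query batch to the
  0-100 integer scale, exactly as the real API reports it.

Because every downstream stage (budget allocation, popularity
calibration, mixed-model fitting) consumes only the emitted tables, the
generator provides ground truth for end-to-end validation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

IUCN_CATEGORIES = ("EX", "CR", "EN", "VU", "NT", "LC", "DD")

#: default IUCN category mix: mostly LC/NT with a threatened tail,
#: loosely matching a European protected-species pool
DEFAULT_IUCN_PROBS = {
    "EX": 0.005,
    "CR": 0.06,
    "EN": 0.14,
    "VU": 0.18,
    "NT": 0.15,
    "LC": 0.44,
    "DD": 0.025,
}


class SynthConfig(BaseModel):
    """Configuration of the synthetic generative model.

    ``beta`` holds the true fixed effects on the log scale of the
    expected project count: ``(intercept, log10-popularity slope,
    log10-bodysize slope, *iucn_offsets)`` where the IUCN offsets follow
    the order of non-reference categories present (reference LC).
    """

    n_species: int = 488
    n_classes: int = 4
    n_orders_per_class: int = 3
    n_families_per_order: int = 3

    intercept: float = -0.5
    beta_pop: float = 0.19
    beta_size: float = 0.0
    iucn_offsets: dict[str, float] = Field(default_factory=dict)

    sigma_class: float = 0.5
    sigma_order: float = 0.3
    sigma_family: float = 0.3
    theta: float = 1.0

    budget_meanlog: float = 13.9
    budget_sdlog: float = 0.8

    pop_meanlog: float = 2.5
    pop_sdlog: float = 1.5
    size_meanlog: float = 5.0
    size_sdlog: float = 1.2
    rho_pop_size: float = 0.6

    iucn_probs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_IUCN_PROBS))

    months: int = 120
    month_sdlog: float = 0.25

    multi_species_fraction: float = 0.3
    max_species_per_project: int = 5
    cotarget_weight_exponent: float = 1.0

    year_range: tuple[int, int] = (1992, 2018)
    biodiversity_theme_fraction: float = 0.02

    seed: int = 0

    @field_validator(
        "n_species", "n_classes", "n_orders_per_class", "n_families_per_order", "months"
    )
    @classmethod
    def _positive_count(cls, v: int) -> int:
        if v < 1:
            raise ValueError("counts must be >= 1")
        return v

    @field_validator("theta")
    @classmethod
    def _theta_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("theta must be > 0")
        return v

    @field_validator(
        "sigma_class", "sigma_order", "sigma_family", "budget_sdlog",
        "pop_sdlog", "size_sdlog", "month_sdlog",
    )
    @classmethod
    def _sd_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("standard deviations must be >= 0")
        return v

    @field_validator("rho_pop_size")
    @classmethod
    def _rho_bounded(cls, v: float) -> float:
        if abs(v) > 1:
            raise ValueError("|rho_pop_size| must be <= 1")
        return v

    @model_validator(mode="after")
    def _check_iucn_probs(self) -> "SynthConfig":
        unknown = set(self.iucn_probs) - set(IUCN_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown IUCN categories in iucn_probs: {sorted(unknown)}")
        total = sum(self.iucn_probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"iucn_probs must sum to 1 (got {total!r})")
        return self


@dataclasses.dataclass
class LatentPopularity:
    """A species' latent monthly search interest in arbitrary common units."""

    species: str
    monthly_interest: np.ndarray
    true_mean: float

    def __post_init__(self) -> None:
        self.monthly_interest = np.asarray(self.monthly_interest, dtype=float)
        if np.any(self.monthly_interest < 0):
            raise ValueError("monthly interest must be nonnegative")
        if not np.isclose(self.true_mean, float(self.monthly_interest.mean())):
            raise ValueError("true_mean must equal the mean of monthly_interest")


@dataclasses.dataclass
class SearchSeries:
    """One species' 0-100 integer monthly series within a query batch."""

    species: str
    batch: str
    values: np.ndarray
    all_zero: bool = False


@dataclasses.dataclass
class SyntheticData:
    """Bundle of generated tables plus ground truth."""

    taxonomy: pd.DataFrame
    traits: pd.DataFrame
    projects: pd.DataFrame
    latent: dict[str, LatentPopularity]
    random_effects: dict[str, dict[str, float]]
    config: SynthConfig


def generate_taxonomy(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign each species to one family, nested in orders and classes.

    Species are distributed round-robin over the full set of
    ``n_classes * n_orders_per_class * n_families_per_order`` families so
    group sizes stay balanced; labels encode the nesting path.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    paths = []
    for c in range(config.n_classes):
        for o in range(config.n_orders_per_class):
            for f in range(config.n_families_per_order):
                paths.append((f"class_{c}", f"order_{c}_{o}", f"family_{c}_{o}_{f}"))
    rows = []
    for i in range(config.n_species):
        cls, order, family = paths[i % len(paths)]
        rows.append({"species": f"sp_{i:04d}", "class": cls, "order": order, "family": family})
    return pd.DataFrame(rows)


def generate_species_traits(
    taxonomy: pd.DataFrame, config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, LatentPopularity]]:
    """Draw latent popularity, body size and IUCN category per species.

    (log popularity, log body size) are bivariate normal with correlation
    ``rho_pop_size``; IUCN categories are multinomial draws independent of
    the continuous traits. Returns the trait table and the latent monthly
    interest series backing the search-volume simulator.
    """
    if taxonomy.empty:
        raise ValueError("taxonomy is empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(taxonomy)

    # explicit Cholesky construction; robust to sd = 0 and |rho| = 1
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = config.rho_pop_size
    log_pop = config.pop_meanlog + config.pop_sdlog * z1
    log_size = config.size_meanlog + config.size_sdlog * (
        rho * z1 + np.sqrt(1.0 - rho**2) * z2
    )
    pop_mean = np.exp(log_pop)
    body_size = np.exp(log_size)

    cats = list(config.iucn_probs)
    probs = np.array([config.iucn_probs[c] for c in cats])
    iucn = rng.choice(cats, size=n, p=probs)

    latent: dict[str, LatentPopularity] = {}
    monthly_means = np.empty(n)
    for i, sp in enumerate(taxonomy["species"]):
        if config.month_sdlog > 0:
            monthly = pop_mean[i] * np.exp(
                rng.normal(-0.5 * config.month_sdlog**2, config.month_sdlog, config.months)
            )
        else:
            monthly = np.full(config.months, pop_mean[i])
        latent[sp] = LatentPopularity(sp, monthly, float(monthly.mean()))
        monthly_means[i] = latent[sp].true_mean

    traits = taxonomy.copy()
    traits["iucn"] = iucn
    traits["body_size"] = body_size
    traits["true_popularity"] = monthly_means
    return traits, latent


def _linear_predictor(
    traits: pd.DataFrame, config: SynthConfig, re: dict[str, dict[str, float]]
) -> np.ndarray:
    eta = (
        config.intercept
        + config.beta_pop * np.log10(traits["true_popularity"].to_numpy() + 1.0)
        + config.beta_size * np.log10(traits["body_size"].to_numpy())
    )
    offsets = np.array([config.iucn_offsets.get(c, 0.0) for c in traits["iucn"]])
    eta = eta + offsets
    for level, col in (("class", "class"), ("order", "order"), ("family", "family")):
        eta = eta + np.array([re[level][g] for g in traits[col]])
    return eta


def generate_projects(
    traits: pd.DataFrame, config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Draw funded projects from the negative-binomial mixed model.

    Each species' primary project count is NB2(mu, theta) with
    ``log mu`` the true linear predictor plus sampled class/order/family
    intercepts. A fraction of projects then co-targets up to
    ``max_species_per_project - 1`` additional species sampled with
    popularity-proportional weights, and budgets are log-normal.

    Returns the project table and the sampled random intercepts.
    """
    required = {"species", "class", "order", "family", "iucn", "body_size", "true_popularity"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")
    if traits[list(required)].isna().any().any():
        raise ValueError("traits table has missing predictor values")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng

    re: dict[str, dict[str, float]] = {}
    for level, col, sd in (
        ("class", "class", config.sigma_class),
        ("order", "order", config.sigma_order),
        ("family", "family", config.sigma_family),
    ):
        groups = traits[col].unique()
        re[level] = {g: (rng.normal(0.0, sd) if sd > 0 else 0.0) for g in groups}

    mu = np.exp(_linear_predictor(traits, config, re))
    theta = config.theta
    if theta > 1e8:  # Poisson limit; NB sampling is numerically unstable there
        counts = rng.poisson(mu)
    else:
        # NB2 via gamma-Poisson mixture
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam)

    species = traits["species"].to_numpy()
    weights = (traits["true_popularity"].to_numpy() + 1e-12) ** config.cotarget_weight_exponent
    weights = weights / weights.sum()

    rows = []
    pid = 0
    lo, hi = config.year_range
    for i, sp in enumerate(species):
        for _ in range(int(counts[i])):
            targets = [sp]
            if config.multi_species_fraction > 0 and rng.random() < config.multi_species_fraction:
                n_extra = rng.integers(1, config.max_species_per_project)
                pool = np.delete(np.arange(len(species)), i)
                w = weights[pool] / weights[pool].sum()
                extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False, p=w)
                targets.extend(species[j] for j in extra)
            if config.budget_sdlog > 0:
                budget = float(np.exp(rng.normal(config.budget_meanlog, config.budget_sdlog)))
            else:
                budget = float(np.exp(config.budget_meanlog))
            theme = (
                "BiodiversityIssues"
                if rng.random() < config.biodiversity_theme_fraction
                else "Species"
            )
            rows.append(
                {
                    "project_id": f"LIFE{pid:05d}",
                    "year": int(rng.integers(lo, hi + 1)),
                    "theme": theme,
                    "budget": budget,
                    "species": ";".join(targets),
                }
            )
            pid += 1
    projects = pd.DataFrame(
        rows, columns=["project_id", "year", "theme", "budget", "species"]
    )
    return projects, re


def simulate_trends_api(
    latent: dict[str, LatentPopularity],
    batch: Sequence[str],
    seed: int | None = None,
    noise_sdlog: float = 0.0,
    round_values: bool = True,
) -> list[SearchSeries]:
    """Report a query batch on the API's relative 0-100 scale.

    Optional multiplicative log-normal noise is applied per (species,
    month); every value is then divided by the batch-wide maximum over
    all species and months, multiplied by 100 and rounded to the nearest
    integer (half to even), so the batch maximum reports as 100. A batch
    whose latent values are all zero reports all zeros with the
    ``all_zero`` flag set rather than raising.

    ``round_values=False`` gives the continuous (rounding-free) variant
    used to isolate quantization error in calibration studies.
    """
    if len(batch) < 1:
        raise ValueError("batch must contain at least one species")
    missing = [sp for sp in batch if sp not in latent]
    if missing:
        raise KeyError(f"no latent series for species: {missing}")
    rng = np.random.default_rng(seed)

    raw = {}
    for sp in batch:
        vals = latent[sp].monthly_interest.astype(float)
        if noise_sdlog > 0:
            vals = vals * np.exp(rng.normal(-0.5 * noise_sdlog**2, noise_sdlog, len(vals)))
        raw[sp] = vals

    batch_id = "batch:" + ",".join(batch)
    peak = max(v.max() for v in raw.values())
    out = []
    for sp in batch:
        if peak <= 0:
            scaled = np.zeros_like(raw[sp])
            out.append(SearchSeries(sp, batch_id, scaled, all_zero=True))
            continue
        scaled = raw[sp] / peak * 100.0
        if round_values:
            scaled = np.rint(scaled)
        out.append(SearchSeries(sp, batch_id, scaled, all_zero=bool(scaled.max() == 0)))
    return out


def generate_dataset(config: SynthConfig) -> SyntheticData:
    """Run the full generator: taxonomy, traits, latent interest, projects."""
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config, rng)
    traits, latent = generate_species_traits(taxonomy, config, rng)
    projects, re = generate_projects(traits, config, rng)
    return SyntheticData(taxonomy, traits, projects, latent, re, config)


def write_dataset(data: SyntheticData, outdir) -> dict[str, str]:
    """Write projects.csv, species.csv and latent.csv under ``outdir``."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    projects_path = outdir / "projects.csv"
    data.projects.to_csv(projects_path, index=False)
    paths["projects"] = str(projects_path)

    species_path = outdir / "species.csv"
    data.traits.to_csv(species_path, index=False)
    paths["species"] = str(species_path)

    latent_rows = []
    for sp, lp in data.latent.items():
        for m, v in enumerate(lp.monthly_interest):
            latent_rows.append({"species": sp, "month_index": m, "interest": v})
    latent_path = outdir / "latent.csv"
    pd.DataFrame(latent_rows).to_csv(latent_path, index=False)
    paths["latent"] = str(latent_path)
    return paths
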