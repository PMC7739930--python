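"""Per-species conservation attention and taxonomic-bias metrics.

A funded project targeting several species has its budget divided
equally among them; summing those shares per species yields the two
attention measures used throughout: the project count and the total
allocated budget. Group summaries and richness-relative bias metrics
(funded fraction, investment per known species and their
vertebrate/invertebrate ratios) follow from the allocation table.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ProjectRecord:
    """One funded project: budget in EUR and its target species."""

    project_id: str
    year: int
    theme: str
    budget: float
    species: list[str]

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError(f"project {self.project_id}: negative budget")
        if not self.species:
            raise ValueError(f"project {self.project_id}: empty species list")
        if len(set(self.species)) != len(self.species):
            raise ValueError(f"project {self.project_id}: duplicate target species")


@dataclasses.dataclass
class GroupSummary:
    group: str
    n_species_funded: int
    n_projects: float
    total_budget: float
    share_of_species: float
    share_of_budget: float


def projects_from_frame(frame: pd.DataFrame, species_sep: str = ";") -> list[ProjectRecord]:
    """Parse a projects table (species lists ';'-separated in one cell)."""
    records = []
    for row in frame.itertuples(index=False):
        species = [s.strip() for s in str(row.species).split(species_sep) if s.strip()]
        records.append(
            ProjectRecord(str(row.project_id), int(row.year), str(row.theme), float(row.budget), species)
        )
    return records


def allocate_budget(projects: Iterable[ProjectRecord]) -> pd.DataFrame:
    """Divide each project's budget equally among its target species.

    Returns one row per species that appears in at least one project,
    with columns ``species``, ``n_projects`` and ``total_budget``. The
    total allocated budget equals the total project budget exactly (up
    to floating point), since each project contributes
    ``budget / n_targets`` to each of its targets.
    """
    n_proj: dict[str, int] = {}
    total: dict[str, float] = {}
    for p in projects:
        if not p.species:
            raise ValueError(f"project {p.project_id}: empty species list")
        share = p.budget / len(p.species)
        for sp in p.species:
            n_proj[sp] = n_proj.get(sp, 0) + 1
            total[sp] = total.get(sp, 0.0) + share
    out = pd.DataFrame(
        {
            "species": list(n_proj),
            "n_projects": list(n_proj.values()),
            "total_budget": [total[sp] for sp in n_proj],
        }
    )
    return out.sort_values("species", ignore_index=True)


def summarize_groups(allocs: pd.DataFrame, group_of: Mapping[str, str]) -> pd.DataFrame:
    """Summarize allocations by group (class, vertebrate/invertebrate, ...).

    Shares are computed within the universe spanned by ``allocs``; over an
    exhaustive grouping they sum to 1.
    """
    unmapped = [sp for sp in allocs["species"] if sp not in group_of]
    if unmapped:
        raise KeyError(f"species without a group mapping: {unmapped[:10]}")
    df = allocs.copy()
    df["group"] = [group_of[sp] for sp in df["species"]]
    agg = df.groupby("group", sort=True).agg(
        n_species_funded=("species", "nunique"),
        n_projects=("n_projects", "sum"),
        total_budget=("total_budget", "sum"),
    )
    agg["share_of_species"] = agg["n_species_funded"] / agg["n_species_funded"].sum()
    agg["share_of_budget"] = agg["total_budget"] / agg["total_budget"].sum()
    return agg.reset_index()


def bias_metrics(
    summary: pd.DataFrame,
    richness: Mapping[str, int],
    numerator: str = "vertebrate",
    denominator: str = "invertebrate",
) -> dict:
    """Richness-relative bias between two groups.

    ``funded_fraction`` is the share of a group's known species that
    received any funding; ``per_known_species_investment`` spreads the
    group's total budget over its known richness. The headline ratios
    divide the numerator group's values by the denominator group's.
    """
    s = summary.set_index("group")
    for g in (numerator, denominator):
        if g not in s.index:
            raise KeyError(f"group {g!r} missing from summary")
        if g not in richness:
            raise KeyError(f"group {g!r} missing from richness table")
        if richness[g] <= 0:
            raise ValueError(f"group {g!r}: richness must be >= 1")

    funded_fraction = {g: s.loc[g, "n_species_funded"] / richness[g] for g in (numerator, denominator)}
    investment = {g: s.loc[g, "total_budget"] / richness[g] for g in (numerator, denominator)}
    return {
        "funded_fraction": funded_fraction,
        "per_known_species_investment": investment,
        "investment_ratio": investment[numerator] / investment[denominator],
        "budget_ratio": s.loc[numerator, "total_budget"] / s.loc[denominator, "total_budget"],
    }


def attention_correlation(allocs: pd.DataFrame) -> float:
    """Pearson r between per-species total budget and project count."""
    if len(allocs) < 3:
        raise ValueError("need at least 3 species for a correlation")
    x = allocs["total_budget"].to_numpy(dtype=float)
    y = allocs["n_projects"].to_numpy(dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)
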