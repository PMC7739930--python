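"""Assembly of the per-species analysis table and data exploration.

Joins taxonomy, IUCN extinction-risk categories, body size, calibrated
popularity and the allocation measures into one table, then applies a
standard exploration protocol: skewness-based log-transform decisions
for continuous predictors and a pairwise Pearson collinearity screen
with a strict |r| > 0.7 flag.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from conservebias.synthio import IUCN_CATEGORIES

#: when a collinear pair is flagged, the variable appearing EARLIER in
#: this priority list is kept (average popularity preferred over the
#: relative variant; project counts preferred over budget as response)
DEFAULT_KEEP_PRIORITY = (
    "log_popularity",
    "popularity",
    "relative_popularity",
    "n_projects",
    "total_budget",
    "log_body_size",
    "body_size",
)


@dataclasses.dataclass
class ExplorationReport:
    transforms: dict[str, str]              # column -> "none" | "log"
    skewness: dict[str, float]
    correlations: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    dropped: dict[str, str] = dataclasses.field(default_factory=dict)
    zero_variance: list[str] = dataclasses.field(default_factory=list)
    notes: list[str] = dataclasses.field(default_factory=list)


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def attach_iucn(species: Sequence[str], lookup: Mapping[str, str]) -> pd.DataFrame:
    """Match species to Red List categories by normalized binomial name.

    Matching strips/collapses whitespace and casefolds both sides.
    Species absent from the lookup are assigned DD with
    ``iucn_missing=True`` rather than being dropped.
    """
    norm_lookup = {}
    for name, cat in lookup.items():
        cat = str(cat).strip().upper()
        if cat not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {cat!r} for {name!r}")
        norm_lookup[_normalize_name(name)] = cat
    rows = []
    for sp in species:
        cat = norm_lookup.get(_normalize_name(sp))
        rows.append(
            {"species": sp, "iucn": cat if cat is not None else "DD", "iucn_missing": cat is None}
        )
    return pd.DataFrame(rows)


def _sample_skewness(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return 0.0  # constant column: treated as symmetric
    return float(stats.skew(x, bias=False))


def decide_transforms(
    table: pd.DataFrame,
    columns: Sequence[str] = ("popularity", "body_size"),
    skew_threshold: float = 1.0,
) -> ExplorationReport:
    """Decide which continuous variables need a log transform.

    A variable is logged iff its sample skewness exceeds
    ``skew_threshold``. Logs are base 10; popularity gets a +1 offset
    (zeros mean "never searched"), body size must be strictly positive
    and is logged without offset. The decision is idempotent: an already
    logged, roughly symmetric column is left alone.
    """
    transforms: dict[str, str] = {}
    skewness: dict[str, float] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        if col == "body_size" and np.any(x <= 0):
            raise ValueError("body_size must be strictly positive")
        g = _sample_skewness(x)
        skewness[col] = g
        transforms[col] = "log" if g > skew_threshold else "none"
    return ExplorationReport(transforms=transforms, skewness=skewness)


def apply_transforms(table: pd.DataFrame, report: ExplorationReport) -> pd.DataFrame:
    """Return a new table with ``log_<col>`` columns added per the report."""
    out = table.copy()
    for col, decision in report.transforms.items():
        if decision != "log":
            continue
        offset = 1.0 if col in ("popularity", "relative_popularity") else 0.0
        out[f"log_{col}"] = np.log10(out[col].to_numpy(dtype=float) + offset)
    return out


def collinearity_screen(
    table: pd.DataFrame,
    predictors: Sequence[str],
    threshold: float = 0.7,
    keep_priority: Sequence[str] = DEFAULT_KEEP_PRIORITY,
) -> ExplorationReport:
    """Flag predictor pairs with |Pearson r| strictly above the threshold.

    Zero-variance columns are excluded from the correlation matrix and
    reported separately. Each flagged pair is resolved by dropping the
    variable that ranks later in ``keep_priority`` (unlisted variables
    rank last, ties broken by column order).
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors to screen")
    usable, zero_var = [], []
    for col in predictors:
        x = table[col].to_numpy(dtype=float)
        (zero_var if np.var(x) == 0 else usable).append(col)

    corr = table[usable].corr(method="pearson") if len(usable) >= 2 else None
    flagged: list[tuple[str, str, float]] = []
    dropped: dict[str, str] = {}
    if corr is not None:
        rank = {name: i for i, name in enumerate(keep_priority)}

        def priority(name: str) -> tuple[int, int]:
            return rank.get(name, len(keep_priority)), usable.index(name)

        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                r = float(corr.loc[a, b])
                if abs(r) > threshold:  # strict: |r| == threshold not flagged
                    flagged.append((a, b, r))
                    keep, drop = sorted((a, b), key=priority)
                    dropped.setdefault(drop, f"|r|={abs(r):.3f} with {keep}")
    return ExplorationReport(
        transforms={},
        skewness={},
        correlations=corr,
        flagged_pairs=flagged,
        dropped=dropped,
        zero_variance=zero_var,
        notes=[
            "homogeneity operationalized as |sample skewness| rule; "
            "collinearity threshold strict |r| > %.2f" % threshold
        ],
    )


def build_analysis_table(
    species: pd.DataFrame,
    popularity: pd.DataFrame,
    allocations: pd.DataFrame,
    iucn_lookup: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join species traits, calibrated popularity and allocations.

    Species with no funded project get ``n_projects = 0`` and zero
    budget (the analysis response includes unfunded species). If an
    ``iucn`` column is absent, categories come from ``iucn_lookup``.
    """
    table = species.copy()
    if "iucn" not in table.columns:
        if iucn_lookup is None:
            raise ValueError("species table lacks 'iucn' and no lookup was given")
        iucn = attach_iucn(table["species"].tolist(), iucn_lookup)
        table = table.merge(iucn, on="species", how="left")
    table = table.merge(
        popularity[["species", "average"]].rename(columns={"average": "popularity"}),
        on="species",
        how="left",
    )
    table = table.merge(allocations, on="species", how="left")
    table["n_projects"] = table["n_projects"].fillna(0).astype(int)
    table["total_budget"] = table["total_budget"].fillna(0.0)
    return table
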