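"""Calibration of comparable popularity from batch-relative search volumes.

Trends-style APIs report search interest per query batch on a relative
0-100 integer scale: values from different batches are not comparable.
Comparability is restored by *anchor chaining*: consecutive batches
share one anchor species, whose two series are related by a pure unit
conversion. The conversion factor is the through-origin least-squares
slope regressing the anchor's already-calibrated values on its
new-batch values; multiplying every series in the new batch by the
(cumulative) factor expresses all species in the units of the first
batch. Anchors are screened by the number of months in which both
series are non-zero and by the regression R², gated at 0.95 by default.

Per-species popularity is then the 120-month average of the calibrated
series.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.95


@dataclasses.dataclass
class Batch:
    batch_id: str
    species: list[str]
    anchor: str | None  # shared with an earlier batch; None for the first


@dataclasses.dataclass
class BatchPlan:
    batches: list[Batch]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, b in enumerate(self.batches):
            if i == 0:
                if b.anchor is not None:
                    raise ValueError("first batch must not have an anchor")
            else:
                if b.anchor is None or b.anchor not in seen:
                    raise ValueError(
                        f"batch {b.batch_id}: anchor must be a species from an earlier batch"
                    )
            seen.update(b.species)

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for b in self.batches:
            for sp in b.species:
                if sp not in seen:
                    seen.add(sp)
                    out.append(sp)
        return out


@dataclasses.dataclass
class ScalingFactor:
    """Through-origin slope converting new-batch units into reference units."""

    batch_id: str
    anchor: str
    factor: float
    r_squared: float
    n_nonzero: int
    below_threshold: bool = False


@dataclasses.dataclass
class CalibratedPopularity:
    species: str
    monthly: np.ndarray
    average: float
    batch_id: str
    cumulative_factor: float


def plan_batches(species: Sequence[str], batch_size: int = 5) -> BatchPlan:
    """Partition species into overlapping query batches.

    The first batch holds up to ``batch_size`` species; every subsequent
    batch re-queries one anchor (the last species of the previous batch,
    so adjacent batches stay closest in magnitude when the input is
    sorted by expected popularity) plus up to ``batch_size - 1`` new
    species. For n species this yields ``1 + ceil((n - B)/(B - 1))``
    batches.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 (anchoring needs room for two species)")
    species = list(species)
    if not species:
        raise ValueError("species list is empty")
    if len(set(species)) != len(species):
        raise ValueError("species list contains duplicates")

    batches = [Batch("b000", species[: batch_size], None)]
    pos = batch_size
    i = 1
    while pos < len(species):
        anchor = batches[-1].species[-1]
        new = species[pos : pos + batch_size - 1]
        batches.append(Batch(f"b{i:03d}", [anchor] + new, anchor))
        pos += batch_size - 1
        i += 1
    return BatchPlan(batches)


def n_batches(n_species: int, batch_size: int) -> int:
    """Closed-form batch count for ``plan_batches``."""
    if n_species <= batch_size:
        return 1
    return 1 + math.ceil((n_species - batch_size) / (batch_size - 1))


def estimate_scaling_factor(
    anchor_ref: np.ndarray,
    anchor_new: np.ndarray,
    threshold: float = DEFAULT_R2_THRESHOLD,
    batch_id: str = "",
    anchor: str = "",
) -> ScalingFactor:
    """Fit the unit conversion between two reportings of one anchor series.

    ``factor = sum(ref * new) / sum(new**2)`` — the least-squares slope of
    the through-origin regression of the calibrated (reference) values on
    the new-batch values. R² is the uncentered 1 - SSR/sum(ref**2) of
    that fit; ``n_nonzero`` counts months where both series are positive.
    """
    ref = np.asarray(anchor_ref, dtype=float)
    new = np.asarray(anchor_new, dtype=float)
    if ref.shape != new.shape:
        raise ValueError("anchor series must have equal length")
    sxx = float(new @ new)
    if sxx == 0.0:
        raise ValueError("anchor has all-zero values in the new batch: no information")
    sxy = float(ref @ new)
    if sxy <= 0.0:
        raise ValueError("anchor series share no signal (slope would be <= 0)")
    factor = sxy / sxx
    sst = float(ref @ ref)
    ssr = float(np.sum((ref - factor * new) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    n_nonzero = int(np.sum((ref > 0) & (new > 0)))
    return ScalingFactor(batch_id, anchor, factor, r2, n_nonzero, below_threshold=r2 <= threshold)


def select_anchor(
    candidates: Sequence[ScalingFactor], threshold: float = DEFAULT_R2_THRESHOLD
) -> ScalingFactor:
    """Pick the anchor for a batch from the calibrated overlap species.

    Candidates are ranked by ``n_nonzero`` descending; the first whose R²
    exceeds the threshold wins. If none passes, the best-R² candidate is
    returned with ``below_threshold`` set and the chain continues with a
    warning.
    """
    if not candidates:
        raise ValueError("no anchor candidates")
    ranked = sorted(candidates, key=lambda sf: -sf.n_nonzero)
    for sf in ranked:
        if sf.r_squared > threshold:
            return dataclasses.replace(sf, below_threshold=False)
    best = max(candidates, key=lambda sf: sf.r_squared)
    logger.warning(
        "batch %s: no anchor with R^2 > %.3g (best %.4f via %s); chaining anyway",
        best.batch_id, threshold, best.r_squared, best.anchor,
    )
    return dataclasses.replace(best, below_threshold=True)


def chain_rescale(
    plan: BatchPlan,
    series: Mapping[str, Mapping[str, np.ndarray]],
    threshold: float = DEFAULT_R2_THRESHOLD,
) -> tuple[dict[str, CalibratedPopularity], list[ScalingFactor]]:
    """Propagate scaling factors along the batch chain.

    ``series`` maps batch id -> species -> monthly values as reported for
    that batch. The first batch defines the common unit (factor 1); each
    later batch is converted through its anchor's fitted factor against
    the anchor's already-calibrated series, so factors accumulate down
    the chain. A species reported in two batches keeps its earliest
    calibration.
    """
    calibrated: dict[str, CalibratedPopularity] = {}
    factors: list[ScalingFactor] = []
    for i, batch in enumerate(plan.batches):
        if batch.batch_id not in series:
            raise KeyError(f"no series for batch {batch.batch_id}")
        batch_series = series[batch.batch_id]
        if i == 0:
            cum = 1.0
        else:
            candidates = []
            for sp in batch.species:
                if sp not in calibrated or sp not in batch_series:
                    continue
                try:
                    candidates.append(
                        estimate_scaling_factor(
                            calibrated[sp].monthly,
                            batch_series[sp],
                            threshold,
                            batch.batch_id,
                            sp,
                        )
                    )
                except ValueError:
                    continue
            if not candidates:
                raise ValueError(
                    f"broken chain at batch {batch.batch_id}: no usable calibrated anchor"
                )
            chosen = select_anchor(candidates, threshold)
            factors.append(chosen)
            cum = chosen.factor
        for sp in batch.species:
            if sp in calibrated or sp not in batch_series:
                continue
            monthly = np.asarray(batch_series[sp], dtype=float) * cum
            calibrated[sp] = CalibratedPopularity(
                sp, monthly, float(monthly.mean()), batch.batch_id, cum
            )
    return calibrated, factors


def calibrate(
    query: Callable[[Sequence[str]], Mapping[str, np.ndarray]],
    species: Sequence[str],
    batch_size: int = 5,
    threshold: float = DEFAULT_R2_THRESHOLD,
    max_reanchor: int = 3,
) -> tuple[dict[str, CalibratedPopularity], list[ScalingFactor]]:
    """Plan batches, query them, and chain-rescale, re-anchoring as needed.

    ``query`` stands in for the search-volume API: it takes a species
    batch and returns the 0-100 series per species. If a batch's anchor
    reports all zeros (no information for a regression), the batch is
    re-queried with a different species from the previous batch as
    anchor, up to ``max_reanchor`` times, before failing.
    """
    plan = plan_batches(species, batch_size)
    series: dict[str, dict[str, np.ndarray]] = {}
    prev_batch: Batch | None = None
    batches: list[Batch] = []
    for batch in plan.batches:
        current = batch
        resp = {sp: np.asarray(v, float) for sp, v in query(current.species).items()}
        if prev_batch is not None:
            tried = set()
            attempts = 0
            while resp[current.anchor].max() == 0 and attempts < max_reanchor:
                tried.add(current.anchor)
                alternatives = [
                    sp for sp in prev_batch.species if sp not in tried and sp not in current.species
                ]
                if not alternatives:
                    break
                new_anchor = alternatives[-1]
                logger.warning(
                    "batch %s: anchor %s all-zero, re-anchoring on %s",
                    current.batch_id, current.anchor, new_anchor,
                )
                new_species = [new_anchor] + [s for s in current.species if s != current.anchor]
                current = Batch(current.batch_id, new_species, new_anchor)
                resp = {sp: np.asarray(v, float) for sp, v in query(current.species).items()}
                attempts += 1
        series[current.batch_id] = resp
        batches.append(current)
        prev_batch = current
    return chain_rescale(BatchPlan(batches), series, threshold)


def popularity_frame(
    calibrated: Mapping[str, CalibratedPopularity], factors: Sequence[ScalingFactor]
) -> pd.DataFrame:
    """Tabulate calibrated averages with their batch's chain diagnostics."""
    diag = {sf.batch_id: sf for sf in factors}
    rows = []
    for sp, cp in calibrated.items():
        sf = diag.get(cp.batch_id)
        rows.append(
            {
                "species": sp,
                "average": cp.average,
                "batch": cp.batch_id,
                "factor": cp.cumulative_factor,
                "r_squared": sf.r_squared if sf else 1.0,
                "below_threshold": sf.below_threshold if sf else False,
            }
        )
    return pd.DataFrame(rows).sort_values("species", ignore_index=True)
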