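"""Top-fraction hotspot selection, rank-sum overlay, and tiering.

Per metric, the top-q% land cells form candidate hotspots.  The final
hotspot set at a threshold merges the per-metric sets: candidates (union
of the top sets) are scored by the sum of their dense ranks within each
metric's full surface and the best ``n_target`` are kept, so the final
count matches the threshold's count.  Cells are tiered by how many of the
per-metric top sets contain them (4 -> I, 3 -> II, 2 -> III, 1 ->
unclassified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import MetricSurface
from .occurrences import PresenceMatrix

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.17, 0.30)
DEFAULT_METRICS = ("SR", "SC_rank", "WE", "PA")


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _order_cells(surface: MetricSurface, sr: MetricSurface) -> np.ndarray:
    """Cell indices sorted best-first: value desc, SR desc, cell id asc."""
    return np.lexsort((surface.cell_ids, -sr.values, -surface.values))


def top_fraction_cells(
    surface: MetricSurface,
    q: float,
    sr_surface: MetricSurface | None = None,
    n_target: int | None = None,
) -> set[int]:
    """The ``k`` highest-valued cells, ``k = floor(q * n_land)`` unless an
    explicit ``n_target`` is given.  Ties at the cut are broken by higher
    SR, then lower cell id."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    n_land = len(surface.cell_ids)
    k = int(n_target) if n_target is not None else math.floor(q * n_land)
    if k <= 0:
        raise ValueError("threshold selects zero cells")
    if sr_surface is None:
        sr_surface = surface
    order = _order_cells(surface, sr_surface)
    return set(int(c) for c in surface.cell_ids[order[:k]])


@dataclass
class HotspotSet:
    q: float
    n_target: int
    final_cells: set[int]
    per_metric_top: dict[str, set[int]]
    rank_sum: dict[int, float]
    tiers: dict[int, str] = field(default_factory=dict)
    warning: str | None = None

    def membership_count(self, cell_id: int) -> int:
        return sum(cell_id in s for s in self.per_metric_top.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.final_cells):
            row = {"cell_id": c, "rank_sum": self.rank_sum.get(c), "tier": self.tiers.get(c)}
            for m, s in self.per_metric_top.items():
                row[f"in_{m}"] = int(c in s)
            rows.append(row)
        return pd.DataFrame(rows)


def classify_tiers(hotspot_set: HotspotSet) -> dict[int, str]:
    """Tier by per-metric membership count: 4 -> I, 3 -> II, 2 -> III,
    otherwise 'unclassified'."""
    tier_of = {4: "I", 3: "II", 2: "III"}
    tiers = {
        c: tier_of.get(hotspot_set.membership_count(c), "unclassified")
        for c in hotspot_set.final_cells
    }
    hotspot_set.tiers = tiers
    return tiers


def combine_rank_sum(
    surfaces: dict[str, MetricSurface],
    q: float,
    sr_surface: MetricSurface | None = None,
    n_target: int | None = None,
) -> HotspotSet:
    """Merge per-metric top sets into the final hotspot set at ``q``.

    Every candidate (union of the top sets) receives the sum over metrics
    of its dense rank in that metric's *full* surface (rank 1 = highest
    value), so candidates missing from one metric's top set remain
    comparable.  The ``n_target`` candidates with the smallest rank sum
    win; ties go to higher membership count, then higher SR, then lower
    cell id.
    """
    if len(surfaces) < 2:
        raise ValueError("rank-sum overlay needs at least 2 metrics")
    names = list(surfaces)
    first = surfaces[names[0]]
    for s in surfaces.values():
        if not np.array_equal(s.cell_ids, first.cell_ids):
            raise ValueError("surfaces are on different cell sets")
    if sr_surface is None:
        sr_surface = surfaces.get("SR", first)

    n_land = len(first.cell_ids)
    k = int(n_target) if n_target is not None else math.floor(q * n_land)
    if k <= 0:
        raise ValueError("threshold selects zero cells")

    per_metric_top = {
        m: top_fraction_cells(surfaces[m], q, sr_surface=sr_surface, n_target=k)
        for m in names
    }
    candidates = sorted(set().union(*per_metric_top.values()))

    # dense rank of every cell within each full surface (1 = best)
    dense_ranks = {}
    for m in names:
        r = rankdata(-surfaces[m].values, method="dense")
        dense_ranks[m] = dict(zip((int(c) for c in first.cell_ids), r))
    rank_sum = {
        c: float(sum(dense_ranks[m][c] for m in names)) for c in candidates
    }

    warning = None
    if len(candidates) < k:
        warning = (
            f"candidate union ({len(candidates)}) smaller than target ({k}); "
            "returning all candidates"
        )
        final = set(candidates)
    else:
        member = {c: sum(c in per_metric_top[m] for m in names) for c in candidates}
        sr_of = dict(zip((int(c) for c in first.cell_ids), sr_surface.values))
        ordered = sorted(
            candidates,
            key=lambda c: (rank_sum[c], -member[c], -sr_of[c], c),
        )
        final = set(ordered[:k])

    hs = HotspotSet(
        q=q,
        n_target=k,
        final_cells=final,
        per_metric_top=per_metric_top,
        rank_sum=rank_sum,
        warning=warning,
    )
    classify_tiers(hs)
    return hs


def species_coverage(
    hotspot_set: HotspotSet,
    P: PresenceMatrix,
    traits: pd.DataFrame,
    ndigits: int = 2,
) -> dict[str, float | None]:
    """Percent of each category's species with >= 1 occupied cell inside
    the final hotspot set.  Categories with no species report None.

    ``traits`` must be indexed (or indexable) by species id with boolean
    columns ``endemic``, ``threatened``, ``protected``.
    """
    t = traits.set_index("species") if "species" in traits.columns else traits
    inside = np.zeros(P.n_species, dtype=bool)
    cols = P.cell_index([c for c in hotspot_set.final_cells if c in set(P.cell_ids.tolist())])
    if len(cols):
        inside = P.matrix[:, cols].any(axis=1)

    out: dict[str, float | None] = {}
    categories = {
        "all": np.ones(P.n_species, dtype=bool),
        "endemic": np.array([bool(t.at[s, "endemic"]) if s in t.index else False for s in P.species_ids]),
        "threatened": np.array([bool(t.at[s, "threatened"]) if s in t.index else False for s in P.species_ids]),
        "protected": np.array([bool(t.at[s, "protected"]) if s in t.index else False for s in P.species_ids]),
    }
    for name, mask in categories.items():
        total = int(mask.sum())
        if total == 0:
            out[name] = None
            continue
        covered = int((mask & inside).sum())
        out[name] = round_half_up(100.0 * covered / total, ndigits)
    return out
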