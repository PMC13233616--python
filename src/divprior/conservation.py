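"""Reserve overlay, conservation-effectiveness and gap accounting.

A hotspot cell is *covered* under a scope (NNR, PNR, or their union) when
at least one reserve polygon of that scope intersects the cell polygon
with positive area; a hotspot cell with no such reserve is a conservation
gap.  Species-level rates count a species as effectively conserved when it
occurs in at least one covered hotspot cell, against the full category
totals from the trait table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.strtree import STRtree
from shapely.validation import make_valid

from . import io as _io
from .grid import Grid
from .hotspots import round_half_up
from .occurrences import PresenceMatrix

SCOPES = ("NNR", "PNR", "NNR-PNR")


@dataclass
class Reserve:
    geometry: object  # shapely polygon
    reserve_class: str  # "NNR" | "PNR"


@dataclass
class ReserveLayer:
    reserves: list[Reserve] = field(default_factory=list)

    def __len__(self):
        return len(self.reserves)

    def of_class(self, cls: str) -> list[Reserve]:
        return [r for r in self.reserves if r.reserve_class == cls]

    def write(self, path) -> None:
        _io.write_geojson(
            path,
            [r.geometry for r in self.reserves],
            [{"class": r.reserve_class} for r in self.reserves],
        )

    @classmethod
    def read(cls, path) -> "ReserveLayer":
        feats = _io.read_geojson(path)
        return cls([Reserve(g, p["class"]) for g, p in feats])


@dataclass
class ProtectionStatus:
    """Per-land-cell coverage flags, aligned with ``cell_ids``."""

    cell_ids: np.ndarray
    nnr: np.ndarray
    pnr: np.ndarray
    skipped_geometries: int = 0

    @property
    def either(self) -> np.ndarray:
        return self.nnr | self.pnr

    def covered_mask(self, scope: str) -> np.ndarray:
        if scope == "NNR":
            return self.nnr
        if scope == "PNR":
            return self.pnr
        if scope == "NNR-PNR":
            return self.either
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")

    def covered_cells(self, scope: str) -> set[int]:
        return set(int(c) for c in self.cell_ids[self.covered_mask(scope)])


def protection_status(
    grid: Grid,
    reserves: ReserveLayer,
    min_fraction: float = 0.0,
) -> ProtectionStatus:
    """Flag each land cell covered by NNR / PNR reserves.

    Coverage means the intersection area exceeds ``min_fraction`` of the
    cell area (default 0: any positive-area overlap).  Invalid geometries
    are repaired with ``make_valid``; irreparable ones are skipped with a
    count in the result.
    """
    cell_ids = grid.land_cell_ids
    polys = [grid.cell_polygon(int(c)) for c in cell_ids]
    flags = {"NNR": np.zeros(len(cell_ids), dtype=bool),
             "PNR": np.zeros(len(cell_ids), dtype=bool)}
    skipped = 0
    min_area = min_fraction * grid.cell_km**2

    geoms, classes = [], []
    for r in reserves.reserves:
        g = r.geometry
        if not g.is_valid:
            g = make_valid(g)
            if g is None or g.is_empty or not g.is_valid:
                skipped += 1
                continue
        if r.reserve_class not in ("NNR", "PNR"):
            raise ValueError(f"unknown reserve class {r.reserve_class!r}")
        geoms.append(g)
        classes.append(r.reserve_class)

    if geoms:
        tree = STRtree(geoms)
        for j, cell in enumerate(polys):
            for gi in tree.query(cell):
                g = geoms[gi]
                inter = cell.intersection(g)
                if inter.area > min_area:
                    flags[classes[gi]][j] = True
    return ProtectionStatus(
        cell_ids=cell_ids, nnr=flags["NNR"], pnr=flags["PNR"],
        skipped_geometries=skipped,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class EffectivenessReport:
    q: float
    scope: str
    hotspot_count: int
    covered_count: int
    grid_effectiveness_pct: float
    species_rates_pct: dict[str, float | None]
    species_covered_counts: dict[str, int]
    species_totals: dict[str, int]
    gap_cells: set[int]
    gap_species_counts: dict[str, int]

    def summary(self) -> dict:
        return {
            "q": self.q,
            "scope": self.scope,
            "hotspot_cells": self.hotspot_count,
            "covered_cells": self.covered_count,
            "grid_effectiveness_pct": self.grid_effectiveness_pct,
            "species_rates_pct": self.species_rates_pct,
            "species_covered_counts": self.species_covered_counts,
            "species_totals": self.species_totals,
            "gap_cell_count": len(self.gap_cells),
            "gap_species_counts": self.gap_species_counts,
        }


def _category_masks(P: PresenceMatrix, traits: pd.DataFrame) -> dict[str, np.ndarray]:
    t = traits.set_index("species") if "species" in traits.columns else traits
    def col(name):
        return np.array(
            [bool(t.at[s, name]) if s in t.index else False for s in P.species_ids]
        )
    return {
        "all": np.ones(P.n_species, dtype=bool),
        "endemic": col("endemic"),
        "threatened": col("threatened"),
        "protected": col("protected"),
    }


def _species_in_cells(P: PresenceMatrix, cells: set[int]) -> np.ndarray:
    known = set(int(c) for c in P.cell_ids)
    cols = P.cell_index([c for c in cells if c in known])
    if len(cols) == 0:
        return np.zeros(P.n_species, dtype=bool)
    return P.matrix[:, cols].any(axis=1)


def effectiveness_report(
    hotspot_cells: set[int],
    status: ProtectionStatus,
    P: PresenceMatrix,
    traits: pd.DataFrame,
    scope: str = "NNR-PNR",
    q: float = float("nan"),
    ndigits: int = 2,
    category_ndigits: dict[str, int] | None = None,
) -> EffectivenessReport:
    """Grid- and species-level conservation effectiveness under a scope.

    ``category_ndigits`` overrides the rounding precision per species
    category (the source tables print some rates at one decimal).
    """
    if not hotspot_cells:
        raise ValueError("hotspot set is empty")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    hotspot_cells = set(int(c) for c in hotspot_cells)
    covered_all = status.covered_cells(scope)
    covered = hotspot_cells & covered_all
    gaps = hotspot_cells - covered_all
    grid_pct = round_half_up(100.0 * len(covered) / len(hotspot_cells), ndigits)

    masks = _category_masks(P, traits)
    in_covered = _species_in_cells(P, covered)
    in_gap = _species_in_cells(P, gaps)

    rates: dict[str, float | None] = {}
    covered_counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    gap_counts: dict[str, int] = {}
    nd = category_ndigits or {}
    for name, mask in masks.items():
        total = int(mask.sum())
        totals[name] = total
        covered_counts[name] = int((mask & in_covered).sum())
        gap_counts[name] = int((mask & in_gap).sum())
        if total == 0:
            rates[name] = None
        else:
            rates[name] = round_half_up(
                100.0 * covered_counts[name] / total, nd.get(name, ndigits)
            )
    return EffectivenessReport(
        q=q,
        scope=scope,
        hotspot_count=len(hotspot_cells),
        covered_count=len(covered),
        grid_effectiveness_pct=grid_pct,
        species_rates_pct=rates,
        species_covered_counts=covered_counts,
        species_totals=totals,
        gap_cells=gaps,
        gap_species_counts=gap_counts,
    )


@dataclass
class GapReport:
    q: float
    gap_cells_by_scope: dict[str, set[int]]
    gap_species_by_scope: dict[str, dict[str, int]]

    def summary(self) -> dict:
        return {
            "q": self.q,
            "gap_cell_counts": {s: len(c) for s, c in self.gap_cells_by_scope.items()},
            "gap_species_counts": self.gap_species_by_scope,
        }


def gap_report(
    hotspot_cells: set[int],
    status: ProtectionStatus,
    P: PresenceMatrix,
    traits: pd.DataFrame,
    q: float = float("nan"),
) -> GapReport:
    """Uncovered hotspot cells and the species occurring in them, for each
    reserve scope."""
    hotspot_cells = set(int(c) for c in hotspot_cells)
    masks = _category_masks(P, traits)
    cells_by_scope = {}
    species_by_scope = {}
    for scope in SCOPES:
        gaps = hotspot_cells - status.covered_cells(scope)
        cells_by_scope[scope] = gaps
        in_gap = _species_in_cells(P, gaps)
        species_by_scope[scope] = {
            name: int((mask & in_gap).sum()) for name, mask in masks.items()
        }
    return GapReport(q=q, gap_cells_by_scope=cells_by_scope,
                     gap_species_by_scope=species_by_scope)
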