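"""Occurrence-record cleaning, thinning, and gridding.

The cleaning step applies five filters in a fixed order, attributing every
removed record to the *first* filter it violates:

1. missing or unparseable coordinates (or empty locality where coordinates
   are absent), including coordinates outside valid degree ranges;
2. latitude numerically equal to longitude;
3. either coordinate exactly zero, or both coordinates integer-valued;
4. point not on land;
5. point outside the species' native-range polygon (skipped, and logged,
   for species without a supplied polygon).

Cleaned records are gridded into a binary species x cell
:class:`PresenceMatrix`, the substrate of every diversity metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .grid import Grid

FILTER_NAMES = {
    1: "missing_locality",
    2: "identical_lat_lon",
    3: "zero_or_integer",
    4: "in_sea",
    5: "outside_native_range",
}

SPECIES_COL = "species"
LAT_COL = "latitude"
LON_COL = "longitude"
LOCALITY_COL = "locality"


@dataclass
class CleaningReport:
    """Per-filter removal accounting for one cleaning run."""

    input_count: int
    retained_count: int
    removed: dict[int, int]
    disposition: np.ndarray  # 0 = retained, else first violated filter id
    skipped_native_range_species: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.retained_count + sum(self.removed.values()) == self.input_count

    def summary(self) -> dict:
        return {
            "input": self.input_count,
            "retained": self.retained_count,
            "removed": {FILTER_NAMES[k]: v for k, v in sorted(self.removed.items())},
            "native_range_filter_skipped_species": sorted(
                self.skipped_native_range_species
            ),
        }


def _coerce_float(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def clean_records(
    table: pd.DataFrame,
    land_mask,
    native_ranges: dict | None = None,
    columns: dict | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the five-step cleaning procedure.

    Parameters
    ----------
    table
        Occurrence table with species / latitude / longitude columns
        (names overridable through ``columns``).
    land_mask
        Shapely polygon (lon/lat degrees) delimiting land.  A point is on
        land when the polygon covers it (boundary counts as land).
    native_ranges
        Optional mapping species id -> shapely polygon in degrees.  Records
        of species without an entry skip filter 5 (logged).
    """
    if table is None or len(table) == 0:
        raise ValueError("occurrence table is empty")
    if land_mask is None:
        raise ValueError("a land mask is required for the in-sea filter")
    cols = {
        "species": SPECIES_COL,
        "latitude": LAT_COL,
        "longitude": LON_COL,
        "locality": LOCALITY_COL,
    }
    if columns:
        cols.update(columns)

    n = len(table)
    species = table[cols["species"]].astype(str).to_numpy()
    lat = _coerce_float(table[cols["latitude"]]).to_numpy()
    lon = _coerce_float(table[cols["longitude"]]).to_numpy()

    disposition = np.zeros(n, dtype=np.int8)

    # (1) missing / unparseable / out-of-range coordinates
    bad1 = (
        np.isnan(lat)
        | np.isnan(lon)
        | (np.abs(lat) > 90.0)
        | (np.abs(lon) > 180.0)
        | (species == "")
    )
    disposition[bad1] = 1

    # (2) latitude == longitude, exact numeric equality
    with np.errstate(invalid="ignore"):
        bad2 = (disposition == 0) & (lat == lon)
    disposition[bad2] = 2

    # (3) either coordinate exactly zero, or both integer-valued
    with np.errstate(invalid="ignore"):
        zero = (lat == 0.0) | (lon == 0.0)
        both_int = (lat == np.floor(lat)) & (lon == np.floor(lon))
    bad3 = (disposition == 0) & (zero | both_int)
    disposition[bad3] = 3

    # (4) not on land
    prepared_land = prep(land_mask)
    pending = np.flatnonzero(disposition == 0)
    for i in pending:
        if not prepared_land.covers(Point(lon[i], lat[i])):
            disposition[i] = 4

    # (5) outside the species' native range
    skipped: set[str] = set()
    if native_ranges is None:
        native_ranges = {}
    prepared_ranges = {}
    pending = np.flatnonzero(disposition == 0)
    for i in pending:
        sp = species[i]
        poly = native_ranges.get(sp)
        if poly is None:
            skipped.add(sp)
            continue
        if sp not in prepared_ranges:
            prepared_ranges[sp] = prep(poly)
        if not prepared_ranges[sp].covers(Point(lon[i], lat[i])):
            disposition[i] = 5

    keep = disposition == 0
    removed = {f: int((disposition == f).sum()) for f in range(1, 6)}
    report = CleaningReport(
        input_count=n,
        retained_count=int(keep.sum()),
        removed=removed,
        disposition=disposition,
        skipped_native_range_species=sorted(skipped),
    )
    cleaned = table.loc[keep].reset_index(drop=True)
    return cleaned, report


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary species x land-cell incidence.

    ``matrix[i, j]`` is 1 iff species ``species_ids[i]`` has at least one
    record in land cell ``cell_ids[j]``.  Species with no on-grid record
    are dropped (and listed in ``dropped_species``).
    """

    species_ids: list[str]
    cell_ids: np.ndarray  # land cell ids, ascending
    matrix: np.ndarray  # bool, S x C
    dropped_species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.matrix.shape != (len(self.species_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match ids")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species (row sums)."""
        return self.matrix.sum(axis=1)

    def species_in_cell(self, cell_id) -> list[str]:
        j = int(np.flatnonzero(self.cell_ids == cell_id)[0])
        return [self.species_ids[i] for i in np.flatnonzero(self.matrix[:, j])]

    def cell_index(self, cell_ids) -> np.ndarray:
        """Column indices for the given cell ids."""
        order = {int(c): j for j, c in enumerate(self.cell_ids)}
        return np.array([order[int(c)] for c in np.atleast_1d(cell_ids)], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Sparse triplet representation (species, cell_id)."""
        si, cj = np.nonzero(self.matrix)
        return pd.DataFrame(
            {
                "species": [self.species_ids[i] for i in si],
                "cell_id": self.cell_ids[cj],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cell_ids=None) -> "PresenceMatrix":
        species = sorted(frame["species"].astype(str).unique())
        if cell_ids is None:
            cell_ids = np.sort(frame["cell_id"].unique())
        cell_ids = np.asarray(cell_ids)
        s_index = {s: i for i, s in enumerate(species)}
        c_index = {int(c): j for j, c in enumerate(cell_ids)}
        m = np.zeros((len(species), len(cell_ids)), dtype=bool)
        for sp, cid in zip(frame["species"].astype(str), frame["cell_id"]):
            m[s_index[sp], c_index[int(cid)]] = True
        return cls(species_ids=species, cell_ids=cell_ids, matrix=m)

    @classmethod
    def read(cls, path, cell_ids=None) -> "PresenceMatrix":
        return cls.from_frame(pd.read_csv(path), cell_ids=cell_ids)


def rasterize_presence(
    cleaned: pd.DataFrame,
    grid: Grid,
    to_xy=None,
    columns: dict | None = None,
) -> tuple[PresenceMatrix, pd.DataFrame]:
    """Grid cleaned records into a :class:`PresenceMatrix`.

    ``to_xy`` maps (lon, lat) -> projected (x, y); defaults to the grid's
    own projection.  Records falling off-grid or on sea cells are returned
    in an overflow table rather than silently dropped.
    """
    cols = {"species": SPECIES_COL, "latitude": LAT_COL, "longitude": LON_COL}
    if columns:
        cols.update(columns)
    if to_xy is None:
        if grid.projection is None:
            raise ValueError("grid has no projection; pass to_xy explicitly")
        to_xy = grid.projection

    lon = cleaned[cols["longitude"]].to_numpy(dtype=float)
    lat = cleaned[cols["latitude"]].to_numpy(dtype=float)
    x, y = to_xy(lon, lat)
    cells = grid.cell_of_point(x, y)
    on_grid = cells >= 0
    on_land = np.zeros(len(cleaned), dtype=bool)
    on_land[on_grid] = grid.land[cells[on_grid]]
    ok = on_grid & on_land
    overflow = cleaned.loc[~ok].copy()

    species_arr = cleaned[cols["species"]].astype(str).to_numpy()[ok]
    cell_arr = cells[ok]
    species = sorted(set(species_arr))
    cell_ids = grid.land_cell_ids
    s_index = {s: i for i, s in enumerate(species)}
    c_index = {int(c): j for j, c in enumerate(cell_ids)}
    m = np.zeros((len(species), len(cell_ids)), dtype=bool)
    for sp, cid in zip(species_arr, cell_arr):
        m[s_index[sp], c_index[int(cid)]] = True

    dropped = sorted(set(cleaned[cols["species"]].astype(str)) - set(species))
    pm = PresenceMatrix(
        species_ids=species, cell_ids=cell_ids, matrix=m, dropped_species=dropped
    )
    return pm, overflow


def thin_per_cell(
    cleaned: pd.DataFrame,
    thin_grid: Grid,
    seed: int,
    to_xy=None,
    columns: dict | None = None,
) -> pd.DataFrame:
    """Keep exactly one record per species per thin-grid cell, chosen
    uniformly at random with the given seed."""
    cols = {"species": SPECIES_COL, "latitude": LAT_COL, "longitude": LON_COL}
    if columns:
        cols.update(columns)
    if to_xy is None:
        if thin_grid.projection is None:
            raise ValueError("thin grid has no projection; pass to_xy explicitly")
        to_xy = thin_grid.projection

    lon = cleaned[cols["longitude"]].to_numpy(dtype=float)
    lat = cleaned[cols["latitude"]].to_numpy(dtype=float)
    x, y = to_xy(lon, lat)
    cells = thin_grid.cell_of_point(x, y)

    rng = np.random.default_rng(seed)
    work = cleaned.copy()
    work["_thin_cell"] = cells
    work["_u"] = rng.random(len(work))
    # deterministic uniform choice: minimum random mark per (species, cell)
    idx = (
        work.sort_values("_u", kind="stable")
        .groupby([cols["species"], "_thin_cell"], sort=True)
        .head(1)
        .index
    )
    out = cleaned.loc[sorted(idx)].reset_index(drop=True)
    return out
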