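"""Equal-area analysis grids.

A :class:`Grid` is a regular lattice of square cells in a projected,
equal-area coordinate system (kilometres).  Cells carry stable integer ids
in row-major order (row 0 at the bottom-left origin), and a boolean land
mask selects the cells that take part in every downstream computation.

Two ways to obtain a grid:

* :func:`build_grid` tiles a geographic extent after projecting it with an
  equal-area projection (Albers conic by default);
* the synthetic-data generator builds grids directly in km space with a
  linear geographic transform (see :mod:`divprior.synthetic`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform
from shapely.prepared import prep

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Projections (forward lon/lat degrees -> x/y km).  Implemented from the
# standard spherical closed forms; both are exactly equal-area on the sphere,
# so square cells tiled in projected space have identical areas.
# ---------------------------------------------------------------------------


class EqualAreaProjection:
    """Interface: callable (lon, lat) -> (x, y) in kilometres."""

    name: str = "identity"

    def __call__(self, lon, lat):
        raise NotImplementedError

    def spec(self) -> dict:
        return {"name": self.name}


@dataclass
class AlbersEqualArea(EqualAreaProjection):
    """Spherical Albers equal-area conic projection.

    Standard parallels default to the one-sixth rule on the latitude span.
    """

    lon_0: float
    lat_0: float
    lat_1: float
    lat_2: float
    name: str = field(default="albers_equal_area", init=False)

    @classmethod
    def from_extent(cls, lon_min, lat_min, lon_max, lat_max) -> "AlbersEqualArea":
        span = lat_max - lat_min
        return cls(
            lon_0=0.5 * (lon_min + lon_max),
            lat_0=0.5 * (lat_min + lat_max),
            lat_1=lat_min + span / 6.0,
            lat_2=lat_max - span / 6.0,
        )

    def __post_init__(self):
        phi1, phi2 = math.radians(self.lat_1), math.radians(self.lat_2)
        if abs(phi1 - phi2) < 1e-12:
            self._n = math.sin(phi1)
        else:
            self._n = 0.5 * (math.sin(phi1) + math.sin(phi2))
        if abs(self._n) < 1e-9:
            raise ValueError("degenerate Albers configuration: n ~ 0")
        self._C = math.cos(phi1) ** 2 + 2.0 * self._n * math.sin(phi1)
        self._rho0 = self._rho(math.radians(self.lat_0))

    def _rho(self, phi):
        return (
            EARTH_RADIUS_KM
            * np.sqrt(self._C - 2.0 * self._n * np.sin(phi))
            / self._n
        )

    def __call__(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon_0)
        phi = np.radians(np.asarray(lat, dtype=float))
        theta = self._n * lam
        rho = self._rho(phi)
        x = rho * np.sin(theta)
        y = self._rho0 - rho * np.cos(theta)
        return x, y

    def spec(self) -> dict:
        return {
            "name": self.name,
            "lon_0": self.lon_0,
            "lat_0": self.lat_0,
            "lat_1": self.lat_1,
            "lat_2": self.lat_2,
        }


@dataclass
class CylindricalEqualArea(EqualAreaProjection):
    """Lambert cylindrical equal-area projection (standard parallel lat_ts)."""

    lon_0: float = 0.0
    lat_ts: float = 0.0
    name: str = field(default="cylindrical_equal_area", init=False)

    def __call__(self, lon, lat):
        k = math.cos(math.radians(self.lat_ts))
        x = EARTH_RADIUS_KM * np.radians(np.asarray(lon, dtype=float) - self.lon_0) * k
        y = EARTH_RADIUS_KM * np.sin(np.radians(np.asarray(lat, dtype=float))) / k
        return x, y

    def spec(self) -> dict:
        return {"name": self.name, "lon_0": self.lon_0, "lat_ts": self.lat_ts}


@dataclass
class LinearTransform(EqualAreaProjection):
    """Affine lon/lat <-> km mapping used by synthetic worlds.

    Treats the synthetic extent as a small flat patch: one degree of
    longitude / latitude corresponds to a fixed number of kilometres.
    Exactly invertible, which keeps planted records and cleaning filters
    mutually consistent.
    """

    lon_0: float = 100.0
    lat_0: float = 20.0
    km_per_deg_lon: float = 104.65
    km_per_deg_lat: float = 110.57
    name: str = field(default="linear", init=False)

    def __call__(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.lon_0) * self.km_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat_0) * self.km_per_deg_lat
        return x, y

    def inverse(self, x, y):
        lon = np.asarray(x, dtype=float) / self.km_per_deg_lon + self.lon_0
        lat = np.asarray(y, dtype=float) / self.km_per_deg_lat + self.lat_0
        return lon, lat

    def spec(self) -> dict:
        return {
            "name": self.name,
            "lon_0": self.lon_0,
            "lat_0": self.lat_0,
            "km_per_deg_lon": self.km_per_deg_lon,
            "km_per_deg_lat": self.km_per_deg_lat,
        }


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class Grid:
    """Regular square-cell grid in projected km coordinates.

    Cell ids run row-major: ``cell_id = row * n_cols + col`` with row 0 at
    the bottom (minimum y).  All cells have identical area by construction.
    """

    n_cols: int
    n_rows: int
    cell_km: float
    x0: float = 0.0
    y0: float = 0.0
    land: np.ndarray | None = None  # flat bool, length n_cols * n_rows
    projection: EqualAreaProjection | None = None

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")
        if self.land is None:
            self.land = np.ones(self.n_cells, dtype=bool)
        else:
            self.land = np.asarray(self.land, dtype=bool).ravel()
            if self.land.size != self.n_cells:
                raise ValueError("land mask size does not match grid")

    # -- identity ----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def n_land(self) -> int:
        return int(self.land.sum())

    @property
    def land_cell_ids(self) -> np.ndarray:
        return np.flatnonzero(self.land)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_id(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    # -- geometry ----------------------------------------------------------
    def cell_polygon(self, cell_id: int):
        row, col = self.rowcol(cell_id)
        x = self.x0 + col * self.cell_km
        y = self.y0 + row * self.cell_km
        return box(x, y, x + self.cell_km, y + self.cell_km)

    def cell_center(self, cell_id):
        row, col = self.rowcol(cell_id)
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_km
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_km
        return x, y

    def cell_of_point(self, x, y) -> np.ndarray:
        """Map projected points to cell ids; -1 when off-grid.

        Cells are half-open with a lower-id tie break: a point lying
        exactly on a shared edge belongs to the cell with the lower id.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        fx = (x - self.x0) / self.cell_km
        fy = (y - self.y0) / self.cell_km
        finite = np.isfinite(fx) & np.isfinite(fy)
        fx = np.where(finite, fx, -1.0)
        fy = np.where(finite, fy, -1.0)
        col = np.floor(fx).astype(np.int64)
        row = np.floor(fy).astype(np.int64)
        # interior shared edges belong to the lower-index neighbour
        on_edge_x = (fx == col) & (col > 0)
        on_edge_y = (fy == row) & (row > 0)
        col = np.where(on_edge_x, col - 1, col)
        row = np.where(on_edge_y, row - 1, row)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(ok, row * self.n_cols + col, -1)
        return out

    def neighbors(self, cell_id: int) -> list[int]:
        """Rook-adjacent cell ids (used by spreading-dye growth)."""
        row, col = int(cell_id) // self.n_cols, int(cell_id) % self.n_cols
        out = []
        if row > 0:
            out.append(cell_id - self.n_cols)
        if row < self.n_rows - 1:
            out.append(cell_id + self.n_cols)
        if col > 0:
            out.append(cell_id - 1)
        if col < self.n_cols - 1:
            out.append(cell_id + 1)
        return out

    def land_union(self) -> BaseGeometry:
        """Union polygon of all land cells, in projected km coordinates."""
        from shapely.ops import unary_union

        return unary_union([self.cell_polygon(int(c)) for c in self.land_cell_ids])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "cell_km": self.cell_km,
            "x0": self.x0,
            "y0": self.y0,
            "land": self.land.astype(int).tolist(),
            "projection": self.projection.spec() if self.projection else None,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        proj = None
        ps = d.get("projection")
        if ps:
            name = ps.get("name")
            if name == "albers_equal_area":
                proj = AlbersEqualArea(ps["lon_0"], ps["lat_0"], ps["lat_1"], ps["lat_2"])
            elif name == "cylindrical_equal_area":
                proj = CylindricalEqualArea(ps["lon_0"], ps["lat_ts"])
            elif name == "linear":
                proj = LinearTransform(
                    ps["lon_0"], ps["lat_0"], ps["km_per_deg_lon"], ps["km_per_deg_lat"]
                )
        return cls(
            n_cols=d["n_cols"],
            n_rows=d["n_rows"],
            cell_km=d["cell_km"],
            x0=d["x0"],
            y0=d["y0"],
            land=np.asarray(d["land"], dtype=bool),
            projection=proj,
        )

    @classmethod
    def read(cls, path) -> "Grid":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_geojson(self, path) -> None:
        """Write land cells as a GeoJSON FeatureCollection (km coordinates)."""
        feats = []
        for cid in self.land_cell_ids:
            poly = self.cell_polygon(int(cid))
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": int(cid)},
                    "geometry": poly.__geo_interface__,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def build_grid(
    extent_deg: tuple[float, float, float, float],
    cell_km: float,
    land_polygon_deg: BaseGeometry | None = None,
    projection: EqualAreaProjection | None = None,
) -> Grid:
    """Tile the projected extent with equal-area square cells.

    Parameters
    ----------
    extent_deg
        (lon_min, lat_min, lon_max, lat_max) in decimal degrees.
    cell_km
        Cell edge length in kilometres.
    land_polygon_deg
        Optional land polygon in degrees; cells intersecting it with
        positive area are flagged as land.  Without it every cell is land.
    projection
        Equal-area projection; defaults to an Albers conic configured from
        the extent.
    """
    lon_min, lat_min, lon_max, lat_max = extent_deg
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate extent")
    if cell_km <= 0:
        raise ValueError("cell size must be positive")
    if projection is None:
        projection = AlbersEqualArea.from_extent(lon_min, lat_min, lon_max, lat_max)

    corners_lon = np.array([lon_min, lon_max, lon_min, lon_max])
    corners_lat = np.array([lat_min, lat_min, lat_max, lat_max])
    cx, cy = projection(corners_lon, corners_lat)
    x0, y0 = float(cx.min()), float(cy.min())
    n_cols = max(2, math.ceil((float(cx.max()) - x0) / cell_km))
    n_rows = max(2, math.ceil((float(cy.max()) - y0) / cell_km))
    grid = Grid(n_cols=n_cols, n_rows=n_rows, cell_km=cell_km, x0=x0, y0=y0,
                projection=projection)

    if land_polygon_deg is not None:
        land_proj = shp_transform(
            lambda lon, lat: projection(np.asarray(lon), np.asarray(lat)),
            land_polygon_deg,
        )
        prepared = prep(land_proj)
        mask = np.zeros(grid.n_cells, dtype=bool)
        for cid in range(grid.n_cells):
            cell = grid.cell_polygon(cid)
            if prepared.intersects(cell) and land_proj.intersection(cell).area > 0:
                mask[cid] = True
        grid.land = mask
    return grid
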