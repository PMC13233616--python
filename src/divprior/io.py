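"""Plain-text readers/writers for rasters and vector layers.

Rasters use the ESRI ASCII grid format (one header block + whitespace-
separated rows); vector layers use GeoJSON.  Both are deliberately
text-based so generated worlds round-trip through ordinary files.
"""

from __future__ import annotations

import json

import numpy as np
from shapely.geometry import shape

NODATA = -9999.0


def write_ascii_grid(path, grid, values: np.ndarray) -> None:
    """Write a full-grid value array (row-major, row 0 = bottom) as ESRI ASCII.

    NaNs become the NODATA value.  Rows are written top-down as the format
    requires.
    """
    vals = np.asarray(values, dtype=float).reshape(grid.n_rows, grid.n_cols)
    out = np.where(np.isnan(vals), NODATA, vals)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x0}\n")
        fh.write(f"yllcorner {grid.y0}\n")
        fh.write(f"cellsize {grid.cell_km}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for r in range(grid.n_rows - 1, -1, -1):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_ascii_grid(path) -> tuple[dict, np.ndarray]:
    """Read an ESRI ASCII grid; returns (header dict, flat row-major array)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    arr = np.array(rows[::-1], dtype=float)  # back to row 0 = bottom
    arr[arr == header.get("nodata_value", NODATA)] = np.nan
    return header, arr.ravel()


def write_geojson(path, geometries, properties) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": props,
            "geometry": geom.__geo_interface__,
        }
        for geom, props in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path):
    """Returns a list of (shapely geometry, properties dict)."""
    with open(path) as fh:
        fc = json.load(fh)
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]
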