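"""Synthetic worlds with known ground truth.

Generates every input the pipeline consumes — a contiguous land mask,
spreading-dye species ranges along a richness gradient, occurrence records
with planted dirty records (each violating exactly one cleaning filter),
species traits, a Yule phylogeny, block-structured use matrices,
rectangular reserve layers of configurable coverage, and smooth climate
predictor rasters with an engineered collinear pair.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

from . import io as _io
from .conservation import Reserve, ReserveLayer, protection_status
from .grid import Grid, LinearTransform

THREAT_CATEGORIES = ("CR", "EN", "VU")


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def make_landscape(
    n_cols: int,
    n_rows: int,
    cell_km: float = 50.0,
    sea_fraction: float = 0.0,
    seed: int = 0,
) -> Grid:
    """Grid with a contiguous land mask of ceil((1 - sea_fraction) * N) cells.

    Land is grown by spreading dye from a random seed cell, so it is always
    one rook-connected component.  The grid carries a linear lon/lat
    transform so records have plausible geographic coordinates.
    """
    if n_cols < 2 or n_rows < 2:
        raise ValueError("grid dimensions must be at least 2 x 2")
    if not 0 <= sea_fraction < 1:
        raise ValueError("sea fraction must lie in [0, 1)")
    n_cells = n_cols * n_rows
    n_land = int(np.ceil((1.0 - sea_fraction) * n_cells))
    grid = Grid(
        n_cols=n_cols,
        n_rows=n_rows,
        cell_km=cell_km,
        projection=LinearTransform(),
    )
    rng = np.random.default_rng(seed)
    land = np.zeros(n_cells, dtype=bool)
    start = int(rng.integers(n_cells))
    land[start] = True
    frontier = set(grid.neighbors(start))
    while land.sum() < n_land:
        choices = sorted(frontier)
        pick = int(choices[rng.integers(len(choices))])
        land[pick] = True
        frontier.discard(pick)
        for nb in grid.neighbors(pick):
            if not land[nb]:
                frontier.add(nb)
    grid.land = land
    return grid


def lonlat_of_cells(grid: Grid, cell_ids) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre lon/lat through the grid's linear transform."""
    x, y = grid.cell_center(np.asarray(cell_ids))
    return grid.projection.inverse(x, y)


def land_polygon_lonlat(grid: Grid):
    """Union of land-cell boxes mapped to lon/lat (linear transforms map
    rectangles to rectangles)."""
    tf: LinearTransform = grid.projection
    boxes = []
    for cid in grid.land_cell_ids:
        poly = grid.cell_polygon(int(cid))
        x0, y0, x1, y1 = poly.bounds
        lon0, lat0 = tf.inverse(x0, y0)
        lon1, lat1 = tf.inverse(x1, y1)
        boxes.append(box(float(lon0), float(lat0), float(lon1), float(lat1)))
    return unary_union(boxes)


# ---------------------------------------------------------------------------
# Species ranges + occurrences
# ---------------------------------------------------------------------------


def _draw_range_sizes(rng, n_species: int, dist: dict, n_land: int) -> np.ndarray:
    kind = dist.get("kind", "lognormal")
    if kind == "lognormal":
        raw = np.exp(rng.normal(dist.get("mu", 2.0), dist.get("sigma", 1.0), n_species))
        sizes = np.rint(raw).astype(int)
    elif kind == "logseries":
        from scipy.stats import logser

        sizes = logser.rvs(dist.get("p", 0.9), size=n_species, random_state=rng)
        sizes = np.asarray(sizes, dtype=int)
    else:
        raise ValueError(f"unknown range-size distribution {kind!r}")
    sizes = np.clip(sizes, 1, n_land)
    if np.any(sizes > n_land):
        raise ValueError("range size exceeds land area")
    return sizes


def _gradient_weights(grid: Grid, direction: tuple[float, float], strength: float):
    """Per-land-cell seed weights increasing along the gradient direction."""
    cells = grid.land_cell_ids
    x, y = grid.cell_center(cells)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0 or strength == 0:
        return np.ones(len(cells)) / len(cells), np.zeros(len(cells))
    t = (x * d[0] + y * d[1]) / norm
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    w = np.exp(strength * t)
    return w / w.sum(), t


def _spread_dye(grid: Grid, rng, seed_cell: int, size: int,
                allowed: np.ndarray) -> list[int]:
    """Grow a connected cell set of ``size`` cells from ``seed_cell``,
    choosing uniformly among the frontier, restricted to ``allowed`` cells."""
    chosen = {int(seed_cell)}
    frontier = {
        nb for nb in grid.neighbors(int(seed_cell))
        if allowed[nb] and grid.land[nb]
    }
    while len(chosen) < size and frontier:
        opts = sorted(frontier)
        pick = int(opts[rng.integers(len(opts))])
        chosen.add(pick)
        frontier.discard(pick)
        for nb in grid.neighbors(pick):
            if allowed[nb] and grid.land[nb] and nb not in chosen:
                frontier.add(nb)
    return sorted(chosen)


def _jitter_point(rng, grid: Grid, cell_id: int) -> tuple[float, float]:
    """Random lon/lat strictly inside the cell, avoiding filter triggers."""
    row, col = grid.rowcol(int(cell_id))
    tf: LinearTransform = grid.projection
    for _ in range(64):
        u, v = rng.uniform(0.05, 0.95, size=2)
        x = grid.x0 + (col + u) * grid.cell_km
        y = grid.y0 + (row + v) * grid.cell_km
        lon, lat = tf.inverse(x, y)
        lon, lat = float(lon), float(lat)
        if lat == lon or lat == 0.0 or lon == 0.0:
            continue
        if lat == np.floor(lat) and lon == np.floor(lon):
            continue
        return lon, lat
    raise RuntimeError("could not draw a clean coordinate")  # pragma: no cover


def simulate_species_ranges(
    grid: Grid,
    n_species: int,
    range_size_distribution: dict | None = None,
    richness_gradient: dict | None = None,
    endemic_fraction: float = 0.3,
    threatened_fraction: float = 0.1,
    protected_fraction: float = 0.1,
    records_per_cell: float = 3.0,
    corrupt_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[int]]]:
    """Simulate ranges, traits, and occurrence records.

    Returns (species_table, occurrences, true_ranges).  Occurrence rows
    carry hidden ``valid`` labels and, for corrupted rows, the planted
    filter id (1-5).  Corruption touches one filter per record and never
    the last valid record of a species.
    """
    for f in (endemic_fraction, threatened_fraction, protected_fraction,
              corrupt_fraction):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if n_species < 1:
        raise ValueError("need at least one species")
    dist = range_size_distribution or {"kind": "lognormal", "mu": 2.0, "sigma": 1.0}
    gradient = richness_gradient or {"direction": (1.0, 0.5), "strength": 2.0}
    rng = np.random.default_rng(seed)
    land_cells = grid.land_cell_ids
    n_land = len(land_cells)
    sizes = _draw_range_sizes(rng, n_species, dist, n_land)

    weights, t = _gradient_weights(
        grid, tuple(gradient.get("direction", (1.0, 0.0))),
        float(gradient.get("strength", 0.0)),
    )
    # designated endemism sub-region: land cells in the gradient-high half
    if t.max() > 0:
        sub_mask_land = t >= np.median(t)
    else:
        x, _ = grid.cell_center(land_cells)
        sub_mask_land = x <= np.median(x)
    subregion = np.zeros(grid.n_cells, dtype=bool)
    subregion[land_cells[sub_mask_land]] = True
    all_allowed = np.ones(grid.n_cells, dtype=bool)

    species_ids = [f"sp{i:04d}" for i in range(n_species)]
    n_endemic_target = int(round(endemic_fraction * n_species))
    sub_cells = land_cells[sub_mask_land]
    sub_weights = weights[sub_mask_land]
    sub_weights = sub_weights / sub_weights.sum()

    ranges: dict[str, list[int]] = {}
    for i, sp in enumerate(species_ids):
        restrict = i < n_endemic_target
        if restrict:
            size = min(int(sizes[i]), len(sub_cells))
            seed_cell = int(rng.choice(sub_cells, p=sub_weights))
            allowed = subregion
        else:
            size = int(sizes[i])
            seed_cell = int(rng.choice(land_cells, p=weights))
            allowed = all_allowed
        ranges[sp] = _spread_dye(grid, rng, seed_cell, size, allowed)

    endemic = np.array(
        [all(subregion[c] for c in ranges[sp]) for sp in species_ids]
    )
    n_threat = int(round(threatened_fraction * n_species))
    threat = np.array(["none"] * n_species, dtype=object)
    threat_idx = rng.choice(n_species, size=n_threat, replace=False)
    threat[threat_idx] = rng.choice(THREAT_CATEGORIES, size=n_threat)
    protected = np.zeros(n_species, dtype=bool)
    n_prot = int(round(protected_fraction * n_species))
    protected[rng.choice(n_species, size=n_prot, replace=False)] = True

    species_table = pd.DataFrame(
        {
            "species": species_ids,
            "range_size": [len(ranges[s]) for s in species_ids],
            "endemic": endemic,
            "threat": threat,
            "threatened": threat != "none",
            "protected": protected,
        }
    )

    # --- occurrence records -------------------------------------------------
    rows = []
    for sp in species_ids:
        cells = ranges[sp]
        lam = records_per_cell * len(cells)
        n_rec = max(1, int(rng.poisson(lam)))
        rec_cells = rng.choice(cells, size=n_rec, replace=True)
        for c in rec_cells:
            lon, lat = _jitter_point(rng, grid, int(c))
            rows.append((sp, lat, lon, f"cell-{int(c)}", True, 0))
    occ = pd.DataFrame(
        rows,
        columns=["species", "latitude", "longitude", "locality", "valid",
                 "planted_filter"],
    )

    if corrupt_fraction > 0:
        occ = _corrupt_records(occ, grid, ranges, corrupt_fraction, rng)
    return species_table, occ, ranges


def _corrupt_records(occ, grid, ranges, corrupt_fraction, rng):
    sea_cells = np.flatnonzero(~grid.land)
    land_set = set(int(c) for c in grid.land_cell_ids)
    n_corrupt = int(np.floor(corrupt_fraction * len(occ)))
    # never corrupt a species' last record
    per_species = occ.groupby("species").size()
    eligible = np.array(
        [i for i in range(len(occ)) if per_species[occ.at[i, "species"]] > 1]
    )
    budget = {sp: int(cnt) - 1 for sp, cnt in per_species.items()}
    rng.shuffle(eligible)
    filters = [1, 2, 3, 4, 5]
    fcycle = 0
    corrupted = 0
    for i in eligible:
        if corrupted >= n_corrupt:
            break
        sp = occ.at[i, "species"]
        if budget[sp] <= 0:
            continue
        f = filters[fcycle % len(filters)]
        if f == 4 and len(sea_cells) == 0:
            fcycle += 1
            f = filters[fcycle % len(filters)]
        if f == 5:
            outside = sorted(land_set - set(ranges[sp]))
            if not outside:
                fcycle += 1
                f = filters[fcycle % len(filters)]
        lat = float(occ.at[i, "latitude"])
        lon = float(occ.at[i, "longitude"])
        if f == 1:
            occ.at[i, "latitude"] = np.nan
        elif f == 2:
            occ.at[i, "longitude"] = lat
        elif f == 3:
            if rng.random() < 0.5:
                occ.at[i, "latitude"] = 0.0
            else:
                la, lo = float(np.floor(lat)), float(np.floor(lon))
                if la == lo:
                    lo += 1.0
                occ.at[i, "latitude"] = la
                occ.at[i, "longitude"] = lo
        elif f == 4:
            c = int(sea_cells[rng.integers(len(sea_cells))])
            nlon, nlat = _jitter_point(rng, grid, c)
            occ.at[i, "latitude"] = nlat
            occ.at[i, "longitude"] = nlon
        elif f == 5:
            outside = sorted(land_set - set(ranges[sp]))
            c = int(outside[rng.integers(len(outside))])
            nlon, nlat = _jitter_point(rng, grid, c)
            occ.at[i, "latitude"] = nlat
            occ.at[i, "longitude"] = nlon
        occ.at[i, "valid"] = False
        occ.at[i, "planted_filter"] = f
        budget[sp] -= 1
        corrupted += 1
        fcycle += 1
    return occ


def native_range_polygons(grid: Grid, ranges: dict[str, list[int]]) -> dict:
    """Per-species lon/lat polygon: union of true-range cell boxes."""
    tf: LinearTransform = grid.projection
    out = {}
    for sp, cells in ranges.items():
        boxes = []
        for c in cells:
            x0, y0, x1, y1 = grid.cell_polygon(int(c)).bounds
            lon0, lat0 = tf.inverse(x0, y0)
            lon1, lat1 = tf.inverse(x1, y1)
            boxes.append(box(float(lon0), float(lat0), float(lon1), float(lat1)))
        out[sp] = unary_union(boxes)
    return out


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


def simulate_phylogeny(species_ids: list[str], birth_rate: float = 1.0,
                       seed: int = 0) -> str:
    """Pure-birth (Yule) tree over the given species ids, as Newick."""
    if len(species_ids) < 2:
        raise ValueError("need at least 2 species")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=len(species_ids),
        rng=rng,
    )
    # the simulator stops at the nth speciation, so the newest tips have
    # zero-length edges; extend every tip by one shared waiting time to the
    # next (unrealized) event, keeping the tree ultrametric
    extra = rng.expovariate(birth_rate * len(species_ids))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for leaf, sp in zip(tree.leaf_node_iter(), species_ids):
        leaf.taxon.label = sp
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Use matrix
# ---------------------------------------------------------------------------


def simulate_use_matrix(
    species_ids: list[str],
    n_groups: int,
    block_plan: list[tuple[list[int], list[int], float]] | None = None,
    background_probability: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary use matrix with planted group/species blocks.

    ``block_plan`` is a list of (group indices, species indices, p); within
    a block each entry is 1 with probability p, elsewhere with the
    background probability.  All-zero species rows are resampled (or, when
    every probability in the row is zero, given a single uniformly random
    use so the no-all-zero-row invariant holds).  Returns (matrix, labels)
    where labels records each species' planted block (-1 = background).
    """
    if not 0 <= background_probability <= 1:
        raise ValueError("background probability must lie in [0, 1]")
    block_plan = block_plan or []
    for groups, spp, p in block_plan:
        if len(groups) == 0 or len(spp) == 0:
            raise ValueError("empty block in plan")
        if not 0 <= p <= 1:
            raise ValueError("block probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    S, G = len(species_ids), n_groups
    prob = np.full((S, G), background_probability, dtype=float)
    block_of = np.full(S, -1, dtype=int)
    for b, (groups, spp, p) in enumerate(block_plan):
        for s in spp:
            block_of[s] = b
            for g in groups:
                prob[s, g] = p
    M = (rng.random((S, G)) < prob).astype(int)
    for s in range(S):
        if M[s].sum() == 0:
            if prob[s].sum() == 0:
                M[s, rng.integers(G)] = 1
            else:
                while M[s].sum() == 0:
                    M[s] = (rng.random(G) < prob[s]).astype(int)
    groups = [f"G{j:02d}" for j in range(G)]
    matrix = pd.DataFrame(M, index=species_ids, columns=groups)
    labels = pd.DataFrame({"species": species_ids, "block": block_of})
    return matrix, labels


# ---------------------------------------------------------------------------
# Reserves
# ---------------------------------------------------------------------------


def simulate_reserves(
    grid: Grid,
    n_nnr: int,
    n_pnr: int,
    target_coverage: float,
    seed: int = 0,
    max_iter: int = 30,
) -> ReserveLayer:
    """Random axis-aligned reserve rectangles calibrated so the realized
    covered-land-cell fraction lands within +/-20% (relative) of target."""
    if not 0 <= target_coverage <= 1:
        raise ValueError("target coverage must lie in [0, 1]")
    m = n_nnr + n_pnr
    if target_coverage == 0 or m == 0:
        return ReserveLayer([])
    rng = np.random.default_rng(seed)
    land_cells = grid.land_cell_ids
    n_land = len(land_cells)
    cell_area = grid.cell_km**2
    # initial per-rectangle area, inflated for expected overlap
    total_target = target_coverage * n_land * cell_area
    scale = 1.3
    best = None
    for _ in range(max_iter):
        rects = []
        centers = rng.choice(land_cells, size=m, replace=True)
        aspects = rng.uniform(0.5, 2.0, size=m)
        areas = rng.uniform(0.5, 1.5, size=m) * (scale * total_target / m)
        for c, asp, area in zip(centers, aspects, areas):
            cx, cy = grid.cell_center(int(c))
            w = float(np.sqrt(area * asp))
            h = float(area / w)
            rects.append(box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
        classes = ["NNR"] * n_nnr + ["PNR"] * n_pnr
        layer = ReserveLayer(
            [Reserve(r, c) for r, c in zip(rects, classes)]
        )
        status = protection_status(grid, layer)
        realized = status.either.sum() / n_land
        err = abs(realized - target_coverage) / target_coverage
        if best is None or err < best[0]:
            best = (err, layer)
        if err <= 0.1:
            return layer
        scale *= np.clip(target_coverage / max(realized, 1e-9), 0.5, 2.0)
    return best[1]


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


def simulate_climate(
    grid: Grid,
    predictor_names: list[str],
    scenario_offsets: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    gradient_strength: float = 1.0,
    noise_sigma: float = 0.3,
    smooth: float = 1.5,
    collinear_jitter: float = 0.02,
    engineer_collinear_pair: bool = True,
) -> dict[str, dict[str, np.ndarray]]:
    """Predictor rasters per scenario: smooth gradient + autocorrelated
    noise, full-grid arrays (NaN on sea).

    With >= 2 predictors and ``engineer_collinear_pair``, the second
    predictor is a jittered copy of the first, guaranteeing one pair with
    |r| > 0.85 for screening tests.  Scenario values are the current field
    plus the stated additive offsets.
    """
    if len(predictor_names) < 1:
        raise ValueError("need at least one predictor")
    rng = np.random.default_rng(seed)
    shape = (grid.n_rows, grid.n_cols)
    xs = np.linspace(0, 1, grid.n_cols)[None, :].repeat(grid.n_rows, axis=0)
    ys = np.linspace(0, 1, grid.n_rows)[:, None].repeat(grid.n_cols, axis=1)

    current: dict[str, np.ndarray] = {}
    for k, name in enumerate(predictor_names):
        if engineer_collinear_pair and k == 1 and len(predictor_names) >= 2:
            base = current[predictor_names[0]].copy()
            jitter = collinear_jitter * rng.standard_normal(grid.n_cells)
            field_vals = base + jitter
        else:
            a, b = rng.uniform(-1, 1, size=2)
            grad = gradient_strength * (a * xs + b * ys)
            noise = rng.standard_normal(shape) * noise_sigma
            if smooth > 0:
                noise = gaussian_filter(noise, sigma=smooth)
            field_vals = (grad + noise).ravel()
        vals = np.where(grid.land, field_vals, np.nan)
        current[name] = vals

    out = {"current": current}
    for scenario, offsets in (scenario_offsets or {}).items():
        layer = {}
        for name in predictor_names:
            off = offsets.get(name, 0.0)
            if isinstance(off, (tuple, list)):  # (additive, multiplicative)
                add, mult = float(off[0]), float(off[1])
            else:
                add, mult = float(off), 1.0
            layer[name] = current[name] * mult + add
        out[scenario] = layer
    return out


def predictors_as_frame(
    climate: dict[str, dict[str, np.ndarray]], grid: Grid, scenario: str,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Land-cell table (index = cell id) of predictor values for a scenario."""
    layer = climate[scenario]
    names = names or list(layer)
    cells = grid.land_cell_ids
    return pd.DataFrame(
        {n: layer[n][cells] for n in names}, index=cells
    )


# ---------------------------------------------------------------------------
# World bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    grid: Grid
    species_table: pd.DataFrame
    occurrences: pd.DataFrame
    true_ranges: dict[str, list[int]]
    phylogeny: str
    use_matrix: pd.DataFrame
    use_blocks: pd.DataFrame
    reserves: ReserveLayer
    climate: dict[str, dict[str, np.ndarray]]
    rng_seed: int
    params: dict = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return list(self.species_table["species"])

    def native_ranges(self) -> dict:
        return native_range_polygons(self.grid, self.true_ranges)

    def land_polygon(self):
        return land_polygon_lonlat(self.grid)

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.grid.write(d / "grid.json")
        self.occurrences.drop(columns=["valid", "planted_filter"]).to_csv(
            d / "occurrences.csv", index=False
        )
        self.occurrences[["valid", "planted_filter"]].to_csv(
            d / "occurrence_validity.csv", index=False
        )
        self.species_table.to_csv(d / "traits.csv", index=False)
        (d / "phylogeny.nwk").write_text(self.phylogeny + "\n")
        self.use_matrix.to_csv(d / "use_matrix.csv")
        self.reserves.write(d / "reserves.geojson")
        cdir = d / "climate"
        cdir.mkdir(exist_ok=True)
        artifacts = []
        for scenario, layer in self.climate.items():
            for name, vals in layer.items():
                p = cdir / f"{scenario}_{name}.asc"
                _io.write_ascii_grid(p, self.grid, vals)
                artifacts.append(str(p.relative_to(d)))
        manifest = {
            "seed": self.rng_seed,
            "params": self.params,
            "artifacts": [
                "grid.json", "occurrences.csv", "occurrence_validity.csv",
                "traits.csv", "phylogeny.nwk", "use_matrix.csv",
                "reserves.geojson", *artifacts,
            ],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_world(
    n_cols: int = 18,
    n_rows: int = 15,
    cell_km: float = 50.0,
    sea_fraction: float = 0.2,
    n_species: int = 60,
    corrupt_fraction: float = 0.1,
    n_groups: int = 8,
    n_nnr: int = 4,
    n_pnr: int = 7,
    reserve_coverage: float = 0.35,
    predictor_names: tuple[str, ...] = ("bio1", "bio1_dup", "bio12", "alt"),
    scenario_offsets: dict | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    """Convenience bundle: one seed drives every generator deterministically."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]
    grid = make_landscape(n_cols, n_rows, cell_km, sea_fraction, seed=seeds[0])
    species_table, occ, ranges = simulate_species_ranges(
        grid, n_species, corrupt_fraction=corrupt_fraction, seed=seeds[1]
    )
    species_ids = list(species_table["species"])
    newick = simulate_phylogeny(species_ids, birth_rate=1.0, seed=seeds[2])
    half = n_groups // 2
    blocks = [
        (list(range(half)), list(range(n_species // 2)), 0.6),
        (list(range(half, n_groups)), list(range(n_species // 2, n_species)), 0.6),
    ]
    use_matrix, use_blocks = simulate_use_matrix(
        species_ids, n_groups, blocks, background_probability=0.05, seed=seeds[3]
    )
    reserves = simulate_reserves(grid, n_nnr, n_pnr, reserve_coverage, seed=seeds[4])
    offsets = scenario_offsets
    if offsets is None:
        offsets = {"RCP4.5": {n: 0.5 for n in predictor_names}}
    climate = simulate_climate(
        grid, list(predictor_names), offsets, seed=seeds[5]
    )
    return SyntheticWorld(
        grid=grid,
        species_table=species_table,
        occurrences=occ,
        true_ranges=ranges,
        phylogeny=newick,
        use_matrix=use_matrix,
        use_blocks=use_blocks,
        reserves=reserves,
        climate=climate,
        rng_seed=seed,
        params={
            "n_cols": n_cols, "n_rows": n_rows, "cell_km": cell_km,
            "sea_fraction": sea_fraction, "n_species": n_species,
            "corrupt_fraction": corrupt_fraction, "n_groups": n_groups,
            "n_nnr": n_nnr, "n_pnr": n_pnr,
            "reserve_coverage": reserve_coverage,
        },
    )
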