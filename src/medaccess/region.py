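"""Seeded synthetic coastal regions for accessibility analysis.

The generator builds a peninsula that carries the statistical and topological
structure the downstream analysis assumes: a fast north-south spine road along
a low ridge, slower branching secondary and local roads, pharmacies
concentrated on the spine plus two coastal towns, a handful of drone stations,
a low-lying flood-prone western fringe, one road-disconnected island (whose
residents cannot drive to any pharmacy), one circular no-fly zone, census
blocks with a realistic 60+ age share, parcels, and building footprints.

Every layer draws from its own random stream split from the master seed, so
regenerating one layer never perturbs another and a fixed seed reproduces the
region byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .grid import Grid, make_grid, mask_to_polygons

# Land-cover codes. Only the zero-density / non-zero distinction matters for
# dasymetric mapping; the code set mirrors the broad classes of a national
# land-cover product.
LC_WATER = 11
LC_DEVELOPED = 21
LC_FOREST = 41
LC_CROPLAND = 81
LC_WETLAND = 90

DEFAULT_ZERO_CLASSES = frozenset({LC_WATER, LC_WETLAND})


class ConfigurationError(ValueError):
    """Raised for invalid region configurations."""


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic coastal region.

    Defaults describe a 12 km x 30 km peninsula: ~120 census blocks whose
    60+ population share follows Beta(4.3, 15.7) (mean 0.215, matching the
    study region's elderly share), seven pharmacies (five on the spine, two
    in coastal towns), four drone stations on the spine numbered north to
    south, a flood threshold of 2 m above sea level that inundates the
    western fringe, one no-fly circle over the northeastern coastal town,
    and one offshore island with no road connection to the mainland.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 16_000.0, 60_000.0)
    n_blocks: int = 120
    pop_mean: float = 85.0  # Poisson mean of block population
    pct60_beta: tuple[float, float] = (4.3, 15.7)  # mean 0.215
    n_pharmacies_spine: int = 5
    n_pharmacies_coastal: int = 2
    n_stations: int = 4
    flood_elevation_m: float = 2.0
    nofly_center: tuple[float, float] | None = None  # default: NE coastal town
    nofly_radius_m: float = 2_500.0
    island: bool = True
    # 55 / 30 / 20 mph
    speeds_mps_by_level: dict[int, float] = field(
        default_factory=lambda: {1: 24.6, 2: 13.4, 3: 8.9}
    )
    buildings_per_block: tuple[int, int] = (6, 18)  # uniform inclusive range
    cell_m: float = 30.0  # raster resolution for elevation / land cover

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ConfigurationError("extent must have positive area")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if any(s <= 0 for s in self.speeds_mps_by_level.values()):
            raise ConfigurationError("speeds must be positive")
        if self.cell_m <= 0:
            raise ConfigurationError("cell_m must be positive")


@dataclass
class SyntheticRegion:
    """All layers of a generated region, in one projected meter CRS."""

    config: RegionConfig
    roads: pd.DataFrame        # geometry (2-pt LineString), length_m, speed_mps, level
    blocks: pd.DataFrame       # block_id, geometry, pop_total, pop_60plus, is_island
    parcels: pd.DataFrame      # parcel_id, block_id, geometry, landuse
    buildings: pd.DataFrame    # building_id, parcel_id, block_id, geometry, is_primary
    pharmacies: pd.DataFrame   # pharmacy_id, geometry
    stations: pd.DataFrame     # station_id, geometry (ids ordered north->south)
    flood_zones: list          # shapely Polygons
    nofly_zones: list          # shapely Polygons
    landcover: Grid
    elevation: Grid
    mainland: Polygon = None
    island_poly: Polygon | None = None

    def copy(self) -> "SyntheticRegion":
        return SyntheticRegion(
            config=self.config,
            roads=self.roads.copy(),
            blocks=self.blocks.copy(),
            parcels=self.parcels.copy(),
            buildings=self.buildings.copy(),
            pharmacies=self.pharmacies.copy(),
            stations=self.stations.copy(),
            flood_zones=list(self.flood_zones),
            nofly_zones=list(self.nofly_zones),
            landcover=self.landcover.like(self.landcover.data.copy()),
            elevation=self.elevation.like(self.elevation.data.copy()),
            mainland=self.mainland,
            island_poly=self.island_poly,
        )


# ----------------------------------------------------------------------
# geometry helpers


def _segmentize(p0, p1, step=1000.0):
    """Straight 2-point segments from p0 to p1, nodes every ~step meters."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(1, int(round(length / step)))
    pts = [p0 + (p1 - p0) * t for t in np.linspace(0.0, 1.0, n + 1)]
    return [LineString([pts[i], pts[i + 1]]) for i in range(n)]


def _banded_partition(rect: tuple[float, float, float, float], n: int):
    """Partition a rectangle into exactly n sub-rectangles.

    Splits the rectangle into horizontal bands and each band into columns so
    that counts sum to n; bands/columns are chosen to keep cells roughly
    square. Exact partition (no gaps, no overlaps).
    """
    xmin, ymin, xmax, ymax = rect
    w, h = xmax - xmin, ymax - ymin
    n_bands = max(1, int(round(np.sqrt(n * h / w))))
    n_bands = min(n_bands, n)
    base, extra = divmod(n, n_bands)
    cols_per_band = [base + (1 if i < extra else 0) for i in range(n_bands)]
    ys = np.linspace(ymin, ymax, n_bands + 1)
    polys = []
    for i, ncols in enumerate(cols_per_band):
        xs = np.linspace(xmin, xmax, ncols + 1)
        for j in range(ncols):
            polys.append(box(xs[j], ys[i], xs[j + 1], ys[i + 1]))
    return polys


# ----------------------------------------------------------------------
# layer builders


def _elevation_surface(cfg: RegionConfig, x_spine: float, x_coast: float,
                       rng: np.random.Generator) -> Grid:
    """Smooth ridge along the spine, peaking at 17 m, dropping to sea level
    at both shores (faster to the west so the western fringe is low-lying),
    plus coarse correlated noise."""
    xmin, ymin, xmax, ymax = cfg.extent
    g = make_grid(cfg.extent, cfg.cell_m)
    xx, yy = np.meshgrid(g.xs(), g.ys())
    sigma_w = (x_spine - x_coast) / 1.5
    sigma_e = (xmax - x_spine) / 2.2
    sigma = np.where(xx < x_spine, sigma_w, sigma_e)
    ridge = 17.0 * np.exp(-(((xx - x_spine) / sigma) ** 2))
    # gentle along-shore undulation so flood fringes are patchy
    wave = 1.2 * np.sin(2 * np.pi * yy / 9_000.0 + 0.7)
    coarse = rng.normal(0.0, 0.8, size=(g.nrows // 12 + 2, g.ncols // 12 + 2))
    noise = np.kron(coarse, np.ones((12, 12)))[: g.nrows, : g.ncols]
    elev = ridge + wave + noise
    # open water west of the coastline sits below sea level
    elev = np.where(xx < x_coast, -1.0, np.maximum(elev, 0.0))
    return g.like(elev)


def _build_roads(cfg: RegionConfig, x_spine: float, x_coast: float,
                 rng: np.random.Generator):
    """Spine + comb of secondary connectors + local links, as 2-pt segments.

    All layers share a 1000-m node lattice anchored at the spine, so
    crossings are real graph nodes and the mainland network is connected.
    """
    xmin, ymin, xmax, ymax = cfg.extent
    speeds = cfg.speeds_mps_by_level
    segs: list[tuple[LineString, int]] = []

    # Level 1 spine: runs the full length of the peninsula along the ridge.
    for s in _segmentize((x_spine, ymin), (x_spine, ymax)):
        segs.append((s, 1))

    # Level 2 connectors: east-west arteries every 3 km at lattice rows,
    # spanning from near the west shore to the east shore across the spine.
    y_connectors = np.arange(ymin + 2_000.0, ymax - 500.0, 3_000.0)
    k_west = int((x_spine - (x_coast + 300.0)) // 1000)
    k_east = int((xmax - 200.0 - x_spine) // 1000)
    x_west = x_spine - 1000.0 * k_west
    x_east = x_spine + 1000.0 * k_east
    for yc in y_connectors:
        for s in _segmentize((x_west, yc), (x_spine, yc)):
            segs.append((s, 2))
        for s in _segmentize((x_spine, yc), (x_east, yc)):
            segs.append((s, 2))

    # Level 3 locals: north-south links between adjacent connectors at
    # lattice offsets from the spine; a random subset is dropped for
    # irregularity.
    x_locals = [x_spine + 1000.0 * k
                for k in (-6, -4, -2, 2, 4, 6)
                if x_west <= x_spine + 1000.0 * k <= x_east]
    for xl in x_locals:
        for i in range(len(y_connectors) - 1):
            if rng.random() < 0.25:
                continue  # missing link
            for s in _segmentize((xl, y_connectors[i]), (xl, y_connectors[i + 1])):
                segs.append((s, 3))

    rows = []
    for geom, level in segs:
        rows.append(
            {
                "geometry": geom,
                "length_m": geom.length,
                "speed_mps": speeds[level],
                "level": level,
            }
        )
    return pd.DataFrame(rows), y_connectors, x_east


def _island_layers(cfg: RegionConfig, rng: np.random.Generator):
    """A small square island in the western bay with a local road cross."""
    xmin, ymin, xmax, ymax = cfg.extent
    w = xmax - xmin
    h = ymax - ymin
    cx, cy = xmin + 0.07 * w, ymin + 0.72 * h
    half = 400.0
    poly = box(cx - half, cy - half, cx + half, cy + half)
    speeds = cfg.speeds_mps_by_level
    road_rows = []
    for a, b in [((cx - half * 0.8, cy), (cx + half * 0.8, cy)),
                 ((cx, cy - half * 0.8), (cx, cy + half * 0.8))]:
        for s in _segmentize(a, b, step=400.0):
            road_rows.append(
                {
                    "geometry": s,
                    "length_m": s.length,
                    "speed_mps": speeds[3],
                    "level": 3,
                }
            )
    return poly, pd.DataFrame(road_rows)


def _populate_blocks(polys, is_island, cfg: RegionConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    a, b = cfg.pct60_beta
    n = len(polys)
    pop = rng.poisson(cfg.pop_mean, size=n).astype(int)
    pop = np.maximum(pop, 1)
    pct60 = rng.beta(a, b, size=n)
    pop60 = np.minimum(np.round(pop * pct60).astype(int), pop)
    return pd.DataFrame(
        {
            "block_id": np.arange(n),
            "geometry": polys,
            "pop_total": pop,
            "pop_60plus": pop60,
            "is_island": is_island,
        }
    )


def _parcels_and_buildings(blocks: pd.DataFrame, roads: pd.DataFrame,
                           cfg: RegionConfig, rng: np.random.Generator):
    """Voronoi parcels inside each block; 1-3 buildings per parcel.

    Buildings cluster near the road network, as residences do in practice
    (and as the network snapping radius assumes). The largest footprint in
    each parcel is flagged the primary residence. A small fraction of
    parcels is marked commercial (uninhabitable for dasymetric mapping).
    """
    from shapely.ops import nearest_points

    lo, hi = cfg.buildings_per_block
    road_geoms = roads["geometry"].to_numpy()
    road_tree = shapely.STRtree(road_geoms)
    parcel_rows, building_rows = [], []
    pid = bid = 0
    for _, blk in blocks.iterrows():
        poly = blk.geometry
        n_bld = int(rng.integers(lo, hi + 1))
        n_parc = max(1, n_bld // 2)
        minx, miny, maxx, maxy = poly.bounds
        pts = []
        while len(pts) < n_parc:
            p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
            if poly.contains(p):
                pts.append(p)
        if n_parc == 1:
            cells = [poly]
        else:
            vd = voronoi_diagram(MultiPoint(pts), envelope=poly)
            cells = []
            for cell in vd.geoms:
                clipped = cell.intersection(poly)
                if not clipped.is_empty and clipped.area > 0:
                    if clipped.geom_type == "MultiPolygon":
                        clipped = max(clipped.geoms, key=lambda g: g.area)
                    cells.append(clipped)
        # deterministic order: sort cells west->east then south->north
        cells.sort(key=lambda g: (g.centroid.x, g.centroid.y))
        n_left = n_bld
        for cell in cells:
            landuse = "commercial" if rng.random() < 0.06 else "residential"
            parcel_rows.append(
                {
                    "parcel_id": pid,
                    "block_id": int(blk.block_id),
                    "geometry": cell,
                    "landuse": landuse,
                }
            )
            anchor = _roadside_anchor(cell, road_tree, road_geoms, rng)
            if anchor is None:  # vacant parcel: no road within driveway reach
                pid += 1
                continue
            k = min(int(rng.integers(1, 4)), max(1, n_left))
            sizes = sorted(rng.uniform(6.0, 18.0, size=k), reverse=True)
            placed = []
            for s in sizes:
                b = _building_in(cell, s, rng, near=anchor)
                if b is not None:
                    placed.append(b)
            for j, geom in enumerate(placed):
                building_rows.append(
                    {
                        "building_id": bid,
                        "parcel_id": pid,
                        "block_id": int(blk.block_id),
                        "geometry": geom,
                        "is_primary": j == 0,
                    }
                )
                bid += 1
            n_left -= len(placed)
            pid += 1
    return pd.DataFrame(parcel_rows), pd.DataFrame(building_rows)


def _roadside_anchor(parcel, road_tree, road_geoms, rng: np.random.Generator,
                     max_driveway_m: float = 300.0):
    """A point inside the parcel near the road network (a driveway end),
    or None when the parcel lies beyond driveway reach of every road."""
    from shapely.ops import nearest_points

    cen = parcel.centroid
    idx = road_tree.query_nearest(parcel, all_matches=False)
    road = road_geoms[int(idx[0])]
    if parcel.distance(road) > max_driveway_m:
        return None
    road_pt = nearest_points(road, cen)[0]
    d = np.array([cen.x - road_pt.x, cen.y - road_pt.y])
    norm = np.hypot(*d)
    u = d / norm if norm > 0 else np.array([1.0, 0.0])
    offset = rng.uniform(25.0, 150.0)
    cand = Point(road_pt.x + u[0] * offset, road_pt.y + u[1] * offset)
    if parcel.contains(cand):
        return cand
    anchor = nearest_points(parcel, road_pt)[0]
    inner = parcel.buffer(-10.0)
    if not inner.is_empty:
        anchor = nearest_points(inner, road_pt)[0]
    return anchor


def _building_in(parcel, side: float, rng: np.random.Generator, near=None):
    """A roughly square footprint of ~side meters fully inside the parcel,
    scattered around ``near`` when given."""
    minx, miny, maxx, maxy = parcel.bounds
    for _ in range(20):
        if near is not None:
            cx = near.x + rng.normal(0.0, 45.0)
            cy = near.y + rng.normal(0.0, 45.0)
        else:
            cx = rng.uniform(minx, maxx)
            cy = rng.uniform(miny, maxy)
        b = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        if parcel.contains(b):
            return b
    # fall back to a clipped footprint at the anchor / representative point
    p = near if near is not None else parcel.representative_point()
    b = box(p.x - side / 2, p.y - side / 2, p.x + side / 2, p.y + side / 2)
    b = b.intersection(parcel)
    if b.is_empty or b.area <= 0:
        return None
    if b.geom_type == "MultiPolygon":
        b = max(b.geoms, key=lambda g: g.area)
    return b if b.geom_type == "Polygon" else None


def _landcover_surface(cfg: RegionConfig, elevation: Grid, roads: pd.DataFrame,
                       x_coast: float, rng: np.random.Generator) -> Grid:
    """Water / wetland / developed / forest / cropland from elevation,
    road proximity and noise."""
    g = elevation
    xx, yy = np.meshgrid(g.xs(), g.ys())
    lc = np.full(g.data.shape, LC_CROPLAND, dtype=int)
    forest = rng.random(g.data.shape) < 0.35
    lc[forest] = LC_FOREST
    # developed strip along roads; road distance sampled on a coarse grid
    coarse = make_grid(cfg.extent, max(cfg.cell_m, 120.0))
    cxx, cyy = coarse.centers()
    tree = shapely.STRtree(roads["geometry"].to_numpy())
    pts = shapely.points(cxx, cyy)
    idx, dists = tree.query_nearest(pts, all_matches=False, return_distance=True)
    dist_c = np.full(len(pts), np.inf)
    dist_c[idx[0]] = dists
    coarse_dist = coarse.like(dist_c.reshape(coarse.data.shape))
    dev = _sample_grid(coarse_dist, xx.ravel(), yy.ravel()).reshape(g.data.shape)
    lc[dev < 220.0] = LC_DEVELOPED
    lc[(g.data >= 0) & (g.data < cfg.flood_elevation_m + 0.5)] = LC_WETLAND
    lc[g.data < 0] = LC_WATER
    return g.like(lc)


# ----------------------------------------------------------------------
# public API


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Generate a synthetic coastal region. Deterministic given the seed."""
    cfg = config
    xmin, ymin, xmax, ymax = cfg.extent
    w = xmax - xmin

    if cfg.island and cfg.n_stations == 0:
        warnings.warn(
            "island=True with no drone stations: island residents are "
            "unreachable by every delivery mode", stacklevel=2
        )

    # independent streams per layer, split from the master seed
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_elev, rng_road, rng_blk, rng_parc, rng_lc, rng_ph, rng_st, rng_isl = (
        np.random.default_rng(s) for s in streams
    )

    x_coast = xmin + 0.18 * w          # western shoreline of the mainland
    x_spine = x_coast + 0.45 * (xmax - x_coast)
    mainland = box(x_coast, ymin, xmax, ymax)

    elevation = _elevation_surface(cfg, x_spine, x_coast, rng_elev)
    roads, y_connectors, x_east = _build_roads(cfg, x_spine, x_coast, rng_road)

    # island (one block, own disconnected roads)
    island_poly = None
    if cfg.island:
        island_poly, island_roads = _island_layers(cfg, rng_isl)
        roads = pd.concat([roads, island_roads], ignore_index=True)
        # island is low-lying
        isl_mask = elevation.contains_mask([island_poly])
        elevation.data[isl_mask] = 1.2

    n_mainland_blocks = cfg.n_blocks - (1 if cfg.island else 0)
    if n_mainland_blocks < 1:
        raise ConfigurationError("n_blocks too small for island configuration")
    block_polys = _banded_partition((x_coast, ymin, xmax, ymax), n_mainland_blocks)
    is_island = [False] * n_mainland_blocks
    if cfg.island:
        block_polys.append(island_poly)
        is_island.append(True)
    blocks = _populate_blocks(block_polys, is_island, cfg, rng_blk)

    parcels, buildings = _parcels_and_buildings(blocks, roads, cfg, rng_parc)

    landcover = _landcover_surface(cfg, elevation, roads, x_coast, rng_lc)

    # pharmacies: n on the central stretch of the spine (remote tips face
    # the longest drives), 2 coastal towns at the east ends of connectors
    # (roughly 0.85H in the NE and 0.2H in the S)
    ph_pts = []
    ys_spine = np.linspace(ymin + 0.3 * (ymax - ymin), ymin + 0.7 * (ymax - ymin),
                           cfg.n_pharmacies_spine)
    for y in ys_spine:
        y_node = round((y - ymin) / 1000.0) * 1000.0 + ymin  # snap to a spine node
        ph_pts.append(Point(x_spine, min(max(y_node, ymin), ymax)))
    if cfg.n_pharmacies_coastal >= 1:
        yc = y_connectors[np.argmin(np.abs(y_connectors - (ymin + 0.85 * (ymax - ymin))))]
        ph_pts.append(Point(x_east, yc))
    if cfg.n_pharmacies_coastal >= 2:
        yc = y_connectors[np.argmin(np.abs(y_connectors - (ymin + 0.2 * (ymax - ymin))))]
        ph_pts.append(Point(x_east, yc))
    for k in range(2, cfg.n_pharmacies_coastal):
        yc = y_connectors[int(rng_ph.integers(0, len(y_connectors)))]
        ph_pts.append(Point(x_east, yc))
    pharmacies = pd.DataFrame(
        {"pharmacy_id": np.arange(1, len(ph_pts) + 1), "geometry": ph_pts}
    )

    # stations on the spine, ids 1..n ordered north (large y) -> south
    st_y = np.linspace(ymax - 0.25 * (ymax - ymin), ymin + 0.18 * (ymax - ymin),
                       cfg.n_stations) if cfg.n_stations else np.array([])
    stations = pd.DataFrame(
        {
            "station_id": np.arange(1, cfg.n_stations + 1),
            "geometry": [Point(x_spine, y) for y in st_y],
        }
    )

    # flood zones: land below the threshold (coarsened for compact polygons)
    coarse = make_grid(cfg.extent, max(cfg.cell_m, 120.0))
    cxx, cyy = np.meshgrid(coarse.xs(), coarse.ys())
    celev = _sample_grid(elevation, cxx.ravel(), cyy.ravel()).reshape(cxx.shape)
    flood_mask = coarse.like((celev >= 0) & (celev < cfg.flood_elevation_m))
    flood_zones = mask_to_polygons(flood_mask)

    # no-fly circle, default over the NE coastal town
    if cfg.nofly_center is None:
        nf_center = (x_east - 1_200.0, ymin + 0.85 * (ymax - ymin))
    else:
        nf_center = cfg.nofly_center
    nofly_zones = [Point(nf_center).buffer(cfg.nofly_radius_m, quad_segs=32)]

    return SyntheticRegion(
        config=cfg,
        roads=roads,
        blocks=blocks,
        parcels=parcels,
        buildings=buildings,
        pharmacies=pharmacies,
        stations=stations,
        flood_zones=flood_zones,
        nofly_zones=nofly_zones,
        landcover=landcover,
        elevation=elevation,
        mainland=mainland,
        island_poly=island_poly,
    )


def _sample_grid(grid: Grid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nearest-cell sample of a grid at arbitrary coordinates."""
    col = np.clip(((x - grid.x0) / grid.cell).astype(int), 0, grid.ncols - 1)
    row = np.clip(((grid.y1 - y) / grid.cell).astype(int), 0, grid.nrows - 1)
    return grid.data[row, col]


def plant_cluster(region: SyntheticRegion, center: tuple[float, float],
                  radius_m: float, age_boost: float,
                  remote: bool = False,
                  slow_factor: float = 0.35) -> SyntheticRegion:
    """Plant an elderly (and optionally remote) cluster for recovery tests.

    Blocks intersecting the disc get their 60+ share raised toward
    ``age_boost``; with ``remote=True``, secondary/local road edges inside the
    disc are slowed by ``slow_factor`` so drive times rise. Returns a new
    region; the input is untouched.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if not 0.0 <= age_boost <= 1.0:
        raise ValueError("age_boost must be in [0, 1]")
    disc = Point(center).buffer(radius_m, quad_segs=32)
    xmin, ymin, xmax, ymax = region.config.extent
    if disc.disjoint(box(xmin, ymin, xmax, ymax)):
        warnings.warn("planted disc lies outside the region extent; no-op",
                      stacklevel=2)
        return region

    out = region.copy()
    hit = shapely.intersects(out.blocks["geometry"].to_numpy(), disc)
    pop = out.blocks["pop_total"].to_numpy()
    p60 = out.blocks["pop_60plus"].to_numpy().astype(int)
    boosted = np.round(pop * age_boost).astype(int)
    p60 = np.where(hit, np.maximum(p60, np.minimum(boosted, pop)), p60)
    out.blocks["pop_60plus"] = p60

    if remote:
        slow = shapely.intersects(out.roads["geometry"].to_numpy(), disc) & (
            out.roads["level"].to_numpy() >= 2
        )
        sp = out.roads["speed_mps"].to_numpy().astype(float)
        sp[slow] = sp[slow] * slow_factor
        out.roads["speed_mps"] = sp
    return out
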