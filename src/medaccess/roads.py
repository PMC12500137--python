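"""Routable road graph and vehicle travel times.

Builds an undirected graph from a road edge table (travel minutes per edge =
length / speed limit / 60, with a 3-level hierarchy carried as an attribute),
snaps buildings and pharmacies to the network, and computes closest-facility
travel times with optional polygon barriers (flood zones) that sever any edge
whose interior they intersect.

Conventions
-----------
* Edges are straight 2-point segments; polyline inputs are exploded.
* Facilities are inserted as real graph nodes by splitting their snapped
  edge; buildings use the snapped point on their nearest edge without
  modifying the graph.
* A building farther than the access radius from every edge, or with no
  surviving path, is UNREACHABLE (NaN minutes, status code) — times are
  never fabricated.
* Round-trip minutes are exactly twice one-way minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .grid import Grid

logger = logging.getLogger(__name__)

UNREACHABLE_BIN = "unreachable"

#: status codes for travel-time rows
OK = "ok"
NO_ACCESS = "no_access"          # beyond snapping radius
NO_PATH = "no_path"              # snapped but network-disconnected
ACCESS_SEVERED = "access_severed"  # snapped edge removed by a barrier


@dataclass
class RoadGraph:
    """Undirected routable graph in projected meter coordinates."""

    nodes: np.ndarray                 # (N, 2) coordinates
    edges: pd.DataFrame               # u, v, length_m, speed_mps, minutes, level, geometry

    def __post_init__(self):
        self._nx = None
        self._tree = None

    @property
    def graph(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.nodes)))
            for idx, e in self.edges.iterrows():
                g.add_edge(int(e.u), int(e.v), minutes=float(e.minutes), eidx=idx)
            self._nx = g
        return self._nx

    @property
    def edge_tree(self) -> shapely.STRtree:
        if self._tree is None:
            self._tree = shapely.STRtree(self.edges["geometry"].to_numpy())
        return self._tree

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


def _explode_segments(roads: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in roads.iterrows():
        geom = r["geometry"]
        speed = float(r["speed_mps"])
        level = int(r.get("level", 3))
        if speed <= 0:
            logger.warning("rejecting edge with non-positive speed %.3f", speed)
            continue
        coords = np.asarray(geom.coords)
        for i in range(len(coords) - 1):
            seg = LineString([coords[i], coords[i + 1]])
            if seg.length <= 0:
                continue
            rows.append({"geometry": seg, "speed_mps": speed, "level": level})
    return pd.DataFrame(rows)


def build_graph(roads: pd.DataFrame, snap_tolerance_m: float = 1.0) -> RoadGraph:
    """Build a RoadGraph from an edge table.

    Endpoints within ``snap_tolerance_m`` of each other are merged into one
    node; duplicate segments (same node pair, same length) are dropped; edges
    with non-positive speed are rejected and logged.
    """
    segs = _explode_segments(roads)
    if segs.empty:
        raise ValueError("no valid road segments")
    coords = np.concatenate(
        [np.asarray([s.coords[0], s.coords[-1]]) for s in segs["geometry"]]
    )
    # merge endpoints within tolerance: snap to a grid of tolerance size,
    # then union-find over remaining close pairs
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(snap_tolerance_m, output_type="ndarray")
    parent = np.arange(len(coords))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(coords))])
    uniq, node_of = np.unique(roots, return_inverse=True)
    node_xy = np.zeros((len(uniq), 2))
    np.add.at(node_xy, node_of, coords)
    counts = np.bincount(node_of).astype(float)
    node_xy /= counts[:, None]

    seen: set[tuple[int, int, int]] = set()
    rows = []
    for i, (_, r) in enumerate(segs.iterrows()):
        u, v = int(node_of[2 * i]), int(node_of[2 * i + 1])
        if u == v:
            continue
        geom = LineString([node_xy[u], node_xy[v]])
        key = (min(u, v), max(u, v), int(round(geom.length * 100)))
        if key in seen:
            continue
        seen.add(key)
        length = geom.length
        speed = float(r["speed_mps"])
        rows.append(
            {
                "u": u,
                "v": v,
                "length_m": length,
                "speed_mps": speed,
                "minutes": length / speed / 60.0,
                "level": int(r["level"]),
                "geometry": geom,
            }
        )
    edges = pd.DataFrame(rows)
    return RoadGraph(nodes=node_xy, edges=edges)


# ----------------------------------------------------------------------
# snapping


def _project_to_edges(graph: RoadGraph, xy: np.ndarray):
    """For each point, its nearest edge and the projection onto it.

    Returns (edge_idx, t in [0,1] along the segment, offset_m).
    """
    pts = shapely.points(xy[:, 0], xy[:, 1])
    nearest = graph.edge_tree.query_nearest(pts, all_matches=False)
    eidx = np.empty(len(pts), dtype=int)
    eidx[nearest[0]] = nearest[1]
    e = graph.edges.iloc[eidx]
    u_xy = graph.nodes[e["u"].to_numpy()]
    v_xy = graph.nodes[e["v"].to_numpy()]
    d = v_xy - u_xy
    L2 = (d ** 2).sum(axis=1)
    t = np.clip(((xy - u_xy) * d).sum(axis=1) / np.where(L2 > 0, L2, 1.0), 0.0, 1.0)
    proj = u_xy + t[:, None] * d
    offset = np.hypot(*(xy - proj).T)
    return eidx, t, offset


def insert_point_node(graph: RoadGraph, point: Point) -> tuple[RoadGraph, int]:
    """Insert a node at the projection of ``point`` onto its nearest edge,
    splitting that edge. Returns (new graph, new node id)."""
    xy = np.asarray([[point.x, point.y]])
    eidx, t, _ = _project_to_edges(graph, xy)
    eidx, t = int(eidx[0]), float(t[0])
    e = graph.edges.iloc[eidx]
    u, v = int(e.u), int(e.v)
    u_xy, v_xy = graph.nodes[u], graph.nodes[v]
    p_xy = u_xy + t * (v_xy - u_xy)
    if t <= 1e-9:
        return graph, u
    if t >= 1 - 1e-9:
        return graph, v
    nodes = np.vstack([graph.nodes, p_xy])
    new_id = len(graph.nodes)
    keep = graph.edges.drop(index=graph.edges.index[eidx])
    speed, level = float(e.speed_mps), int(e.level)
    halves = []
    for a, b, a_xy, b_xy in [(u, new_id, u_xy, p_xy), (new_id, v, p_xy, v_xy)]:
        geom = LineString([a_xy, b_xy])
        halves.append(
            {
                "u": a,
                "v": b,
                "length_m": geom.length,
                "speed_mps": speed,
                "minutes": geom.length / speed / 60.0,
                "level": level,
                "geometry": geom,
            }
        )
    edges = pd.concat([keep, pd.DataFrame(halves)], ignore_index=True)
    return RoadGraph(nodes=nodes, edges=edges), new_id


def _barrier_removed_mask(graph: RoadGraph, barriers) -> np.ndarray:
    """Edges whose interior intersects a barrier polygon (touching at a
    point does not sever)."""
    removed = np.zeros(len(graph.edges), dtype=bool)
    geoms = graph.edges["geometry"].to_numpy()
    for poly in barriers:
        hits = shapely.intersects(geoms, poly) & ~shapely.touches(geoms, poly)
        removed |= hits
    return removed


# ----------------------------------------------------------------------
# closest facility


def closest_facility_times(
    graph: RoadGraph,
    buildings: pd.DataFrame,
    facilities: pd.DataFrame,
    barriers=None,
    access_radius_m: float = 500.0,
    id_col: str = "building_id",
    facility_id_col: str = "pharmacy_id",
    keep_routes: bool = False,
) -> pd.DataFrame:
    """One-way and round-trip minutes from each building to its nearest
    facility; UNREACHABLE (NaN) where no path exists.

    With ``barriers``, any edge intersecting a barrier polygon's interior is
    removed before routing; a building whose own access edge is severed is
    unreachable (status ``access_severed``).
    """
    if facilities.empty:
        raise ValueError("no facilities")
    facilities = facilities.sort_values(facility_id_col)  # tie -> lowest id
    g = graph
    fac_nodes: list[int] = []
    for _, f in facilities.iterrows():
        pt = f["geometry"]
        pt = pt if isinstance(pt, Point) else pt.centroid
        g, node = insert_point_node(g, pt)
        fac_nodes.append(node)

    removed = (
        _barrier_removed_mask(g, barriers)
        if barriers is not None and len(barriers)
        else np.zeros(len(g.edges), dtype=bool)
    )
    gx = nx.Graph()
    gx.add_nodes_from(range(len(g.nodes)))
    kept = g.edges.loc[~removed]
    for _, e in kept.iterrows():
        gx.add_edge(int(e.u), int(e.v), minutes=float(e.minutes))

    # minutes from every node to each facility
    n_nodes = len(g.nodes)
    fac_ids = facilities[facility_id_col].to_numpy()
    dist = np.full((len(fac_nodes), n_nodes), np.inf)
    paths: list[dict] = []
    for k, fn in enumerate(fac_nodes):
        if keep_routes:
            lengths, p = nx.single_source_dijkstra(gx, fn, weight="minutes")
            paths.append(p)
        else:
            lengths = nx.single_source_dijkstra_path_length(
                gx, fn, weight="minutes"
            )
        idx = np.fromiter(lengths.keys(), dtype=int)
        dist[k, idx] = np.fromiter(lengths.values(), dtype=float)

    cent = np.asarray(
        [[geom.centroid.x, geom.centroid.y] for geom in buildings["geometry"]]
    )
    eidx, t, offset = _project_to_edges(g, cent)
    e = g.edges.iloc[eidx]
    u = e["u"].to_numpy()
    v = e["v"].to_numpy()
    length = e["length_m"].to_numpy()
    speed = e["speed_mps"].to_numpy()
    min_u = (t * length) / speed / 60.0
    min_v = ((1 - t) * length) / speed / 60.0

    via_u = dist[:, u] + min_u[None, :]
    via_v = dist[:, v] + min_v[None, :]
    per_fac = np.minimum(via_u, via_v)          # (n_fac, n_buildings)
    best = per_fac.min(axis=0)
    best_fac = per_fac.argmin(axis=0)           # first (lowest) index on ties

    one_way = best.copy()
    status = np.full(len(cent), OK, dtype=object)
    status[~np.isfinite(one_way)] = NO_PATH
    sev = removed[eidx]
    one_way[sev] = np.inf
    status[sev] = ACCESS_SEVERED
    far = offset > access_radius_m
    one_way[far] = np.inf
    status[far] = NO_ACCESS

    reachable = np.isfinite(one_way)
    out = pd.DataFrame(
        {
            id_col: buildings[id_col].to_numpy(),
            "one_way_min": np.where(reachable, one_way, np.nan),
            "round_trip_min": np.where(reachable, 2.0 * one_way, np.nan),
            "nearest_pharmacy_id": np.where(
                reachable, fac_ids[best_fac], -1
            ),
            "status": status,
            "snap_edge": eidx,
            "snap_offset_m": offset,
        }
    )
    if keep_routes:
        routes = []
        endpoint = np.where(via_u[best_fac, np.arange(len(cent))]
                            <= via_v[best_fac, np.arange(len(cent))], u, v)
        for i in range(len(cent)):
            if not np.isfinite(one_way[i]):
                routes.append(None)
                continue
            node_path = paths[best_fac[i]].get(int(endpoint[i]), [])
            coords = [tuple(g.nodes[nn]) for nn in node_path]
            # append the snapped access point at the building end
            e_i = g.edges.iloc[eidx[i]]
            p = g.nodes[int(e_i.u)] + t[i] * (
                g.nodes[int(e_i.v)] - g.nodes[int(e_i.u)]
            )
            coords.append((float(p[0]), float(p[1])))
            routes.append(LineString(coords) if len(coords) >= 2 else None)
        out["route"] = routes
    return out


def bin_round_trip(times: pd.DataFrame, interval_min: float = 10.0,
                   column: str = "round_trip_min") -> pd.Series:
    """Bin travel times into left-open / right-closed intervals.

    Bin k covers ((k-1)*interval, k*interval]; a time of exactly 10 minutes
    falls in the first ("<=10") bin. UNREACHABLE rows get their own bin.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    t = times[column].to_numpy(dtype=float)
    labels = np.empty(len(t), dtype=object)
    finite = np.isfinite(t)
    k = np.zeros(len(t), dtype=int)
    k[finite] = np.maximum(1, np.ceil(t[finite] / interval_min - 1e-12)).astype(int)
    for i in range(len(t)):
        labels[i] = UNREACHABLE_BIN if not finite[i] else bin_label(k[i], interval_min)
    return pd.Series(labels, index=times.index, name="bin")


def bin_label(k: int, interval_min: float = 10.0) -> str:
    hi = k * interval_min
    if k == 1:
        return f"<={_fmt(hi)}"
    lo = (k - 1) * interval_min
    return f"{_fmt(lo)}-{_fmt(hi)}"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def vehicle_zone_grid(graph: RoadGraph, facilities: pd.DataFrame,
                      template: Grid, interval_min: float = 10.0,
                      access_radius_m: float | None = None) -> Grid:
    """Round-trip travel-time bin index per raster cell (0 = unreachable).

    Cell centers snap to their nearest edge; this raster stands in for
    network service-area polygons when overlaying population, so by default
    no access-radius cutoff is applied — a cell is unreachable only when its
    nearest edge has no route to any facility (the disconnected island).
    """
    g = graph
    fac_nodes = []
    for _, f in facilities.iterrows():
        g, node = insert_point_node(g, f["geometry"])
        fac_nodes.append(node)
    gx = nx.Graph()
    gx.add_nodes_from(range(len(g.nodes)))
    for _, e in g.edges.iterrows():
        gx.add_edge(int(e.u), int(e.v), minutes=float(e.minutes))
    node_min = np.full(len(g.nodes), np.inf)
    lengths = nx.multi_source_dijkstra_path_length(gx, set(fac_nodes), weight="minutes")
    idx = np.fromiter(lengths.keys(), dtype=int)
    node_min[idx] = np.fromiter(lengths.values(), dtype=float)

    xx, yy = template.centers()
    xy = np.column_stack([xx, yy])
    eidx, t, offset = _project_to_edges(g, xy)
    e = g.edges.iloc[eidx]
    u = e["u"].to_numpy()
    v = e["v"].to_numpy()
    length = e["length_m"].to_numpy()
    speed = e["speed_mps"].to_numpy()
    one_way = np.minimum(
        node_min[u] + (t * length) / speed / 60.0,
        node_min[v] + ((1 - t) * length) / speed / 60.0,
    )
    if access_radius_m is not None:
        one_way[offset > access_radius_m] = np.inf
    rt = 2.0 * one_way
    k = np.zeros(len(rt), dtype=int)
    finite = np.isfinite(rt)
    k[finite] = np.maximum(1, np.ceil(rt[finite] / interval_min - 1e-12)).astype(int)
    return template.like(k.reshape(template.data.shape))
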