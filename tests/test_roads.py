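"""Road graph construction, closest-facility routing, time binning."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from medaccess.roads import (
    UNREACHABLE_BIN,
    bin_label,
    bin_round_trip,
    build_graph,
    closest_facility_times,
)

from conftest import brute_force_shortest_minutes, points_frame, roads_frame


def test_edge_minutes_are_length_over_speed():
    g = build_graph(roads_frame([(0, 0, 1000, 0)], speed=11.176))
    assert g.edges["minutes"].iloc[0] == pytest.approx(1000 / 11.176 / 60, abs=1e-4)
    assert g.edges["minutes"].iloc[0] == pytest.approx(1.4914, abs=1e-3)


def test_shared_endpoint_merges_into_three_nodes_two_edges():
    g = build_graph(roads_frame([(0, 0, 100, 0), (100, 0, 100, 100)]))
    assert len(g.nodes) == 3
    assert len(g.edges) == 2


def test_duplicate_edges_deduplicated():
    segs = [(0, 0, 100, 0), (0, 0, 100, 0), (100, 0, 200, 0)]
    g = build_graph(roads_frame(segs))
    # hash-based duplicate scan over input geometries
    unique = {(s[0], s[1], s[2], s[3]) for s in segs}
    assert len(g.edges) == len(unique)


def test_nonpositive_speed_edges_rejected():
    df = roads_frame([(0, 0, 100, 0)])
    df.loc[0, "speed_mps"] = 0.0
    df = pd.concat([df, roads_frame([(100, 0, 200, 0)])], ignore_index=True)
    g = build_graph(df)
    assert len(g.edges) == 1


def test_building_at_pharmacy_node_has_zero_minutes():
    g = build_graph(roads_frame([(0, 0, 1000, 0)]))
    buildings = points_frame([(0, 0)], "building_id")
    pharmacies = points_frame([(0, 0)], "pharmacy_id")
    t = closest_facility_times(g, buildings, pharmacies)
    assert t["one_way_min"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert t["round_trip_min"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_toy_graph_matches_exhaustive_enumeration():
    # 6-node graph: a square with a diagonal plus a spur, 2 pharmacies
    pts = {0: (0, 0), 1: (1000, 0), 2: (1000, 1000), 3: (0, 1000),
           4: (2000, 0), 5: (2000, 1000)}
    pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (1, 3), (1, 4), (2, 5)]
    speed = 10.0
    segs = [(*pts[u], *pts[v]) for u, v in pairs]
    g = build_graph(roads_frame(segs, speed=speed))
    edges = [
        (u, v, np.hypot(pts[u][0] - pts[v][0], pts[u][1] - pts[v][1]) / speed / 60)
        for u, v in pairs
    ]
    buildings = points_frame(list(pts.values()), "building_id")
    fac_nodes = [4, 3]
    pharmacies = points_frame([pts[n] for n in fac_nodes], "pharmacy_id")
    t = closest_facility_times(g, buildings, pharmacies)
    for i, node in enumerate(pts):
        expected = min(
            brute_force_shortest_minutes(edges, node, f) for f in fac_nodes
        )
        assert t["one_way_min"].iloc[i] == pytest.approx(expected, abs=1e-9)
        assert t["round_trip_min"].iloc[i] == pytest.approx(2 * expected, abs=1e-9)


def _random_node_graph(rng, n_nodes):
    while True:
        xy = rng.uniform(0, 5_000, size=(n_nodes, 2))
        if np.min(
            np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
            + np.eye(n_nodes) * 1e9
        ) > 50:
            break
    pairs = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.45
    ]
    # every node must touch an edge so snapping lands on it exactly
    used = {u for p in pairs for u in p}
    for i in range(n_nodes):
        if i not in used:
            j = (i + 1) % n_nodes
            pairs.append((min(i, j), max(i, j)))
            used.update((i, j))
    pairs = sorted(set(pairs))
    speed = float(rng.uniform(5, 25))
    return xy, pairs, speed


def test_random_small_graphs_match_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 9))
        xy, pairs, speed = _random_node_graph(rng, n)
        segs = [(*xy[u], *xy[v]) for u, v in pairs]
        g = build_graph(roads_frame(segs, speed=speed), snap_tolerance_m=1.0)
        edges = [
            (u, v, float(np.linalg.norm(xy[u] - xy[v])) / speed / 60)
            for u, v in pairs
        ]
        fac = int(rng.integers(0, n))
        buildings = points_frame([tuple(p) for p in xy], "building_id")
        pharmacies = points_frame([tuple(xy[fac])], "pharmacy_id")
        t = closest_facility_times(g, buildings, pharmacies)
        for i in range(n):
            expected = brute_force_shortest_minutes(edges, i, fac)
            got = t["one_way_min"].iloc[i]
            if np.isinf(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


def test_route_geometry_runs_facility_to_snap_point():
    segs = [(0, 0, 1000, 0), (1000, 0, 2000, 0), (1000, 0, 1000, 1000)]
    g = build_graph(roads_frame(segs, speed=10.0))
    buildings = points_frame([(1000, 900)], "building_id")
    pharmacies = points_frame([(0, 0)], "pharmacy_id")
    t = closest_facility_times(g, buildings, pharmacies, keep_routes=True)
    route = t["route"].iloc[0]
    assert list(route.coords) == [(0.0, 0.0), (1000.0, 0.0), (1000.0, 900.0)]
    # route length in minutes equals the reported one-way time
    assert route.length / 10.0 / 60.0 == pytest.approx(
        t["one_way_min"].iloc[0], abs=1e-9
    )


def test_barrier_never_shortens_and_severed_access_is_unreachable():
    # corridor with a parallel detour; barrier cuts the direct edge
    segs = [(0, 0, 1000, 0), (1000, 0, 2000, 0),
            (0, 0, 0, 500), (0, 500, 2000, 500), (2000, 500, 2000, 0)]
    g = build_graph(roads_frame(segs, speed=10.0))
    buildings = points_frame([(1000, 0), (0, 500)], "building_id")
    pharmacies = points_frame([(2000, 0)], "pharmacy_id")
    base = closest_facility_times(g, buildings, pharmacies)
    barrier = box(400, -50, 600, 50)  # severs the (0,0)-(1000,0) edge
    with_b = closest_facility_times(g, buildings, pharmacies, barriers=[barrier])
    for i in range(len(buildings)):
        b, w = base["one_way_min"].iloc[i], with_b["one_way_min"].iloc[i]
        if not np.isnan(w):
            assert w >= b - 1e-12
    # building 1 on the detour is unaffected
    assert with_b["one_way_min"].iloc[1] == pytest.approx(
        base["one_way_min"].iloc[1]
    )


def test_barrier_touching_edge_at_point_does_not_sever():
    g = build_graph(roads_frame([(0, 0, 1000, 0)], speed=10.0))
    buildings = points_frame([(0, 0)], "building_id")
    pharmacies = points_frame([(1000, 0)], "pharmacy_id")
    touching = Polygon([(500, 0), (600, 100), (400, 100)])  # touches at (500,0)
    t = closest_facility_times(g, buildings, pharmacies, barriers=[touching])
    assert np.isfinite(t["one_way_min"].iloc[0])


def test_building_beyond_access_radius_unreachable():
    g = build_graph(roads_frame([(0, 0, 1000, 0)]))
    buildings = points_frame([(500, 2000)], "building_id")
    pharmacies = points_frame([(0, 0)], "pharmacy_id")
    t = closest_facility_times(g, buildings, pharmacies, access_radius_m=500.0)
    assert np.isnan(t["one_way_min"].iloc[0])
    assert t["status"].iloc[0] == "no_access"


def test_isochrone_nesting(small_graph, small_region, small_residences):
    times = closest_facility_times(
        small_graph, small_residences, small_region.pharmacies
    )
    rt = times["round_trip_min"].to_numpy()
    for lo, hi in [(10, 20), (20, 30), (30, 50)]:
        within_lo = set(times["building_id"][rt <= lo])
        within_hi = set(times["building_id"][rt <= hi])
        assert within_lo <= within_hi


class TestBinning:
    @pytest.mark.parametrize(
        "rt,expected",
        [
            (9.99, "<=10"),
            (10.0, "<=10"),   # closed right edge
            (10.01, "10-20"),
            (47.0, "40-50"),
            (0.0, "<=10"),
            (np.nan, UNREACHABLE_BIN),
        ],
    )
    def test_bin_assignment(self, rt, expected):
        df = pd.DataFrame({"round_trip_min": [rt]})
        assert bin_round_trip(df).iloc[0] == expected

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            bin_round_trip(pd.DataFrame({"round_trip_min": [1.0]}), 0)

    def test_labels(self):
        assert bin_label(1) == "<=10"
        assert bin_label(5) == "40-50"
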