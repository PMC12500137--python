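import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from medaccess.region import RegionConfig, generate_region
from medaccess.roads import build_graph


def small_config(seed: int = 11, **overrides) -> RegionConfig:
    """A compact region for fast tests: same structure, smaller extent."""
    kw = dict(
        seed=seed,
        extent=(0.0, 0.0, 8_000.0, 20_000.0),
        n_blocks=40,
        buildings_per_block=(4, 10),
        cell_m=120.0,
    )
    kw.update(overrides)
    return RegionConfig(**kw)


@pytest.fixture(scope="session")
def small_region():
    return generate_region(small_config())


@pytest.fixture(scope="session")
def small_graph(small_region):
    return build_graph(small_region.roads)


@pytest.fixture(scope="session")
def small_residences(small_region):
    return (
        small_region.buildings[small_region.buildings["is_primary"]]
        .reset_index(drop=True)
    )


def roads_frame(segments, speed=10.0, level=3):
    """Edge table from [(x0, y0, x1, y1), ...] (or LineStrings)."""
    rows = []
    for s in segments:
        geom = s if isinstance(s, LineString) else LineString(
            [(s[0], s[1]), (s[2], s[3])]
        )
        rows.append({"geometry": geom, "speed_mps": speed, "level": level})
    return pd.DataFrame(rows)


def points_frame(coords, id_col, start=1):
    return pd.DataFrame(
        {
            id_col: np.arange(start, start + len(coords)),
            "geometry": [Point(c) for c in coords],
        }
    )


def brute_force_shortest_minutes(edges, source, target):
    """Exhaustive simple-path enumeration over an edge list.

    ``edges`` is a list of (u, v, minutes). Independent oracle for network
    routing: depth-first enumeration of every simple path.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, m in edges:
        adj.setdefault(u, []).append((v, m))
        adj.setdefault(v, []).append((u, m))
    best = float("inf")
    stack = [(source, 0.0, {source})]
    while stack:
        node, cost, seen = stack.pop()
        if node == target:
            best = min(best, cost)
            continue
        for nxt, m in adj.get(node, []):
            if nxt not in seen:
                stack.append((nxt, cost + m, seen | {nxt}))
    return best
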