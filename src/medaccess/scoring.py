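"""Patient-vulnerability scoring: age, travel-time and flood sub-scores and
the VAT / VATF composite indices.

Each building inherits the 60+ population share of its census block, a
round-trip drive-time score and a flood-interruption score, on equal-interval
rubrics:

* age (% of block population aged 60+): [0,20] -> 1, (20,40] -> 2,
  (40,60] -> 3, (60,80] -> 4, (80,100] -> 5
* round-trip minutes: [0,10] -> 1, (10,20] -> 2, (20,30] -> 3,
  (30,40] -> 4, > 40 (or unreachable) -> 5
* flood condition: code 1-4 used directly

VAT = age + time (range 2-10); VATF = VAT + flood (range 3-14). Higher is
more vulnerable. The rubric's integer-labelled bands are realized as
half-open real intervals so boundary values take the lower score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

AGE_EDGES = (20.0, 40.0, 60.0, 80.0)
TIME_EDGES = (10.0, 20.0, 30.0, 40.0)


def assign_age_pct(buildings: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-building 60+ percentage from the containing census block.

    Uses the footprint's representative point; a footprint straddling blocks
    is assigned the block of largest overlap. A footprint outside every
    block is left unassigned (NaN, flagged); a block with zero population
    yields 0% with a flag.
    """
    tree = shapely.STRtree(blocks["geometry"].to_numpy())
    pct = 100.0 * blocks["pop_60plus"].to_numpy() / np.maximum(
        blocks["pop_total"].to_numpy(), 1
    )
    empty = blocks["pop_total"].to_numpy() == 0
    ids = blocks["block_id"].to_numpy()

    out_pct = np.full(len(buildings), np.nan)
    out_blk = np.full(len(buildings), -1, dtype=int)
    out_flag = np.full(len(buildings), "", dtype=object)
    geoms = buildings["geometry"].to_numpy()
    reps = shapely.point_on_surface(geoms)
    hits = tree.query(reps, predicate="within")
    by_bldg: dict[int, list[int]] = {}
    for b, blk in zip(*hits):
        by_bldg.setdefault(int(b), []).append(int(blk))
    for i, geom in enumerate(geoms):
        cand = by_bldg.get(i)
        if cand is None:
            # representative point on a boundary or outside: use overlap area
            cand = [int(j) for j in tree.query(geom, predicate="intersects")]
            if not cand:
                out_flag[i] = "outside_blocks"
                continue
        if len(cand) > 1:
            areas = [geom.intersection(blocks["geometry"].iloc[j]).area for j in cand]
            j = cand[int(np.argmax(areas))]
        else:
            j = cand[0]
        out_blk[i] = ids[j]
        if empty[j]:
            out_pct[i] = 0.0
            out_flag[i] = "empty_block"
        else:
            out_pct[i] = pct[j]
    return pd.DataFrame(
        {
            "building_id": buildings["building_id"].to_numpy(),
            "age_pct": out_pct,
            "block_id": out_blk,
            "age_flag": out_flag,
        }
    )


def score_components(age_pct, round_trip_min, flood_code):
    """(age_score, time_score, flood_score) on the equal-interval rubrics.

    ``round_trip_min`` may contain NaN for unreachable buildings (score 5).
    Scalar or array inputs.
    """
    age = np.atleast_1d(np.asarray(age_pct, dtype=float))
    t = np.atleast_1d(np.asarray(round_trip_min, dtype=float))
    f = np.atleast_1d(np.asarray(flood_code, dtype=int))
    if np.any((age < 0) | (age > 100)):
        raise ValueError("age_pct must lie in [0, 100]")
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("travel minutes must be non-negative")
    if np.any((f < 1) | (f > 4)):
        raise ValueError("flood code must be 1..4")

    age_score = 1 + sum((age > e).astype(int) for e in AGE_EDGES)
    time_score = 1 + sum((t > e).astype(int) for e in TIME_EDGES)
    time_score = np.where(np.isfinite(t), time_score, 5).astype(int)
    scalar = np.isscalar(age_pct) and np.isscalar(round_trip_min)
    if scalar:
        return int(age_score[0]), int(time_score[0]), int(f[0])
    return age_score.astype(int), time_score, f


def compute_indices(
    age: pd.DataFrame,
    times: pd.DataFrame,
    flood: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three components and compute VAT and VATF per building.

    Rows missing any component (e.g. a footprint outside all blocks) are
    flagged ``incomplete`` and carry NaN indices; downstream hotspot analysis
    drops them.
    """
    df = (
        age.merge(times[["building_id", "round_trip_min", "status"]],
                  on="building_id", how="outer")
        .merge(flood[["building_id", "flood_code", "flood_label", "no_route"]],
               on="building_id", how="outer")
        .sort_values("building_id")
        .reset_index(drop=True)
    )
    incomplete = df["age_pct"].isna() | df["flood_code"].isna()
    df["incomplete"] = incomplete
    ok = ~incomplete
    age_s = np.full(len(df), np.nan)
    time_s = np.full(len(df), np.nan)
    flood_s = np.full(len(df), np.nan)
    if ok.any():
        a, t, f = score_components(
            df.loc[ok, "age_pct"].to_numpy(),
            df.loc[ok, "round_trip_min"].to_numpy(),
            df.loc[ok, "flood_code"].to_numpy(dtype=int),
        )
        age_s[ok.to_numpy()] = a
        time_s[ok.to_numpy()] = t
        flood_s[ok.to_numpy()] = f
    df["age_score"] = age_s
    df["time_score"] = time_s
    df["flood_score"] = flood_s
    df["VAT"] = df["age_score"] + df["time_score"]
    df["VATF"] = df["VAT"] + df["flood_score"]
    return df
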