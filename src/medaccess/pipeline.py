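"""End-to-end pipeline: region -> travel times -> drone surface ->
population -> flood -> scores -> hotspots -> reports.

``run_pipeline`` is deterministic given the seed; every artifact is a text
file (CSV, GeoJSON, ASCII grid, JSON) and the run manifest records the full
configuration and a SHA-256 hash of each output, so two runs with the same
configuration can be compared byte for byte.

Patient locations are the primary residences: the largest building footprint
in each parcel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drone as drone_mod
from . import flood as flood_mod
from . import hotspots as hs_mod
from . import population as pop_mod
from . import roads as roads_mod
from . import scoring as scoring_mod
from .drone import DroneParams
from .geoio import write_geojson
from .region import DEFAULT_ZERO_CLASSES, RegionConfig, generate_region, plant_cluster

logger = logging.getLogger(__name__)

STAGES = ("generate", "drive", "drone", "population", "flood", "score",
          "hotspots", "report")


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable into the run manifest."""

    region: RegionConfig = field(default_factory=RegionConfig)
    drone: DroneParams = field(default_factory=DroneParams)
    interval_min: float = 10.0
    access_radius_m: float = 500.0
    gi_k: int = 30
    flood_eps_min: float = 0.01
    zero_classes: tuple[int, ...] = tuple(sorted(DEFAULT_ZERO_CLASSES))
    # optional planted cluster (testing / power analysis)
    cluster_center: tuple[float, float] | None = None
    cluster_radius_m: float = 0.0
    cluster_age_boost: float = 0.0
    cluster_remote: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"]["speeds_mps_by_level"] = {
            str(k): v for k, v in d["region"]["speeds_mps_by_level"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        reg = dict(d.pop("region", {}))
        if "speeds_mps_by_level" in reg:
            reg["speeds_mps_by_level"] = {
                int(k): float(v) for k, v in reg["speeds_mps_by_level"].items()
            }
        for key in ("extent", "pct60_beta", "buildings_per_block", "nofly_center"):
            if key in reg and reg[key] is not None:
                reg[key] = tuple(reg[key])
        dr = dict(d.pop("drone", {}))
        for key in ("zero_classes", "cluster_center"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(region=RegionConfig(**reg), drone=DroneParams(**dr), **d)


@dataclass
class PipelineResult:
    """In-memory artifact bundle of a full run."""

    config: PipelineConfig
    region: object
    graph: object
    residences: pd.DataFrame
    times: pd.DataFrame
    drone_surface: object
    pop_total: object = None
    pop_60plus: object = None
    zonal: pd.DataFrame | None = None
    flood: pd.DataFrame | None = None
    scored: pd.DataFrame | None = None
    gi: dict | None = None
    band_m: dict | None = None
    station_table: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    manifest: dict | None = None


def run_pipeline(config: PipelineConfig, out_dir=None,
                 upto: str = "report",
                 skip_population: bool = False) -> PipelineResult:
    """Run the pipeline through stage ``upto`` and (optionally) write
    artifacts under ``out_dir``.

    ``skip_population`` bypasses the raster disaggregation/zonal stage, which
    the vulnerability and hotspot stages do not need; used by multi-seed
    power studies.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    stop = STAGES.index(upto)
    cfg = config

    logger.info("stage=generate seed=%d", cfg.region.seed)
    region = generate_region(cfg.region)
    if cfg.cluster_center is not None and cfg.cluster_radius_m > 0:
        region = plant_cluster(
            region, cfg.cluster_center, cfg.cluster_radius_m,
            cfg.cluster_age_boost, remote=cfg.cluster_remote,
        )
    residences = region.buildings[region.buildings["is_primary"]].reset_index(
        drop=True
    )
    res = PipelineResult(
        config=cfg, region=region, graph=None, residences=residences,
        times=None, drone_surface=None,
    )
    logger.info("stage=generate blocks=%d residences=%d",
                len(region.blocks), len(residences))
    if stop >= 1:
        res.graph = roads_mod.build_graph(region.roads)
        res.times = roads_mod.closest_facility_times(
            res.graph, residences, region.pharmacies,
            access_radius_m=cfg.access_radius_m, keep_routes=True,
        )
        res.times["bin"] = roads_mod.bin_round_trip(res.times, cfg.interval_min)
        logger.info("stage=drive reachable=%d of %d",
                    int(res.times["one_way_min"].notna().sum()), len(res.times))
    if stop >= 2:
        res.drone_surface = drone_mod.drone_time_layers(
            region.stations, region.landcover, residences,
            region.nofly_zones, cfg.drone, cfg.interval_min,
        )
        logger.info("stage=drone excluded=%d",
                    int(res.drone_surface.buildings["excluded"].sum()))
    if stop >= 3 and not skip_population:
        mask = pop_mod.uninhabitable_mask(
            region.landcover, region.parcels, region.roads
        )
        res.pop_total, res.pop_60plus, _ = pop_mod.disaggregate(
            region.blocks, region.landcover, mask, set(cfg.zero_classes)
        )
        vzones = roads_mod.vehicle_zone_grid(
            res.graph, region.pharmacies, region.landcover, cfg.interval_min,
        )
        res.zonal = pop_mod.zonal_population(
            res.pop_total, res.pop_60plus,
            {
                "vehicle": (vzones, roads_mod.UNREACHABLE_BIN),
                "drone": (res.drone_surface.bins, drone_mod.EXCLUDED_BIN),
            },
            cfg.interval_min,
        )
        logger.info("stage=population total=%.1f",
                    float(res.pop_total.data.sum()))
    if stop >= 4:
        res.flood = flood_mod.classify_flood_impact(
            residences, res.graph, region.pharmacies, region.flood_zones,
            eps_min=cfg.flood_eps_min, access_radius_m=cfg.access_radius_m,
            baseline=res.times,
        )
        logger.info("stage=flood counts=%s",
                    res.flood["flood_code"].value_counts().to_dict())
    if stop >= 5:
        age = scoring_mod.assign_age_pct(residences, region.blocks)
        res.scored = scoring_mod.compute_indices(age, res.times, res.flood)
        logger.info("stage=score mean_VAT=%.3f mean_VATF=%.3f",
                    res.scored["VAT"].mean(), res.scored["VATF"].mean())
    if stop >= 6:
        res.gi, res.band_m = {}, {}
        for index_col in ("VAT", "VATF"):
            tab, d = hs_mod.hotspots_for_index(
                res.scored, residences, index_col, k=cfg.gi_k
            )
            res.gi[index_col] = tab
            res.band_m[index_col] = d
        logger.info("stage=hotspots band_m=%s", res.band_m)
    if stop >= 7:
        res.station_table = station_summary(
            res.scored, res.drone_surface.buildings
        )
        if res.zonal is not None:
            res.comparison = comparison_table(res.zonal)

    if out_dir is not None:
        res.manifest = _write_artifacts(res, Path(out_dir))
    return res


def station_summary(scored: pd.DataFrame, drone_buildings: pd.DataFrame
                    ) -> pd.DataFrame:
    """Per-station residence counts and VAT/VATF moments.

    Buildings inside no-fly zones are excluded. The standard deviation uses
    the population divisor n, matching the dispersion measure used by the
    Gi* statistic. Stations are ordered by id (north to south by
    construction).
    """
    df = scored.merge(drone_buildings[["building_id", "station_id", "excluded"]],
                      on="building_id", how="inner")
    df = df[~df["excluded"]]
    rows = []
    for sid, grp in df.groupby("station_id", sort=True):
        row = {"station_id": int(sid), "building_count": len(grp)}
        for col in ("VAT", "VATF"):
            x = grp[col].dropna().to_numpy()
            row[f"{col}_mean"] = x.mean() if len(x) else np.nan
            row[f"{col}_std"] = x.std(ddof=0) if len(x) else np.nan
            for q in (0.25, 0.5, 0.75):
                row[f"{col}_q{int(q * 100)}"] = (
                    float(np.quantile(x, q)) if len(x) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(zonal: pd.DataFrame) -> pd.DataFrame:
    """Wide per-bin population shares for vehicle round trips vs. one-way
    drone delivery (plus each mode's unreachable/excluded row)."""
    piv = zonal.pivot_table(
        index=["bin_index", "bin"], columns="mode",
        values=["share_total", "share_60plus"], aggfunc="first",
    )
    piv.columns = [f"{mode}_{val}" for val, mode in piv.columns]
    return piv.reset_index().sort_values("bin_index").reset_index(drop=True)


# ----------------------------------------------------------------------
# artifact writing


def _write_artifacts(res: PipelineResult, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False, float_format="%.6f")
        written.append(p)

    region = res.region
    for name, df in (
        ("roads.geojson", region.roads),
        ("blocks.geojson", region.blocks),
        ("pharmacies.geojson", region.pharmacies),
        ("stations.geojson", region.stations),
    ):
        write_geojson(df, out / name)
        written.append(out / name)
    if res.times is not None:
        save_csv(
            res.times[["building_id", "one_way_min", "round_trip_min",
                       "nearest_pharmacy_id", "status", "bin"]],
            "vehicle_times.csv",
        )
        if "route" in res.times:
            routed = res.times[res.times["route"].notna()]
            write_geojson(
                routed[["building_id", "nearest_pharmacy_id", "route"]].rename(
                    columns={"route": "geometry"}
                ),
                out / "vehicle_routes.geojson",
            )
            written.append(out / "vehicle_routes.geojson")
    if res.drone_surface is not None:
        save_csv(res.drone_surface.buildings, "drone_times.csv")
    if res.zonal is not None:
        save_csv(res.zonal, "zonal_population.csv")
    if res.flood is not None:
        save_csv(res.flood, "flood_classes.csv")
    if res.scored is not None:
        save_csv(res.scored.drop(columns=["age_flag"], errors="ignore"),
                 "vulnerability_scores.csv")
    if res.gi:
        save_csv(pd.concat(res.gi.values(), ignore_index=True), "gi_star.csv")
    if res.station_table is not None:
        save_csv(res.station_table, "station_summary.csv")
    if res.comparison is not None:
        save_csv(res.comparison, "mode_comparison.csv")

    manifest = {
        "config": res.config.to_dict(),
        "band_distance_m": res.band_m,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
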