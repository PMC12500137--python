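"""One-way drone delivery times from stations.

Delivery time in minutes is (T_t + T_d + dist/D_mps) / 60: a fixed takeoff
and drop-off overhead plus straight-line cruise at a constant speed. Times
are one-way (the medication arrives with the drone). Buildings and raster
cells inside a no-fly polygon are EXCLUDED — they carry no delivery time and
do not enter station assignment or any drone statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist

from .grid import Grid

EXCLUDED_BIN = "excluded"


@dataclass(frozen=True)
class DroneParams:
    """Operational constants of the delivery drone.

    takeoff_s / dropoff_s: fixed overheads in seconds (defaults 35 and 45);
    speed_mps: cruise speed in m/s (default 22.35, about 50 mph).
    """

    takeoff_s: float = 35.0
    dropoff_s: float = 45.0
    speed_mps: float = 22.35

    def __post_init__(self):
        if min(self.takeoff_s, self.dropoff_s, self.speed_mps) <= 0:
            raise ValueError("drone parameters must be strictly positive")

    @property
    def overhead_min(self) -> float:
        """Minimum possible delivery time (zero distance), in minutes."""
        return (self.takeoff_s + self.dropoff_s) / 60.0


def delivery_minutes(dist_m, params: DroneParams = DroneParams()):
    """One-way delivery minutes for a straight-line distance in meters."""
    dist_m = np.asarray(dist_m, dtype=float)
    if np.any(dist_m < 0):
        raise ValueError("distance must be non-negative")
    out = (params.takeoff_s + params.dropoff_s + dist_m / params.speed_mps) / 60.0
    return float(out) if out.ndim == 0 else out


def service_radius_m(minutes: float, params: DroneParams = DroneParams()) -> float:
    """Distance reachable within ``minutes`` — the inverse of
    :func:`delivery_minutes`."""
    if minutes < params.overhead_min:
        raise ValueError("below minimum delivery time")
    return (minutes * 60.0 - params.takeoff_s - params.dropoff_s) * params.speed_mps


def nearest_station(buildings: pd.DataFrame, stations: pd.DataFrame) -> pd.Series:
    """Euclidean nearest station per building; ties go to the lowest id."""
    if stations.empty:
        raise ValueError("no stations")
    st = stations.sort_values("station_id")
    st_xy = np.asarray([[p.x, p.y] for p in st["geometry"]])
    b_xy = np.asarray(
        [[g.centroid.x, g.centroid.y] for g in buildings["geometry"]]
    )
    d = cdist(b_xy, st_xy)
    ids = st["station_id"].to_numpy()[d.argmin(axis=1)]  # argmin: first on tie
    return pd.Series(ids, index=buildings.index, name="station_id")


@dataclass
class DroneTimeSurface:
    """Per-cell and per-building one-way drone minutes."""

    minutes: Grid          # min over stations; NaN where excluded
    bins: Grid             # integer bin index; 0 = excluded
    nofly_mask: Grid       # boolean
    buildings: pd.DataFrame  # building_id, drone_min, drone_bin, station_id, excluded


def drone_time_layers(
    stations: pd.DataFrame,
    template: Grid,
    buildings: pd.DataFrame,
    nofly,
    params: DroneParams = DroneParams(),
    interval_min: float = 10.0,
) -> DroneTimeSurface:
    """Minimum-over-stations delivery-minute surface and per-building times,
    binned into ``interval_min`` classes, with no-fly exclusions applied."""
    if stations.empty:
        raise ValueError("no stations")
    st = stations.sort_values("station_id")
    st_xy = np.asarray([[p.x, p.y] for p in st["geometry"]])
    st_ids = st["station_id"].to_numpy()

    xx, yy = template.centers()
    cell_xy = np.column_stack([xx, yy])
    d = cdist(cell_xy, st_xy)
    cell_min = delivery_minutes(d.min(axis=1), params)

    nofly = list(nofly) if nofly is not None else []
    mask = np.zeros(len(xx), dtype=bool)
    for poly in nofly:
        mask |= shapely.contains_xy(poly, xx, yy)
    cell_min = np.where(mask, np.nan, cell_min)
    k = np.zeros(len(cell_min), dtype=int)
    finite = np.isfinite(cell_min)
    k[finite] = np.maximum(
        1, np.ceil(cell_min[finite] / interval_min - 1e-12)
    ).astype(int)

    b_xy = np.asarray(
        [[g.centroid.x, g.centroid.y] for g in buildings["geometry"]]
    )
    excluded = np.zeros(len(b_xy), dtype=bool)
    for poly in nofly:
        excluded |= shapely.contains_xy(poly, b_xy[:, 0], b_xy[:, 1])
    db = cdist(b_xy, st_xy)
    b_min = delivery_minutes(db.min(axis=1), params)
    b_station = st_ids[db.argmin(axis=1)]
    from .roads import bin_label

    b_bin = np.array(
        [
            bin_label(max(1, int(np.ceil(m / interval_min - 1e-12))), interval_min)
            for m in b_min
        ],
        dtype=object,
    )
    b_min = np.where(excluded, np.nan, b_min)
    b_station = np.where(excluded, -1, b_station)
    b_bin[excluded] = EXCLUDED_BIN

    btab = pd.DataFrame(
        {
            "building_id": buildings["building_id"].to_numpy(),
            "drone_min": b_min,
            "drone_bin": b_bin,
            "station_id": b_station,
            "excluded": excluded,
        }
    )
    shape = template.data.shape
    return DroneTimeSurface(
        minutes=template.like(cell_min.reshape(shape)),
        bins=template.like(k.reshape(shape)),
        nofly_mask=template.like(mask.reshape(shape)),
        buildings=btab,
    )
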