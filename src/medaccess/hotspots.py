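"""Getis-Ord Gi* hotspot detection over building footprints.

The local statistic for location i with binary fixed-distance-band weights
w_ij (1 iff d(i,j) <= d, self included) is

    Gi* = (sum_j w_ij x_j - Xbar * W_i)
          / ( S * sqrt[ (n * W_i - W_i^2) / (n - 1) ] )

with W_i = sum_j w_ij, Xbar = mean(x) and S = sqrt(mean(x^2) - Xbar^2) (the
population standard deviation). Because the weights are binary,
sum_j w_ij^2 = W_i. The statistic is a z-score: large positive values mark
clusters of high vulnerability (hot spots), large negative values clusters of
low vulnerability (cold spots).

The search distance follows the study's convention: the mean, over points,
of the distance to the k-th nearest neighboring footprint (k = 30 by
default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

Z_THRESHOLDS = ((2.576, "99"), (1.960, "95"), (1.645, "90"))


class ConstantFieldError(ValueError):
    """All values identical: Gi* is undefined (S = 0)."""


def _as_xy(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return pts


def band_distance(points, k: int = 30) -> float:
    """Mean over points of the distance to the k-th nearest neighbor
    (self excluded). Used as the Gi* fixed-band search distance."""
    xy = _as_xy(points)
    n = len(xy)
    if n <= k:
        raise ValueError(
            f"need more than k={k} points (got {n}); use a smaller k"
        )
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=k + 1)
    return float(d[:, k].mean())


def gi_star(points, values, d: float) -> pd.DataFrame:
    """Gi* z-score per point with a fixed distance band of radius ``d``.

    Raises :class:`ConstantFieldError` when all values are equal. A point
    whose band covers every point (W_i = n) has an undefined statistic and
    gets NaN with ``isolated=True``.
    """
    xy = _as_xy(points)
    x = np.asarray(values, dtype=float)
    if len(x) != len(xy):
        raise ValueError("values length mismatch")
    if d <= 0:
        raise ValueError("band distance must be positive")
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.maximum((x ** 2).mean() - xbar ** 2, 0.0))
    if s == 0.0:
        raise ConstantFieldError("constant field: S = 0")

    tree = cKDTree(xy)
    pairs = tree.query_pairs(d, output_type="ndarray")
    w_sum = np.ones(n)                # self weight
    wx_sum = x.copy()
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(w_sum, i, 1.0)
        np.add.at(w_sum, j, 1.0)
        np.add.at(wx_sum, i, x[j])
        np.add.at(wx_sum, j, x[i])

    inner = (n * w_sum - w_sum ** 2) / (n - 1)
    isolated = inner <= 0
    denom = s * np.sqrt(np.where(isolated, np.nan, inner))
    z = (wx_sum - xbar * w_sum) / denom
    return pd.DataFrame(
        {
            "z": z,
            "w_sum": w_sum,
            "isolated": isolated,
            "category": [classify_z(v) for v in z],
        }
    )


def classify_z(z: float) -> str:
    """Hot/cold category at 90/95/99% confidence from a Gi* z-score."""
    if not np.isfinite(z):
        return "ns"
    for thr, level in Z_THRESHOLDS:
        if abs(z) >= thr:
            return ("hot" if z > 0 else "cold") + level
    return "ns"


def hotspots_for_index(
    scored: pd.DataFrame,
    buildings: pd.DataFrame,
    index_col: str,
    k: int = 30,
    d: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Run Gi* on a vulnerability index over building centroids.

    Incomplete rows are dropped. Returns (per-building table, band distance
    used)."""
    df = scored.merge(
        buildings[["building_id", "geometry"]], on="building_id", how="inner"
    )
    df = df[~df[index_col].isna()].reset_index(drop=True)
    xy = np.asarray([[g.centroid.x, g.centroid.y] for g in df["geometry"]])
    if d is None:
        d = band_distance(xy, k=k)
    res = gi_star(xy, df[index_col].to_numpy(), d)
    out = pd.DataFrame(
        {
            "building_id": df["building_id"].to_numpy(),
            "index": index_col,
            "value": df[index_col].to_numpy(),
            "z": res["z"].to_numpy(),
            "category": res["category"].to_numpy(),
        }
    )
    return out, d
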