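"""GeoJSON-backed I/O for vector feature tables.

Feature layers travel through the package as pandas DataFrames with a
``geometry`` column of shapely geometries; attribute columns are plain pandas
columns. Coordinates are projected meters throughout — no CRS transforms are
performed, and GeoJSON files written here carry the layer's native planar
coordinates.
"""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import mapping, shape


def write_geojson(df: pd.DataFrame, path, geometry_col: str = "geometry") -> None:
    features = []
    for _, row in df.iterrows():
        props = {k: _jsonable(v) for k, v in row.items() if k != geometry_col}
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(row[geometry_col]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path, geometry_col: str = "geometry") -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        row = dict(feat.get("properties") or {})
        row[geometry_col] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(v):
    if hasattr(v, "item"):  # numpy scalar
        return v.item()
    return v
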