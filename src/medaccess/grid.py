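"""Lightweight raster container on a regular meter grid.

All rasters in this package share one convention: row 0 is the northern-most
row, column 0 the western-most column, and cell values sit at cell centers.
Grids are serialized as ESRI ASCII grids (plain text), which any desktop GIS
can read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely


@dataclass
class Grid:
    """A single-band raster with a square cell size in meters.

    Parameters
    ----------
    data:
        2-D array, shape ``(nrows, ncols)``; row 0 is the top (north).
    x0:
        x coordinate of the west edge (left edge of column 0).
    y1:
        y coordinate of the north edge (top edge of row 0).
    cell:
        cell size in meters (square cells).
    nodata:
        value written for missing cells on export.
    """

    data: np.ndarray
    x0: float
    y1: float
    cell: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        return (
            self.x0,
            self.y1 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y1,
        )

    def xs(self) -> np.ndarray:
        """Cell-center x coordinates (west to east)."""
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell

    def ys(self) -> np.ndarray:
        """Cell-center y coordinates (north to south, matching row order)."""
        return self.y1 - (np.arange(self.nrows) + 0.5) * self.cell

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) cell-center coordinates in row-major order."""
        xx, yy = np.meshgrid(self.xs(), self.ys())
        return xx.ravel(), yy.ravel()

    def like(self, data: np.ndarray) -> "Grid":
        """A new grid on the same georeferencing with different data."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return Grid(data, self.x0, self.y1, self.cell, self.nodata)

    def full(self, value: float, dtype=float) -> "Grid":
        return self.like(np.full(self.data.shape, value, dtype=dtype))

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.x0 == other.x0
            and self.y1 == other.y1
            and self.cell == other.cell
        )

    def contains_mask(self, geoms) -> np.ndarray:
        """Boolean 2-D mask: cell center covered by any of ``geoms``."""
        xx, yy = self.centers()
        mask = np.zeros(xx.shape[0], dtype=bool)
        for g in np.atleast_1d(geoms):
            if g is None or g.is_empty:
                continue
            mask |= shapely.contains_xy(g, xx, yy)
        return mask.reshape(self.data.shape)

    # --- text I/O -------------------------------------------------------

    def write_ascii(self, path, fmt: str = "%.6g") -> None:
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0:.6f}\n"
            f"yllcorner {self.y1 - self.nrows * self.cell:.6f}\n"
            f"cellsize {self.cell:.6f}\n"
            f"NODATA_value {self.nodata:.6g}\n"
        )
        data = np.where(np.isfinite(self.data.astype(float)), self.data, self.nodata)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt=fmt)

    @classmethod
    def read_ascii(cls, path) -> "Grid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
        data = data.reshape(nrows, ncols)
        cell = meta["cellsize"]
        nodata = meta.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        return cls(
            data,
            x0=meta["xllcorner"],
            y1=meta["yllcorner"] + nrows * cell,
            cell=cell,
            nodata=nodata,
        )


def make_grid(bounds: tuple[float, float, float, float], cell: float,
              fill: float = 0.0, dtype=float) -> Grid:
    """An empty grid covering ``bounds`` = (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate bounds")
    ncols = int(np.ceil((xmax - xmin) / cell))
    nrows = int(np.ceil((ymax - ymin) / cell))
    data = np.full((nrows, ncols), fill, dtype=dtype)
    return Grid(data, x0=xmin, y1=ymin + nrows * cell, cell=cell)


def mask_to_polygons(mask: Grid):
    """Dissolve the True cells of a boolean grid into polygons.

    Returns a list of shapely Polygons (the connected clumps of the mask),
    used to turn a thresholded elevation surface into flood-zone polygons.
    """
    rows, cols = np.nonzero(mask.data.astype(bool))
    if rows.size == 0:
        return []
    x_left = mask.x0 + cols * mask.cell
    y_top = mask.y1 - rows * mask.cell
    boxes = shapely.box(x_left, y_top - mask.cell, x_left + mask.cell, y_top)
    merged = shapely.union_all(boxes)
    merged = shapely.make_valid(merged)
    if merged.geom_type == "Polygon":
        return [merged]
    return [g for g in merged.geoms if g.geom_type == "Polygon"]
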