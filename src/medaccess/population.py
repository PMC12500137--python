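"""Dasymetric population disaggregation and zonal aggregation.

Census-block counts (total and 60+) are spread onto a raster: land-cover
classes with a preset density of zero (open water, wetland by default) and an
uninhabitable mask (commercial/government parcels, buffered major roads)
receive nothing; the block's population is split uniformly over its remaining
habitable cells (areal weighting). Mass is conserved per block to 1e-6
relative: re-aggregating the raster over a block recovers the census count.

Blocks with no habitable cell fall back to a uniform spread over the whole
block footprint (conservation outranks ancillary fidelity); blocks smaller
than a single cell put all mass in the cell containing their representative
point. Both fallbacks are logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .grid import Grid
from .region import DEFAULT_ZERO_CLASSES

logger = logging.getLogger(__name__)


def uninhabitable_mask(
    template: Grid,
    parcels: pd.DataFrame | None = None,
    roads: pd.DataFrame | None = None,
    uninhabitable_landuse: tuple[str, ...] = ("commercial", "government"),
    road_buffer_m: float = 30.0,
    road_levels: tuple[int, ...] = (1,),
) -> Grid:
    """Boolean raster of cells no one lives in: flagged parcels plus a
    buffer around major (level-1) roads."""
    xx, yy = template.centers()
    mask = np.zeros(len(xx), dtype=bool)
    if parcels is not None and len(parcels):
        flagged = parcels[parcels["landuse"].isin(uninhabitable_landuse)]
        for geom in flagged["geometry"]:
            mask |= shapely.contains_xy(geom, xx, yy)
    if roads is not None and len(roads):
        major = roads[roads["level"].isin(road_levels)]
        if len(major):
            buf = shapely.union_all(
                shapely.buffer(major["geometry"].to_numpy(), road_buffer_m)
            )
            mask |= shapely.contains_xy(buf, xx, yy)
    return template.like(mask.reshape(template.data.shape))


def block_id_grid(blocks: pd.DataFrame, template: Grid) -> Grid:
    """Integer raster of the containing block id per cell (-1 = none)."""
    xx, yy = template.centers()
    out = np.full(len(xx), -1, dtype=int)
    for _, blk in blocks.iterrows():
        geom = blk["geometry"]
        minx, miny, maxx, maxy = geom.bounds
        cand = np.nonzero(
            (xx >= minx) & (xx <= maxx) & (yy >= miny) & (yy <= maxy)
        )[0]
        if cand.size == 0:
            continue
        inside = shapely.contains_xy(geom, xx[cand], yy[cand])
        hit = cand[inside]
        out[hit[out[hit] == -1]] = int(blk["block_id"])
    return template.like(out.reshape(template.data.shape))


def disaggregate(
    blocks: pd.DataFrame,
    landcover: Grid,
    mask: Grid | None = None,
    zero_classes=DEFAULT_ZERO_CLASSES,
    block_ids: Grid | None = None,
) -> tuple[Grid, Grid, Grid]:
    """Spread block populations over habitable cells.

    Returns (pop_total, pop_60plus, block_id) grids. Cell values are
    fractional persons; rounding happens only in reports.
    """
    # zero classes absent from the map are legal: config lists may be broader
    zero_classes = set(zero_classes)
    if block_ids is None:
        block_ids = block_id_grid(blocks, landcover)
    if mask is not None and not landcover.same_georef(mask):
        raise ValueError("mask grid mismatch")
    if not landcover.same_georef(block_ids):
        raise ValueError("block id grid mismatch")

    habitable = ~np.isin(landcover.data.astype(int), sorted(zero_classes))
    if mask is not None:
        habitable &= ~mask.data.astype(bool)

    pop_t = np.zeros(landcover.data.shape)
    pop_60 = np.zeros(landcover.data.shape)
    bid = block_ids.data
    for _, blk in blocks.iterrows():
        b = int(blk["block_id"])
        in_block = bid == b
        cells = in_block & habitable
        n = int(cells.sum())
        if n == 0:
            cells = in_block
            n = int(cells.sum())
            if n == 0:
                # block smaller than a cell: all mass at its representative point
                p = blk["geometry"].representative_point()
                col = int(np.clip((p.x - landcover.x0) / landcover.cell, 0,
                                  landcover.ncols - 1))
                row = int(np.clip((landcover.y1 - p.y) / landcover.cell, 0,
                                  landcover.nrows - 1))
                pop_t[row, col] += blk["pop_total"]
                pop_60[row, col] += blk["pop_60plus"]
                logger.info("block %d below raster resolution; point fallback", b)
                continue
            logger.info("block %d has no habitable cells; uniform fallback", b)
        pop_t[cells] += blk["pop_total"] / n
        pop_60[cells] += blk["pop_60plus"] / n
    return landcover.like(pop_t), landcover.like(pop_60), block_ids


def zonal_population(
    pop_total: Grid,
    pop_60plus: Grid,
    zones: dict[str, tuple[Grid, str]],
    interval_min: float = 10.0,
) -> pd.DataFrame:
    """Aggregate population by travel-time zone for each delivery mode.

    ``zones`` maps mode name -> (bin-index grid, label for bin 0); bin 0 is
    the mode's unreachable/excluded class. Shares per mode sum to 1 over
    bins plus the special row.
    """
    from .roads import bin_label

    rows = []
    for mode, (zgrid, zero_label) in zones.items():
        if not pop_total.same_georef(zgrid):
            raise ValueError(f"zone grid mismatch for mode {mode!r}")
        k = zgrid.data.astype(int)
        total = pop_total.data.sum()
        total60 = pop_60plus.data.sum()
        for kk in sorted(np.unique(k)):
            sel = k == kk
            pt = pop_total.data[sel].sum()
            p60 = pop_60plus.data[sel].sum()
            label = zero_label if kk == 0 else bin_label(kk, interval_min)
            rows.append(
                {
                    "mode": mode,
                    "bin_index": kk,
                    "bin": label,
                    "pop_total": pt,
                    "pop_60plus": p60,
                    "share_total": pt / total if total else 0.0,
                    "share_60plus": p60 / total60 if total60 else 0.0,
                }
            )
    return pd.DataFrame(rows)
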