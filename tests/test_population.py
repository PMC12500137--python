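"""Dasymetric disaggregation: mass conservation, zero classes, zonal sums."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from medaccess.grid import Grid, make_grid
from medaccess.population import (
    block_id_grid,
    disaggregate,
    uninhabitable_mask,
    zonal_population,
)
from medaccess.region import LC_CROPLAND, LC_WATER, generate_region

from conftest import small_config


def _landcover(codes, cell=10.0):
    codes = np.asarray(codes)
    return Grid(codes, x0=0.0, y1=codes.shape[0] * cell, cell=cell)


def _blocks(polys, pops, pop60s):
    return pd.DataFrame(
        {
            "block_id": range(len(polys)),
            "geometry": polys,
            "pop_total": pops,
            "pop_60plus": pop60s,
        }
    )


class TestMask:
    def test_empty_inputs_give_all_false(self):
        t = make_grid((0, 0, 100, 100), 10.0)
        m = uninhabitable_mask(t)
        assert not m.data.any()

    def test_commercial_parcel_masks_its_cells(self):
        t = make_grid((0, 0, 100, 100), 10.0)
        parcels = pd.DataFrame(
            {"geometry": [box(0, 0, 30, 30)], "landuse": ["commercial"]}
        )
        m = uninhabitable_mask(t, parcels=parcels)
        xx, yy = t.centers()
        inside = (xx < 30) & (yy < 30)
        assert m.data.ravel()[inside].all()
        assert not m.data.ravel()[~inside].any()

    def test_masked_area_matches_polygon_area(self):
        t = make_grid((0, 0, 1_000, 1_000), 10.0)
        poly = box(100, 100, 600, 450)
        parcels = pd.DataFrame({"geometry": [poly], "landuse": ["government"]})
        m = uninhabitable_mask(t, parcels=parcels)
        cell_area = t.cell ** 2
        assert m.data.sum() * cell_area == pytest.approx(poly.area, rel=0.02)


class TestDisaggregate:
    def test_areal_weighting_splits_by_habitable_cells(self):
        # one block over a 1x10 strip; 4 west cells are water
        lc = _landcover([[LC_WATER] * 4 + [LC_CROPLAND] * 6])
        blocks = _blocks([box(0, 0, 100, 10)], [100], [40])
        pt, p60, _ = disaggregate(blocks, lc)
        assert pt.data[0, :4].sum() == 0.0
        assert pt.data[0, 4:].sum() == pytest.approx(100.0, abs=1e-9)
        # 60:40 split of habitable cells splits the population 60:40
        assert pt.data[0, 4:7].sum() == pytest.approx(50.0)
        assert p60.data.sum() == pytest.approx(40.0)

    def test_all_water_block_falls_back_uniform_and_conserves(self):
        lc = _landcover([[LC_WATER] * 10])
        blocks = _blocks([box(0, 0, 100, 10)], [100], [10])
        pt, _, _ = disaggregate(blocks, lc)
        assert pt.data.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(pt.data, 10.0)

    def test_three_block_fixture_conserves_each_block(self):
        lc = _landcover(np.full((6, 6), LC_CROPLAND))
        polys = [box(0, 0, 60, 20), box(0, 20, 60, 40), box(0, 40, 60, 60)]
        blocks = _blocks(polys, [120, 7, 55], [30, 3, 11])
        pt, p60, bid = disaggregate(blocks, lc)
        for _, blk in blocks.iterrows():
            sel = bid.data == blk["block_id"]
            assert pt.data[sel].sum() == pytest.approx(
                blk["pop_total"], rel=1e-6
            )
            assert p60.data[sel].sum() == pytest.approx(
                blk["pop_60plus"], rel=1e-6
            )

    def test_region_wide_conservation_and_zero_classes(self):
        region = generate_region(small_config(seed=21))
        mask = uninhabitable_mask(region.landcover, region.parcels, region.roads)
        pt, p60, bid = disaggregate(region.blocks, region.landcover, mask)
        for _, blk in region.blocks.iterrows():
            sel = bid.data == blk["block_id"]
            if not sel.any():
                continue
            assert pt.data[sel].sum() == pytest.approx(
                float(blk["pop_total"]), rel=1e-6
            )
        zero = np.isin(region.landcover.data.astype(int), [11, 90])
        habitable_zero = zero & (bid.data >= 0)
        # zero-density cells receive population only via whole-block fallback
        fallback_blocks = []
        for _, blk in region.blocks.iterrows():
            sel = (bid.data == blk["block_id"]) & ~zero & ~mask.data.astype(bool)
            if sel.sum() == 0:
                fallback_blocks.append(blk["block_id"])
        regular = habitable_zero & ~np.isin(bid.data, fallback_blocks)
        assert pt.data[regular].sum() == 0.0

    def test_grid_mismatch_rejected(self):
        lc = _landcover(np.full((4, 4), LC_CROPLAND))
        other = make_grid((0, 0, 999, 999), 31.0)
        blocks = _blocks([box(0, 0, 40, 40)], [10], [1])
        with pytest.raises(ValueError):
            disaggregate(blocks, lc, mask=other)


class TestZonal:
    def test_single_bin_reproduces_totals_and_partition_sums(self):
        lc = _landcover(np.full((4, 4), LC_CROPLAND))
        blocks = _blocks([box(0, 0, 40, 40)], [200], [50])
        pt, p60, _ = disaggregate(blocks, lc)
        ones = lc.like(np.ones((4, 4), dtype=int))
        tab = zonal_population(pt, p60, {"drone": (ones, "excluded")})
        assert len(tab) == 1
        assert tab["pop_total"].iloc[0] == pytest.approx(200.0)
        assert tab["share_total"].iloc[0] == pytest.approx(1.0)

        zones = lc.like(np.array([[1, 1, 2, 2]] * 4, dtype=int))
        tab2 = zonal_population(pt, p60, {"vehicle": (zones, "unreachable")})
        assert tab2["pop_total"].sum() == pytest.approx(200.0)
        assert tab2["share_total"].sum() == pytest.approx(1.0)
        assert tab2["share_60plus"].sum() == pytest.approx(1.0)

    def test_unreachable_rows_reported_separately(self):
        lc = _landcover(np.full((2, 2), LC_CROPLAND))
        blocks = _blocks([box(0, 0, 20, 20)], [80], [20])
        pt, p60, _ = disaggregate(blocks, lc)
        zones = lc.like(np.array([[0, 1], [1, 1]], dtype=int))
        tab = zonal_population(pt, p60, {"vehicle": (zones, "unreachable")})
        row0 = tab[tab["bin"] == "unreachable"].iloc[0]
        assert row0["pop_total"] == pytest.approx(20.0)

    def test_grid_mismatch_rejected(self):
        lc = _landcover(np.full((2, 2), LC_CROPLAND))
        blocks = _blocks([box(0, 0, 20, 20)], [8], [2])
        pt, p60, _ = disaggregate(blocks, lc)
        bad = make_grid((0, 0, 30, 30), 10.0, dtype=int)
        with pytest.raises(ValueError):
            zonal_population(pt, p60, {"vehicle": (bad, "unreachable")})
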