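"""Vulnerability rubric: sub-scores, VAT/VATF composites, block joins."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

from medaccess.scoring import (
    assign_age_pct,
    compute_indices,
    score_components,
)


class TestScoreComponents:
    @pytest.mark.parametrize(
        "age,rt,flood,expected",
        [
            (45.0, 25.0, 1, (3, 3, 1)),   # mid-rubric worked example
            (10.0, 8.0, 1, (1, 1, 1)),    # minima: VAT 2, VATF 3
            (90.0, 55.0, 4, (5, 5, 4)),   # maxima: VAT 10, VATF 14
        ],
    )
    def test_rubric_lookups(self, age, rt, flood, expected):
        assert score_components(age, rt, flood) == expected

    @pytest.mark.parametrize(
        "age,expected", [(0, 1), (20, 1), (20.001, 2), (40, 2), (60, 3),
                         (80, 4), (80.001, 5), (100, 5)]
    )
    def test_age_boundaries_take_lower_score(self, age, expected):
        assert score_components(age, 5.0, 1)[0] == expected

    @pytest.mark.parametrize(
        "rt,expected", [(0, 1), (10, 1), (10.001, 2), (20, 2), (30, 3),
                        (40, 4), (40.001, 5), (120, 5)]
    )
    def test_time_boundaries_take_lower_score(self, rt, expected):
        assert score_components(50.0, rt, 1)[1] == expected

    def test_unreachable_gets_maximum_time_score(self):
        assert score_components(10.0, np.nan, 1)[1] == 5

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_components(101.0, 5.0, 1)
        with pytest.raises(ValueError):
            score_components(50.0, 5.0, 0)
        with pytest.raises(ValueError):
            score_components(50.0, -1.0, 1)

    def test_full_grid_attains_documented_ranges(self):
        ages = [10, 30, 50, 70, 90]
        times = [5, 15, 25, 35, 45]
        vat, vatf = set(), set()
        for a, t, f in itertools.product(ages, times, range(1, 5)):
            sa, st_, sf = score_components(a, t, f)
            vat.add(sa + st_)
            vatf.add(sa + st_ + sf)
        assert vat == set(range(2, 11))
        assert vatf == set(range(3, 15))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        a1=st.floats(0, 100), a2=st.floats(0, 100),
        t1=st.floats(0, 200), t2=st.floats(0, 200),
    )
    def test_subscores_monotone_in_raw_inputs(self, a1, a2, t1, t2):
        lo_a, hi_a = sorted((a1, a2))
        lo_t, hi_t = sorted((t1, t2))
        s_lo = score_components(lo_a, lo_t, 1)
        s_hi = score_components(hi_a, hi_t, 1)
        assert s_hi[0] >= s_lo[0]
        assert s_hi[1] >= s_lo[1]


class TestAssignAgePct:
    def _blocks(self):
        return pd.DataFrame(
            {
                "block_id": [0, 1, 2],
                "geometry": [box(0, 0, 10, 10), box(10, 0, 20, 10),
                             box(20, 0, 30, 10)],
                "pop_total": [100, 100, 0],
                "pop_60plus": [45, 10, 0],
            }
        )

    def test_simple_containment(self):
        b = pd.DataFrame({"building_id": [1],
                          "geometry": [Point(5, 5).buffer(1)]})
        out = assign_age_pct(b, self._blocks())
        assert out["age_pct"].iloc[0] == pytest.approx(45.0)

    def test_straddling_footprint_takes_largest_overlap(self):
        # blocks span y in [0,10]; footprint pokes above so its interior
        # point falls outside and the area rule decides: 8 m in block 0 vs
        # 10 m in block 1
        geom = box(2, 9.5, 20, 12)
        b = pd.DataFrame({"building_id": [1], "geometry": [geom]})
        out = assign_age_pct(b, self._blocks())
        assert out["block_id"].iloc[0] == 1
        assert out["age_pct"].iloc[0] == pytest.approx(10.0)

    def test_empty_block_flagged_zero(self):
        b = pd.DataFrame({"building_id": [1],
                          "geometry": [Point(25, 5).buffer(1)]})
        out = assign_age_pct(b, self._blocks())
        assert out["age_pct"].iloc[0] == 0.0
        assert out["age_flag"].iloc[0] == "empty_block"

    def test_footprint_outside_all_blocks_unassigned(self):
        b = pd.DataFrame({"building_id": [1],
                          "geometry": [Point(99, 99).buffer(1)]})
        out = assign_age_pct(b, self._blocks())
        assert np.isnan(out["age_pct"].iloc[0])
        assert out["age_flag"].iloc[0] == "outside_blocks"


class TestComputeIndices:
    def _inputs(self):
        age = pd.DataFrame(
            {"building_id": [1, 2, 3], "age_pct": [45.0, 10.0, 90.0],
             "block_id": [0, 0, 1], "age_flag": ["", "", ""]}
        )
        times = pd.DataFrame(
            {"building_id": [1, 2, 3],
             "round_trip_min": [25.0, 8.0, np.nan],
             "status": ["ok", "ok", "no_path"]}
        )
        flood = pd.DataFrame(
            {"building_id": [1, 2, 3], "flood_code": [1, 1, 4],
             "flood_label": ["not_affected"] * 2 + ["inundated"],
             "no_route": [False, False, True]}
        )
        return age, times, flood

    def test_rowwise_sums_match_independent_recomputation(self):
        age, times, flood = self._inputs()
        out = compute_indices(age, times, flood)
        for _, row in out.iterrows():
            a, t, f = score_components(
                row["age_pct"], row["round_trip_min"], int(row["flood_code"])
            )
            assert row["VAT"] == a + t
            assert row["VATF"] == a + t + f

    def test_vatf_minus_vat_is_flood_score(self):
        age, times, flood = self._inputs()
        out = compute_indices(age, times, flood)
        assert ((out["VATF"] - out["VAT"]) == out["flood_score"]).all()

    def test_missing_component_flagged_incomplete(self):
        age, times, flood = self._inputs()
        age.loc[0, "age_pct"] = np.nan
        out = compute_indices(age, times, flood)
        assert out["incomplete"].iloc[0]
        assert np.isnan(out["VAT"].iloc[0])
        assert not out["incomplete"].iloc[1:].any()

    def test_sorted_by_building_id(self):
        age, times, flood = self._inputs()
        out = compute_indices(age.iloc[::-1], times, flood)
        assert list(out["building_id"]) == sorted(out["building_id"])
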