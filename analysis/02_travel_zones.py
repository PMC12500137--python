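#!/usr/bin/env python
"""Vehicle round trips vs one-way drone delivery per residence.

Computes closest-pharmacy network times (doubled to round trips, binned at
10 minutes) and the drone delivery-time surface, then prints the per-bin
residence counts — the travel-zone comparison at building level.
"""

from pathlib import Path

from medaccess.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    res = run_pipeline(PipelineConfig(), out_dir=OUT, upto="drone")
    vt = res.times
    print("vehicle round-trip bins (residences):")
    print(vt["bin"].value_counts().sort_index().to_string())
    print(f"unreachable by road: {int(vt['one_way_min'].isna().sum())} "
          "(road-disconnected island)")
    db = res.drone_surface.buildings
    print("\ndrone one-way bins (residences):")
    print(db["drone_bin"].value_counts().sort_index().to_string())
    print(f"no-fly-excluded: {int(db['excluded'].sum())}")
    served = db[~db["excluded"]]
    print(f"\nshare of served residences within 10 min by drone: "
          f"{(served['drone_min'] <= 10).mean():.1%}")
    reach = vt[vt["round_trip_min"].notna()]
    print(f"share of road-connected residences within 10 min round trip: "
          f"{(reach['round_trip_min'] <= 10).mean():.1%}")


if __name__ == "__main__":
    main()
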