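#!/usr/bin/env python
"""Population reached per travel-time zone, by delivery mode.

Disaggregates block populations (total and 60+) dasymetrically onto the
land-cover grid, overlays the vehicle and drone zone rasters, and prints the
per-bin population shares — the served-population comparison between modes.
"""

from pathlib import Path

from medaccess.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    res = run_pipeline(PipelineConfig(), out_dir=OUT, upto="population")
    zon = res.zonal.copy()
    zon["share_total"] = (100 * zon["share_total"]).round(1)
    zon["share_60plus"] = (100 * zon["share_60plus"]).round(1)
    print(zon[["mode", "bin", "pop_total", "pop_60plus",
               "share_total", "share_60plus"]].round(1).to_string(index=False))
    drone10 = zon[(zon["mode"] == "drone") & (zon["bin_index"] == 1)]
    veh10 = zon[(zon["mode"] == "vehicle") & (zon["bin_index"] == 1)]
    print(f"\nwithin 10 minutes: drone reaches {drone10['share_total'].sum():.1f}% "
          f"of the population vs {veh10['share_total'].sum():.1f}% by car "
          "round trip")


if __name__ == "__main__":
    main()
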