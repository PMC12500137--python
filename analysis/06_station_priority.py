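#!/usr/bin/env python
"""Drone-station prioritization by served-population vulnerability.

Assigns each residence (outside no-fly zones) to its Euclidean-nearest
station and prints per-station counts and VAT/VATF moments — the table that
says which stations serve the most vulnerable patients.
"""

from pathlib import Path

from medaccess.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    res = run_pipeline(PipelineConfig(), out_dir=OUT, upto="report")
    st = res.station_table
    cols = ["station_id", "building_count", "VAT_mean", "VAT_std",
            "VATF_mean", "VATF_std"]
    print(st[cols].round(2).to_string(index=False))
    top = st.loc[st["VATF_mean"].idxmax()]
    print(f"\nstation {int(top['station_id'])} serves the most vulnerable "
          f"population (mean VATF {top['VATF_mean']:.2f}) and is the "
          "priority for resource allocation")
    print(f"artifacts written to {OUT}")


if __name__ == "__main__":
    main()
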