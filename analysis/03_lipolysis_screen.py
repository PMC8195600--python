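#!/usr/bin/env python
"""Lipolysis screen analysis: normalization, hit calling, QC.

Loads the simulated 16-plate screen written by 01_simulate_inputs.py
(regenerating it if absent), runs the full pipeline — pooled glycerol
standard curve, per-position normalization across plates, fold change vs
DMSO, inclusive >= 40%-reduction hit calling — and compares the called
hits against the planted truth.  Writes compound results, the top-10
table and per-plate QC under results/screen/.
"""

from pathlib import Path

import pandas as pd

from adipoquant import screen, synth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    wells_csv = DATA / "screen_wells.csv"
    if not wells_csv.exists():
        import importlib
        sim = importlib.import_module("01_simulate_inputs")
        sim.main()
    plates = screen.load_screen_long_csv(wells_csv)
    truth = pd.read_csv(DATA / "screen_truth.csv")

    out = screen.run_screen_pipeline(plates)
    out["results"].to_csv(OUT / "compound_results.csv", index=False)
    out["top10"].to_csv(OUT / "top10.csv", index=False)
    out["qc"].to_csv(OUT / "plate_qc.csv", index=False)

    c = out["curve"]
    print(f"standard curve: slope {c.slope:.4f} AU/(mg/ml), intercept {c.intercept:.4f} AU, "
          f"r^2 {c.r_squared:.6f}")

    planted = set(truth.loc[truth.true_reduction > 0, "compound_id"])
    called = set(out["hits"]["compound_id"])
    print(f"hits: {len(called)}/{len(out['results'])} compounds at >= 40% reduction "
          f"(planted {len(planted)}; true positives {len(called & planted)}, "
          f"false positives {len(called - planted)})")
    print(f"QC: {int(out['qc'].flag_no_stimulation.sum())} plates flagged for failed "
          f"stimulation, {int(out['qc'].flag_dmso_cv.sum())} for DMSO CV; "
          f"mean positive-control fold {out['qc'].positive_control_fold.mean():.2f}")
    print("top 10 inhibitors by log2 fold change:")
    print(out["top10"][["compound_id", "plate_id", "log2_fold", "reduction"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
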