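#!/usr/bin/env python
"""Generate one of every synthetic input the pipeline consumes.

Writes a reporter fish image, a BODIPY-stained fish image (as TIFF +
sidecar + ground-truth masks), a 16-plate lipolysis screen with edge bias
and 29 planted inhibitors, a fed/fasted growth cohort, and a pair of flow
samples — all under results/data/.
"""

from pathlib import Path

import pandas as pd
import tifffile

from adipoquant import imgio, screen, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20210611


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    img, truth = synth.generate_fish_image(synth.ImageSimParams(seed=SEED))
    imgio.write_fish_image(img, OUT / "fish.tif", extra_meta={"seed": SEED})
    tifffile.imwrite(OUT / "fish_truth_adipose.tif", truth.adipose_mask.astype("uint8"))
    print(f"fish image: planted adipose area {truth.adipose_area_px} px "
          f"({truth.adipose_area_px * img.pixel_size**2:.0f} um^2), "
          f"{len(truth.per_blob_params)} blobs")

    bimg, btruth = synth.generate_bodipy_image(synth.ImageSimParams(seed=SEED + 1))
    imgio.write_fish_image(bimg, OUT / "bodipy.tif", extra_meta={"seed": SEED + 1})
    print(f"bodipy image: planted adipose area {btruth.adipose_area_px} px")

    layouts = [synth.default_layout(i) for i in range(16)]
    inhibitors = synth.plant_inhibitors(layouts, 29, 0.5, seed=SEED)
    plates, truth_table = synth.generate_screen(synth.ScreenSimParams(
        position_bias=synth.edge_bias_grid(), inhibitor_effects=inhibitors,
        cv=0.05, seed=SEED))
    screen.plates_to_long(plates).to_csv(OUT / "screen_wells.csv", index=False)
    truth_table.to_csv(OUT / "screen_truth.csv", index=False)
    print(f"screen: {len(plates)} plates, {len(truth_table)} compounds, "
          f"{len(inhibitors)} planted inhibitors at 50% reduction")

    cohort_df = synth.generate_cohort(synth.CohortSimParams(seed=SEED))
    cohort_df.to_csv(OUT / "cohort_fed_fasted.csv", index=False)
    hfd_df = synth.generate_cohort(synth.CohortSimParams(
        groups=[("control_feed", 24), ("HFD", 24)], days=[0, 7, 14], seed=SEED + 2))
    hfd_df.to_csv(OUT / "cohort_hfd.csv", index=False)
    print(f"cohorts: {cohort_df.fish_id.nunique()} fed/fasted fish, "
          f"{hfd_df.fish_id.nunique()} diet fish")

    for name, frac, seed in (("flow_oleic", 0.65, SEED + 3), ("flow_bsa", 0.0, SEED + 4)):
        s = synth.generate_flow_sample(50_000, frac, seed=seed, condition=name)
        pd.DataFrame({"tdtomato_au": s.tdtomato, "gfp_au": s.gfp,
                      "true_label": s.true_label}).to_csv(OUT / f"{name}.csv", index=False)
    print("flow: 50k-event oleic-acid (65% positive) and BSA control samples")


if __name__ == "__main__":
    main()
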