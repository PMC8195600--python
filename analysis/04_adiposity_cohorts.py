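#!/usr/bin/env python
"""Longitudinal adiposity: fed vs fasted and control vs high-fat diet.

Summarizes the simulated repeated-measures cohorts (mean, 95% CI per
group per day) for area, standard length and area/SL, runs the per-day
nonparametric comparisons, and plots the trajectories.  Outputs under
results/cohorts/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from adipoquant import cohort, synth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "cohorts"


def analyze(df: pd.DataFrame, tag: str) -> None:
    cohort.validate_cohort(df)
    for metric in ("area", "standard_length", "area_per_sl"):
        s = cohort.summarize_longitudinal(df, metric)
        s.to_csv(OUT / f"{tag}_summary_{metric}.csv", index=False)
    tests = []
    for day in sorted(df["day"].unique()):
        rep = cohort.compare_groups(df, "area_per_sl", day=day)
        tests.append({"day": day, "test": rep["test"],
                      "statistic": rep["statistic"], "p": rep["p"]})
    tdf = pd.DataFrame(tests)
    tdf.to_csv(OUT / f"{tag}_tests_area_per_sl.csv", index=False)

    s = cohort.summarize_longitudinal(df, "area_per_sl")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for g, grp in s.groupby("group"):
        ax.errorbar(grp["day"], grp["mean"],
                    yerr=[grp["mean"] - grp["ci_low"], grp["ci_high"] - grp["mean"]],
                    marker="o", capsize=3, label=g)
    ax.set_xlabel("day")
    ax.set_ylabel("adipose area / SL (um^2/mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / f"{tag}_area_per_sl.png", dpi=150)
    plt.close(fig)

    print(f"[{tag}] per-day Mann-Whitney on area/SL:")
    print(tdf.to_string(index=False))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if not (DATA / "cohort_fed_fasted.csv").exists():
        import importlib
        importlib.import_module("01_simulate_inputs").main()

    ff = pd.read_csv(DATA / "cohort_fed_fasted.csv")
    analyze(ff, "fed_fasted")
    fasted = ff[ff.group == "fasted"].groupby("day")["area_um2"].mean()
    print(f"fasted mean area vs day 0: "
          + ", ".join(f"day {d:g}: {v / fasted[0.0]:.2f}x" for d, v in fasted.items()))

    hfd = pd.read_csv(DATA / "cohort_hfd.csv")
    analyze(hfd, "hfd")


if __name__ == "__main__":
    main()
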