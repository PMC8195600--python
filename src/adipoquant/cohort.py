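"""Downstream adiposity statistics.

Adipose area is normalized to standard length (a BMI-like index for fish),
longitudinal cohorts are summarized as per-group, per-day means with
t-based 95% confidence intervals, group comparisons use nonparametric
tests (Mann-Whitney for two groups; Kruskal-Wallis with Dunn's pairwise
post-hoc for more), and flow-cytometry percent-positive is gated on a
quantile of a negative-control sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import FlowSample

__all__ = [
    "normalize_bmi",
    "validate_cohort",
    "summarize_longitudinal",
    "compare_groups",
    "dunn_posthoc",
    "percent_positive",
]

METRICS = {
    "area": "area_um2",
    "standard_length": "standard_length_mm",
    "area_per_sl": "area_per_sl_um2_per_mm",
}


def normalize_bmi(area: float | np.ndarray, standard_length: float | np.ndarray) -> float | np.ndarray:
    """Adipose area (µm²) per mm of standard length — the adiposity index."""
    sl = np.asarray(standard_length, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("standard_length must be > 0 mm")
    out = np.asarray(area, dtype=float) / sl
    return float(out) if np.isscalar(area) and np.isscalar(standard_length) else out


def validate_cohort(data: pd.DataFrame) -> None:
    """Enforce the repeated-measures bookkeeping: one row per (fish, day)."""
    if data.duplicated(subset=["fish_id", "day"]).any():
        raise ValueError("duplicate (fish_id, day) measurement rows")
    if (data["area_um2"] < 0).any():
        raise ValueError("negative adipose area")
    if (data["standard_length_mm"] <= 0).any():
        raise ValueError("non-positive standard length")


def summarize_longitudinal(data: pd.DataFrame, metric: str = "area_per_sl") -> pd.DataFrame:
    """Per-group, per-day mean with t-based 95% CI and n.

    Groups with n < 2 on a day get NaN CI bounds and ``ci_defined=False``.
    """
    col = METRICS.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    rows = []
    for (group, day), grp in data.groupby(["group", "day"], sort=True):
        vals = grp[col].to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            half = float(stats.t.ppf(0.975, n - 1)) * sem
            lo, hi, defined = mean - half, mean + half, True
        else:
            lo = hi = np.nan
            defined = False
        rows.append({"group": group, "day": day, "metric": metric, "mean": mean,
                     "ci_low": lo, "ci_high": hi, "n": n, "ci_defined": defined})
    return pd.DataFrame(rows)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided Mann-Whitney; exact null distribution for small samples
    without ties, tie-corrected normal approximation otherwise."""
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size) <= 20 and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return {"test": "mannwhitney", "mode": "exact" if exact else "asymptotic",
            "statistic": float(res.statistic), "p": float(res.pvalue)}


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after Kruskal-Wallis.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)).  Raw two-sided p-values
    are adjusted by Holm (default), Bonferroni or Sidak.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = {g: groups[g].size for g in labels}
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, start = {}, 0
    for g in labels:
        mean_rank[g] = ranks[start:start + n[g]].mean()
        start += n[g]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_base * (1 / n[a] + 1 / n[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(min(p, 1.0))})
    df = pd.DataFrame(rows)

    m = len(df)
    p = df["p_raw"].to_numpy()
    if adjust == "bonferroni":
        adj = np.minimum(p * m, 1.0)
    elif adjust == "sidak":
        adj = 1 - (1 - p) ** m
    elif adjust == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df["p_adjusted"] = adj
    df["adjustment"] = adjust
    return df


def compare_groups(data: pd.DataFrame, metric: str = "area_per_sl",
                   day: int | None = None, adjust: str = "holm") -> dict:
    """Nonparametric group comparison at one day (or pooled over days).

    Two groups: two-sided Mann-Whitney.  More: Kruskal-Wallis followed by
    Dunn's pairwise z-tests with multiplicity adjustment.
    """
    col = METRICS.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    sub = data if day is None else data[data["day"] == day]
    groups = {g: grp[col].to_numpy(dtype=float) for g, grp in sub.groupby("group", sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    if any(v.size == 0 for v in groups.values()):
        raise ValueError("empty group")
    ns = {g: int(v.size) for g, v in groups.items()}

    if len(groups) == 2:
        x, y = groups.values()
        out = _mannwhitney(x, y)
        out["n"] = ns
        return out

    kw_stat, kw_p = stats.kruskal(*groups.values())
    posthoc = dunn_posthoc(groups, adjust)
    return {"test": "kruskal", "statistic": float(kw_stat), "p": float(kw_p),
            "posthoc": posthoc, "n": ns}


def percent_positive(sample: FlowSample, control: FlowSample,
                     control_quantile: float = 0.99) -> float:
    """Fraction of sample events above a gate set on the negative control.

    The gate is the ``control_quantile`` (default 99th percentile) of the
    lipid-droplet-low control's tdTomato intensities; events strictly above
    the gate count as positive.
    """
    if sample.tdtomato.size == 0:
        raise ValueError("empty sample")
    if control.tdtomato.size == 0:
        raise ValueError("empty control")
    if not 0 <= control_quantile <= 1:
        raise ValueError("control_quantile must be in [0, 1]")
    gate = float(np.quantile(control.tdtomato, control_quantile))
    return float(np.mean(sample.tdtomato > gate))
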