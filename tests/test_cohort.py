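"""Adiposity statistics: BMI-like index, CIs, rank tests, flow gating."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipoquant import cohort, synth


def test_normalize_bmi_arithmetic_and_linearity():
    assert cohort.normalize_bmi(0.0, 5.0) == 0.0
    assert cohort.normalize_bmi(1000.0, 5.0) == pytest.approx(200.0)
    assert cohort.normalize_bmi(2000.0, 10.0) == pytest.approx(
        2 * cohort.normalize_bmi(1000.0, 10.0))
    with pytest.raises(ValueError):
        cohort.normalize_bmi(100.0, 0.0)


def _cohort_df(values_by_group, day=0):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append({"fish_id": f"{g}{i}", "group": g, "day": day,
                         "area_um2": v, "standard_length_mm": 1.0,
                         "area_per_sl_um2_per_mm": v})
    return pd.DataFrame(rows)


def test_identical_values_give_zero_width_ci():
    df = _cohort_df({"a": [5.0] * 6})
    s = cohort.summarize_longitudinal(df, "area")
    assert s.loc[0, "ci_low"] == s.loc[0, "ci_high"] == s.loc[0, "mean"] == 5.0


def test_singleton_group_ci_undefined():
    s = cohort.summarize_longitudinal(_cohort_df({"a": [5.0]}), "area")
    assert not s.loc[0, "ci_defined"]
    assert np.isnan(s.loc[0, "ci_low"])


def test_noiseless_cohort_means_equal_generator_curves():
    params = synth.CohortSimParams(between_fish_sd=0, within_fish_sd=0, seed=0)
    df = synth.generate_cohort(params)
    s = cohort.summarize_longitudinal(df, "area")
    fed = s[s.group == "fed"].sort_values("day")
    expected = synth.DEFAULT_GROUP_CURVES["fed"][1](np.asarray(params.days, dtype=float))
    assert np.allclose(fed["mean"].to_numpy(), expected)


def test_unknown_metric_rejected():
    with pytest.raises(ValueError, match="unknown metric"):
        cohort.summarize_longitudinal(_cohort_df({"a": [1.0, 2.0]}), "mass")


def test_t_ci_coverage_near_nominal():
    """~95% of t-based CIs cover the true mean over 1000 simulated groups."""
    rng = np.random.default_rng(2)
    covered = 0
    n_rep, n = 1000, 8
    for _ in range(n_rep):
        vals = rng.normal(100.0, 15.0, n)
        df = _cohort_df({"a": vals})
        s = cohort.summarize_longitudinal(df, "area")
        covered += s.loc[0, "ci_low"] <= 100.0 <= s.loc[0, "ci_high"]
    assert covered / n_rep == pytest.approx(0.95, abs=0.02)


# -- group comparisons -----------------------------------------------------


def _exact_mw_p(x, y):
    """Full-enumeration oracle for the two-sided Mann-Whitney p-value."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    n1n2 = n1 * len(y)
    d_obs = abs(u_obs - n1n2 / 2)
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(abs(u - n1n2 / 2) >= d_obs - 1e-12 for u in us)
    return extreme / len(us)


def test_identical_groups_symmetric_u_and_p_one():
    df = _cohort_df({"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 1.0, 3.0, 2.0]})
    rep = cohort.compare_groups(df, "area")
    assert rep["statistic"] == pytest.approx(8.0)  # n1*n2/2
    assert rep["p"] == pytest.approx(1.0)


def test_separated_triplets_exact_p():
    # {1,2,3} vs {4,5,6}: U = 0, 2 of 20 orderings as extreme -> p = 0.1
    df = _cohort_df({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    rep = cohort.compare_groups(df, "area")
    assert rep["mode"] == "exact"
    assert rep["p"] == pytest.approx(0.1)
    assert rep["p"] == pytest.approx(_exact_mw_p([1, 2, 3], [4, 5, 6]))


@pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4), (2, 6), (3, 5)])
def test_exact_p_matches_enumeration_all_small_sizes(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    x = rng.normal(0, 1, n1)
    y = rng.normal(0.5, 1, n2)
    df = _cohort_df({"a": x, "b": y})
    rep = cohort.compare_groups(df, "area")
    assert rep["mode"] == "exact"
    assert rep["p"] == pytest.approx(_exact_mw_p(x, y), abs=1e-12)


def test_empty_group_rejected():
    df = _cohort_df({"a": [1.0, 2.0]})
    with pytest.raises(ValueError, match=">= 2 groups"):
        cohort.compare_groups(df, "area")


def test_three_groups_run_kruskal_with_dunn():
    rng = np.random.default_rng(0)
    df = _cohort_df({"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12),
                     "c": rng.normal(2, 1, 12)})
    rep = cohort.compare_groups(df, "area")
    assert rep["test"] == "kruskal"
    ph = rep["posthoc"]
    assert len(ph) == 3
    # the shifted group separates from both others
    sig = ph[(ph.group_a == "c") | (ph.group_b == "c")]
    assert (sig["p_adjusted"] < 0.05).all()


def test_dunn_adjusted_never_below_raw_and_bounded():
    rng = np.random.default_rng(1)
    groups = {g: rng.normal(i * 0.3, 1, 10) for i, g in enumerate("abcd")}
    for adjust in ("holm", "bonferroni", "sidak"):
        ph = cohort.dunn_posthoc(groups, adjust)
        assert (ph["p_adjusted"] >= ph["p_raw"] - 1e-12).all()
        assert (ph["p_adjusted"] <= 1.0).all()


def test_dunn_holm_monotone_in_raw_p_order():
    rng = np.random.default_rng(5)
    groups = {g: rng.normal(i * 0.5, 1, 8) for i, g in enumerate("abc")}
    ph = cohort.dunn_posthoc(groups, "holm").sort_values("p_raw")
    assert (ph["p_adjusted"].diff().dropna() >= -1e-12).all()


def test_type_one_error_calibrated():
    """Null rejection rate at alpha = 0.05 stays near nominal (2000 reps)."""
    rng = np.random.default_rng(7)
    rej = 0
    n_rep = 2000
    for _ in range(n_rep):
        df = _cohort_df({"a": rng.standard_normal(10), "b": rng.standard_normal(10)})
        rej += cohort.compare_groups(df, "area")["p"] <= 0.05
    assert 0.04 <= rej / n_rep <= 0.06


# -- flow gating -----------------------------------------------------------


def test_self_gating_leaves_quantile_tail():
    s = synth.generate_flow_sample(50_000, 0.0, seed=0)
    c = synth.generate_flow_sample(50_000, 0.0, seed=1)
    frac = cohort.percent_positive(s, c, 0.99)
    assert frac == pytest.approx(0.01, abs=0.003)


def test_all_below_control_minimum_gives_zero():
    c = synth.FlowSample(np.array([10.0, 20.0, 30.0]), np.zeros(3))
    s = synth.FlowSample(np.array([1.0, 2.0]), np.zeros(2))
    assert cohort.percent_positive(s, c) == 0.0


def test_mixture_fraction_recovered():
    s = synth.generate_flow_sample(100_000, 0.3, seed=3)
    c = synth.generate_flow_sample(100_000, 0.0, seed=4)
    frac = cohort.percent_positive(s, c)
    assert frac == pytest.approx(0.30, abs=0.01)


def test_gate_invariant_under_monotone_transform():
    s = synth.generate_flow_sample(20_000, 0.3, seed=5)
    c = synth.generate_flow_sample(20_000, 0.0, seed=6)
    base = cohort.percent_positive(s, c)
    for f in (np.sqrt, np.log1p, lambda v: v ** 1.7):
        ts = synth.FlowSample(f(s.tdtomato), s.gfp)
        tc = synth.FlowSample(f(c.tdtomato), c.gfp)
        assert cohort.percent_positive(ts, tc) == pytest.approx(base, abs=2e-4)


def test_validate_cohort_catches_duplicates():
    df = _cohort_df({"a": [1.0, 2.0]})
    dup = pd.concat([df, df.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        cohort.validate_cohort(dup)
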