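"""Plate-screen analysis: curve fitting, normalization algebra, hit calling."""

import numpy as np
import pandas as pd
import pytest

from adipoquant import screen, synth


def test_exact_line_fit():
    c = screen.fit_standard_curve([(0, 0), (1, 0.5), (2, 1.0)])
    assert (c.slope, c.intercept) == pytest.approx((0.5, 0.0), abs=1e-12)
    assert c.r_squared == pytest.approx(1.0, abs=1e-12)


def test_two_point_line():
    c = screen.fit_standard_curve([(0, 0.1), (1, 0.6)])
    assert (c.slope, c.intercept) == pytest.approx((0.5, 0.1), abs=1e-12)


def test_noisy_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    conc = np.linspace(0, 1, 20)
    absb = 0.8 * conc + 0.05 + rng.normal(0, 0.01, 20)
    c = screen.fit_standard_curve(list(zip(conc, absb)))
    # closed-form least squares oracle
    X = np.c_[conc, np.ones_like(conc)]
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ absb)
    assert c.slope == pytest.approx(slope, rel=1e-12)
    assert c.intercept == pytest.approx(intercept, rel=1e-12)


def test_degenerate_standards_rejected():
    with pytest.raises(screen.DegenerateCurveError):
        screen.fit_standard_curve([(1.0, 0.5), (1.0, 0.6)])


def test_absorbance_inversion_and_clamping():
    c = screen.StandardCurve(0.5, 0.0, 1.0)
    assert screen.absorbance_to_glycerol(0.25, c) == pytest.approx(0.5)
    assert screen.absorbance_to_glycerol(0.0, screen.StandardCurve(0.5, 0.1, 1.0)) == 0.0
    with pytest.raises(screen.DegenerateCurveError):
        screen.absorbance_to_glycerol(1.0, screen.StandardCurve(0.0, 0.0, 1.0))


def test_noiseless_round_trip_is_exact(sixteen_plate_screen):
    """conc -> absorbance -> conc inverts to planted glycerol at 1e-9
    relative for every well of a noiseless simulated screen."""
    plates, _, params = sixteen_plate_screen
    curve = screen.fit_curve_from_plates(plates)
    bias = params.position_bias
    for p in plates[:4]:
        g = screen.absorbance_to_glycerol(p.absorbance, curve)
        for r, c in p.layout.wells("dmso"):
            expected = params.baseline_glycerol * bias[r, c]
            assert abs(g[r, c] - expected) <= 1e-9 * expected
        for r, c in p.layout.wells("standard"):
            expected = p.layout.standard_concs[r, c]
            assert abs(g[r, c] - expected) <= 1e-9 * max(expected, 1.0)


# -- position normalization ------------------------------------------------


def test_constant_plates_normalize_to_one():
    lay = synth.default_layout(0)
    curve = screen.StandardCurve(1.0, 0.0, 1.0)
    plates = [synth.ScreenPlate(f"P{i}", np.full((8, 12), 3.0), lay) for i in range(3)]
    _, table = screen.position_normalize(plates, curve)
    assert np.allclose(table["position_normalized"], 1.0)


def test_two_plate_factor_arithmetic():
    lay = synth.default_layout(0)
    curve = screen.StandardCurve(1.0, 0.0, 1.0)
    a1 = np.full((8, 12), 3.0)
    a2 = np.full((8, 12), 3.0)
    a1[0, 1], a2[0, 1] = 2.0, 4.0   # compound position
    plates = [synth.ScreenPlate("A", a1, lay), synth.ScreenPlate("B", a2, lay)]
    nm, table = screen.position_normalize(plates, curve)
    assert nm.factors[0, 1] == pytest.approx(3.0)
    got = table[(table.row == 0) & (table.col == 1)].sort_values("plate_id")["position_normalized"]
    assert list(got) == pytest.approx([2 / 3, 4 / 3])


def test_multiplicative_bias_fully_removed(sixteen_plate_screen):
    plates, _, _ = sixteen_plate_screen
    curve = screen.fit_curve_from_plates(plates)
    _, table = screen.position_normalize(plates, curve)
    compounds = table[table.role == "compound"]
    assert np.max(np.abs(compounds["position_normalized"] - 1.0)) < 1e-9


def test_standards_and_empties_excluded_from_normalized_table(sixteen_plate_screen):
    plates, _, _ = sixteen_plate_screen
    curve = screen.fit_curve_from_plates(plates)
    _, table = screen.position_normalize(plates, curve)
    assert set(table["role"]) <= {"compound", "dmso"}


# -- hit calling -----------------------------------------------------------


def _table_with_folds(folds):
    rows = [{"plate_id": "P0", "row": 0, "col": 0, "role": "dmso",
             "compound_id": None, "raw_glycerol_mg_ml": 1.0, "position_normalized": 1.0}]
    for i, f in enumerate(folds):
        rows.append({"plate_id": "P0", "row": 0, "col": i + 1, "role": "compound",
                     "compound_id": f"C{i}", "raw_glycerol_mg_ml": f, "position_normalized": f})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("fold,expected_hit", [(0.59, True), (0.60, True), (0.61, False)])
def test_hit_boundary_inclusive_at_40_percent(fold, expected_hit):
    """'At least a 40% reduction' reads inclusively: fold 0.60 is a hit."""
    res = screen.call_hits(_table_with_folds([fold]))
    assert bool(res.loc[0, "is_hit"]) is expected_hit


def test_compound_result_internal_identities():
    res = screen.call_hits(_table_with_folds([0.25, 0.5, 1.0, 1.5]))
    assert np.allclose(res["reduction"], 1 - res["fold_vs_dmso"])
    assert np.allclose(res["log2_fold"], np.log2(res["fold_vs_dmso"]))


def test_hits_invariant_to_global_rescale(sixteen_plate_screen):
    plates, _, _ = sixteen_plate_screen
    lay = [synth.default_layout(i) for i in range(16)]
    inhib = synth.plant_inhibitors(lay, 10, 0.5, seed=0)
    params = synth.ScreenSimParams(position_bias=synth.edge_bias_grid(),
                                   inhibitor_effects=inhib, cv=0.02, seed=4)
    plates, _ = synth.generate_screen(params)
    curve = screen.fit_curve_from_plates(plates)

    def hits_of(plts):
        _, table = screen.position_normalize(plts, curve)
        return set(screen.call_hits(table).query("is_hit")["compound_id"])

    # rescale all glycerol by one constant (scale absorbances about the intercept)
    scaled = [synth.ScreenPlate(p.plate_id,
                                curve.intercept + 2.0 * (p.absorbance - curve.intercept),
                                p.layout) for p in plates]
    assert hits_of(plates) == hits_of(scaled)


def test_missing_dmso_is_control_error():
    df = _table_with_folds([0.5])
    df = df[df.role != "dmso"]
    with pytest.raises(screen.ControlMissingError):
        screen.call_hits(df)


def test_planted_hits_recovered_at_low_noise():
    """29 planted inhibitors at 50% reduction among 1280 compounds are all
    called with no false positives at cv = 0.05."""
    lay = [synth.default_layout(i) for i in range(16)]
    inhib = synth.plant_inhibitors(lay, 29, 0.5, seed=1)
    plates, _ = synth.generate_screen(synth.ScreenSimParams(
        position_bias=synth.edge_bias_grid(), inhibitor_effects=inhib, cv=0.05, seed=1))
    out = screen.run_screen_pipeline(plates)
    called = set(out["hits"]["compound_id"])
    assert called == set(inhib)


def test_top_hits_ranked_by_log2_fold_with_id_tiebreak():
    res = screen.call_hits(_table_with_folds([0.5, 0.25, 0.25, 1.0]))
    top = screen.top_hits(res, n=3)
    assert list(top["compound_id"]) == ["C1", "C2", "C0"]


# -- QC --------------------------------------------------------------------


def test_qc_reports_stimulated_fold_exactly_at_cv0():
    plates, _ = synth.generate_screen(synth.ScreenSimParams(n_plates=4, cv=0.0,
                                                            stimulated_fold=3.0, seed=0))
    curve = screen.fit_curve_from_plates(plates)
    qc = screen.control_qc(plates, curve)
    assert np.allclose(qc["positive_control_fold"], 3.0)
    assert not qc["flag_no_stimulation"].any()


def test_qc_flags_unstimulated_plates():
    plates, _ = synth.generate_screen(synth.ScreenSimParams(n_plates=4, cv=0.0,
                                                            stimulated_fold=1.0, seed=0))
    curve = screen.fit_curve_from_plates(plates)
    qc = screen.control_qc(plates, curve)
    assert qc["flag_no_stimulation"].all()


def test_qc_dmso_cv_near_simulated_cv():
    plates, _ = synth.generate_screen(synth.ScreenSimParams(n_plates=16, cv=0.1, seed=6))
    curve = screen.fit_curve_from_plates(plates)
    qc = screen.control_qc(plates, curve)
    # 16 plates x 4 dmso wells: mean sample CV should sit near 0.1
    assert qc["dmso_cv"].mean() == pytest.approx(0.1, abs=0.03)


# -- long-CSV round trip ---------------------------------------------------


def test_long_csv_round_trip(tmp_path, sixteen_plate_screen):
    plates, _, _ = sixteen_plate_screen
    df = screen.plates_to_long(plates[:3])
    df.to_csv(tmp_path / "wells.csv", index=False)
    back = screen.load_screen_long_csv(tmp_path / "wells.csv")
    assert len(back) == 3
    for a, b in zip(plates[:3], back):
        assert np.allclose(a.absorbance, b.absorbance)
        assert np.array_equal(a.layout.roles, b.layout.roles)
        assert np.array_equal(a.layout.compound_ids == None, b.layout.compound_ids == None)  # noqa: E712
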