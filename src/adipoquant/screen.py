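"""Lipolysis plate-screen analysis.

Glycerol released into the medium is the readout of adipocyte lipolysis:
absorbance at 540 nm is converted to glycerol (mg/ml) through a linear
standard curve, per-well-position normalization factors (the mean glycerol
at each of the 96 positions across all plates) remove edge effects, and
compounds are scored as fold change versus the DMSO vehicle wells of their
plate.  A compound is a hit when it reduces lipolysis by at least the hit
threshold (default 40%, boundary inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import PLATE_SHAPE, PlateLayout, ScreenPlate

__all__ = [
    "StandardCurve",
    "NormalizationMap",
    "DegenerateCurveError",
    "ControlMissingError",
    "fit_standard_curve",
    "absorbance_to_glycerol",
    "plates_to_glycerol",
    "position_normalize",
    "call_hits",
    "top_hits",
    "control_qc",
    "plates_to_long",
    "load_screen_long_csv",
    "run_screen_pipeline",
]

log = logging.getLogger(__name__)


class DegenerateCurveError(ValueError):
    """Standard curve cannot be fitted or inverted."""


class ControlMissingError(ValueError):
    """A plate lacks the control wells an operation requires."""


@dataclass
class StandardCurve:
    """Linear glycerol standard curve: absorbance = slope*conc + intercept."""

    slope: float        # AU per mg/ml
    intercept: float    # AU
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared must be in [0,1], got {self.r_squared}")


@dataclass
class NormalizationMap:
    """Per-position factors: mean glycerol at each well position across plates."""

    factors: np.ndarray   # 8x12; NaN where the position holds no compound/dmso well

    def __post_init__(self) -> None:
        if self.factors.shape != PLATE_SHAPE:
            raise ValueError(f"factors must be {PLATE_SHAPE}")


def fit_standard_curve(standards: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (concentration, absorbance) pairs."""
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateCurveError("standard curve needs >= 2 distinct concentrations")
    res = stats.linregress(conc, absb)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    return StandardCurve(float(res.slope), float(res.intercept), min(r2, 1.0))


def absorbance_to_glycerol(a: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve; negative concentrations clamp to 0 with a warning."""
    if curve.slope == 0:
        raise DegenerateCurveError("standard curve slope is 0; cannot invert")
    g = (np.asarray(a, dtype=float) - curve.intercept) / curve.slope
    if np.any(g < 0):
        log.warning("clamping %d negative glycerol value(s) to 0", int(np.sum(g < 0)))
        g = np.clip(g, 0, None)
    return float(g) if np.isscalar(a) else g


def plates_to_glycerol(plates: list[ScreenPlate], curve: StandardCurve) -> list[np.ndarray]:
    return [absorbance_to_glycerol(p.absorbance, curve) for p in plates]


def plates_to_long(plates: list[ScreenPlate]) -> pd.DataFrame:
    """Flatten plates to a tidy frame: one row per well."""
    rows = []
    for p in plates:
        lay = p.layout
        for r in range(PLATE_SHAPE[0]):
            for c in range(PLATE_SHAPE[1]):
                rows.append({
                    "plate_id": p.plate_id, "row": r, "col": c,
                    "role": lay.roles[r, c],
                    "compound_id": lay.compound_ids[r, c],
                    "standard_conc_mg_ml": lay.standard_concs[r, c],
                    "absorbance_au": p.absorbance[r, c],
                })
    return pd.DataFrame(rows)


def load_screen_long_csv(path) -> list[ScreenPlate]:
    """Read a whole screen from one long CSV (plate_id,row,col,role,
    compound_id,standard_conc_mg_ml,absorbance_au) back into plates."""
    df = pd.read_csv(path)
    plates = []
    for pid, grp in df.groupby("plate_id", sort=True):
        roles = np.full(PLATE_SHAPE, "empty", dtype=object)
        ids = np.full(PLATE_SHAPE, None, dtype=object)
        concs = np.full(PLATE_SHAPE, np.nan)
        absb = np.zeros(PLATE_SHAPE)
        for _, w in grp.iterrows():
            r, c = int(w["row"]), int(w["col"])
            roles[r, c] = w["role"]
            cid = w.get("compound_id")
            ids[r, c] = None if pd.isna(cid) else str(cid)
            concs[r, c] = w.get("standard_conc_mg_ml", np.nan)
            absb[r, c] = w["absorbance_au"]
        plates.append(ScreenPlate(str(pid), absb, PlateLayout(roles, ids, concs)))
    return plates


def position_normalize(plates: list[ScreenPlate],
                       curve: StandardCurve) -> tuple[NormalizationMap, pd.DataFrame]:
    """Remove well-position (edge) bias.

    The factor for position (r, c) is the arithmetic mean, across plates,
    of the glycerol measured there — computed over compound and DMSO wells
    only (standards and empties carry no biology).  Each such well's
    normalized value is its glycerol divided by its position's factor.
    """
    if not plates:
        raise ValueError("need >= 1 plate")
    geom = plates[0].layout.roles
    for p in plates[1:]:
        if not np.array_equal(p.layout.roles, geom):
            raise ValueError("all plates must share layout geometry")

    glycerol = plates_to_glycerol(plates, curve)
    biological = np.isin(geom, ["compound", "dmso"])

    stack = np.stack(glycerol)                      # plates x 8 x 12
    factors = np.full(PLATE_SHAPE, np.nan)
    factors[biological] = stack[:, biological].mean(axis=0)
    bad = biological & ~(factors > 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"normalization factor <= 0 at position (row={r}, col={c})")

    rows = []
    for p, g in zip(plates, glycerol):
        lay = p.layout
        for r, c in np.argwhere(biological):
            clamped = g[r, c] == 0
            if clamped:
                log.warning("plate %s well (%d,%d): clamped-negative glycerol enters factors as 0",
                            p.plate_id, r, c)
            rows.append({
                "plate_id": p.plate_id, "row": int(r), "col": int(c),
                "role": lay.roles[r, c], "compound_id": lay.compound_ids[r, c],
                "raw_glycerol_mg_ml": g[r, c],
                "position_normalized": g[r, c] / factors[r, c],
                "clamped": bool(clamped),
            })
    return NormalizationMap(factors), pd.DataFrame(rows)


def call_hits(table: pd.DataFrame, hit_threshold: float = 0.40) -> pd.DataFrame:
    """Score compounds against their plate's DMSO wells and call hits.

    fold_vs_dmso = position-normalized compound value / mean position-
    normalized DMSO value on the same plate; reduction = 1 - fold; a
    compound is a hit when reduction >= hit_threshold ("at least" a 40%
    reduction by default, so the boundary is inclusive).
    """
    results = []
    for pid, grp in table.groupby("plate_id", sort=True):
        dmso = grp.loc[grp["role"] == "dmso", "position_normalized"]
        if dmso.empty:
            raise ControlMissingError(f"plate {pid} has no dmso wells; cannot call hits")
        dmso_mean = dmso.mean()
        for _, w in grp[grp["role"] == "compound"].iterrows():
            fold = w["position_normalized"] / dmso_mean
            results.append({
                "compound_id": w["compound_id"], "plate_id": pid,
                "row": w["row"], "col": w["col"],
                "raw_glycerol_mg_ml": w["raw_glycerol_mg_ml"],
                "position_normalized": w["position_normalized"],
                "fold_vs_dmso": fold,
                "log2_fold": np.log2(fold) if fold > 0 else -np.inf,
                "reduction": 1 - fold,
                "is_hit": bool(1 - fold >= hit_threshold),
            })
    return pd.DataFrame(results)


def top_hits(results: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Strongest lipolysis inhibitors: ascending log2 fold change, ties
    broken by compound id for determinism."""
    return results.sort_values(["log2_fold", "compound_id"]).head(n).reset_index(drop=True)


def count_hits_from_log2(log2_values: np.ndarray | pd.Series,
                         hit_threshold: float = 0.40) -> int:
    """Hit count from already-normalized log2 fold changes.

    Published screen tables often report the normalized log2 fold change
    per compound rather than raw absorbances; a reduction of at least
    ``hit_threshold`` corresponds to log2(fold) <= log2(1 - hit_threshold)
    (boundary inclusive).
    """
    v = np.asarray(log2_values, dtype=float)
    v = v[np.isfinite(v)]
    return int(np.sum(v <= np.log2(1 - hit_threshold) + 1e-12))


def control_qc(plates: list[ScreenPlate], curve: StandardCurve,
               dmso_cv_limit: float = 0.2) -> pd.DataFrame:
    """Per-plate control quality report.

    DMSO mean and CV, positive-control (isoproterenol) fold over DMSO on
    raw glycerol, and flags: ``flag_no_stimulation`` when the positive-
    control fold <= 1, ``flag_dmso_cv`` when the DMSO CV exceeds the limit.
    """
    rows = []
    for p in plates:
        g = absorbance_to_glycerol(p.absorbance, curve)
        dmso = [g[r, c] for r, c in p.layout.wells("dmso")]
        pos = [g[r, c] for r, c in p.layout.wells("positive_control")]
        if not dmso or not pos:
            raise ControlMissingError(f"plate {p.plate_id} lacks dmso or positive-control wells")
        dmso_mean = float(np.mean(dmso))
        dmso_cv = float(np.std(dmso, ddof=1) / dmso_mean) if len(dmso) > 1 and dmso_mean > 0 else 0.0
        pos_fold = float(np.mean(pos) / dmso_mean) if dmso_mean > 0 else np.inf
        rows.append({
            "plate_id": p.plate_id, "dmso_mean_mg_ml": dmso_mean, "dmso_cv": dmso_cv,
            "positive_control_fold": pos_fold,
            "flag_no_stimulation": pos_fold <= 1,
            "flag_dmso_cv": dmso_cv > dmso_cv_limit,
        })
    return pd.DataFrame(rows)


def fit_curve_from_plates(plates: list[ScreenPlate]) -> StandardCurve:
    """Pool every standard well across plates into one curve fit."""
    pairs = []
    for p in plates:
        for r, c in p.layout.wells("standard"):
            pairs.append((p.layout.standard_concs[r, c], p.absorbance[r, c]))
    if len(pairs) < 2:
        raise DegenerateCurveError("screen contains < 2 standard wells")
    return fit_standard_curve(pairs)


def run_screen_pipeline(plates: list[ScreenPlate], curve: StandardCurve | None = None,
                        hit_threshold: float = 0.40) -> dict:
    """Standard curve -> glycerol -> position normalization -> hit calls -> QC."""
    curve = curve or fit_curve_from_plates(plates)
    norm_map, table = position_normalize(plates, curve)
    results = call_hits(table, hit_threshold)
    qc = control_qc(plates, curve)
    return {"curve": curve, "normalization": norm_map, "table": table,
            "results": results, "hits": results[results["is_hit"]],
            "top10": top_hits(results), "qc": qc}
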