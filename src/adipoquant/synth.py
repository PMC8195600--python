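"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: transparent-fish
fluorescence images (lipid-droplet reporter in tdTomato, gut/gallbladder
autofluorescence bleeding into GFP/tdTomato/Cy5), BODIPY-stained variants,
96-well lipolysis screens with planted well-position bias and planted
inhibitors, fed/fasted/high-fat-diet growth cohorts, and two-population
cell-fluorescence samples.  Each generator takes one explicit integer seed
and is bit-for-bit reproducible; no global RNG state is touched.

The planted masks and effect sizes are returned alongside the data so that
every downstream operation can be tested as a parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imgio import ChannelImage, FishImage

__all__ = [
    "GroundTruth",
    "ImageSimParams",
    "ScreenSimParams",
    "CohortSimParams",
    "FlowSample",
    "PlacementError",
    "generate_fish_image",
    "generate_bodipy_image",
    "default_layout",
    "edge_bias_grid",
    "generate_screen",
    "generate_cohort",
    "generate_flow_sample",
]

PLATE_SHAPE = (8, 12)


class PlacementError(RuntimeError):
    """Rejection sampling failed to place all adipose blobs."""


@dataclass
class GroundTruth:
    """Planted truth emitted next to each synthetic image.

    ``adipose_area_px`` is the lattice-point count of the ideal rasterized
    ellipses *before* edge blur; recovery tolerances must absorb the blur.
    """

    adipose_mask: np.ndarray
    gut_mask: np.ndarray
    adipose_area_px: int
    per_blob_params: list[tuple[float, float, float, float, float, float]]

    def __post_init__(self) -> None:
        assert self.adipose_mask.shape == self.gut_mask.shape
        assert int(self.adipose_mask.sum()) == self.adipose_area_px


@dataclass
class ImageSimParams:
    """Knobs of the fish-image simulator.

    Intensities are arbitrary units (AU) on a linear camera scale; the
    defaults are placeholders chosen to resemble a clean stereo-zoom
    acquisition (bright reporter over a dim, noisy background) — the true
    distributions of adipocyte sizes and gut autofluorescence are not
    published, so none of these defaults is a measured value.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0              # µm per pixel
    n_adipose_blobs: int = 5
    blob_axes_range: tuple[float, float] = (6.0, 16.0)   # semi-axes, px
    adipose_peak: float = 180.0
    gut_peak_gfp: float = 150.0
    gut_peak_tdt: float = 120.0
    gut_peak_cy5: float = 140.0
    adipose_gfp_leak: float = 5.0        # reporter bleed into GFP; << any background threshold
    noise_sd: float = 8.0                # additive Gaussian, AU
    background_level: float = 20.0
    blur_sigma: float = 1.0              # Gaussian edge blur, px; 0 disables
    noise_model: str = "gaussian"        # or "poisson"
    gut_overlap_fraction: float = 0.0    # allowed adipose/gut overlap
    placement_frac: tuple[float, float] = (0.3, 0.7)  # fractional box for blob centers
    blob_centers: Sequence[tuple[float, float]] | None = None  # fixed placements, optional
    blob_axes: Sequence[tuple[float, float]] | None = None
    blob_orientations: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("adipose_peak", "gut_peak_gfp", "gut_peak_tdt", "gut_peak_cy5",
                     "adipose_gfp_leak", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], theta: float) -> np.ndarray:
    """Lattice rasterization: pixel centers with normalized radius <= 1."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _gut_mask(shape: tuple[int, int]) -> np.ndarray:
    """One elongated autofluorescent region along the bottom image edge,
    mimicking the position of the intestinal loops."""
    rows, cols = shape
    center = (rows - rows / 7.0, cols / 2.0)
    axes = (0.35 * cols, 0.09 * rows)  # (semi-axis along cols, along rows)
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((cc - center[1]) / axes[0]) ** 2 + ((rr - center[0]) / axes[1]) ** 2 <= 1.0


_MAX_PLACEMENT_ATTEMPTS = 200


def _place_blobs(params: ImageSimParams, gut: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, list]:
    """Rejection-sample disjoint elliptical blobs avoiding the gut region
    (unless overlap is allowed).  Raises PlacementError after the attempt
    budget is exhausted for any blob."""
    shape = params.shape
    adipose = np.zeros(shape, dtype=bool)
    blob_params = []
    lo, hi = params.blob_axes_range
    fixed = params.blob_centers is not None
    for i in range(params.n_adipose_blobs):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            if fixed:
                center = params.blob_centers[i]
                axes = params.blob_axes[i] if params.blob_axes else ((lo + hi) / 2,) * 2
                theta = params.blob_orientations[i] if params.blob_orientations else 0.0
            else:
                axes = tuple(rng.uniform(lo, hi, size=2))
                margin = max(axes) + 2
                f0, f1 = params.placement_frac
                # visceral depot is compact: centers confined to a central box
                r_lo = max(f0 * shape[0], margin)
                r_hi = min(f1 * shape[0], shape[0] - margin)
                c_lo = max(f0 * shape[1], margin)
                c_hi = min(f1 * shape[1], shape[1] - margin)
                center = (rng.uniform(r_lo, r_hi), rng.uniform(c_lo, c_hi))
                theta = rng.uniform(0, np.pi)
            blob = _ellipse_mask(shape, center, axes, theta)
            area = blob.sum()
            if area == 0:
                continue
            gut_overlap = (blob & gut).sum() / area
            if (blob & adipose).any() or gut_overlap > params.gut_overlap_fraction:
                if fixed:
                    raise PlacementError(
                        f"fixed blob {i} at {center} overlaps gut/another blob")
                continue
            adipose |= blob
            blob_params.append((center[0], center[1], axes[0], axes[1], theta,
                                params.adipose_peak))
            break
        else:
            raise PlacementError(
                f"could not place blob {i + 1}/{params.n_adipose_blobs} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} rejection-sampling attempts")
    return adipose, blob_params


def _finish_channels(raw: dict[str, np.ndarray], params: ImageSimParams,
                     rng: np.random.Generator) -> dict[str, ChannelImage]:
    out = {}
    for name, img in raw.items():
        if params.blur_sigma > 0:
            img = gaussian_filter(img, params.blur_sigma)
        if params.noise_model == "poisson":
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if params.noise_sd > 0:
                img = img + rng.normal(0, params.noise_sd, img.shape)
        elif params.noise_sd > 0:
            img = img + rng.normal(0, params.noise_sd, img.shape)
        out[name] = ChannelImage(np.clip(img, 0, None), name, params.pixel_size)
    return out


def generate_fish_image(params: ImageSimParams) -> tuple[FishImage, GroundTruth]:
    """Simulate a lipid-droplet-reporter fish image.

    Adipose blobs carry ``adipose_peak`` in tdTomato (and a small
    ``adipose_gfp_leak`` in GFP); the gut region autofluoresces in GFP,
    tdTomato and Cy5 at its per-channel peaks; a constant background plus
    noise covers everything.  Returns the image and the planted truth.
    """
    rng = np.random.default_rng(params.seed)
    gut = _gut_mask(params.shape)
    adipose, blob_params = _place_blobs(params, gut, rng)

    bg = params.background_level
    raw = {
        "GFP": bg + adipose * params.adipose_gfp_leak + gut * params.gut_peak_gfp,
        "tdTomato": bg + adipose * params.adipose_peak + gut * params.gut_peak_tdt,
        "Cy5": bg + gut * params.gut_peak_cy5,
    }
    channels = _finish_channels(raw, params, rng)
    truth = GroundTruth(adipose, gut, int(adipose.sum()), blob_params)
    return FishImage(channels), truth


def generate_bodipy_image(params: ImageSimParams) -> tuple[FishImage, GroundTruth]:
    """Simulate a BODIPY-stained fish: the dye reads out in GFP, gut
    autofluorescence appears in GFP and Cy5, tdTomato stays at background."""
    rng = np.random.default_rng(params.seed)
    gut = _gut_mask(params.shape)
    adipose, blob_params = _place_blobs(params, gut, rng)

    bg = params.background_level
    raw = {
        "GFP": bg + adipose * params.adipose_peak + gut * params.gut_peak_gfp,
        "tdTomato": np.full(params.shape, float(bg)),
        "Cy5": bg + gut * params.gut_peak_cy5,
    }
    channels = _finish_channels(raw, params, rng)
    truth = GroundTruth(adipose, gut, int(adipose.sum()), blob_params)
    return FishImage(channels), truth


# --------------------------------------------------------------------------
# Plate screens


@dataclass
class PlateLayout:
    """Role of every well on an 8x12 plate.

    ``roles`` holds one of {compound, dmso, positive_control, standard,
    empty} per well; ``compound_ids`` names compound wells (None elsewhere);
    ``standard_concs`` holds mg/ml for standard wells (NaN elsewhere).
    """

    roles: np.ndarray
    compound_ids: np.ndarray
    standard_concs: np.ndarray

    VALID_ROLES = ("compound", "dmso", "positive_control", "standard", "empty")

    def __post_init__(self) -> None:
        if self.roles.shape != PLATE_SHAPE:
            raise ValueError(f"layout must be {PLATE_SHAPE}, got {self.roles.shape}")
        bad = set(self.roles.ravel()) - set(self.VALID_ROLES)
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")
        std = self.roles == "standard"
        if np.any(std & ~np.isfinite(self.standard_concs)):
            raise ValueError("standard wells must carry concentrations")

    def wells(self, role: str) -> list[tuple[int, int]]:
        rr, cc = np.nonzero(self.roles == role)
        return list(zip(rr.tolist(), cc.tolist()))


def default_layout(plate_index: int = 0,
                   standard_concs: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                   ) -> PlateLayout:
    """The default screen plate: 80 compound wells in columns 1-10,
    column 0 split between DMSO (rows 0-3) and isoproterenol positive
    controls (rows 4-7), column 11 carrying a glycerol standard ladder
    (rows 0-5) and two empty wells.  Compound ids are C<plate><well#>."""
    roles = np.full(PLATE_SHAPE, "empty", dtype=object)
    ids = np.full(PLATE_SHAPE, None, dtype=object)
    concs = np.full(PLATE_SHAPE, np.nan)
    roles[0:4, 0] = "dmso"
    roles[4:8, 0] = "positive_control"
    k = 0
    for c in range(1, 11):
        for r in range(8):
            roles[r, c] = "compound"
            ids[r, c] = f"C{plate_index:02d}{k:02d}"
            k += 1
    for i, conc in enumerate(standard_concs):
        roles[i, 11] = "standard"
        concs[i, 11] = conc
    return PlateLayout(roles, ids, concs)


def edge_bias_grid(edge_factor: float = 0.85, ring2_factor: float = 0.95) -> np.ndarray:
    """Multiplicative well-position bias: outermost ring depressed (partial
    evaporation at the plate edge), second ring mildly depressed, interior
    unbiased."""
    bias = np.ones(PLATE_SHAPE)
    bias[[0, -1], :] = edge_factor
    bias[:, [0, -1]] = edge_factor
    bias[1, 1:-1] = ring2_factor
    bias[-2, 1:-1] = ring2_factor
    bias[1:-1, 1] = ring2_factor
    bias[1:-1, -2] = ring2_factor
    return bias


@dataclass
class ScreenPlate:
    """Absorbance grid (AU at 540 nm) plus well annotations for one plate."""

    plate_id: str
    absorbance: np.ndarray
    layout: PlateLayout

    def __post_init__(self) -> None:
        if self.absorbance.shape != PLATE_SHAPE:
            raise ValueError(f"absorbance grid must be {PLATE_SHAPE}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class ScreenSimParams:
    """Knobs of the lipolysis-screen simulator.

    Per-well glycerol (mg/ml) is baseline x (1 - planted reduction) x
    position bias x lognormal noise with coefficient of variation ``cv``;
    positive-control wells are stimulated by ``stimulated_fold``.
    Absorbance follows the linear standard curve.
    """

    n_plates: int = 16
    layouts: list[PlateLayout] | None = None  # default: default_layout per plate
    position_bias: np.ndarray | None = None   # default: flat (no bias)
    baseline_glycerol: float = 0.4             # mg/ml released by vehicle wells
    inhibitor_effects: dict[str, float] = field(default_factory=dict)
    stimulated_fold: float = 3.0
    cv: float = 0.0
    absorbance_sd: float = 0.0
    curve_slope: float = 0.8                   # AU per mg/ml
    curve_intercept: float = 0.05              # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.absorbance_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.position_bias is not None:
            self.position_bias = np.asarray(self.position_bias, dtype=float)
            if self.position_bias.shape != PLATE_SHAPE:
                raise ValueError(f"position_bias must be {PLATE_SHAPE}")
            if np.any(self.position_bias <= 0):
                raise ValueError("position_bias must be strictly positive")
        for cid, red in self.inhibitor_effects.items():
            if not 0 <= red <= 1:
                raise ValueError(f"fractional reduction for {cid} must be in [0,1], got {red}")


def plant_inhibitors(layouts: list[PlateLayout], n: int, reduction: float,
                     seed: int = 0) -> dict[str, float]:
    """Choose ``n`` compounds to plant as inhibitors, one per distinct well
    position.

    Position-normalization factors are estimated from one well per plate at
    each position, so stacking several planted effects on one position
    would bias that position's factor (the normalization assumes most
    compounds at a position are inactive).  Planting at distinct positions
    keeps the planted truth orthogonal to the positional bias under study.
    """
    rng = np.random.default_rng(seed)
    by_pos: dict[tuple[int, int], list[str]] = {}
    for lay in layouts:
        for (r, c) in lay.wells("compound"):
            by_pos.setdefault((r, c), []).append(lay.compound_ids[r, c])
    positions = sorted(by_pos)
    if n > len(positions):
        raise ValueError(f"cannot plant {n} inhibitors at distinct positions; only {len(positions)} compound positions")
    chosen = rng.choice(len(positions), size=n, replace=False)
    return {by_pos[positions[i]][rng.integers(len(by_pos[positions[i]]))]: reduction
            for i in chosen}


def generate_screen(params: ScreenSimParams) -> tuple[list[ScreenPlate], pd.DataFrame]:
    """Simulate a multi-plate glycerol-release screen.

    Returns the plates and a truth table (one row per compound) recording
    each compound's planted fractional reduction in lipolysis.
    """
    rng = np.random.default_rng(params.seed)
    layouts = params.layouts or [default_layout(i) for i in range(params.n_plates)]
    if len(layouts) != params.n_plates:
        raise ValueError("need one layout per plate")
    bias = params.position_bias if params.position_bias is not None else np.ones(PLATE_SHAPE)

    all_ids = {cid for lay in layouts for cid in lay.compound_ids.ravel() if cid}
    missing = set(params.inhibitor_effects) - all_ids
    if missing:
        raise ValueError(f"inhibitor_effects reference compounds absent from layout: {sorted(missing)}")

    # lognormal with unit mean and fractional sd ~ cv
    sigma = np.sqrt(np.log1p(params.cv ** 2))

    plates, truth_rows = [], []
    for p, lay in enumerate(layouts):
        glycerol = np.zeros(PLATE_SHAPE)
        for r in range(8):
            for c in range(12):
                role = lay.roles[r, c]
                if role == "compound":
                    cid = lay.compound_ids[r, c]
                    red = params.inhibitor_effects.get(cid, 0.0)
                    g = params.baseline_glycerol * (1 - red) * bias[r, c]
                    truth_rows.append({"compound_id": cid, "plate_id": f"P{p:02d}",
                                       "row": r, "col": c, "true_reduction": red})
                elif role == "dmso":
                    g = params.baseline_glycerol * bias[r, c]
                elif role == "positive_control":
                    g = params.baseline_glycerol * params.stimulated_fold * bias[r, c]
                elif role == "standard":
                    g = lay.standard_concs[r, c]
                else:
                    g = 0.0
                if params.cv > 0 and role in ("compound", "dmso", "positive_control"):
                    g *= rng.lognormal(-sigma ** 2 / 2, sigma)
                glycerol[r, c] = g
        absorbance = params.curve_slope * glycerol + params.curve_intercept
        if params.absorbance_sd > 0:
            absorbance = absorbance + rng.normal(0, params.absorbance_sd, PLATE_SHAPE)
        plates.append(ScreenPlate(f"P{p:02d}", absorbance, lay))

    return plates, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# Growth cohorts


def _fed_sl(day: np.ndarray) -> np.ndarray:
    return 6.0 + 0.20 * day            # mm, steady juvenile growth


def _fasted_sl(day: np.ndarray) -> np.ndarray:
    return np.full_like(day, 6.0, dtype=float)   # growth stalls under fasting


def _fed_area(day: np.ndarray) -> np.ndarray:
    return 30_000.0 + 6_000.0 * day    # µm², strictly increasing


def _fasted_area(day: np.ndarray) -> np.ndarray:
    """Adiposity holds (within 3%) through day 2 of fasting, then declines:
    lipolysis of the visceral depot lags the onset of nutrient deprivation."""
    day = np.asarray(day, dtype=float)
    a0 = 30_000.0
    early = a0 * (1 - 0.015 * day)               # >= 0.97 a0 at day 2
    late = a0 * 0.97 * np.exp(-0.25 * (day - 2))  # strict decline after day 2
    return np.where(day <= 2, early, late)


def _hfd_area(day: np.ndarray) -> np.ndarray:
    return 30_000.0 + 11_000.0 * day   # faster accrual on a high-fat diet


DEFAULT_GROUP_CURVES = {
    "fed": (_fed_sl, _fed_area),
    "fasted": (_fasted_sl, _fasted_area),
    "control_feed": (_fed_sl, _fed_area),
    "HFD": (_fed_sl, _hfd_area),
}


@dataclass
class CohortSimParams:
    """Longitudinal cohort simulator: repeated (area, standard length)
    measurements per fish with fish-level and observation-level noise.

    Default group curves encode the study conditions: fed fish grow in both
    SL and area; fasted fish hold adiposity through day 2 of fasting and
    decline after; high-fat-diet fish accrue area faster at unchanged SL.
    """

    groups: list[tuple[str, int]] = field(default_factory=lambda: [("fed", 24), ("fasted", 24)])
    days: list[int] = field(default_factory=lambda: [0, 2, 5, 7])
    curves: dict | None = None            # label -> (sl_fn, area_fn); default DEFAULT_GROUP_CURVES
    between_fish_sd: float = 0.15         # fractional, fish-level
    within_fish_sd: float = 0.05          # fractional, per observation
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted ascending")
        if self.between_fish_sd < 0 or self.within_fish_sd < 0:
            raise ValueError("noise sds must be >= 0")
        curves = self.curves or DEFAULT_GROUP_CURVES
        day = np.asarray(self.days, dtype=float)
        for label, _n in self.groups:
            if label not in curves:
                raise ValueError(f"no expected curves for group {label!r}")
            sl_fn, area_fn = curves[label]
            sl = sl_fn(day)
            if "fast" not in label.lower() and np.any(np.diff(sl) < 0):
                raise ValueError(f"expected SL for fed-type group {label!r} must be non-decreasing")
            if "fast" in label.lower() and len(day) and day[0] == 0:
                area = area_fn(np.asarray([0.0, 2.0]))
                if area[1] < 0.95 * area[0]:
                    raise ValueError("fasted expected area at day 2 must stay >= 0.95 x day-0 value")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a repeated-measures cohort.

    Returns a tidy frame with one row per fish-day: fish_id, group, day,
    area_um2, standard_length_mm, area_per_sl_um2_per_mm.  Fish identity is
    preserved across days; noiseless parameters reproduce the group mean
    curves exactly.
    """
    rng = np.random.default_rng(params.seed)
    curves = params.curves or DEFAULT_GROUP_CURVES
    day = np.asarray(params.days, dtype=float)
    rows = []
    for label, n_fish in params.groups:
        sl_fn, area_fn = curves[label]
        sl_mean, area_mean = sl_fn(day), area_fn(day)
        for i in range(n_fish):
            fid = f"{label}_{i:03d}"
            fish_area = 1 + params.between_fish_sd * rng.standard_normal()
            fish_sl = 1 + (params.between_fish_sd / 3) * rng.standard_normal()
            for d, sl_m, a_m in zip(params.days, sl_mean, area_mean):
                area = a_m * fish_area * (1 + params.within_fish_sd * rng.standard_normal())
                sl = sl_m * fish_sl * (1 + (params.within_fish_sd / 3) * rng.standard_normal())
                area, sl = max(area, 0.0), max(sl, 1e-6)
                rows.append({"fish_id": fid, "group": label, "day": d,
                             "area_um2": area, "standard_length_mm": sl,
                             "area_per_sl_um2_per_mm": area / sl})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Flow-cytometry samples


@dataclass
class FlowSample:
    """Per-cell fluorescence events, optionally with true mixture labels."""

    tdtomato: np.ndarray
    gfp: np.ndarray
    condition: str = "sample"
    true_label: np.ndarray | None = None   # 1 = lipid-droplet-positive

    def __post_init__(self) -> None:
        self.tdtomato = np.asarray(self.tdtomato, dtype=float)
        if self.tdtomato.size < 1:
            raise ValueError("FlowSample needs >= 1 event")
        if np.any(self.tdtomato < 0):
            raise ValueError("intensities must be >= 0")


def generate_flow_sample(n_cells: int, fraction_positive: float,
                         neg_mu_sigma: tuple[float, float] = (4.0, 0.4),
                         pos_mu_sigma: tuple[float, float] = (7.0, 0.4),
                         seed: int = 0, condition: str = "sample") -> FlowSample:
    """Draw tdTomato intensities from a two-component lognormal mixture
    (lipid-droplet-negative and -positive populations) with known labels.

    ``neg_mu_sigma``/``pos_mu_sigma`` are the log-scale mean and sd of each
    component.
    """
    if not 0 <= fraction_positive <= 1:
        raise ValueError("fraction_positive must be in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_cells) < fraction_positive).astype(int)
    mu = np.where(labels == 1, pos_mu_sigma[0], neg_mu_sigma[0])
    sigma = np.where(labels == 1, pos_mu_sigma[1], neg_mu_sigma[1])
    tdt = rng.lognormal(mu, sigma)
    gfp = rng.lognormal(5.0, 0.3, n_cells)   # constitutive cytoplasmic GFP
    return FlowSample(tdt, gfp, condition, labels)
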