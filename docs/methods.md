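# Methods

## Image model and segmentation

### What the simulator emulates

A juvenile transparent zebrafish imaged on a fluorescence stereo zoom
microscope with GFP, tdTomato and Cy5 filter sets. Two tissue signals
matter for quantification:

- **Visceral adipose tissue**: a compact cluster of adipocytes near the
  swim bladder. Modeled as `n_adipose_blobs` filled ellipses (semi-axes
  drawn from `blob_axes_range`, default 6–16 px; random orientation) placed
  disjointly by rejection sampling inside a central box (30–70% of each
  image dimension — the visceral depot is anatomically compact, and this
  guarantees a fixed-size crop can cover it). In reporter images the blobs
  carry `adipose_peak` (180 AU) in tdTomato and a small bleed
  (`adipose_gfp_leak`, 5 AU) in GFP; in BODIPY images they carry the peak in
  GFP only.
- **Gut/gallbladder autofluorescence**: a single elongated elliptical
  region along the bottom image edge, autofluorescing in all three channels
  (GFP 150, tdTomato 120, Cy5 140 AU). By default it is disjoint from the
  adipose mask (`gut_overlap_fraction = 0`).

On top: constant background (20 AU), optional Gaussian edge blur
(`blur_sigma`, default 1 px, applied to the noiseless image), then additive
Gaussian noise (`noise_sd`, default 8 AU; Poisson optional), clipped at 0.
All intensity defaults are placeholders: the source imaging study does not
report adipocyte size or autofluorescence intensity distributions, so these
values are chosen only to be *separable but not trivially so* (blob contrast
≈ 20σ of noise, gut present in the gate channel at ≈ 16σ).

Ground-truth area is defined **pre-blur** on the ideal rasterized ellipse
(pixel centers with normalized radius ≤ 1). Edge blur moves the apparent
boundary, so exactness tests run at `blur_sigma = 0` and recovery tests at
defaults budget a few percent of relative error for blur + noise.

What the generator does **not** model: optical PSFs, depth effects,
anatomy beyond the two signal classes, brightfield, uneven illumination,
motion. Passing recovery tests therefore demonstrates correctness of the
algorithmic chain, not robustness to every real-world artifact.

### Reporter (tdTomato) segmentation

1. `subtract_background`: tdTomato pixels with GFP ≥ `gfp_background_thresh`
   are zeroed (mask exclusion). The alternative reading — subtracting the
   GFP intensity — is available as `subtract_mode="intensity"`; mask
   exclusion is the default because the purpose of the step is to *remove*
   autofluorescent gut signal, and an intensity difference of two
   autofluorescent channels has no physical unit of its own.
2. `detect_crop`: a box of exactly `crop_size` centered on the
   intensity-weighted centroid of pixels ≥ `tdt_detect_thresh`, shifted
   (never shrunk) to fit the image — the crop is "a set size" by contract.
   `crop_size` default 200×200 px on the default 256×256 field, which
   provably covers the default placement box.
3. `segment_in_crop`: coarse mask = detect-threshold pixels dilated by a
   disk of radius `mask_dilation_px` (default 2); final mask = coarse-mask
   pixels ≥ `tdt_segment_thresh`; 8-connected components smaller than
   `min_component_px` (default 20) are dropped. The two-threshold design
   separates *finding* tissue (low threshold tolerant of dim edges) from
   *delineating* it (high threshold robust to halo).
4. Area: pixel count × pixel_size². Multiple depots sum into one total.

Threshold defaults (GFP 60, detect 60, segment 90 AU) are declared
conventions tied to the simulator's intensity scale; `quantile_mode`
reinterprets them as image quantiles for data on other scales.

### BODIPY segmentation

`mask = (GFP ≥ isodata(GFP)) AND NOT (Cy5 ≥ isodata(Cy5))`, intersected
with the rasterized ROI when given (whole image otherwise — the
batch-friendly replacement of interactive polygon drawing). The
auto-threshold is isodata — iterate `t ← (mean(px < t) + mean(px ≥ t))/2`
from the midrange until `|Δt| < 0.5 AU` — the historical default of
interactive thresholding tools; Otsu is selectable and the report records
the method and iteration count. Cy5 removal is a mask-level set
difference, not an intensity subtraction.

### Rasterization and coordinates

Everything is 0-based (row, col), row 0 on top; a pixel is the unit square
centered on its integer coordinates. ROI rasterization includes a pixel iff
its center is inside the polygon under the even-odd rule, or exactly on the
boundary (inclusive, tolerance 1e-9). Tests verify this pixel-for-pixel
against an independent geometric-predicate oracle on random simple
polygons.

## Screen model and analysis

Per-well glycerol (mg/ml):
`g = baseline · (1 − reduction) · bias(r,c) · LogNormal(cv)`, with
positive-control wells at `baseline · stimulated_fold` and standards at
their nominal concentration; absorbance `A = slope·g + intercept` (slope
0.8 AU/(mg/ml), intercept 0.05 AU). The lognormal noise has unit mean so
`cv=0` is exactly noiseless, making the curve round trip exact by
construction — an invariant the tests assert at 1e-9 relative. The default
16 plates × 80 compound wells give 1280 compounds; the default layout puts
DMSO and isoproterenol controls in column 0 and a 0–1 mg/ml glycerol
standard ladder in column 11.

Analysis choices, where the underlying procedure left room:

- Position factors are computed on **glycerol** (post-curve), not raw
  absorbance, so the curve intercept cannot leak into factors; they average
  compound and DMSO wells only (standards/empties carry no biology).
  Normalization **divides** by the factor — the only choice under which
  "normalized value 1" means "no effect" and log2 reporting is coherent.
- Fold change is taken **versus the plate's DMSO mean** (the designated
  negative control), not the plate average; the reference is a parameter.
- Hit rule: `reduction = 1 − fold ≥ 0.40`, boundary inclusive ("at least").
- Well positions whose glycerol clamps negative enter factors as 0 and are
  flagged; ranking uses ascending log2 fold with compound-id tie-break.
- QC computes the positive-control fold on raw glycerol per plate (position
  factors are undefined at control-only positions); with flat bias and
  `cv=0` this equals `stimulated_fold` exactly.

Planted inhibitors for recovery studies are placed at **distinct well
positions** (`plant_inhibitors`): each position's factor is estimated from
one well per plate, so stacking several planted effects on one position
would bias that factor — the normalization's own premise is that most
compounds at a position are inactive. The recovery study condition is 29
inhibitors at 50% reduction among 1280 compounds, `cv = 0.05`, edge bias
0.85/0.95/1.0 by ring.

## Cohort model and statistics

Default group curves (per day `d`): fed SL `6 + 0.2d` mm, fed area
`30000 + 6000d` µm²; fasted SL constant 6 mm, fasted area
`30000·(1 − 0.015d)` through day 2 (≥ 95% of baseline — adipose lipolysis
lags fasting onset) then `0.97·30000·e^{−0.25(d−2)}`; high-fat diet area
`30000 + 11000d` at fed SL. Noise is multiplicative: a fish-level factor
(fractional SD 0.15 for area, one third of that for SL) fixed across days,
plus per-observation noise (0.05). Noiseless settings reproduce the curves
exactly, which the tests use as construction oracles.

- `area_per_sl = area / SL` (µm²/mm) — the BMI-like adiposity index. Areas
  in px² are accepted only with an explicit flag so units never mix.
- Summaries: per-group, per-day mean and Student-t 95% CI (a declared
  convention; coverage is verified by Monte-Carlo at ~95% ± 2%); groups
  with n < 2 get an undefined-CI flag.
- Two groups: two-sided Mann-Whitney, exact null distribution when
  n1+n2 ≤ 20 without ties, tie-corrected normal approximation otherwise.
  Exact p-values are verified against full enumeration of all rank
  assignments for every size with n1+n2 ≤ 8. With n = 10 per group the
  discrete exact test's attainable level at α = 0.05 is 0.0433, so the
  simulated type-I rate sits just below nominal.
- More groups: Kruskal-Wallis, then Dunn's pairwise z-tests
  (`z = ΔR̄ / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ))`) with Holm
  adjustment by default (Bonferroni/Šidák selectable); raw and adjusted
  p-values are both reported.
- Flow gating: gate = 99th percentile (configurable, logged) of the
  lipid-droplet-low control's tdTomato values; events strictly above count
  as positive. The statistic is invariant under any strictly monotone
  transform applied to both samples. The simulator draws intensities from a
  two-component lognormal mixture (log-means 4.0/7.0, log-SD 0.4) with
  labels returned for recovery tests.

## Problem sizes and determinism

Study sizes used throughout: 50 fish for segmentation recovery, 16 plates /
1280 compounds for the screen, 24 fish per cohort group over days
{0,2,5,7}, 10⁴ replicates for test calibration, 10⁵ events for flow
recovery. Every generator consumes one explicit integer seed
(`numpy.random.default_rng`); identical parameters and seed reproduce
outputs bit for bit, and no global RNG state is read or written.

## Known limitations

- Thresholds are global, not locally adaptive; strong illumination
  gradients would need the quantile mode or preprocessing.
- The screen analysis implements position-mean normalization only; B-score
  or median-polish alternatives would be natural extensions.
- CZI microscope files are not read; convert to TIFF externally.
- No per-adipocyte instance segmentation, no mixed-effects longitudinal
  modeling, no dose–response fitting.
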