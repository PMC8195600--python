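"""Reporter-channel adipose segmentation.

The core pipeline for lipid-droplet-reporter (tdTomato) images: the
zebrafish gut and gallbladder autofluoresce strongly in both the GFP and
tdTomato channels, while the reporter is tdTomato-only, so GFP serves as an
autofluorescence gate.  The steps are

1. background subtraction — zero every tdTomato pixel whose GFP value
   reaches the background threshold (mask exclusion; an intensity-
   subtraction mode is available),
2. a fixed-size crop centered on the remaining tdTomato signal,
3. within the crop, a coarse detect-threshold mask (dilated), inside which
   a higher segment threshold defines adipose pixels; tiny connected
   components are discarded,
4. pixel counting, converted to µm² via the pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.measure import label
from skimage.morphology import dilation, disk

from .imgio import ChannelImage, FishImage, RegistrationError

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "subtract_background",
    "detect_crop",
    "segment_in_crop",
    "quantify_fish",
]


@dataclass
class SegmentationConfig:
    """Thresholds and geometry of the reporter segmentation.

    All thresholds are absolute intensities (AU) by default; set
    ``quantile_mode=True`` to interpret them as quantiles of the image
    instead.  ``tdt_segment_thresh`` must not be below
    ``tdt_detect_thresh`` — the segment threshold refines the detect mask.
    """

    gfp_background_thresh: float = 60.0
    tdt_detect_thresh: float = 60.0
    tdt_segment_thresh: float = 90.0
    crop_size: tuple[int, int] = (200, 200)
    min_component_px: int = 20
    mask_dilation_px: int = 2
    subtract_mode: str = "mask"      # "mask" (zero gated pixels) or "intensity"
    quantile_mode: bool = False

    def __post_init__(self) -> None:
        if self.tdt_segment_thresh < self.tdt_detect_thresh:
            raise ValueError("tdt_segment_thresh must be >= tdt_detect_thresh")
        if self.crop_size[0] <= 0 or self.crop_size[1] <= 0:
            raise ValueError("crop_size must be positive")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")
        if self.subtract_mode not in ("mask", "intensity"):
            raise ValueError(f"unknown subtract_mode {self.subtract_mode!r}")


@dataclass
class SegmentationResult:
    """Final mask (full-image coordinates), crop box, and areas."""

    adipose_mask: np.ndarray
    crop_box: tuple[int, int, int, int] | None   # (row0, col0, row1, col1), half-open
    area_px: int
    area_um2: float
    thresholds_used: dict = field(default_factory=dict)
    detected: bool = True

    def __post_init__(self) -> None:
        assert self.area_px == int(self.adipose_mask.sum())
        if not self.detected:
            assert self.area_px == 0


def _resolve(thresh: float, pixels: np.ndarray, quantile_mode: bool) -> float:
    return float(np.quantile(pixels, thresh)) if quantile_mode else thresh


def subtract_background(tdt: ChannelImage, gfp: ChannelImage,
                        gfp_background_thresh: float,
                        mode: str = "mask") -> ChannelImage:
    """Remove gut/gallbladder autofluorescence from the reporter channel.

    ``mask`` mode zeroes every tdTomato pixel whose co-registered GFP value
    is >= the background threshold; ``intensity`` mode subtracts the GFP
    value there instead (clipped at 0).  Idempotent in both modes.
    """
    if tdt.shape != gfp.shape:
        raise RegistrationError(f"tdTomato {tdt.shape} and GFP {gfp.shape} are not co-registered")
    out = tdt.pixels.astype(float).copy()
    bg = gfp.pixels >= gfp_background_thresh
    if mode == "mask":
        out[bg] = 0.0
    elif mode == "intensity":
        out[bg] = np.clip(out[bg] - gfp.pixels[bg], 0, None)
    else:
        raise ValueError(f"unknown subtraction mode {mode!r}")
    return ChannelImage(out, tdt.channel, tdt.pixel_size)


def detect_crop(tdt_bs: ChannelImage, tdt_detect_thresh: float,
                crop_size: tuple[int, int]) -> tuple[int, int, int, int] | None:
    """Locate the fixed-size crop around reporter-positive signal.

    The box of exactly ``crop_size`` is centered on the intensity-weighted
    centroid of supra-threshold pixels and shifted — never shrunk — to fit
    inside the image.  Returns None when no pixel reaches the detect
    threshold.
    """
    rows, cols = tdt_bs.shape
    ch, cw = crop_size
    if ch > rows or cw > cols:
        raise ValueError(f"crop_size {crop_size} exceeds image shape {(rows, cols)}")
    px = tdt_bs.pixels
    hit = px >= tdt_detect_thresh
    if not hit.any():
        return None
    rr, cc = np.nonzero(hit)
    w = px[rr, cc].astype(float)
    cy = float(np.sum(rr * w) / w.sum())
    cx = float(np.sum(cc * w) / w.sum())
    r0 = int(round(cy - (ch - 1) / 2))
    c0 = int(round(cx - (cw - 1) / 2))
    r0 = min(max(r0, 0), rows - ch)
    c0 = min(max(c0, 0), cols - cw)
    return (r0, c0, r0 + ch, c0 + cw)


def segment_in_crop(tdt_bs: ChannelImage, crop_box: tuple[int, int, int, int],
                    tdt_detect_thresh: float, tdt_segment_thresh: float,
                    min_component_px: int = 0, mask_dilation_px: int = 0) -> np.ndarray:
    """Masked high-threshold segmentation inside the crop.

    The coarse adipose mask is the supra-detect-threshold region dilated by
    ``mask_dilation_px``; within it, pixels at or above the (higher)
    segment threshold survive; 8-connected components smaller than
    ``min_component_px`` are removed.  Returned in full-image coordinates,
    zero outside the crop.
    """
    r0, c0, r1, c1 = crop_box
    rows, cols = tdt_bs.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"crop_box {crop_box} outside image {(rows, cols)}")
    crop = tdt_bs.pixels[r0:r1, c0:c1]
    coarse = crop >= tdt_detect_thresh
    if mask_dilation_px > 0:
        coarse = dilation(coarse, disk(mask_dilation_px))
    fine = coarse & (crop >= tdt_segment_thresh)
    if min_component_px > 0 and fine.any():
        labels = label(fine, connectivity=2)
        sizes = np.bincount(labels.ravel())
        small = sizes < min_component_px
        small[0] = False
        fine[small[labels]] = False
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r1, c0:c1] = fine
    return mask


def quantify_fish(img: FishImage, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full reporter segmentation on one fish image.

    Composes background subtraction, crop detection and in-crop
    segmentation; the reported area is the pixel count of the final mask
    scaled by the squared pixel size.
    """
    cfg = cfg or SegmentationConfig()
    if "tdTomato" not in img.channels or "GFP" not in img.channels:
        raise KeyError("quantify_fish needs both 'tdTomato' and 'GFP' channels")
    tdt, gfp = img["tdTomato"], img["GFP"]

    gfp_thr = _resolve(cfg.gfp_background_thresh, gfp.pixels, cfg.quantile_mode)
    tdt_bs = subtract_background(tdt, gfp, gfp_thr, cfg.subtract_mode)
    det_thr = _resolve(cfg.tdt_detect_thresh, tdt_bs.pixels, cfg.quantile_mode)
    seg_thr = _resolve(cfg.tdt_segment_thresh, tdt_bs.pixels, cfg.quantile_mode)

    used = asdict(cfg)
    used.update(gfp_background_thresh=gfp_thr, tdt_detect_thresh=det_thr,
                tdt_segment_thresh=seg_thr)

    box = detect_crop(tdt_bs, det_thr, cfg.crop_size)
    if box is None:
        empty = np.zeros(img.shape, dtype=bool)
        return SegmentationResult(empty, None, 0, 0.0, used, detected=False)
    mask = segment_in_crop(tdt_bs, box, det_thr, seg_thr,
                           cfg.min_component_px, cfg.mask_dilation_px)
    area_px = int(mask.sum())
    return SegmentationResult(mask, box, area_px,
                              area_px * img.pixel_size ** 2, used,
                              detected=True)
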