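"""BODIPY-stain adipose quantification.

The dye variant of the pipeline: adipose tissue is read out in the GFP
channel (BODIPY 493/503), gut autofluorescence is identified by
auto-thresholding the Cy5 channel and removed as a mask-level set
difference, and the remaining area is counted inside an optional
user-drawn ROI polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .imgio import ChannelImage, RegistrationError, RoiPolygon, rasterize_roi
from .segment_plin2 import SegmentationResult

__all__ = ["AutoThresholdReport", "DegenerateImageError", "auto_threshold", "bodipy_area"]


class DegenerateImageError(ValueError):
    """Auto-thresholding is undefined on a constant image."""


@dataclass
class AutoThresholdReport:
    """Outcome of automatic thresholding on one channel.

    ``threshold`` separates background (below) from signal (at/above);
    ``method`` records which rule produced it so results are reproducible.
    """

    threshold: float
    method: str
    iterations: int
    converged: bool


_ISODATA_TOL = 0.5  # AU; iteration stops when the threshold moves less than this


def auto_threshold(img: ChannelImage | np.ndarray, method: str = "isodata") -> AutoThresholdReport:
    """Automatic intensity threshold for a fluorescence channel.

    ``isodata`` (default) iterates t <- (mean below t + mean at/above t)/2
    from the midrange start until the threshold moves by less than 0.5 AU
    — the classic interactive-tool default.  ``otsu`` minimizes intra-class
    variance instead.  Raises :class:`DegenerateImageError` on a constant
    image.
    """
    px = np.asarray(img.pixels if isinstance(img, ChannelImage) else img, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        raise DegenerateImageError("constant image: auto-threshold undefined")

    if method == "otsu":
        return AutoThresholdReport(float(threshold_otsu(px)), "otsu", 0, True)
    if method != "isodata":
        raise ValueError(f"unknown auto-threshold method {method!r}")

    # any t in (lo, hi) leaves both classes nonempty, and the update keeps
    # t strictly inside (lo, hi), so the class means are always defined
    t = (lo + hi) / 2.0
    for it in range(1, 1000):
        t_new = (px[px < t].mean() + px[px >= t].mean()) / 2.0
        if abs(t_new - t) < _ISODATA_TOL:
            return AutoThresholdReport(float(t_new), "isodata", it, True)
        t = t_new
    return AutoThresholdReport(float(t), "isodata", 999, False)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 0 or not mask.any():
        return mask
    labels = label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    small = sizes < min_px
    small[0] = False
    out = mask.copy()
    out[small[labels]] = False
    return out


def bodipy_area(gfp: ChannelImage, cy5: ChannelImage,
                roi: RoiPolygon | None = None,
                min_component_px: int = 0,
                method: str = "isodata") -> SegmentationResult:
    """Quantify BODIPY-stained adipose area.

    mask = (GFP >= auto_threshold(GFP)) AND NOT (Cy5 >= auto_threshold(Cy5)),
    intersected with the rasterized ROI when one is provided (otherwise the
    whole image); components smaller than ``min_component_px`` are removed.
    """
    if gfp.shape != cy5.shape:
        raise RegistrationError(f"GFP {gfp.shape} and Cy5 {cy5.shape} are not co-registered")
    try:
        gfp_rep = auto_threshold(gfp, method)
    except DegenerateImageError as e:
        raise DegenerateImageError(f"GFP channel: {e}") from e
    try:
        cy5_rep = auto_threshold(cy5, method)
    except DegenerateImageError as e:
        raise DegenerateImageError(f"Cy5 channel: {e}") from e

    mask = (gfp.pixels >= gfp_rep.threshold) & ~(cy5.pixels >= cy5_rep.threshold)
    if roi is not None:
        mask &= rasterize_roi(roi, gfp.shape)
    mask = _remove_small(mask, min_component_px)

    area_px = int(mask.sum())
    rows, cols = gfp.shape
    return SegmentationResult(
        mask, (0, 0, rows, cols), area_px, area_px * gfp.pixel_size ** 2,
        thresholds_used={"gfp_auto": gfp_rep.threshold, "cy5_auto": cy5_rep.threshold,
                         "method": method, "min_component_px": min_component_px},
        detected=area_px > 0,
    )
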