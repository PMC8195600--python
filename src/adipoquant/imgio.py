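"""Image data model and file I/O.

Multi-channel fluorescence images travel as multi-page TIFF (one page per
channel) with a JSON sidecar naming the channels and carrying the pixel
calibration.  Regions of interest are plain polygons in pixel coordinates.

Coordinate convention, used everywhere in this package: 0-based (row, col),
row 0 at the top of the image.  A pixel's *center* sits at integer
coordinates, so pixel (3, 7) is the unit square centered on row 3, col 7.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "FLUORESCENCE_CHANNELS",
    "ChannelImage",
    "FishImage",
    "RoiPolygon",
    "FormatError",
    "RegistrationError",
    "read_fish_image",
    "write_fish_image",
    "read_roi",
    "write_roi",
    "rasterize_roi",
]

#: Channel names understood by the pipeline.  GFP doubles as the BODIPY
#: readout channel; Cy5 carries gut/gallbladder autofluorescence only.
FLUORESCENCE_CHANNELS = ("GFP", "tdTomato", "Cy5")
ALL_CHANNELS = FLUORESCENCE_CHANNELS + ("brightfield",)


class FormatError(ValueError):
    """A file does not match the expected on-disk layout or metadata."""


class RegistrationError(ValueError):
    """Channels that must be co-registered disagree in shape or calibration."""


@dataclass
class ChannelImage:
    """A single 2D fluorescence channel with pixel calibration.

    Parameters
    ----------
    pixels : 2D array of non-negative, finite intensities (arbitrary units).
    channel : one of ``ALL_CHANNELS``.
    pixel_size : physical edge length of a pixel in micrometres.
    """

    pixels: np.ndarray
    channel: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"channel {self.channel!r}: expected a 2D grid, got ndim={self.pixels.ndim}")
        if self.channel not in ALL_CHANNELS:
            raise FormatError(f"unknown channel name {self.channel!r}; expected one of {ALL_CHANNELS}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError(f"channel {self.channel!r}: non-finite pixel values")
        if np.any(self.pixels < 0):
            raise FormatError(f"channel {self.channel!r}: negative pixel values")
        if not (self.pixel_size > 0):
            raise FormatError(f"pixel_size must be > 0 µm, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FishImage:
    """Co-registered multi-channel image of one fish at one time point."""

    channels: Mapping[str, ChannelImage]
    fish_id: str = "fish"
    dpf: int | None = None
    group: str | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not any(name in self.channels for name in FLUORESCENCE_CHANNELS):
            raise FormatError("FishImage needs at least one fluorescence channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise RegistrationError(f"channel shapes disagree: {sorted(shapes)}")
        sizes = {ch.pixel_size for ch in self.channels.values()}
        if len(sizes) > 1:
            raise RegistrationError(f"channel pixel sizes disagree: {sorted(sizes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def __getitem__(self, channel: str) -> ChannelImage:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(f"image has no {channel!r} channel (has {sorted(self.channels)})") from None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fish_image(img: FishImage, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a multi-page TIFF (one page per channel) plus a JSON sidecar.

    Channel order in the TIFF matches the ``channels`` key in the sidecar.
    Returns the sidecar path.
    """
    path = Path(path)
    names = list(img.channels)
    pages = np.stack([img.channels[n].pixels for n in names])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "channels": names,
        "pixel_size_um": img.pixel_size,
        "fish_id": img.fish_id,
        "dpf": img.dpf,
        "group": img.group,
        "day": img.day,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_fish_image(path: str | Path) -> FishImage:
    """Read a multi-page TIFF with its JSON sidecar into a :class:`FishImage`.

    Raises :class:`FormatError` when the sidecar is missing, the page count
    disagrees with the channel list, pages are RGB, or shapes mismatch.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar} naming channels and pixel_size")
    meta = json.loads(sidecar.read_text())
    if "channels" not in meta or "pixel_size_um" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks required keys 'channels'/'pixel_size_um'")
    names = list(meta["channels"])
    pixel_size = float(meta["pixel_size_um"])

    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    # A single 3D stack written as one page: split along the leading axis.
    if len(pages) == 1 and pages[0].ndim == 3 and pages[0].shape[0] == len(names):
        pages = list(pages[0])
    if any(p.ndim != 2 for p in pages):
        raise FormatError(f"{path}: RGB/multi-sample pages rejected; channels must be separate grayscale pages")
    if len(pages) != len(names):
        raise FormatError(f"{path}: {len(pages)} TIFF pages but metadata names {len(names)} channels")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"{path}: TIFF page shapes disagree: {sorted(shapes)}")

    channels = {n: ChannelImage(p, n, pixel_size) for n, p in zip(names, pages)}
    return FishImage(
        channels,
        fish_id=meta.get("fish_id") or "fish",
        dpf=meta.get("dpf"),
        group=meta.get("group"),
        day=meta.get("day"),
    )


# --------------------------------------------------------------------------
# ROI polygons


@dataclass
class RoiPolygon:
    """A simple polygon in 0-based (row, col) pixel coordinates.

    Vertices are ordered; the closing edge back to the first vertex is
    implicit.  The polygon must be simple (non-self-intersecting) and have
    at least three vertices.
    """

    vertices: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if len(self.vertices) < 3:
            raise FormatError(f"ROI polygon needs >= 3 vertices, got {len(self.vertices)}")
        poly = _ShapelyPolygon([(c, r) for r, c in self.vertices])
        if not poly.is_simple or poly.area == 0:
            raise ValueError("ROI polygon is self-intersecting or degenerate")


def read_roi(path: str | Path) -> RoiPolygon:
    """Read a polygon from JSON ``{"vertices": [[row, col], ...]}`` or a
    two-column CSV (row, col; an optional header row is tolerated)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        verts = data["vertices"] if isinstance(data, dict) else data
        return RoiPolygon([(v[0], v[1]) for v in verts])
    verts = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                verts.append((float(row[0]), float(row[1])))
            except ValueError:
                continue  # header line
    return RoiPolygon(verts)


def write_roi(roi: RoiPolygon, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"vertices": [list(v) for v in roi.vertices]}))


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask of the given image shape.

    A pixel belongs to the mask iff its center lies strictly inside the
    polygon under the even-odd rule, or exactly on the boundary
    (boundary-inclusive).  Raises ``ValueError`` if any vertex falls outside
    the image grid.
    """
    rows, cols = shape
    verts = np.asarray(roi.vertices, dtype=float)
    if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
            or verts[:, 0].max() > rows - 1 or verts[:, 1].max() > cols - 1):
        raise ValueError(f"ROI vertex outside image of shape {shape}")

    r0 = int(np.floor(verts[:, 0].min()))
    r1 = int(np.ceil(verts[:, 0].max()))
    c0 = int(np.floor(verts[:, 1].min()))
    c1 = int(np.ceil(verts[:, 1].max()))

    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    py = rr.astype(float).ravel()  # y = row
    px = cc.astype(float).ravel()  # x = col

    inside = np.zeros(px.size, dtype=bool)
    on_edge = np.zeros(px.size, dtype=bool)
    n = len(verts)
    eps = 1e-9
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        # boundary test: zero cross product and point within segment bbox
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (px >= min(x1, x2) - eps) & (px <= max(x1, x2) + eps)
            & (py >= min(y1, y2) - eps) & (py <= max(y1, y2) + eps)
        )
        on_edge |= (np.abs(cross) <= eps * max(1.0, abs(x2 - x1) + abs(y2 - y1))) & within
        # even-odd ray cast: horizontal ray towards +x
        crosses = ((y1 > py) != (y2 > py))
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)

    mask = np.zeros(shape, dtype=bool)
    mask[rr.ravel(), cc.ravel()] = inside | on_edge
    return mask
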