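"""Raster data model, TIFF I/O, thresholding, ROI construction and
intensity-density quantification.

The central readout of the multi-cluster assay is the mean reflection
signal density inside a cell-free rectangular ROI placed between two
fibroblast clusters, computed per Z-section and averaged across the stack.
The same densitometry is reused for the GFP reporter channel.

Conventions: rasters are ordered (z, y, x) with the origin at the top-left
pixel; x indexes columns, y indexes rows; all intervals are half-open;
micron-to-pixel conversions round half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import tifffile

CHANNELS = ("reflection", "hoechst", "pi", "factin", "gfp")

__all__ = [
    "CHANNELS",
    "VolumeImage",
    "RectROI",
    "ThresholdResult",
    "DensityResult",
    "read_stack",
    "write_stack",
    "threshold_image",
    "interspheroid_roi",
    "intensity_density",
    "um_to_px",
]


def um_to_px(value_um: float, pixel_size_xy: float) -> int:
    """Convert microns to integer pixels, rounding half away from zero."""
    x = value_um / pixel_size_xy
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class VolumeImage:
    """One channel's Z-stack with physical spacing metadata.

    voxels : float array ordered (z, y, x), all intensities >= 0
    pixel_size_xy : lateral sampling in um/pixel (> 0)
    z_step : axial section spacing in um (> 0)
    channel : one of CHANNELS
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step: float
    channel: str

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 section")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if not (np.isfinite(self.pixel_size_xy) and self.pixel_size_xy > 0):
            raise ValueError("pixel_size_xy must be positive and finite")
        if not (np.isfinite(self.z_step) and self.z_step > 0):
            raise ValueError("z_step must be positive and finite")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def n_sections(self) -> int:
        return self.voxels.shape[0]

    @property
    def section_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def section(self, z: int) -> np.ndarray:
        return self.voxels[z]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, half-open: [x0, x1) x [y0, y1) in pixels."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("RectROI requires x0 < x1 and y0 < y1")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area_px(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center of the rectangle."""
        return ((self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0)

    def check_inside(self, section_shape: tuple[int, int]) -> None:
        h, w = section_shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(
                f"ROI {self} exceeds section bounds (h={h}, w={w})"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the ROI in a 2D section."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def extract(self, section: np.ndarray) -> np.ndarray:
        self.check_inside(section.shape)
        ys, xs = self.slices()
        return section[ys, xs]

    def shifted(self, dx: int, dy: int) -> "RectROI":
        return RectROI(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)


@dataclass
class ThresholdResult:
    """Foreground mask from thresholding one section.

    mask : boolean raster, True = foreground (collagen fiber / signal)
    threshold : the intensity cut applied
    degenerate : True when the section was constant and no threshold exists
    """

    mask: np.ndarray
    threshold: float
    degenerate: bool = False


@dataclass
class DensityResult:
    """Per-section intensity densities and their stack mean (the score).

    Density is the mean intensity per included ROI pixel, which makes the
    score invariant to ROI size; multiply by the pixel count for totals.
    """

    per_z: np.ndarray
    mean: float
    n_pixels_per_z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.per_z = np.asarray(self.per_z, dtype=float)
        if np.any(self.per_z < 0):
            raise ValueError("densities must be non-negative")
        if not np.isclose(self.mean, float(np.mean(self.per_z))):
            raise ValueError("mean must equal the arithmetic mean of per_z")


def read_stack(path, channel: str, pixel_size_xy: float, z_step: float) -> VolumeImage:
    """Read a single- or multi-page TIFF into a VolumeImage.

    Page order maps to ascending Z. Pages of differing shape are rejected.
    """
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"TIFF pages have inconsistent shapes: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    return VolumeImage(voxels=data, pixel_size_xy=pixel_size_xy,
                       z_step=z_step, channel=channel)


def write_stack(path, image: VolumeImage) -> None:
    """Write a VolumeImage as a multi-page float32 TIFF (one page per Z)."""
    tifffile.imwrite(path, image.voxels.astype(np.float32))


def threshold_image(section: np.ndarray, method: str = "otsu",
                    value: Optional[float] = None) -> ThresholdResult:
    """Binarize one section into foreground (True) and background.

    method="otsu" maximizes between-class variance; a constant section has
    no such threshold and returns an empty foreground flagged degenerate.
    method="fixed" marks pixels strictly above ``value`` as foreground.
    """
    section = np.asarray(section, dtype=float)
    if section.size == 0:
        raise ValueError("section is empty")
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        return ThresholdResult(mask=section > value, threshold=float(value))
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    lo, hi = float(section.min()), float(section.max())
    if lo == hi:
        return ThresholdResult(mask=np.zeros(section.shape, dtype=bool),
                               threshold=lo, degenerate=True)
    from skimage.filters import threshold_otsu

    t = float(threshold_otsu(section))
    return ThresholdResult(mask=section > t, threshold=t)


def _roi_overlaps_exclusion(roi: RectROI, exclusion: np.ndarray) -> bool:
    ys, xs = roi.slices()
    return bool(exclusion[ys, xs].any())


def interspheroid_roi(center_a: tuple[float, float], center_b: tuple[float, float],
                      width_um: float, height_um: float, pixel_size_xy: float,
                      section_shape: tuple[int, int],
                      exclusion: Optional[np.ndarray] = None) -> RectROI:
    """Place the cell-free rectangular ROI between two cluster centers.

    Centers are (x, y) pixel coordinates. The rectangle is centered on the
    inter-center midpoint with its long side (``width_um``) laid along
    whichever image axis is closer to the inter-center axis, i.e. the
    rectangle is axis-aligned. If an exclusion mask (True = excluded, e.g.
    optical-reflection artefact spots) overlaps the rectangle, the ROI is
    shifted along the inter-center axis to the nearest clear position;
    failing that, an error is raised.
    """
    (xa, ya), (xb, yb) = center_a, center_b
    if (xa, ya) == (xb, yb):
        raise ValueError("cluster centers must be distinct")
    dx, dy = xb - xa, yb - ya
    along_x = abs(dx) >= abs(dy)
    w_px = max(1, um_to_px(width_um, pixel_size_xy))
    h_px = max(1, um_to_px(height_um, pixel_size_xy))
    if not along_x:
        w_px, h_px = h_px, w_px  # long axis follows the inter-center axis

    mx, my = (xa + xb) / 2.0, (ya + yb) / 2.0
    x0 = um_to_px(mx - w_px / 2.0, 1.0)
    y0 = um_to_px(my - h_px / 2.0, 1.0)
    base = RectROI(x0, y0, x0 + w_px, y0 + h_px)

    center_gap = np.hypot(dx, dy)
    long_side = w_px if along_x else h_px
    if long_side > center_gap:
        raise ValueError(
            "clusters are too close for the requested ROI length "
            f"({long_side} px ROI vs {center_gap:.0f} px center distance)"
        )
    base.check_inside(section_shape)

    if exclusion is None or not _roi_overlaps_exclusion(base, exclusion):
        return base

    # scan symmetric offsets along the inter-center axis, nearest first
    max_off = int(center_gap - long_side) // 2 + 1
    h, w = section_shape
    for off in range(1, max_off + 1):
        for sign in (-1, 1):
            cand = base.shifted(sign * off, 0) if along_x else base.shifted(0, sign * off)
            if cand.x0 < 0 or cand.y0 < 0 or cand.x1 > w or cand.y1 > h:
                continue
            if not _roi_overlaps_exclusion(cand, exclusion):
                return cand
    raise ValueError("no artefact-free ROI position found between the clusters")


def intensity_density(stack: VolumeImage, roi: RectROI,
                      foreground_only: bool = False,
                      mask: Optional[np.ndarray] = None,
                      background_offset: float = 0.0) -> DensityResult:
    """Mean signal density in the ROI per Z-section, averaged over the stack.

    per_z[i] is the mean intensity over non-excluded ROI pixels of section
    i; ``mask`` (True = excluded) removes artefact pixels; with
    ``foreground_only`` each section is Otsu-thresholded and only
    foreground pixels inside the ROI contribute. ``background_offset`` is
    subtracted (clipped at zero) before averaging. The result is linear in
    global intensity scaling.
    """
    roi.check_inside(stack.section_shape)
    ys, xs = roi.slices()
    excl = None
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.section_shape:
            raise ValueError("mask shape must match section shape")
        excl = mask[ys, xs]
        if excl.all():
            raise ValueError("ROI is fully excluded by the mask")
    per_z, n_px = [], []
    for z in range(stack.n_sections):
        patch = stack.voxels[z, ys, xs]
        include = np.ones(patch.shape, dtype=bool)
        if excl is not None:
            include &= ~excl
        if foreground_only:
            fg = threshold_image(patch, "otsu")
            include &= fg.mask
        vals = patch[include]
        if vals.size == 0:
            per_z.append(0.0)
            n_px.append(0)
            continue
        if background_offset:
            vals = np.clip(vals - background_offset, 0.0, None)
        per_z.append(float(vals.mean()))
        n_px.append(int(vals.size))
    per_z = np.asarray(per_z)
    return DensityResult(per_z=per_z, mean=float(per_z.mean()),
                         n_pixels_per_z=np.asarray(n_px))
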