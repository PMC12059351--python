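"""Orientation-distribution analytics for protruding cells.

Cells protruding from a fibroblast cluster towards the remodeled ECM
bridge are detected in the F-actin channel, each cell is assigned one
axial orientation, and three readouts follow: the orientation histogram
over [0, 180), a Gaussian fit with a 0-1 goodness score (1 = good,
0 = poor), and the proportion of cells whose orientation falls within a
tolerance (default +-10 deg) of the reference fiber angle of the bridge,
averaged across Z-sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import label, regionprops

from .circstats import axial_distance, axial_mean, wrap_axial
from .alignment import orientation_field
from .imaging import threshold_image

__all__ = [
    "OrientationHistogram",
    "GaussianFit",
    "AlignmentProportion",
    "cell_orientations",
    "orientation_histogram",
    "fit_gaussian",
    "aligned_proportion",
]


@dataclass
class OrientationHistogram:
    """Weighted orientation counts on a partition of [0, 180)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit of an orientation histogram.

    goodness = max(0, 1 - SS_res / SS_tot), clamped to [0, 1]
    (1 = good fit, 0 = poor); valid is False on non-convergence or a
    degenerate (flat) histogram.
    """

    mean: float
    sd: float
    amplitude: float
    baseline: float
    goodness: float
    valid: bool = True

    def __post_init__(self):
        if self.valid and self.sd <= 0:
            raise ValueError("sd must be positive for a valid fit")
        self.goodness = float(min(1.0, max(0.0, self.goodness)))


@dataclass
class AlignmentProportion:
    """Per-section aligned-cell proportions and their mean.

    Sections without any detected cell are excluded from the mean (their
    indices are listed in empty_sections) rather than scored zero: absence
    of cells is not evidence of misalignment.
    """

    reference_angle: float
    tolerance: float
    per_z: np.ndarray
    mean: float
    empty_sections: tuple[int, ...] = ()

    def __post_init__(self):
        if np.any((self.per_z < 0) | (self.per_z > 1)):
            raise ValueError("proportions must lie in [0, 1]")


def cell_orientations(factin_section: np.ndarray,
                      cluster_mask: Optional[np.ndarray] = None,
                      pixel_size_xy: float = 1.0,
                      min_area_um2: float = 20.0,
                      tensor_sigma_um: float = 3.0) -> list[float]:
    """One axial orientation per protruding-cell object, in degrees.

    The F-actin section is Otsu-thresholded, cluster-body pixels
    (cluster_mask True) are excluded, connected components smaller than
    ``min_area_um2`` are discarded, and each remaining component is
    assigned the weighted circular mean of its structure-tensor
    orientation-field angles.
    """
    factin_section = np.asarray(factin_section, dtype=float)
    fg = threshold_image(factin_section, "otsu")
    mask = fg.mask
    if cluster_mask is not None:
        cluster_mask = np.asarray(cluster_mask, dtype=bool)
        if cluster_mask.shape != mask.shape:
            raise ValueError("cluster_mask shape must match the section")
        mask &= ~cluster_mask
    if not mask.any():
        return []
    fld = orientation_field(factin_section, tensor_sigma_um, pixel_size_xy)
    min_px = max(1, int(round(min_area_um2 / pixel_size_xy**2)))
    angles: list[float] = []
    for region in regionprops(label(mask)):
        if region.area < min_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        w = fld.weight[rr, cc]
        if w.sum() <= 0:
            continue
        angles.append(axial_mean(fld.angle[rr, cc], w))
    return angles


def orientation_histogram(angles_deg: Sequence[float],
                          weights: Optional[Sequence[float]] = None,
                          bin_width_deg: float = 2.0) -> OrientationHistogram:
    """Weighted histogram of axial angles on [0, 180)."""
    if 180.0 % bin_width_deg:
        raise ValueError("bin width must divide 180")
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    counts, _ = np.histogram(wrap_axial(angles_deg), bins=edges, weights=weights)
    return OrientationHistogram(bin_edges=edges, counts=counts.astype(float))


def _wrapped_gaussian(theta, amplitude, mean, sd, baseline):
    # shortest signed axial offset, in (-90, 90]
    d = (theta - mean + 90.0) % 180.0 - 90.0
    return amplitude * np.exp(-(d**2) / (2.0 * sd**2)) + baseline


def fit_gaussian(hist: OrientationHistogram) -> GaussianFit:
    """Fit amplitude*exp(-d(theta, mean)^2 / 2 sd^2) + baseline to a
    histogram, with the angular offset wrapped on the 180-deg period.

    Needs at least 5 non-empty bins; otherwise, on non-convergence, or on
    a flat histogram (zero total sum of squares), the fit is flagged
    invalid with goodness 0.
    """
    y = hist.counts
    x = hist.centers
    invalid = GaussianFit(mean=0.0, sd=1.0, amplitude=0.0,
                          baseline=float(y.mean()), goodness=0.0, valid=False)
    if np.count_nonzero(y) < 5:
        return invalid
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return invalid
    p0 = (float(y.max() - y.min()), float(x[np.argmax(y)]),
          20.0, float(y.min()))
    try:
        popt, _ = curve_fit(
            _wrapped_gaussian, x, y, p0=p0,
            bounds=([0.0, -360.0, 1e-3, 0.0],
                    [np.inf, 360.0, 90.0, np.inf]),
            maxfev=20000)
    except RuntimeError:
        return invalid
    amplitude, mean, sd, baseline = popt
    ss_res = float(np.sum((y - _wrapped_gaussian(x, *popt)) ** 2))
    return GaussianFit(mean=float(mean % 180.0), sd=float(sd),
                       amplitude=float(amplitude), baseline=float(baseline),
                       goodness=max(0.0, 1.0 - ss_res / ss_tot))


def aligned_proportion(per_z_angles: Sequence[Sequence[float]],
                       reference_angle: float,
                       tolerance: float = 10.0) -> AlignmentProportion:
    """Fraction of cells aligned with the reference fiber axis, per section.

    A cell counts as aligned when the axial distance between its
    orientation and ``reference_angle`` is <= ``tolerance`` degrees. The
    summary mean averages the per-section proportions over sections that
    contain at least one cell.
    """
    if not 0.0 <= reference_angle < 180.0:
        raise ValueError("reference_angle must lie in [0, 180)")
    per_z, empty = [], []
    for z, angles in enumerate(per_z_angles):
        angles = np.asarray(list(angles), dtype=float)
        if angles.size == 0:
            empty.append(z)
            per_z.append(np.nan)
            continue
        close = axial_distance(angles, reference_angle) <= tolerance
        per_z.append(float(np.mean(close)))
    arr = np.asarray(per_z)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("no section contains a detected cell")
    return AlignmentProportion(
        reference_angle=reference_angle, tolerance=tolerance,
        per_z=np.nan_to_num(arr, nan=0.0), mean=float(valid.mean()),
        empty_sections=tuple(empty))
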