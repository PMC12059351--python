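"""Axial (period-180°) circular statistics.

Fiber and cell orientations are *axial*: a fiber at 10° is the same fiber
at 190°. All statistics therefore operate on doubled angles — the standard
embedding that maps the half-circle [0, 180) onto the full circle — and
halve back at the end. Angles are degrees, counter-clockwise from the +x
image axis, wrapped to [0, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_distance",
    "axial_resultant_length",
    "axial_mean",
    "sample_axial_vonmises",
]


def wrap_axial(angles_deg) -> np.ndarray:
    """Wrap angles (degrees) to the axial range [0, 180)."""
    wrapped = np.asarray(angles_deg, dtype=float) % 180.0
    # a % 180 can round to exactly 180.0 for tiny negative inputs
    return np.where(wrapped >= 180.0, 0.0, wrapped)


def axial_distance(a_deg, b_deg) -> np.ndarray:
    """Smallest angular separation between two axial orientations.

    d(a, b) = min(|a-b| mod 180, 180 - |a-b| mod 180), in [0, 90].
    """
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)

def _doubled_resultant(angles_deg, weights):
    theta2 = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(theta2)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != theta2.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("at least one positive weight is required")
    c = float(np.sum(w * np.cos(theta2))) / wsum
    s = float(np.sum(w * np.sin(theta2))) / wsum
    return c, s


def axial_resultant_length(angles_deg, weights=None) -> float:
    """Weighted mean resultant length of doubled angles, in [0, 1].

    1 means perfect alignment, 0 an exactly balanced (e.g. uniform or
    orthogonal-pair) orientation distribution. This is the alignment index
    used throughout the package.
    """
    c, s = _doubled_resultant(angles_deg, weights)
    return float(min(1.0, np.hypot(c, s)))


def axial_mean(angles_deg, weights=None) -> float:
    """Weighted circular mean orientation on the axial scale, in [0, 180)."""
    c, s = _doubled_resultant(angles_deg, weights)
    return float((np.rad2deg(np.arctan2(s, c)) / 2.0) % 180.0)


def sample_axial_vonmises(mean_deg: float, kappa: float, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw n axial orientations from a von Mises law on doubled angles.

    ``kappa`` is the concentration on the doubled-angle scale; kappa = 0
    reduces to the uniform axial distribution on [0, 180).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0
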