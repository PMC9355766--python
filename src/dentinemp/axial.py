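"""Circular statistics for axial (180°-periodic) orientation data.

Fiber orientations are axial: 10° and 190° are the same direction.  All
helpers here work in degrees on the half-circle [0°, 180°) by doubling the
angles onto the full circle, and report dispersions as root-mean-square
angular deviation from the axial mean, wrapped to (−90°, 90°].  That
deviation is bounded by 90° and approaches 180/sqrt(12) ≈ 51.96° for a
uniform orientation distribution.
"""

from __future__ import annotations

import numpy as np


def wrap_axial_deg(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap axial angles into [0°, 180°)."""
    return np.mod(angles_deg, 180.0)


def wrap_deviation_deg(delta_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap an axial angular difference into (−90°, 90°]."""
    return -np.mod(-np.asarray(delta_deg, dtype=float) + 90.0, 180.0) + 90.0


def axial_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted axial circular mean in [0°, 180°).

    Computed on the doubled angles; raises if the resultant vanishes
    (perfectly balanced orientations have no mean direction).
    """
    a = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    c = float(np.sum(w * np.cos(a)))
    s = float(np.sum(w * np.sin(a)))
    if np.hypot(c, s) < 1e-12 * max(float(np.sum(np.abs(w))), 1e-300):
        raise ValueError("axial mean undefined: balanced orientation distribution")
    return float(np.rad2deg(np.arctan2(s, c)) / 2.0 % 180.0)


def axial_dispersion_deg(angles_deg: np.ndarray,
                         weights: np.ndarray | None = None,
                         mean_deg: float | None = None) -> float:
    """Weighted RMS axial deviation (degrees) from the axial mean.

    Bounded in [0°, 90°]; equals the ordinary standard deviation for
    tightly clustered orientations and ≈51.96° for a uniform distribution.
    """
    a = np.asarray(angles_deg, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if mean_deg is None:
        try:
            mean_deg = axial_mean_deg(a, w)
        except ValueError:
            # balanced distribution: deviations from any axis; use 0° reference
            mean_deg = 0.0
    d = wrap_deviation_deg(a - mean_deg)
    return float(np.sqrt(np.sum(w * np.asarray(d) ** 2) / np.sum(w)))


def axial_distance_deg(a_deg: float, b_deg: float) -> float:
    """Unsigned axial distance between two orientations, in [0°, 90°]."""
    return float(abs(wrap_deviation_deg(a_deg - b_deg)))
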