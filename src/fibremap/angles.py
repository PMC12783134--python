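"""Circular arithmetic helpers for azimuths (period 360°) and orientations (period 180°).

In-plane fibre orientations are axial quantities: a fibre at 10° and one at
190° are the same fibre, so orientations live in [0, 180).  Scattering
azimuths are full-circle quantities in [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap360",
    "wrap180",
    "orientation_difference",
    "orientation_separation",
    "orientation_mean",
]


def wrap360(angle):
    """Wrap an azimuth (degrees) into [0, 360)."""
    return np.mod(angle, 360.0)


def wrap180(angle):
    """Fold an orientation (degrees) into [0, 180)."""
    return np.mod(angle, 180.0)


def orientation_difference(a, b):
    """Signed orientation difference a − b, wrapped to (−90, 90] degrees.

    Orientations are 180°-periodic, so this is the unique minimal signed
    difference; the boundary case of exactly 90° apart is assigned +90.
    """
    return 90.0 - np.mod(90.0 - (np.asarray(a, dtype=float) - b), 180.0)


def orientation_separation(a, b):
    """Unsigned circular separation between two orientations, in [0, 90]."""
    return np.abs(orientation_difference(a, b))


def orientation_mean(angles, weights=None):
    """Weighted circular mean of orientations (degrees in [0, 180)).

    Uses the doubled-angle vector mean, the standard estimator for axial
    data; ill-defined for perfectly balanced perpendicular inputs.
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    doubled = np.deg2rad(2.0 * angles)
    s = np.sum(weights * np.sin(doubled))
    c = np.sum(weights * np.cos(doubled))
    return wrap180(np.rad2deg(np.arctan2(s, c)) / 2.0)
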