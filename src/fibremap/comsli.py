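"""Scattered-light orientation analysis: peaks, pairs, and orientation maps.

The chain per pixel is: azimuthal line profile → circular peak detection
with a prominence filter → pairing of peaks roughly 180° apart → the pair
mid-position gives the in-plane fibre orientation.  Out-of-plane tilt shows
up as a peak-pair separation below 180°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .angles import orientation_mean, orientation_separation, wrap180, wrap360
from .containers import AngularStack, FibreOrientationMap

__all__ = [
    "PeakSet",
    "ComsliParams",
    "average_intensity_map",
    "detect_peaks",
    "pair_peaks",
    "orientations_from_peaks",
    "compute_fom",
    "peak_distance_map",
    "mask_fom",
    "smallest_resolved_crossing",
]

#: Prominence filter threshold: peaks below this fraction of the profile's
#: amplitude (max − min) are discarded as noise.
DEFAULT_PROMINENCE_FRAC = 0.08
#: Peaks are paired when their separation is within 180° ± this tolerance.
DEFAULT_PAIRING_TOL = 35.0
#: Orientations closer than this are merged into one bundle.
DEFAULT_MERGE_TOL = 10.0


@dataclass
class PeakSet:
    """Refined peak azimuths (degrees, ascending in [0, 360)) + prominences."""

    positions: np.ndarray
    prominences: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.prominences = np.atleast_1d(np.asarray(self.prominences, dtype=float))
        if self.positions.shape != self.prominences.shape:
            raise ValueError("positions/prominences length mismatch")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.prominences = self.prominences[order]

    def __len__(self):
        return len(self.positions)


@dataclass
class ComsliParams:
    """Tunable parameters of the scattered-light analysis chain."""

    prominence_frac: float = DEFAULT_PROMINENCE_FRAC
    pairing_tol_deg: float = DEFAULT_PAIRING_TOL
    merge_tol_deg: float = DEFAULT_MERGE_TOL
    refinement: str = "parabolic"  # "parabolic", "centroid" or "none"


def average_intensity_map(stack: AngularStack) -> np.ndarray:
    """Mean intensity over the azimuth axis (used for background masking)."""
    if stack.intensities.shape[2] == 0:
        raise ValueError("empty stack")
    return stack.intensities.mean(axis=2)


def _refine_peak(values, idx, angles, method):
    """Sub-sample peak position from the maximum and its two neighbours.

    ``parabolic`` fits a quadratic through the three samples (vertex of the
    parabola); ``centroid`` takes the intensity-weighted mean azimuth.  Both
    are exact for a peak centred on a sample.
    """
    n = len(values)
    step = 360.0 / n
    wl = values[(idx - 1) % n]
    wc = values[idx]
    wr = values[(idx + 1) % n]
    if method == "none":
        offset = 0.0
    elif method == "parabolic":
        denom = wl - 2.0 * wc + wr
        offset = 0.0 if denom == 0 else 0.5 * step * (wl - wr) / denom
    elif method == "centroid":
        total = wl + wc + wr
        offset = 0.0 if total == 0 else step * (wr - wl) / total
    else:
        raise ValueError(f"unknown refinement method {method!r}")
    offset = float(np.clip(offset, -step / 2.0, step / 2.0))
    return wrap360(angles[idx] + offset)


def detect_peaks(
    values,
    angles=None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    refinement: str = "parabolic",
) -> PeakSet:
    """Circular peak detection on an azimuthal line profile.

    Local maxima are found with wrap-around at 360°; a peak is kept when its
    circular prominence is at least ``prominence_frac`` of the profile's
    amplitude (max − min).  Positions are refined from the maximum and its
    two neighbours.  A constant profile yields an empty peak set.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError("profile must have at least 8 samples")
    if angles is None:
        angles = np.arange(n) * 360.0 / n
    else:
        angles = np.asarray(angles, dtype=float)
        if len(angles) != n:
            raise ValueError("angles/values length mismatch")
    amplitude = values.max() - values.min()
    if amplitude <= 0:
        return PeakSet(np.empty(0), np.empty(0))
    threshold = prominence_frac * amplitude
    # Tiling the profile three times gives every peak of the middle copy its
    # full circular neighbourhood, so scipy's prominence is the circular one.
    tiled = np.concatenate([values, values, values])
    idx, props = find_peaks(tiled, prominence=threshold)
    keep = (idx >= n) & (idx < 2 * n)
    idx = idx[keep] - n
    proms = props["prominences"][keep]
    positions = np.array(
        [_refine_peak(values, i, angles, refinement) for i in idx], dtype=float
    )
    return PeakSet(positions, proms)


def pair_peaks(
    peaks: PeakSet, tolerance_deg: float = DEFAULT_PAIRING_TOL
) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Greedily pair peaks whose separation is within 180° ± tolerance.

    Candidate pairs are taken closest-to-180° first; each peak is used at
    most once.  Returns (pairs, lone) as index lists into the peak set.
    """
    pos = peaks.positions
    n = len(pos)
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            sep = pos[j] - pos[i]
            dev = abs(sep - 180.0)
            if dev <= tolerance_deg:
                candidates.append((dev, i, j))
    candidates.sort()
    used = np.zeros(n, dtype=bool)
    pairs = []
    for _, i, j in candidates:
        if not used[i] and not used[j]:
            pairs.append((i, j))
            used[i] = used[j] = True
    lone = [i for i in range(n) if not used[i]]
    return pairs, lone


def orientations_from_peaks(
    peaks: PeakSet,
    pairs: List[Tuple[int, int]],
    lone: List[int],
    merge_tol_deg: float = DEFAULT_MERGE_TOL,
    max_orientations: int = FibreOrientationMap.MAX_ORIENTATIONS,
):
    """Convert peak pairs and lone peaks into in-plane orientations.

    A pair (p1, p2) with p2 > p1 yields orientation ((p1+p2)/2) mod 180 and
    separation p2 − p1; a lone peak p yields (p + 90) mod 180 with undefined
    separation (the scattering maximum is perpendicular to the fibre).
    Candidates are ranked by prominence; orientations closer than the merge
    tolerance collapse to their circular mean, and at most
    ``max_orientations`` are kept (overflow flagged).

    Returns (orientations, separations, overflow) with orientations sorted
    ascending.
    """
    cands = []  # (prominence, orientation, separation)
    for i, j in pairs:
        p1, p2 = peaks.positions[i], peaks.positions[j]
        ori = wrap180((p1 + p2) / 2.0)
        prom = 0.5 * (peaks.prominences[i] + peaks.prominences[j])
        sep = p2 - p1
        if sep > 180.0:  # circular pair distance, ≤ 180 by definition
            sep = 360.0 - sep
        cands.append([prom, ori, sep])
    for i in lone:
        cands.append([peaks.prominences[i], wrap180(peaks.positions[i] + 90.0), np.nan])
    cands.sort(key=lambda t: -t[0])

    merged = []  # [prominence, orientation, separation]
    for prom, ori, sep in cands:
        hit = None
        for m in merged:
            if orientation_separation(ori, m[1]) < merge_tol_deg:
                hit = m
                break
        if hit is None:
            merged.append([prom, ori, sep])
        else:
            hit[1] = orientation_mean([hit[1], ori], weights=[hit[0], prom])
            if np.isnan(hit[2]):
                hit[2] = sep
            elif not np.isnan(sep):
                hit[2] = 0.5 * (hit[2] + sep)
            hit[0] = max(hit[0], prom)
    overflow = len(merged) > max_orientations
    merged = merged[:max_orientations]
    merged.sort(key=lambda t: t[1])
    orientations = np.array([m[1] for m in merged], dtype=float)
    separations = np.array([m[2] for m in merged], dtype=float)
    return orientations, separations, overflow


def compute_fom(
    stack: AngularStack, params: Optional[ComsliParams] = None
) -> FibreOrientationMap:
    """Per-pixel peak analysis of an angular stack → fibre orientation map."""
    params = params or ComsliParams()
    h, w = stack.shape
    angles = np.asarray(stack.schedule.azimuths_deg, dtype=float)
    cap = FibreOrientationMap.MAX_ORIENTATIONS
    ori = np.full((h, w, cap), np.nan)
    sep = np.full((h, w, cap), np.nan)
    overflow = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            peaks = detect_peaks(
                stack.intensities[r, c],
                angles,
                prominence_frac=params.prominence_frac,
                refinement=params.refinement,
            )
            if len(peaks) == 0:
                continue
            pairs, lone = pair_peaks(peaks, params.pairing_tol_deg)
            o, s, ov = orientations_from_peaks(
                peaks, pairs, lone, params.merge_tol_deg, cap
            )
            ori[r, c, : len(o)] = o
            sep[r, c, : len(s)] = s
            overflow[r, c] = ov
    return FibreOrientationMap(ori, sep, overflow)


def peak_distance_map(fom: FibreOrientationMap) -> np.ndarray:
    """Mean peak-pair separation per pixel, degrees; NaN where no pair.

    Separations below 180° indicate out-of-plane tilted fibres.
    """
    sep = fom.separations
    valid = ~np.isnan(sep)
    n = valid.sum(axis=2)
    total = np.where(valid, sep, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def mask_fom(
    fom: FibreOrientationMap, average_map: np.ndarray, threshold: float
) -> FibreOrientationMap:
    """Remove orientations where the average scattering intensity is low."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    average_map = np.asarray(average_map, dtype=float)
    if average_map.shape != fom.shape:
        raise ValueError("average map shape mismatch")
    out = fom.copy()
    low = average_map < threshold
    out.orientations[low] = np.nan
    out.separations[low] = np.nan
    out.overflow[low] = False
    return out


def smallest_resolved_crossing(
    step_deg: float = 15.0,
    peak_sd: float = 8.0,
    base_delta_deg: float = 0.0,
    max_angle_deg: int = 90,
    tolerance_deg: float = 3.0,
    params: Optional[ComsliParams] = None,
) -> float:
    """Smallest crossing angle resolved into two distinct orientations.

    Sweeps the crossing angle from 1° to ``max_angle_deg`` in 1° steps.  For
    each angle a noise-free azimuthal line profile is generated for two
    equal-amplitude in-plane bundles (the first fixed at ``base_delta_deg``)
    and pushed through the full peak → pair → orientation chain.  An angle
    counts as resolved when exactly two orientations are returned, each
    within ``tolerance_deg`` of its ground truth.  Returns the first such
    angle, or NaN when none resolves.
    """
    from .simulate import make_schedule, profile_for_populations
    from .phantom import FibrePopulation

    params = params or ComsliParams()
    psi = np.array(make_schedule(step_deg).azimuths_deg)
    for chi in range(1, max_angle_deg + 1):
        pops = (
            FibrePopulation(wrap180(base_delta_deg)),
            FibrePopulation(wrap180(base_delta_deg + chi)),
        )
        profile = profile_for_populations(pops, psi, peak_sd=peak_sd)
        peaks = detect_peaks(
            profile, psi, params.prominence_frac, params.refinement
        )
        pairs, lone = pair_peaks(peaks, params.pairing_tol_deg)
        oris, _, _ = orientations_from_peaks(
            peaks, pairs, lone, params.merge_tol_deg
        )
        if len(oris) != 2:
            continue
        truth = np.sort([wrap180(base_delta_deg), wrap180(base_delta_deg + chi)])
        errs = orientation_separation(np.sort(oris), truth)
        if np.all(errs <= tolerance_deg):
            return float(chi)
    return float("nan")
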