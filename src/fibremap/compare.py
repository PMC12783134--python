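"""Registration and pixel-wise comparison of two fibre orientation maps.

The two modalities image the same section at different pixel sizes and in
slightly different frames, so one map is resampled and brought into the
other's frame with a parameterised similarity transform (scale, rotation,
translation — the registration parameters are inputs, not estimated).
Matched pixels are compared orientation-by-orientation; the signed
differences Δφ, wrapped to (−90°, 90°], are summarised by a histogram,
its mode, and its full width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .angles import orientation_difference, wrap180
from .containers import FibreOrientationMap

__all__ = [
    "RigidTransform",
    "OrientationDifferenceMap",
    "ComparisonStats",
    "upscale_fom",
    "apply_transform",
    "orientation_difference",
    "match_and_diff",
    "histogram_stats",
    "full_comparison",
]

EXCLUDE_NONE = 0  # compared
EXCLUDE_EMPTY = 1  # no orientation in either map
EXCLUDE_COUNT = 2  # orientation-count mismatch


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform: isotropic scale, rotation (degrees,
    anticlockwise), then translation (pixels, (dx, dy) with y pointing up).
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        dx, dy = self.translation
        # inverse of p' = s·R·p + t is p = R⁻¹(p' − t)/s
        inv_dx = -(c * dx + s * dy) / self.scale
        inv_dy = -(-s * dx + c * dy) / self.scale
        return RigidTransform(1.0 / self.scale, -self.rotation_deg, (inv_dx, inv_dy))


@dataclass
class OrientationDifferenceMap:
    """Per-pixel signed orientation differences plus exclusion reasons.

    ``differences`` is (H, W, 3) with NaN padding; ``exclusion`` is an
    (H, W) int map of reason codes (0 compared, 1 empty, 2 count mismatch).
    """

    differences: np.ndarray
    exclusion: np.ndarray

    def values(self) -> np.ndarray:
        """All compared Δφ values as a flat array."""
        v = self.differences[self.exclusion == EXCLUDE_NONE]
        return v[~np.isnan(v)]

    @property
    def n_compared(self) -> int:
        return int(np.sum(self.exclusion == EXCLUDE_NONE))

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.exclusion != EXCLUDE_NONE))


@dataclass
class ComparisonStats:
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_deg: float
    fwhm_deg: float
    n_compared: int
    n_excluded: int

    def as_dict(self) -> dict:
        return {
            "mode_deg": float(self.mode_deg),
            "fwhm_deg": float(self.fwhm_deg),
            "n_compared": int(self.n_compared),
            "n_excluded": int(self.n_excluded),
        }


def upscale_fom(
    fom: FibreOrientationMap, source_pixel_size: float, target_pixel_size: float
) -> FibreOrientationMap:
    """Nearest-neighbour resampling to a finer/coarser pixel grid.

    The resampling factor is source/target (e.g. 2.87 µm → 2.37 µm enlarges
    the grid); orientation values are untouched.
    """
    if source_pixel_size <= 0 or target_pixel_size <= 0:
        raise ValueError("pixel sizes must be positive")
    factor = source_pixel_size / target_pixel_size
    h, w = fom.shape
    nh, nw = int(round(h * factor)), int(round(w * factor))
    rows = np.clip((np.arange(nh) / factor).astype(int), 0, h - 1)
    cols = np.clip((np.arange(nw) / factor).astype(int), 0, w - 1)
    return FibreOrientationMap(
        fom.orientations[np.ix_(rows, cols)],
        fom.separations[np.ix_(rows, cols)],
        fom.overflow[np.ix_(rows, cols)],
    )


def apply_transform(fom: FibreOrientationMap, t: RigidTransform) -> FibreOrientationMap:
    """Apply a similarity transform to an orientation map.

    The pixel grid is warped by inverse nearest-neighbour mapping about the
    image centre (rotation anticlockwise in the standard orientation frame,
    i.e. with the image y axis pointing up), and the rotation is then added
    to every orientation value modulo 180°: rotating an orientation image
    must rotate the orientations themselves.  Separations are unchanged.
    """
    h, w = fom.shape
    inv = t.inverse()
    th = np.deg2rad(inv.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # centred coordinates with y up
    x = cc - cx
    y = (cy - rr).astype(float)
    xs = inv.scale * (c * x - s * y) + inv.translation[0]
    ys = inv.scale * (s * x + c * y) + inv.translation[1]
    src_c = np.rint(xs + cx).astype(int)
    src_r = np.rint(cy - ys).astype(int)
    inside = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    src_r = np.clip(src_r, 0, h - 1)
    src_c = np.clip(src_c, 0, w - 1)
    ori = fom.orientations[src_r, src_c]
    sep = fom.separations[src_r, src_c]
    ovf = fom.overflow[src_r, src_c]
    ori[~inside] = np.nan
    sep[~inside] = np.nan
    ovf[~inside] = False
    ori = np.where(np.isnan(ori), np.nan, wrap180(ori + t.rotation_deg))
    return FibreOrientationMap(ori, sep, ovf)


def match_and_diff(
    fom_a: FibreOrientationMap, fom_b: FibreOrientationMap
) -> OrientationDifferenceMap:
    """Pixel-wise signed orientation differences a − b.

    Pixels where either map is empty, or where the orientation counts
    differ, are excluded with a reason code.  With multiple orientations,
    each pixel's orientations are sorted ascending in both maps and
    differenced slot by slot, each difference wrapped to (−90°, 90°].
    """
    if fom_a.shape != fom_b.shape:
        raise ValueError("orientation maps must share a pixel grid")
    h, w = fom_a.shape
    cap = FibreOrientationMap.MAX_ORIENTATIONS
    diffs = np.full((h, w, cap), np.nan)
    excl = np.zeros((h, w), dtype=int)
    na = fom_a.n_orientations()
    nb = fom_b.n_orientations()
    empty = (na == 0) | (nb == 0)
    mismatch = ~empty & (na != nb)
    excl[empty] = EXCLUDE_EMPTY
    excl[mismatch] = EXCLUDE_COUNT
    for r, c in zip(*np.nonzero(excl == EXCLUDE_NONE)):
        a = np.sort(fom_a.pixel(r, c))
        b = np.sort(fom_b.pixel(r, c))
        diffs[r, c, : len(a)] = orientation_difference(a, b)
    return OrientationDifferenceMap(diffs, excl)


def histogram_stats(
    diff: OrientationDifferenceMap, bin_width_deg: float = 1.0
) -> ComparisonStats:
    """Histogram of Δφ over (−90°, 90°] with mode and FWHM.

    The mode is the centre of the highest bin (ties resolved towards 0°);
    the FWHM is the distance between the outermost half-maximum crossings,
    linearly interpolated between bin centres, floored at one bin width.
    """
    values = diff.values()
    if values.size == 0:
        raise ValueError("no compared orientation differences")
    # Bins are centred on multiples of the bin width (0 ± bw/2, ...), so a
    # near-zero distribution reports mode 0° at 1° granularity.
    n_bins = int(round(180.0 / bin_width_deg)) + 1
    edges = -90.0 - bin_width_deg / 2.0 + bin_width_deg * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centres = edges[:-1] + bin_width_deg / 2.0
    top = counts.max()
    tied = np.nonzero(counts == top)[0]
    mode = centres[tied[np.argmin(np.abs(centres[tied]))]]
    half = top / 2.0
    above = np.nonzero(counts >= half)[0]
    i0, i1 = above[0], above[-1]
    if i0 == 0:
        left = centres[0]
    else:
        left = centres[i0 - 1] + bin_width_deg * (half - counts[i0 - 1]) / (
            counts[i0] - counts[i0 - 1]
        )
    if i1 == len(counts) - 1:
        right = centres[-1]
    else:
        right = centres[i1] + bin_width_deg * (counts[i1] - half) / (
            counts[i1] - counts[i1 + 1]
        )
    fwhm = max(right - left, bin_width_deg)
    return ComparisonStats(
        edges, counts, float(mode), float(fwhm), diff.n_compared, diff.n_excluded
    )


def full_comparison(
    comsli_fom: FibreOrientationMap,
    pshg_fom: FibreOrientationMap,
    transform: Optional[RigidTransform] = None,
    comsli_pixel_size: float = 1.0,
    pshg_pixel_size: float = 1.0,
    bin_width_deg: float = 1.0,
    direction: str = "comsli_to_pshg",
):
    """End-to-end comparison: upscale → transform → crop → diff → stats.

    The scattered-light map is first resampled to the pSHG pixel size; the
    similarity transform is then applied to the moving map (the
    scattered-light one by default; ``direction="pshg_to_comsli"`` reverses
    the registration, as needed when the pSHG map is the easier moving
    image).  Both maps are cropped to their common extent before the
    pixel-wise comparison.  Returns (ComparisonStats,
    OrientationDifferenceMap).
    """
    moving = upscale_fom(comsli_fom, comsli_pixel_size, pshg_pixel_size)
    fixed = pshg_fom
    if direction == "pshg_to_comsli":
        moving, fixed = fixed, moving
    elif direction != "comsli_to_pshg":
        raise ValueError(f"unknown registration direction {direction!r}")
    if transform is not None:
        moving = apply_transform(moving, transform)
    h = min(moving.shape[0], fixed.shape[0])
    w = min(moving.shape[1], fixed.shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("orientation maps have no common extent")

    def crop(f):
        return FibreOrientationMap(
            f.orientations[:h, :w], f.separations[:h, :w], f.overflow[:h, :w]
        )

    a, b = crop(moving), crop(fixed)
    if direction == "pshg_to_comsli":
        a, b = b, a  # keep the Δφ convention: ComSLI minus pSHG
    diff = match_and_diff(a, b)
    stats = histogram_stats(diff, bin_width_deg)
    return stats, diff
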