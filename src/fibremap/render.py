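"""Colour rendering of fibre orientation maps.

Orientation is mapped to hue on a cyclic colour wheel (hue 0 at 0°,
increasing anticlockwise, wrapping at 180°) at full saturation and value.
Each source pixel becomes a 2×2 sub-pixel block: one orientation fills all
four sub-pixels, two orientations occupy diagonal pairs (the lower
orientation on the main diagonal), and three orientations take three
sub-pixels with the fourth left black.  Empty pixels are black.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .containers import FibreOrientationMap

__all__ = ["orientation_to_rgb", "render_fom"]


def orientation_to_rgb(orientation_deg) -> np.ndarray:
    """Map orientations (degrees, [0, 180)) to RGB colours in [0, 1]."""
    ori = np.asarray(orientation_deg, dtype=float)
    hsv = np.stack(
        [np.mod(ori, 180.0) / 180.0, np.ones_like(ori), np.ones_like(ori)], axis=-1
    )
    return hsv_to_rgb(hsv)


# Sub-pixel (row, col) slots within the 2×2 block, by orientation count.
_SLOTS = {
    1: [[(0, 0), (0, 1), (1, 0), (1, 1)]],
    2: [[(0, 0), (1, 1)], [(0, 1), (1, 0)]],
    3: [[(0, 0)], [(0, 1)], [(1, 0)]],  # (1, 1) stays black
}


def render_fom(fom: FibreOrientationMap) -> np.ndarray:
    """Render an orientation map as a (2H, 2W, 3) float RGB image."""
    h, w = fom.shape
    out = np.zeros((2 * h, 2 * w, 3))
    for r in range(h):
        for c in range(w):
            oris = np.sort(fom.pixel(r, c))
            if len(oris) == 0:
                continue
            colours = orientation_to_rgb(oris)
            for colour, slots in zip(colours, _SLOTS[len(oris)]):
                for dr, dc in slots:
                    out[2 * r + dr, 2 * c + dc] = colour
    return out
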