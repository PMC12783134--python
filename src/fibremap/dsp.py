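"""Double-Stokes polarimetry: in-plane fibre orientation from a 6×6 stack.

Six incident polarisation states (HLP, VLP, ±45°, RCP, LCP) are each
analysed through the same six states.  Per incident state the outgoing
Stokes components are assembled from the analyser intensities, and the
effective in-plane orientation δ follows from the linear-dichroism-like
ratio A, the chiral ratio σ, and tan(2δ) ≈ [(A−1)−(A+1)σ]/[(A+1)+(A−1)σ],
with the branch of 2δ fixed by the signs of the SHG_LD and SHG_45
anisotropy parameters.  All quantities are ratios of intensities, so the
result is invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter

from .angles import wrap180
from .containers import DSP_STATES, DspResult, PolarimetricStack, StokesResponses

__all__ = [
    "preprocess",
    "assemble_stokes",
    "compute_A",
    "compute_sigma",
    "compute_shg_ld",
    "compute_shg_45",
    "compute_delta",
    "dsp_pipeline",
]

#: Pixels whose mean intensity over the stack is below this are discarded.
DEFAULT_COUNT_THRESHOLD = 5.0
DEFAULT_MEDIAN_WINDOW = 3
#: Ratio denominators below this fraction of the local s0 scale are masked.
DENOM_TOL = 1e-9


def preprocess(
    stack: PolarimetricStack,
    count_threshold: float = DEFAULT_COUNT_THRESHOLD,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
) -> Tuple[PolarimetricStack, np.ndarray]:
    """Low-signal masking and per-image median filtering.

    The validity mask keeps pixels whose mean intensity across all stack
    images is at least ``count_threshold`` counts; every image is then
    filtered with a square median window (reflect edge handling).
    """
    if median_window % 2 != 1 or median_window < 1:
        raise ValueError("median window must be odd and positive")
    mask = stack.data.mean(axis=(0, 1)) >= count_threshold
    filtered = np.empty_like(stack.data)
    for i in range(stack.data.shape[0]):
        for j in range(stack.data.shape[1]):
            filtered[i, j] = median_filter(
                stack.data[i, j], size=median_window, mode="reflect"
            )
    out = PolarimetricStack(filtered, stack.in_states, stack.out_states, stack.kind)
    return out, mask


def assemble_stokes(stack: PolarimetricStack) -> StokesResponses:
    """Outgoing Stokes components per incident state from analyser images.

    s0 = I_HLP + I_VLP, s1 = I_HLP − I_VLP, s2 = I_+45 − I_−45,
    s3 = I_RCP − I_LCP (analyser-side intensities).
    """
    missing = [s for s in DSP_STATES if s not in list(stack.out_states)]
    if missing:
        raise ValueError(f"stack is missing analyser state(s): {missing}")
    n_in = len(stack.in_states)
    h, w = stack.shape
    s = np.empty((n_in, 4, h, w))
    for i in range(n_in):
        img = {lab: stack.data[i, list(stack.out_states).index(lab)] for lab in DSP_STATES}
        s[i, 0] = img["HLP"] + img["VLP"]
        s[i, 1] = img["HLP"] - img["VLP"]
        s[i, 2] = img["+45"] - img["-45"]
        s[i, 3] = img["RCP"] - img["LCP"]
    return StokesResponses(s, list(stack.in_states))


def _require_incident(stokes: StokesResponses, labels):
    missing = [s for s in labels if s not in list(stokes.in_states)]
    if missing:
        raise ValueError(f"missing incident state(s): {missing}")


def _s0_scale(stokes: StokesResponses) -> np.ndarray:
    """Per-pixel intensity scale used for denominator tolerance tests."""
    scale = np.mean(
        [stokes.component(s, 0) for s in ("HLP", "VLP", "+45", "-45")], axis=0
    )
    return np.maximum(np.abs(scale), np.finfo(float).tiny)


def _safe_ratio(num, den, scale):
    """num/den with pixels masked (NaN) where |den| is negligible."""
    bad = np.abs(den) < DENOM_TOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / np.where(bad, 1.0, den)
    return np.where(bad, np.nan, out)


def compute_A(stokes: StokesResponses) -> np.ndarray:
    """Linear anisotropy ratio A from the four linear-state s0 responses."""
    _require_incident(stokes, ("HLP", "VLP", "+45", "-45"))
    d1 = stokes.component("HLP", 0) - stokes.component("VLP", 0)
    d2 = stokes.component("+45", 0) - stokes.component("-45", 0)
    return _safe_ratio(d1 - d2, d1 + d2, _s0_scale(stokes))


def compute_sigma(stokes: StokesResponses) -> np.ndarray:
    """Chiral ratio σ = 2C·cosΔ/(R+1) from linear-state s1/s2 responses."""
    _require_incident(stokes, ("HLP", "VLP", "+45", "-45"))
    num = (
        stokes.component("HLP", 2)
        - stokes.component("VLP", 2)
        - stokes.component("+45", 1)
        + stokes.component("-45", 1)
    )
    den = (
        stokes.component("HLP", 1)
        - stokes.component("VLP", 1)
        + stokes.component("+45", 2)
        - stokes.component("-45", 2)
    )
    return _safe_ratio(num / 3.0, den, _s0_scale(stokes))


def compute_shg_ld(stokes: StokesResponses) -> np.ndarray:
    """Linear-dichroism anisotropy of s0 between the HLP/VLP states."""
    _require_incident(stokes, ("HLP", "VLP"))
    a = stokes.component("HLP", 0)
    b = stokes.component("VLP", 0)
    return _safe_ratio(2.0 * (a - b), a + b, _s0_scale(stokes))


def compute_shg_45(stokes: StokesResponses) -> np.ndarray:
    """Diagonal anisotropy of s0 between the ±45° states."""
    _require_incident(stokes, ("+45", "-45"))
    a = stokes.component("+45", 0)
    b = stokes.component("-45", 0)
    return _safe_ratio(2.0 * (a - b), a + b, _s0_scale(stokes))


def compute_delta(A, sigma, shg_ld=None, shg_45=None) -> np.ndarray:
    """Effective in-plane fibre orientation δ (degrees, [0, 180)).

    The orientation formula fixes only the magnitude ratio |tan(2δ)|
    unambiguously — the signs of its numerator and denominator depend on
    state-labelling conventions that the Stokes analysis alone cannot pin
    down.  The quadrant of 2δ is therefore taken from the signs of
    (SHG_LD, SHG_45), which behave as (cos 2δ, sin 2δ) up to a common
    positive factor: 2δ = atan2(|num|·sign(SHG_45), |den|·sign(SHG_LD)).
    Without those parameters the raw arctangent branch is used.
    """
    A = np.asarray(A, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    num = (A - 1.0) - (A + 1.0) * sigma
    den = (A + 1.0) + (A - 1.0) * sigma
    if shg_ld is not None and shg_45 is not None:
        num = np.abs(num) * np.sign(np.asarray(shg_45, dtype=float))
        den = np.abs(den) * np.sign(np.asarray(shg_ld, dtype=float))
    two_delta = np.arctan2(num, den)
    delta = wrap180(np.rad2deg(two_delta) / 2.0)
    return np.where(np.isnan(A) | np.isnan(sigma), np.nan, delta)


def dsp_pipeline(
    stack: PolarimetricStack,
    count_threshold: float = DEFAULT_COUNT_THRESHOLD,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
) -> DspResult:
    """Full double-Stokes chain: threshold → median → Stokes → δ maps."""
    filtered, mask = preprocess(stack, count_threshold, median_window)
    stokes = assemble_stokes(filtered)
    A = compute_A(stokes)
    sigma = compute_sigma(stokes)
    shg_ld = compute_shg_ld(stokes)
    shg_45 = compute_shg_45(stokes)
    delta = compute_delta(A, sigma, shg_ld, shg_45)
    mask = mask & ~np.isnan(delta)
    delta = np.where(mask, delta, np.nan)
    return DspResult(delta, A, sigma, shg_ld, shg_45, mask)
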