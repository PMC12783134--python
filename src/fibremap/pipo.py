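"""PIPO analysis: per-pixel nonlinear fit of the two-fibre intensity model.

The polarisation-in/polarisation-out SHG intensity for up to two crossing
fibre populations at orientations δ1, δ2 with shared susceptibility ratios
R and C is a sum of modulus-squared field terms

    I(θ, φ) ∝ |sin(φ−δi)·sin 2(θ−δi) + cos(φ−δi)·sin²(θ−δi)
               + R·cos(φ−δi)·cos²(θ−δi) + 2C·cos(θ−δi)·sin(θ−φ)|²,

summed over i, where θ and φ are the incident and analysed linear
polarisation angles.  Fitting this model on an 8×8 grid of states recovers
the discrete orientations of crossing fibres, unlike the double-Stokes
method which only yields their effective average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .angles import orientation_separation, wrap180
from .containers import FibreOrientationMap, PolarimetricStack
from .dsp import preprocess

__all__ = [
    "PipoParams",
    "PipoFitResult",
    "PipoFitConfig",
    "pipo_field_term",
    "pipo_intensity",
    "fit_pipo_pixel",
    "fit_pipo_image",
]


def pipo_field_term(theta_rad, phi_rad, delta_rad, R, C):
    """Single-fibre SHG field amplitude for incident θ and analyser φ."""
    a = theta_rad - delta_rad
    b = phi_rad - delta_rad
    return (
        np.sin(b) * np.sin(2.0 * a)
        + np.cos(b) * np.sin(a) ** 2
        + R * np.cos(b) * np.cos(a) ** 2
        + 2.0 * C * np.cos(a) * np.sin(theta_rad - phi_rad)
    )


@dataclass(frozen=True)
class PipoParams:
    """Parameters of the (one- or two-fibre) PIPO intensity model.

    delta1_deg ≤ delta2_deg after canonicalisation; R and C are shared by
    both fibres; amplitude is an overall intensity scale.
    """

    delta1_deg: float
    delta2_deg: float
    R: float = 2.0
    C: float = 0.0
    amplitude: float = 1.0

    def canonical(self) -> "PipoParams":
        d1 = wrap180(self.delta1_deg)
        d2 = wrap180(self.delta2_deg)
        if d1 > d2:
            d1, d2 = d2, d1
        return PipoParams(d1, d2, self.R, self.C, self.amplitude)


@dataclass
class PipoFitResult:
    params: PipoParams
    residual: float
    n_orientations: int
    converged: bool

    def orientations(self) -> np.ndarray:
        if self.n_orientations == 1:
            return np.array([self.params.delta1_deg])
        return np.array([self.params.delta1_deg, self.params.delta2_deg])


@dataclass
class PipoFitConfig:
    """Fit configuration: bounds, multi-start grid, model-selection rule."""

    r_bounds: tuple = (0.5, 4.0)
    c_bounds: tuple = (-1.0, 1.0)
    grid_step_deg: float = 15.0
    n_refine_starts: int = 3
    #: Prefer the two-fibre model only when it cuts the residual by at
    #: least this factor and the fitted orientations are genuinely apart.
    improvement_factor: float = 0.2
    separation_floor_deg: float = 10.0
    cost_tol: float = 1e-10
    #: Residuals below this fraction of the signal energy count as exact.
    residual_floor: float = 1e-12


def pipo_intensity(theta_deg, phi_deg, params: PipoParams, single: bool = False):
    """Evaluate the PIPO intensity model at incident θ / analyser φ degrees.

    With ``single`` the second fibre term is dropped.  Broadcasts over
    array-valued angles.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    out = pipo_field_term(theta, phi, np.deg2rad(params.delta1_deg), params.R, params.C) ** 2
    if not single:
        out = out + pipo_field_term(
            theta, phi, np.deg2rad(params.delta2_deg), params.R, params.C
        ) ** 2
    return params.amplitude * out


def _model_matrix(theta, phi, deltas, R, C):
    """Stack of squared field terms, one row set per candidate δ."""
    return pipo_field_term(theta[None, :], phi[None, :], deltas[:, None], R, C) ** 2


def _coarse_starts(theta, phi, y, config, single):
    """Rank coarse-grid (δ1[, δ2]) starts by profiled-amplitude residual."""
    grid = np.deg2rad(np.arange(0.0, 180.0, config.grid_step_deg))
    terms = _model_matrix(theta, phi, grid, 2.0, 0.0)  # (G, M)
    if single:
        models = terms
        combos = [(i,) for i in range(len(grid))]
    else:
        combos = list(combinations(range(len(grid)), 2))
        models = np.stack([terms[i] + terms[j] for i, j in combos])
    mm = np.einsum("gm,gm->g", models, models)
    my = models @ y
    amp = np.where(mm > 0, my / np.where(mm > 0, mm, 1.0), 0.0)
    amp = np.clip(amp, 0.0, None)
    costs = np.sum((y[None, :] - amp[:, None] * models) ** 2, axis=1)
    order = np.argsort(costs)
    starts = []
    for g in order[: config.n_refine_starts]:
        ds = [np.rad2deg(grid[k]) for k in combos[g]]
        starts.append((ds, max(amp[g], 1e-12 * max(y.max(), 1.0))))
    return starts


def _refine(theta_deg, phi_deg, y, start_deltas, start_amp, config, single):
    lo_r, hi_r = config.r_bounds
    lo_c, hi_c = config.c_bounds
    theta = np.asarray(theta_deg, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)

    def residuals(x):
        if single:
            amp, d1, R, C = x
            p = PipoParams(d1, d1, R, C, amp)
        else:
            amp, d1, d2, R, C = x
            p = PipoParams(d1, d2, R, C, amp)
        return pipo_intensity(theta, phi, p, single=single) - y

    if single:
        x0 = [start_amp, start_deltas[0], 2.0, 0.0]
        lb = [0.0, -360.0, lo_r, lo_c]
        ub = [np.inf, 720.0, hi_r, hi_c]
    else:
        x0 = [start_amp, start_deltas[0], start_deltas[1], 2.0, 0.0]
        lb = [0.0, -360.0, -360.0, lo_r, lo_c]
        ub = [np.inf, 720.0, 720.0, hi_r, hi_c]
    sol = least_squares(
        residuals, x0, bounds=(lb, ub), ftol=config.cost_tol, xtol=1e-12, gtol=1e-12
    )
    cost = 2.0 * sol.cost  # sum of squared errors
    if single:
        amp, d1, R, C = sol.x
        params = PipoParams(wrap180(d1), wrap180(d1), R, C, amp)
    else:
        amp, d1, d2, R, C = sol.x
        params = PipoParams(d1, d2, R, C, amp).canonical()
    return params, cost, sol.success


def fit_pipo_pixel(
    measurements: np.ndarray,
    theta_deg: np.ndarray,
    phi_deg: np.ndarray,
    config: Optional[PipoFitConfig] = None,
) -> PipoFitResult:
    """Fit the PIPO model to one pixel's (θ, φ) intensity measurements.

    ``measurements`` is flattened over the state grid alongside
    ``theta_deg``/``phi_deg``.  Both the single- and two-fibre models are
    fitted with multi-start bounded least squares; the two-fibre model is
    selected only when it improves the residual by the configured factor
    and its orientations are separated by more than the floor.
    """
    config = config or PipoFitConfig()
    y = np.asarray(measurements, dtype=float).ravel()
    theta = np.asarray(theta_deg, dtype=float).ravel()
    phi = np.asarray(phi_deg, dtype=float).ravel()
    if y.size < 16:
        raise ValueError("need at least 16 measurements for a PIPO fit")
    if not np.any(y > 0):
        return PipoFitResult(PipoParams(0.0, 0.0, 2.0, 0.0, 0.0), np.inf, 1, False)

    theta_r, phi_r = np.deg2rad(theta), np.deg2rad(phi)
    best = {}
    for single in (True, False):
        best_params, best_cost, best_ok = None, np.inf, False
        for start_deltas, start_amp in _coarse_starts(
            theta_r, phi_r, y, config, single
        ):
            params, cost, ok = _refine(
                theta, phi, y, start_deltas, start_amp, config, single
            )
            if cost < best_cost:
                best_params, best_cost, best_ok = params, cost, ok
        best[single] = (best_params, best_cost, best_ok)

    p1, c1, ok1 = best[True]
    p2, c2, ok2 = best[False]
    energy = float(np.sum(y**2))
    sep = orientation_separation(p2.delta1_deg, p2.delta2_deg)
    use_double = (
        c1 > config.residual_floor * energy
        and c2 < (1.0 - config.improvement_factor) * c1
        and sep > config.separation_floor_deg
    )
    if use_double:
        return PipoFitResult(p2, c2, 2, ok2)
    return PipoFitResult(p1, c1, 1, ok1)


def fit_pipo_image(
    stack: PolarimetricStack,
    config: Optional[PipoFitConfig] = None,
    count_threshold: float = 5.0,
    median_window: int = 3,
):
    """Per-pixel PIPO fits over a validity mask.

    Applies the same preprocessing as the double-Stokes chain (count
    threshold + median filter), then fits every valid pixel.  Returns a
    dict of parameter maps (delta1, delta2, R, C, amplitude, residual,
    n_orientations, mask) and a :class:`FibreOrientationMap` carrying one
    or two orientations per pixel.
    """
    if stack.kind != "pipo":
        raise ValueError("fit_pipo_image expects a PIPO-type stack")
    config = config or PipoFitConfig()
    filtered, mask = preprocess(stack, count_threshold, median_window)
    theta = np.asarray(filtered.in_states, dtype=float)
    phi = np.asarray(filtered.out_states, dtype=float)
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    h, w = stack.shape
    maps = {
        k: np.full((h, w), np.nan)
        for k in ("delta1", "delta2", "R", "C", "amplitude", "residual")
    }
    n_ori = np.zeros((h, w), dtype=int)
    cap = FibreOrientationMap.MAX_ORIENTATIONS
    ori = np.full((h, w, cap), np.nan)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            res = fit_pipo_pixel(filtered.data[:, :, r, c], tg, pg, config)
            if not res.converged:
                mask[r, c] = False
                continue
            p = res.params
            maps["delta1"][r, c] = p.delta1_deg
            maps["delta2"][r, c] = p.delta2_deg
            maps["R"][r, c] = p.R
            maps["C"][r, c] = p.C
            maps["amplitude"][r, c] = p.amplitude
            maps["residual"][r, c] = res.residual
            n_ori[r, c] = res.n_orientations
            o = res.orientations()
            ori[r, c, : len(o)] = np.sort(o)
    maps["n_orientations"] = n_ori
    maps["mask"] = mask
    return maps, FibreOrientationMap(ori)
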