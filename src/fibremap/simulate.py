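"""Forward simulation of both acquisition modalities from a fibre phantom.

Scattered-light stacks are built from the perpendicular-scattering rule:
each fibre bundle contributes a pair of wrapped-Gaussian azimuthal peaks
centred 90° either side of the fibre axis, i.e. at δ+90° and δ+270°.
Out-of-plane tilt pulls the pair together: the separation is modelled as
180° − k·α with a configurable linear slope k.

Polarimetric SHG stacks are built at field level from the second-order
susceptibility tensor in the fibre frame (χ_zzz = R, χ_zxx = χ_xxz = 1,
chiral element Cmag·e^{iΔ}·sin α), rotated per population into the
laboratory frame; populations add incoherently (intensities sum).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import DSP_STATES, AngularSchedule, AngularStack, PolarimetricStack
from .phantom import FibreGroundTruth, SusceptibilityParams

__all__ = [
    "make_schedule",
    "simulate_comsli_stack",
    "simulate_dsp_stack",
    "simulate_pipo_stack",
    "pipo_state_angles",
]

#: Default width (standard deviation, degrees) of a scattering peak.
DEFAULT_PEAK_SD = 8.0
#: Default slope of the tilt → peak-separation mapping, degrees per degree.
DEFAULT_TILT_SLOPE = 0.5
#: Default constant background, as a fraction of a unit-amplitude peak.
DEFAULT_BACKGROUND = 0.05

# Frame conventions for the polarimetric field model.  Orientations are
# measured anticlockwise from horizontal; the perpendicular fibre-frame axis
# and the chiral-term sign are fixed so that the double-Stokes equations
# recover +δ and σ = +2C·cosΔ/(R+1) (see docs/methods.md).
_PERP_SIGN = 1.0
_CHIRAL_SIGN = -1.0

# Jones vectors of the six polarisation states, laboratory frame (x, y).
_JONES = {
    "HLP": np.array([1.0, 0.0], dtype=complex),
    "VLP": np.array([0.0, 1.0], dtype=complex),
    "+45": np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0),
    "-45": np.array([1.0, -1.0], dtype=complex) / np.sqrt(2.0),
    "RCP": np.array([1.0, -1.0j], dtype=complex) / np.sqrt(2.0),
    "LCP": np.array([1.0, 1.0j], dtype=complex) / np.sqrt(2.0),
}


def make_schedule(step_deg: float, polar_deg: float = 45.0) -> AngularSchedule:
    """Uniform full-circle azimuth schedule starting at 0°.

    ``step_deg`` must divide 360; a 15° step gives the standard 24-image
    ring measurement.
    """
    n = 360.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step_deg}° does not divide 360°")
    n = int(round(n))
    return AngularSchedule(tuple(i * step_deg for i in range(n)), polar_deg)


def _wrapped_gaussian(psi_deg, centre_deg, sd_deg):
    """Wrapped-Gaussian bump on the circle, unit height at the centre."""
    d = np.mod(np.asarray(psi_deg, dtype=float) - centre_deg + 180.0, 360.0) - 180.0
    return np.exp(-0.5 * (d / sd_deg) ** 2)


def profile_for_populations(
    populations,
    psi_deg,
    peak_sd: float = DEFAULT_PEAK_SD,
    tilt_slope: float = DEFAULT_TILT_SLOPE,
    background: float = DEFAULT_BACKGROUND,
):
    """Noise-free azimuthal line profile for one pixel's fibre populations.

    Each population contributes a peak pair centred on δ+180° with
    separation 180° − tilt_slope·α, so an in-plane fibre peaks exactly at
    δ+90° and δ+270°, and the pair mid-position always recovers δ.
    """
    psi = np.asarray(psi_deg, dtype=float)
    out = np.full(psi.shape, float(background))
    for pop in populations:
        sep = 180.0 - tilt_slope * pop.alpha_deg
        mid = pop.delta_deg + 180.0
        for centre in (mid - sep / 2.0, mid + sep / 2.0):
            out = out + pop.amplitude * _wrapped_gaussian(psi, centre, peak_sd)
    return out


def _apply_noise(data, noise, rng):
    if noise is None:
        return data
    kind = noise.get("kind")
    if kind == "gaussian":
        return np.clip(data + rng.normal(0.0, noise["sigma"], size=data.shape), 0.0, None)
    if kind == "poisson":
        photons = noise.get("photons", 1000.0)
        return rng.poisson(np.clip(data, 0.0, None) * photons) / photons
    raise ValueError(f"unknown noise kind {kind!r}")


def simulate_comsli_stack(
    gt: FibreGroundTruth,
    schedule: AngularSchedule,
    peak_sd: float = DEFAULT_PEAK_SD,
    tilt_slope: float = DEFAULT_TILT_SLOPE,
    background: float = DEFAULT_BACKGROUND,
    noise: Optional[dict] = None,
    seed: Optional[int] = None,
) -> AngularStack:
    """Forward-simulate a scattered-light angular stack for a phantom.

    noise : None, {"kind": "gaussian", "sigma": s} (additive, intensity
        units) or {"kind": "poisson", "photons": n} (shot noise at n photons
        per unit intensity).  Applied after the clean profile, seeded.
    """
    if peak_sd <= 0:
        raise ValueError("peak_sd must be positive")
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    psi = np.asarray(schedule.azimuths_deg, dtype=float)
    h, w = gt.shape
    data = np.empty((h, w, len(psi)))
    for r, c, pops in gt.iter_pixels():
        data[r, c] = profile_for_populations(
            pops, psi, peak_sd=peak_sd, tilt_slope=tilt_slope, background=background
        )
    rng = np.random.default_rng(seed)
    data = _apply_noise(data, noise, rng)
    return AngularStack(data, schedule)


def _shg_jones_field(e_lab, delta_rad, R, chiral):
    """Second-harmonic Jones fields radiated by one fibre population.

    e_lab : incident Jones vector (..., 2), laboratory frame.
    chiral: complex effective chiral ratio (already includes sin α).
    Returns (achiral, chiral) outgoing Jones fields (..., 2), laboratory
    frame, kept separate so the detected intensity can be linearised in the
    chiral ratio (see :func:`simulate_dsp_stack`).
    """
    c, s = np.cos(delta_rad), np.sin(delta_rad)
    ex, ey = e_lab[..., 0], e_lab[..., 1]
    e_par = ex * c + ey * s
    e_perp = _PERP_SIGN * (-ex * s + ey * c)
    ch = _CHIRAL_SIGN * chiral
    pa_par = R * e_par**2 + e_perp**2
    pa_perp = 2.0 * e_par * e_perp
    pc_par = 2.0 * ch * e_par * e_perp
    pc_perp = -2.0 * ch * e_par**2
    achiral = np.stack(
        [pa_par * c - _PERP_SIGN * pa_perp * s, pa_par * s + _PERP_SIGN * pa_perp * c],
        axis=-1,
    )
    chiral_f = np.stack(
        [pc_par * c - _PERP_SIGN * pc_perp * s, pc_par * s + _PERP_SIGN * pc_perp * c],
        axis=-1,
    )
    return achiral, chiral_f


def simulate_dsp_stack(
    gt: FibreGroundTruth,
    params: Optional[SusceptibilityParams] = None,
    scale: float = 1000.0,
    noise: Optional[dict] = None,
    seed: Optional[int] = None,
) -> PolarimetricStack:
    """Forward-simulate the 6×6-state double-Stokes polarimetric stack.

    For every incident state the SHG Jones field of each population is
    computed in the fibre frame, rotated back to the laboratory frame, and
    analysed through the six analyser states; population intensities add
    incoherently, weighted by the population amplitude.  Background pixels
    (no populations) emit nothing.

    The detected intensity is linearised in the chiral ratio,
    I = |P_achiral|² + 2·Re(P_achiral*·P_chiral): off resonance the chiral
    ratio is small, and to this order the Stokes chiral relation
    σ = 2C·cosΔ/(R+1) holds exactly.
    """
    params = params or gt.susceptibility
    h, w = gt.shape
    data = np.zeros((len(DSP_STATES), len(DSP_STATES), h, w))
    analysers = np.stack([_JONES[s] for s in DSP_STATES])  # (6, 2)
    for r, c, pops in gt.iter_pixels():
        for pop in pops:
            delta = np.deg2rad(pop.delta_deg)
            chiral = (
                params.Cmag
                * np.exp(1j * params.delta_phase)
                * np.sin(np.deg2rad(pop.alpha_deg))
            )
            for i, in_state in enumerate(DSP_STATES):
                pa, pc = _shg_jones_field(_JONES[in_state], delta, params.R, chiral)
                amp_a = analysers.conj() @ pa  # (6,)
                amp_c = analysers.conj() @ pc
                intensity = np.abs(amp_a) ** 2 + 2.0 * np.real(
                    np.conj(amp_a) * amp_c
                )
                data[i, :, r, c] += pop.amplitude * np.clip(intensity, 0.0, None)
    data *= scale
    rng = np.random.default_rng(seed)
    data = _apply_noise(data, noise, rng)
    return PolarimetricStack(data, list(DSP_STATES), list(DSP_STATES), kind="dsp")


def pipo_state_angles(n_states: int) -> np.ndarray:
    """Equally spaced linear polariser angles covering [0, 180), degrees."""
    if n_states < 4:
        raise ValueError("need at least 4 linear polarisation states")
    return np.arange(n_states) * 180.0 / n_states


def simulate_pipo_stack(
    gt: FibreGroundTruth,
    params: Optional[SusceptibilityParams] = None,
    n_states: int = 8,
    scale: float = 1000.0,
    noise: Optional[dict] = None,
    seed: Optional[int] = None,
) -> PolarimetricStack:
    """Forward-simulate a PIPO stack on equally spaced linear state grids.

    Evaluates the two-fibre polarisation-in/polarisation-out intensity model
    directly per population (each population contributes one modulus-squared
    term, weighted by its amplitude), with effective real chiral ratio
    C = Cmag·sin α.
    """
    from .pipo import pipo_field_term  # local import to avoid a cycle

    params = params or gt.susceptibility
    angles = pipo_state_angles(n_states)
    theta = np.deg2rad(angles)[:, None]  # incident
    phi = np.deg2rad(angles)[None, :]  # analyser
    h, w = gt.shape
    data = np.zeros((n_states, n_states, h, w))
    for r, c, pops in gt.iter_pixels():
        for pop in pops:
            ceff = params.Cmag * np.sin(np.deg2rad(pop.alpha_deg))
            term = pipo_field_term(theta, phi, np.deg2rad(pop.delta_deg), params.R, ceff)
            data[:, :, r, c] += pop.amplitude * term**2
    data *= scale
    rng = np.random.default_rng(seed)
    data = _apply_noise(data, noise, rng)
    return PolarimetricStack(data, list(angles), list(angles), kind="pipo")
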