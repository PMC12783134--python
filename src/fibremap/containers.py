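"""Shared in-memory containers for acquisition stacks and orientation maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AngularSchedule",
    "AngularStack",
    "PolarimetricStack",
    "StokesResponses",
    "FibreOrientationMap",
    "DspResult",
    "DSP_STATES",
]

#: Polarisation state labels used by the double-Stokes scheme, in acquisition
#: order: four linear states then right/left circular.
DSP_STATES = ("HLP", "VLP", "+45", "-45", "RCP", "LCP")


@dataclass(frozen=True)
class AngularSchedule:
    """Azimuthal illumination schedule for a scattered-light measurement.

    Parameters
    ----------
    azimuths_deg
        Strictly increasing azimuth angles in [0, 360).
    polar_deg
        Nominal polar illumination angle (the ring's inclination), degrees.
    """

    azimuths_deg: tuple
    polar_deg: float = 45.0

    def __post_init__(self):
        az = tuple(float(a) for a in self.azimuths_deg)
        if len(az) == 0:
            raise ValueError("schedule must contain at least one azimuth")
        if any(b <= a for a, b in zip(az, az[1:])):
            raise ValueError("azimuths must be strictly increasing")
        if az[0] < 0 or az[-1] >= 360.0:
            raise ValueError("azimuths must lie in [0, 360)")
        object.__setattr__(self, "azimuths_deg", az)

    def __len__(self):
        return len(self.azimuths_deg)

    @property
    def step_deg(self) -> float:
        """Angular step, valid for uniformly spaced schedules."""
        return 360.0 / len(self.azimuths_deg)


@dataclass
class AngularStack:
    """H×W×N stack of scattered-light intensities, one page per azimuth."""

    intensities: np.ndarray
    schedule: AngularSchedule

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be H×W×N")
        if self.intensities.shape[2] != len(self.schedule):
            raise ValueError(
                f"stack has {self.intensities.shape[2]} pages but the schedule "
                f"lists {len(self.schedule)} azimuths"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self):
        return self.intensities.shape[:2]


@dataclass
class PolarimetricStack:
    """SHG intensities indexed by (incident state, analyser state).

    ``data`` has shape (n_in, n_out, H, W).  For the double-Stokes scheme the
    labels are the six state names in :data:`DSP_STATES`; for PIPO they are
    linear polariser angles in degrees.
    """

    data: np.ndarray
    in_states: Sequence
    out_states: Sequence
    kind: str = "dsp"  # "dsp" or "pipo"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (n_in, n_out, H, W)")
        if self.data.shape[0] != len(self.in_states):
            raise ValueError("in_states length mismatch")
        if self.data.shape[1] != len(self.out_states):
            raise ValueError("out_states length mismatch")
        if self.kind not in ("dsp", "pipo"):
            raise ValueError("kind must be 'dsp' or 'pipo'")

    @property
    def shape(self):
        return self.data.shape[2:]

    def image(self, in_state, out_state) -> np.ndarray:
        """Return the H×W image for one (incident, analyser) state pair."""
        try:
            i = list(self.in_states).index(in_state)
        except ValueError:
            raise KeyError(f"incident state {in_state!r} not present") from None
        try:
            j = list(self.out_states).index(out_state)
        except ValueError:
            raise KeyError(f"analyser state {out_state!r} not present") from None
        return self.data[i, j]


@dataclass
class StokesResponses:
    """Outgoing Stokes components s0..s3 per pixel and incident state.

    ``s`` has shape (n_in, 4, H, W); superscript = incident state label,
    subscript = Stokes component index.
    """

    s: np.ndarray
    in_states: Sequence

    def component(self, in_state, index) -> np.ndarray:
        i = list(self.in_states).index(in_state)
        return self.s[i, index]


class FibreOrientationMap:
    """Per-pixel in-plane fibre orientations (up to three per pixel).

    ``orientations`` and ``separations`` are (H, W, 3) float arrays in
    degrees; NaN marks an absent slot.  ``separations`` holds the azimuthal
    peak-pair separation that produced each orientation (NaN for orientations
    derived from lone peaks or not from scattering profiles at all).
    ``overflow`` flags pixels where more than three candidates competed.
    """

    MAX_ORIENTATIONS = 3

    def __init__(self, orientations, separations=None, overflow=None):
        orientations = np.asarray(orientations, dtype=float)
        if orientations.ndim != 3 or orientations.shape[2] != self.MAX_ORIENTATIONS:
            raise ValueError("orientations must be (H, W, 3)")
        valid = ~np.isnan(orientations)
        if np.any((orientations[valid] < 0) | (orientations[valid] >= 180)):
            raise ValueError("orientations must lie in [0, 180)")
        self.orientations = orientations
        if separations is None:
            separations = np.full_like(orientations, np.nan)
        self.separations = np.asarray(separations, dtype=float)
        if self.separations.shape != orientations.shape:
            raise ValueError("separations shape mismatch")
        if overflow is None:
            overflow = np.zeros(orientations.shape[:2], dtype=bool)
        self.overflow = np.asarray(overflow, dtype=bool)

    @classmethod
    def empty(cls, height, width):
        return cls(np.full((height, width, cls.MAX_ORIENTATIONS), np.nan))

    @property
    def shape(self):
        return self.orientations.shape[:2]

    def n_orientations(self) -> np.ndarray:
        """Per-pixel count of assigned orientations (H×W int array)."""
        return np.sum(~np.isnan(self.orientations), axis=2)

    def pixel(self, row, col) -> np.ndarray:
        """Orientations assigned to one pixel, as a 1-D array (no NaNs)."""
        vals = self.orientations[row, col]
        return vals[~np.isnan(vals)]

    def copy(self) -> "FibreOrientationMap":
        return FibreOrientationMap(
            self.orientations.copy(), self.separations.copy(), self.overflow.copy()
        )


@dataclass
class DspResult:
    """Outputs of the double-Stokes orientation computation.

    All maps are H×W; ``delta_deg`` is the in-plane (effective) fibre
    orientation in [0, 180), NaN where masked.
    """

    delta_deg: np.ndarray
    A: np.ndarray
    sigma: np.ndarray
    shg_ld: np.ndarray
    shg_45: np.ndarray
    mask: np.ndarray  # True where the pixel is valid

    def to_fom(self) -> FibreOrientationMap:
        """Wrap the δ map as a single-orientation fibre orientation map."""
        h, w = self.delta_deg.shape
        ori = np.full((h, w, FibreOrientationMap.MAX_ORIENTATIONS), np.nan)
        ori[:, :, 0] = np.where(self.mask, self.delta_deg, np.nan)
        return FibreOrientationMap(ori)
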