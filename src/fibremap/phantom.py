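"""Fibre ground-truth phantoms: tendon-like bands, folds, and tilted layers.

A phantom assigns every pixel a list of up to three fibre populations, each
with an in-plane orientation δ (degrees, [0, 180)), an out-of-plane tilt α
(degrees, [0, 90]) and a relative amplitude.  Regions are axis-aligned
rectangles; overlapping regions stack their populations, which is how folded
tissue with two or three crossing layers is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .angles import wrap180

__all__ = [
    "FibrePopulation",
    "SusceptibilityParams",
    "FibreGroundTruth",
    "BandRegion",
    "PhantomSpec",
    "generate_phantom",
]

MAX_POPULATIONS = 3


@dataclass(frozen=True)
class FibrePopulation:
    """One fibre bundle within a pixel.

    delta_deg : in-plane orientation, degrees in [0, 180)
    alpha_deg : out-of-plane tilt, degrees in [0, 90]
    amplitude : relative signal weight, > 0
    """

    delta_deg: float
    alpha_deg: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.delta_deg < 180.0):
            raise ValueError(f"delta_deg must be in [0, 180), got {self.delta_deg}")
        if not (0.0 <= self.alpha_deg <= 90.0):
            raise ValueError(f"alpha_deg must be in [0, 90], got {self.alpha_deg}")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class SusceptibilityParams:
    """Second-order susceptibility ratios of the fibre material.

    R          : achiral tensor element ratio χ_zzz/χ_zxx (z along the fibre)
    Cmag       : chiral tensor element ratio magnitude |χ_xyz|/χ_zxx
    delta_phase: chiral/achiral phase difference Δ, radians

    Off-resonance Kleinman symmetry is assumed (χ_xxz ≈ χ_zxx), so the
    achiral part of the tensor is fully described by R.  The chiral ratio
    entering the measurement is C = Cmag·sin(α) for a fibre tilted by α.
    """

    R: float = 2.0
    Cmag: float = 0.0
    delta_phase: float = 0.0

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError("R must be positive")
        if self.Cmag < 0:
            raise ValueError("Cmag must be non-negative")


class FibreGroundTruth:
    """Pixel grid of fibre populations plus global susceptibility ratios."""

    def __init__(self, populations, susceptibility: SusceptibilityParams = None):
        # populations: nested list [row][col] -> tuple of FibrePopulation
        self._pops = populations
        self.height = len(populations)
        self.width = len(populations[0]) if self.height else 0
        for row in populations:
            if len(row) != self.width:
                raise ValueError("ragged population grid")
            for cell in row:
                if len(cell) > MAX_POPULATIONS:
                    raise ValueError(
                        f"at most {MAX_POPULATIONS} populations per pixel"
                    )
        self.susceptibility = susceptibility or SusceptibilityParams()

    @property
    def shape(self) -> Tuple[int, int]:
        return self.height, self.width

    def populations(self, row: int, col: int) -> Tuple[FibrePopulation, ...]:
        return self._pops[row][col]

    def n_populations(self) -> np.ndarray:
        return np.array(
            [[len(c) for c in row] for row in self._pops], dtype=int
        )

    def iter_pixels(self):
        for r in range(self.height):
            for c in range(self.width):
                yield r, c, self._pops[r][c]


@dataclass(frozen=True)
class BandRegion:
    """A rectangular band of parallel fibres.

    ``rect`` is (row0, row1, col0, col1) with half-open bounds, in pixels.
    """

    rect: Tuple[int, int, int, int]
    delta_deg: float
    alpha_deg: float = 0.0
    amplitude: float = 1.0

    def population(self) -> FibrePopulation:
        return FibrePopulation(wrap180(self.delta_deg), self.alpha_deg, self.amplitude)


@dataclass
class PhantomSpec:
    """Declarative description of a phantom: image size plus band regions.

    Overlapping bands stack, so a fold with two crossing layers is two bands
    sharing pixels.  ``jitter_sd_deg`` adds seeded per-pixel orientation
    jitter (0 disables it, the default: the stated region angles then hold
    exactly).
    """

    width: int
    height: int
    regions: List[BandRegion] = field(default_factory=list)
    susceptibility: SusceptibilityParams = field(default_factory=SusceptibilityParams)
    jitter_sd_deg: float = 0.0

    def add_band(self, rect, delta_deg, alpha_deg=0.0, amplitude=1.0):
        self.regions.append(BandRegion(rect, delta_deg, alpha_deg, amplitude))
        return self


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> FibreGroundTruth:
    """Rasterise a phantom description into per-pixel fibre populations.

    Deterministic for a fixed (spec, seed).  Raises if a region lies outside
    the image or if stacking would exceed three populations in a pixel.
    """
    rng = np.random.default_rng(seed)
    pops = [[[] for _ in range(spec.width)] for _ in range(spec.height)]
    for region in spec.regions:
        r0, r1, c0, c1 = region.rect
        if not (0 <= r0 < r1 <= spec.height and 0 <= c0 < c1 <= spec.width):
            raise ValueError(
                f"region {region.rect} outside image bounds "
                f"{spec.height}×{spec.width}"
            )
        base = region.population()
        for r in range(r0, r1):
            for c in range(c0, c1):
                if len(pops[r][c]) >= MAX_POPULATIONS:
                    raise ValueError(
                        f"pixel ({r}, {c}) would exceed {MAX_POPULATIONS} "
                        "fibre populations"
                    )
                if spec.jitter_sd_deg > 0:
                    delta = wrap180(
                        base.delta_deg + rng.normal(0.0, spec.jitter_sd_deg)
                    )
                    pops[r][c].append(
                        FibrePopulation(delta, base.alpha_deg, base.amplitude)
                    )
                else:
                    pops[r][c].append(base)
    grid = [[tuple(c) for c in row] for row in pops]
    return FibreGroundTruth(grid, spec.susceptibility)
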