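"""Acquisition geometry constants of the two imaging modalities.

These describe the reference instruments the simulations emulate: a
scattered-light rig with a full-frame camera behind a macro lens, and a
laser-scanning polarimetric SHG microscope with a low-NA objective chosen
to match the scattered-light lateral resolution.
"""

from __future__ import annotations

__all__ = [
    "COMSLI_PIXEL_SIZE_UM",
    "PSHG_PIXEL_SIZE_UM",
    "COMSLI_FOV_MM",
    "PSHG_TYPICAL_FOV_MM",
    "COMSLI_STEP_DEG",
    "fov_area_mm2",
    "fov_ratio",
]

#: Image pixel size of the scattered-light camera, micrometres.
COMSLI_PIXEL_SIZE_UM = 2.87
#: Image pixel size of the polarimetric SHG scan, micrometres.
PSHG_PIXEL_SIZE_UM = 2.37
#: Scattered-light field of view (width, height), millimetres.
COMSLI_FOV_MM = (15.7, 10.5)
#: Typical raster-scanned polarimetric SHG field of view, millimetres.
PSHG_TYPICAL_FOV_MM = (1.0, 1.0)
#: Azimuthal step of the ring illumination schedule, degrees.
COMSLI_STEP_DEG = 15.0


def fov_area_mm2(fov) -> float:
    """Field-of-view area in mm² from a (width, height) pair."""
    return float(fov[0]) * float(fov[1])


def fov_ratio() -> float:
    """How many typical pSHG fields of view fit in one scattered-light FoV."""
    return fov_area_mm2(COMSLI_FOV_MM) / fov_area_mm2(PSHG_TYPICAL_FOV_MM)
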