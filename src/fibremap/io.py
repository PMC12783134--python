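"""On-disk formats: multi-page TIFF stacks with JSON metadata sidecars.

Every stack is a float32 multi-page TIFF named ``<stem>.tif`` accompanied
by ``<stem>.json`` describing the acquisition (azimuth schedule or
polarisation state labels).  Orientation maps are float32 TIFFs with three
orientation planes followed by three separation planes (NaN = absent slot).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import (
    AngularSchedule,
    AngularStack,
    FibreOrientationMap,
    PolarimetricStack,
)

__all__ = [
    "write_angular_stack",
    "read_angular_stack",
    "write_polarimetric_stack",
    "read_polarimetric_stack",
    "write_fom",
    "read_fom",
    "write_stats",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_angular_stack(stack: AngularStack, path) -> None:
    path = Path(path)
    pages = np.moveaxis(stack.intensities, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "kind": "comsli",
        "azimuths_deg": list(stack.schedule.azimuths_deg),
        "polar_deg": stack.schedule.polar_deg,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_angular_stack(path) -> AngularStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no angular stack at {path}")
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "comsli":
        raise ValueError(f"{path} metadata does not describe an angular stack")
    pages = tifffile.imread(path)
    schedule = AngularSchedule(tuple(meta["azimuths_deg"]), meta.get("polar_deg", 45.0))
    return AngularStack(np.moveaxis(pages, 0, 2), schedule)


def write_polarimetric_stack(stack: PolarimetricStack, path) -> None:
    path = Path(path)
    n_in, n_out, h, w = stack.data.shape
    pages = stack.data.reshape(n_in * n_out, h, w).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "kind": stack.kind,
        "in_states": list(stack.in_states),
        "out_states": list(stack.out_states),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_polarimetric_stack(path) -> PolarimetricStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no polarimetric stack at {path}")
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") not in ("dsp", "pipo"):
        raise ValueError(f"{path} metadata does not describe a polarimetric stack")
    pages = tifffile.imread(path)
    n_in = len(meta["in_states"])
    n_out = len(meta["out_states"])
    data = np.asarray(pages).reshape(n_in, n_out, *pages.shape[1:])
    return PolarimetricStack(data, meta["in_states"], meta["out_states"], meta["kind"])


def write_fom(fom: FibreOrientationMap, path) -> None:
    path = Path(path)
    planes = np.concatenate(
        [np.moveaxis(fom.orientations, 2, 0), np.moveaxis(fom.separations, 2, 0)]
    ).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    meta = {"kind": "fom", "n_slots": fom.orientations.shape[2]}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_fom(path) -> FibreOrientationMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no orientation map at {path}")
    planes = np.asarray(tifffile.imread(path), dtype=float)
    n = planes.shape[0] // 2
    return FibreOrientationMap(
        np.moveaxis(planes[:n], 0, 2), np.moveaxis(planes[n:], 0, 2)
    )


def write_stats(stats, path) -> None:
    """Write comparison statistics as JSON plus a CSV histogram."""
    path = Path(path)
    path.write_text(json.dumps(stats.as_dict(), indent=1))
    centres = stats.bin_edges[:-1] + np.diff(stats.bin_edges) / 2.0
    lines = ["bin_centre_deg,count"]
    lines += [f"{c:.4f},{int(n)}" for c, n in zip(centres, stats.counts)]
    path.with_suffix(".csv").write_text("\n".join(lines) + "\n")
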