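"""TIFF + JSON-sidecar readers and writers for acquisitions and result maps.

Acquisitions are multi-page grayscale TIFFs (16-bit unsigned from the
instrument; float pages are accepted) with a JSON sidecar carrying the
angle grid, pixel size and calibration.  Orientation maps are written as
32-bit float single-page TIFFs with ϕ in degrees in [−90, 90); validity
masks as 8-bit (0/255).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .directionality import FBPair
from .orientation import OrientationResult, PolarizationStack

__all__ = [
    "read_polarization_stack",
    "read_fb_pair",
    "write_orientation_maps",
]


def read_polarization_stack(tiff_path, sidecar_path=None) -> PolarizationStack:
    """Read a polarization series (angle-major pages) and its sidecar.

    The sidecar (default: same stem with .json) must provide
    ``angles_deg``; ``repeats`` (default 1) repeat pages per angle are
    mean-averaged.  Page count must equal len(angles)·repeats.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else \
        tiff_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    if "angles_deg" not in meta:
        raise ValueError(f"sidecar {sidecar_path} lacks 'angles_deg'")
    angles = np.asarray(meta["angles_deg"], dtype=float)
    repeats = int(meta.get("repeats", 1))
    pages = tifffile.imread(tiff_path).astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != angles.size * repeats:
        raise ValueError(
            f"{tiff_path.name}: {pages.shape[0]} pages but sidecar declares "
            f"{angles.size} angles x {repeats} repeats")
    raw = pages.reshape(angles.size, repeats, *pages.shape[1:])
    return PolarizationStack.from_repeats(
        raw, angles, pixel_size_um=float(meta.get("pixel_size_um", 2.0)))


def read_fb_pair(forward_path, backward_path, sidecar_path=None,
                 default_calibration_c: float = 0.4) -> tuple[FBPair, dict]:
    """Read forward/backward multi-page TIFFs and their sidecar.

    Returns (pair, warnings-dict).  A missing ``calibration_c`` key falls
    back to ``default_calibration_c`` and is reported in the dict.
    """
    meta = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
    notes = {}
    if "calibration_c" not in meta:
        notes["calibration_c"] = (
            f"missing from sidecar; defaulting to {default_calibration_c}")
    c = float(meta.get("calibration_c", default_calibration_c))
    fwd = tifffile.imread(forward_path).astype(float)
    bwd = tifffile.imread(backward_path).astype(float)
    return FBPair(fwd, bwd, calibration_c=c), notes


def write_orientation_maps(out_dir, result: OrientationResult,
                           prefix: str = "") -> dict[str, Path]:
    """Write ϕ (degrees), ρ and validity maps; returns {name: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    phi_deg = np.degrees(result.phi).astype(np.float32)
    for name, arr in [("phi_deg", phi_deg),
                      ("rho", result.rho.astype(np.float32))]:
        paths[name] = out_dir / f"{prefix}{name}.tif"
        tifffile.imwrite(paths[name], arr)
    paths["valid"] = out_dir / f"{prefix}valid.tif"
    tifffile.imwrite(paths["valid"],
                     (result.valid.astype(np.uint8) * 255))
    if result.A is not None:
        paths["A"] = out_dir / f"{prefix}A.tif"
        tifffile.imwrite(paths["A"], result.A.astype(np.float32))
    return paths
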