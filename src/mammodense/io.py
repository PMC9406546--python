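"""Readers and writers for the pipeline's on-disk formats.

Input images are single-frame grayscale DICOM (MONOCHROME1 inverted to
MONOCHROME2 on load) or 8/16-bit grayscale PNG.  Masks travel as 8-bit PNG
with values {0, 255}; normalized images as 16-bit PNG plus a JSON sidecar
holding the flip flag and breast threshold so predictions can be mapped back
to the original orientation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocessing import NormalizedImage, RawMammogram

__all__ = ["read_image", "read_dicom", "read_png", "write_image_png",
           "write_mask_png", "read_mask_png", "write_normalized",
           "read_normalized"]


def read_image(path: str | Path) -> RawMammogram:
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(path)
    return read_png(path)


def read_dicom(path: str | Path) -> RawMammogram:
    import pydicom
    ds = pydicom.dcmread(str(path))
    px = ds.pixel_array.astype(np.float64)
    if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
        px = px.max() - px    # invert so brighter = denser
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    view = str(getattr(ds, "ViewPosition", "") or "unknown")
    if view not in ("CC", "MLO"):
        view = "unknown"
    return RawMammogram(px, pixel_spacing=spacing, view=view)


def read_png(path: str | Path) -> RawMammogram:
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16"):
        img = img.convert("L")
    return RawMammogram(np.asarray(img, dtype=np.float64))


def write_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """16-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 65535)
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as {0, 255} 8-bit PNG (bit-exact round trip)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def write_normalized(path: str | Path, norm: NormalizedImage,
                     breast_threshold: float | None = None) -> None:
    """16-bit PNG of [0,1] intensities + JSON sidecar with provenance."""
    path = Path(path)
    write_image_png(path, np.round(norm.pixels * 65535))
    sidecar = {"flipped": bool(norm.flipped),
               "breast_threshold": (None if breast_threshold is None
                                    else float(breast_threshold))}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_normalized(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    px = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return px, meta
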