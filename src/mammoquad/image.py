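"""Mammographic image container and plain-file IO.

A :class:`MammogramImage` couples a 2-D gray-value array with the acquisition
metadata the downstream geometry needs: the projection view (CC or MLO), the
laterality, and the detector pixel spacing in millimetres.

Orientation convention
----------------------
Images are stored chest-wall-at-left and superior-at-top for *both*
lateralities; right-breast acquisitions are assumed pre-flipped horizontally.
All geometric operations (chest-wall tracing, quadrant bisection) rely on this
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as _PILImage

from .errors import InputError

VIEWS = ("CC", "MLO")
LATERALITIES = ("L", "R")


@dataclass
class MammogramImage:
    """One mammographic view: pixel grid plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of gray values (float or integer); finite, non-empty.
    view
        Projection, ``"CC"`` (craniocaudal) or ``"MLO"`` (mediolateral
        oblique).
    laterality
        ``"L"`` or ``"R"``.
    pixel_spacing
        Detector pixel pitch in mm/pixel; strictly positive.
    bit_depth
        Nominal acquisition bit depth (8-16); used only when writing files.
    """

    pixels: np.ndarray
    view: str
    laterality: str
    pixel_spacing: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("pixels contain non-finite values")
        if self.view not in VIEWS:
            raise InputError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.laterality not in LATERALITIES:
            raise InputError(f"laterality must be one of {LATERALITIES}")
        if not (self.pixel_spacing > 0):
            raise InputError("pixel_spacing must be > 0")
        if not (1 <= int(self.bit_depth) <= 16):
            raise InputError("bit_depth must be in [1, 16]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        """Write pixels as 16-bit single-channel TIFF or PNG (by extension)
        with a JSON metadata sidecar next to it."""
        path = Path(path)
        arr = np.clip(np.rint(self.pixels), 0, 2**16 - 1).astype(np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        elif path.suffix.lower() == ".png":
            _PILImage.fromarray(arr, mode="I;16").save(path)
        else:
            raise InputError(f"unsupported image extension: {path.suffix}")
        meta = {
            "view": self.view,
            "laterality": self.laterality,
            "pixel_spacing": self.pixel_spacing,
            "bit_depth": self.bit_depth,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "MammogramImage":
        """Read an image written by :meth:`save` (metadata sidecar required)."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif path.suffix.lower() == ".png":
            arr = np.asarray(_PILImage.open(path))
        else:
            raise InputError(f"unsupported image extension: {path.suffix}")
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise InputError(f"missing metadata sidecar: {sidecar}")
        meta = json.loads(sidecar.read_text())
        return cls(
            pixels=arr,
            view=meta["view"],
            laterality=meta["laterality"],
            pixel_spacing=float(meta["pixel_spacing"]),
            bit_depth=int(meta.get("bit_depth", 16)),
        )


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0 / 255)."""
    arr = (np.asarray(mask, bool).astype(np.uint8)) * 255
    _PILImage.fromarray(arr, mode="L").save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary PNG mask back to a boolean array."""
    return np.asarray(_PILImage.open(Path(path))) > 0
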