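"""Image and mask I/O.

Images are held internally as 2-D float64 arrays on the canonical
[0, 1] intensity scale; masks as 2-D uint8 arrays of {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


@dataclass(frozen=True)
class GrayImage:
    """A grayscale image on the canonical [0, 1] scale.

    ``values`` is a float64 array; ``source_bit_depth`` records the bit
    depth of the file it was read from (8 for synthetic images).
    """

    values: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("image must be a 2-D array with positive shape")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF/PGM image as a [0, 1] grayscale array.

    8- or 16-bit single-channel input is divided by ``2**depth - 1``;
    RGB input is first reduced by the plain channel average.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = Image.open(path)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if getattr(img, "n_frames", 1) > 1:
        raise FormatError(f"{path} is a multi-frame image")
    arr = np.asarray(img)
    if img.mode in ("I;16", "I;16B", "I;16L", "I") or arr.dtype.itemsize > 1:
        depth = 16
    else:
        depth = 8
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise FormatError(f"{path}: unsupported array shape {arr.shape}")
    values = arr.astype(np.float64) / (2**depth - 1)
    return GrayImage(np.clip(values, 0.0, 1.0), source_bit_depth=depth)


def write_gray_image(path: str | Path, img: GrayImage | np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit PNG/TIFF/PGM (by extension)."""
    values = img.values if isinstance(img, GrayImage) else np.asarray(img)
    out = np.rint(np.clip(values, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(out).save(path)


def as_mask(values: np.ndarray) -> np.ndarray:
    """Validate and normalize a {0,1} mask array to uint8."""
    m = np.asarray(values)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    return m.astype(np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: any nonzero pixel counts as foreground."""
    img = read_gray_image(path)
    return (img.values > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit {0,255} PNG (lossless round-trip)."""
    m = as_mask(mask)
    Image.fromarray(m * np.uint8(255)).save(path)


__all__ = [
    "GrayImage",
    "FormatError",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
    "as_mask",
]
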