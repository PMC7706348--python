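"""Shared domain types and raster I/O.

Every stage of the pipeline exchanges three kinds of objects: :class:`RgbImage`
(the raw 8-bit observation), :class:`BinaryMask` (a boolean map aligned to an
image, tagged with the stage that produced it), and :class:`PixelCoord`
(0-based ``(row, col)``, origin at the top-left corner, row-major).

Images are read from PNG/TIFF/JPEG; every raster the package *writes* is PNG so
round-trips are lossless.  Masks serialize as single-channel ``{0, 255}`` PNG —
visually inspectable, and read back tolerantly (``{0, 1}`` files are accepted).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "MaskProvenance",
    "RgbImage",
    "BinaryMask",
    "PixelCoord",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: Minimum image side so a 31x31 patch fits.
MIN_SIDE = 31


class MaskProvenance(str, enum.Enum):
    """Which stage produced a mask."""

    BINARIZATION = "binarization"
    CNN = "cnn"
    COMBINED = "combined"
    GROUND_TRUTH = "ground_truth"


@dataclass(frozen=True)
class PixelCoord:
    """0-based pixel coordinate, ``row`` downwards, ``col`` rightwards."""

    row: int
    col: int

    def validate(self, height: int, width: int) -> "PixelCoord":
        if not (0 <= self.row < height and 0 <= self.col < width):
            raise ValueError(
                f"coordinate ({self.row}, {self.col}) outside {height}x{width} image"
            )
        return self


@dataclass
class RgbImage:
    """An H×W×3 8-bit image plus an identifier (usually the filename stem)."""

    pixels: np.ndarray
    id: str = "image"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def require_min_size(self) -> "RgbImage":
        """Enforce the pipeline's minimum size (a 31x31 patch must fit)."""
        if self.height < MIN_SIDE or self.width < MIN_SIDE:
            raise ValueError(
                f"image {self.id!r} is {self.height}x{self.width}; "
                f"pipeline requires at least {MIN_SIDE}x{MIN_SIDE}"
            )
        return self


@dataclass
class BinaryMask:
    """Boolean H×W map aligned to an :class:`RgbImage`."""

    values: np.ndarray
    provenance: MaskProvenance = MaskProvenance.GROUND_TRUTH
    image_id: str = field(default="image")

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {vals.shape}")
        self.values = vals.astype(bool)
        if isinstance(self.provenance, str):
            self.provenance = MaskProvenance(self.provenance)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def true_count(self) -> int:
        return int(self.values.sum())

    def check_shape(self, other) -> None:
        if self.values.shape != np.shape(other)[:2]:
            raise ValueError(
                f"mask shape {self.values.shape} does not match {np.shape(other)[:2]}"
            )


def read_image(path: str | Path) -> RgbImage:
    """Read a PNG/TIFF/JPEG raster as an 8-bit RGB image.

    Single-channel input is replicated to three channels.  Bit depths other
    than 8 raise a format error naming the depth found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I;16L", "I"):
            raise ValueError(
                f"unsupported bit depth in {path.name}: found {im.mode} "
                "(16/32-bit), expected 8-bit"
            )
        if im.mode == "RGBA":
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth in {path.name}: found {arr.dtype}, expected uint8"
        )
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ValueError(f"expected 1 or 3 channels, got {arr.shape[2]} in {path.name}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return RgbImage(pixels=arr, id=path.stem)


def write_image(image: RgbImage, path: str | Path) -> Path:
    """Write an RGB image as PNG (lossless)."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    return path


def read_mask(
    path: str | Path,
    provenance: MaskProvenance | str = MaskProvenance.GROUND_TRUTH,
) -> BinaryMask:
    """Read a two-valued single-channel raster as a boolean mask.

    Nonzero pixels map to True.  A file with more than two distinct values is
    rejected (it is not a binary mask) with the offending values listed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    with Image.open(path) as im:
        if im.mode not in ("L", "1", "P", "I;16"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.ndim != 2:
        arr = arr[:, :, 0]
    distinct = np.unique(arr)
    if distinct.size > 2:
        raise ValueError(
            f"mask {path.name} has {distinct.size} distinct values "
            f"{distinct.tolist()}; expected at most two"
        )
    return BinaryMask(values=arr != 0, provenance=provenance, image_id=path.stem)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as single-channel PNG with True -> 255, False -> 0."""
    path = Path(path)
    arr = np.where(mask.values, np.uint8(255), np.uint8(0))
    Image.fromarray(arr, mode="L").save(path, format="PNG")
    return path
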