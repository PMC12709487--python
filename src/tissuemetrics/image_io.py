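"""Reading, standardizing and thresholding brightfield microscopy images.

Every analysis in the package works on a common substrate: a grayscale
raster with intensities in [0, 255], standardized to a square side that is
a power of two (512 by default), optionally thresholded to a binary
foreground/background mask, and partitioned into non-overlapping square
sub-boxes.  This module owns those operations.

Conventions
-----------
* Pixel coordinates are row-major, 0-based, origin at the top-left, with
  half-open pixel ranges.
* The binary *foreground* is, by default, the set of pixels strictly below
  the threshold cut.  In transmission imaging, optically dense (mass-rich)
  tissue absorbs light and appears dark, so low intensity marks occupied
  tissue.  Pass ``invert=True`` to flip the convention.
* Thresholds are fractions of the full 8-bit dynamic range (cut value =
  fraction x 255), not of the per-image maximum, so a "65% threshold"
  means the same cut on every image of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

__all__ = [
    "RGBImage",
    "GrayImage",
    "BinaryImage",
    "Block",
    "load_image",
    "to_grayscale",
    "extract_channel",
    "resize_to_standard",
    "binarize",
    "partition",
]

#: ITU-R BT.601 luminance weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_SIDE = 512


@dataclass(frozen=True)
class RGBImage:
    """A three-channel intensity raster with 8-bit range per channel."""

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 255]
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RGBImage needs an (H, W, 3) array, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel raster, real-valued in [0, 255]."""

    pixels: np.ndarray  # (H, W) float64
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"GrayImage needs a 2-D array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < -1e-9 or px.max() > 255 + 1e-9:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 255.0))

    @property
    def side(self) -> int:
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("side is only defined for square images")
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryImage:
    """A thresholded raster: True marks foreground pixels.

    The threshold fraction that produced the mask is carried with it, so
    downstream tables can always report the binarization condition.
    """

    pixels: np.ndarray  # (H, W) bool
    threshold_fraction: float
    inverted: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"BinaryImage needs a 2-D array, got shape {px.shape}")
        if not 0.0 <= self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Block:
    """One sub-box of a partitioned image, tagged with its grid position."""

    row: int
    col: int
    pixels: np.ndarray


def load_image(path: str | Path) -> RGBImage:
    """Read a PNG or TIFF file into an :class:`RGBImage`.

    Grayscale files are promoted to three identical channels; 16-bit
    rasters are rescaled onto [0, 255] (divide by 257, the exact 16-bit to
    8-bit ratio 65535/255).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise ValueError(f"unsupported or corrupt image format: {path}") from exc
    if arr.dtype == np.uint16:
        arr = arr.astype(float) / 257.0
    elif arr.dtype == bool:
        arr = arr.astype(float) * 255.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]  # drop alpha
    else:
        raise ValueError(f"cannot interpret image of shape {arr.shape}: {path}")
    return RGBImage(pixels=arr, source_path=str(path))


def to_grayscale(img: RGBImage) -> GrayImage:
    """Collapse RGB to luminance with the standard BT.601 weights."""
    w = np.asarray(LUMA_WEIGHTS)
    gray = img.pixels @ w
    return GrayImage(pixels=gray, source_path=img.source_path)


def extract_channel(img: RGBImage, channel: int) -> GrayImage:
    """Return one color plane (0=red, 1=green, 2=blue) unmodified."""
    if channel not in (0, 1, 2):
        raise ValueError(f"channel index must be 0, 1 or 2, got {channel}")
    return GrayImage(pixels=img.pixels[:, :, channel], source_path=img.source_path)


def resize_to_standard(img: GrayImage, side: int = DEFAULT_SIDE) -> GrayImage:
    """Resample to ``side x side`` pixels with bilinear interpolation.

    The default 512 standardizes cohorts captured at differing
    magnifications onto a common grid whose side is divisible by every
    dyadic sub-box size used downstream.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if (side & (side - 1)) != 0:
        raise ValueError("side must be a power of two")
    if img.pixels.shape == (side, side):
        return GrayImage(pixels=img.pixels.copy(), source_path=img.source_path)
    out = _sk_resize(
        img.pixels, (side, side), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return GrayImage(pixels=np.clip(out, 0.0, 255.0), source_path=img.source_path)


def binarize(
    img: GrayImage, threshold_fraction: float, invert: bool = False
) -> BinaryImage:
    """Threshold a grayscale image into foreground/background.

    Foreground = intensity strictly below ``threshold_fraction * 255``
    (dark tissue); with ``invert=True``, strictly above.
    """
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError(
            f"threshold_fraction must lie in [0, 1], got {threshold_fraction}"
        )
    cut = threshold_fraction * 255.0
    mask = img.pixels > cut if invert else img.pixels < cut
    return BinaryImage(pixels=mask, threshold_fraction=threshold_fraction,
                       inverted=invert)


def partition(
    img: GrayImage | BinaryImage | np.ndarray, block_side: int
) -> list[Block]:
    """Split a square image into non-overlapping ``block_side`` sub-boxes.

    Blocks come back in row-major grid order, each tagged with its
    (row, col) grid position; their union tiles the input exactly.
    """
    px = img if isinstance(img, np.ndarray) else img.pixels
    h, w = px.shape
    if h != w:
        raise ValueError("partition requires a square image")
    if block_side <= 0 or h % block_side != 0:
        raise ValueError(f"block_side {block_side} must divide the image side {h}")
    n = h // block_side
    blocks: list[Block] = []
    for r in range(n):
        for c in range(n):
            sub = px[r * block_side:(r + 1) * block_side,
                     c * block_side:(c + 1) * block_side]
            blocks.append(Block(row=r, col=c, pixels=sub))
    return blocks
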