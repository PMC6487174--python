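"""Image containers and PNG/TIFF/JPEG I/O.

Two light wrappers around integer numpy rasters are used throughout the
package: :class:`ColorImage` (H×W×3) and :class:`GrayImage` (H×W).  A
``ColorImage`` carries a ``color_space`` tag so downstream stages can tell
an ordinary RGB micrograph from a reconstructed gradient/GLCM/LBP image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

COLOR_SPACES = ("rgb", "reconstructed")

#: Minimum side length: the texture operators need a 3×3 neighborhood.
MIN_SIDE = 3


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically degenerate
    (e.g. an all-black channel that the gray-world correction cannot scale)."""


def _check_raster(pixels: np.ndarray, ndim: int) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != ndim:
        raise ValueError(f"expected a {ndim}-d raster, got shape {pixels.shape}")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError(f"pixel values must be integers, got dtype {pixels.dtype}")
    if pixels.min() < 0 or pixels.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return pixels


@dataclass(frozen=True)
class ColorImage:
    """An 8-bit 3-channel raster with tracked channel semantics.

    For ``color_space == "reconstructed"`` the channels are, in order, the
    gradient, GLCM-statistic and LBP maps of the source image.
    """

    pixels: np.ndarray
    color_space: str = "rgb"

    def __post_init__(self) -> None:
        pixels = _check_raster(self.pixels, 3)
        if pixels.shape[2] != 3:
            raise ValueError(f"expected 3 channels, got {pixels.shape[2]}")
        if pixels.shape[0] < MIN_SIDE or pixels.shape[1] < MIN_SIDE:
            raise ValueError(f"image sides must be >= {MIN_SIDE} px")
        if self.color_space not in COLOR_SPACES:
            raise ValueError(f"unknown color space {self.color_space!r}")
        object.__setattr__(self, "pixels", pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit single-channel raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_raster(self.pixels, 2))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path, color_space: str = "rgb") -> ColorImage:
    """Read an 8-bit PNG/TIFF/JPEG into a :class:`ColorImage`."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return ColorImage(arr.astype(np.int64), color_space=color_space)


def write_image(img: ColorImage, path: str | Path) -> None:
    """Write a :class:`ColorImage` to disk.

    Reconstructed images must go to PNG (or TIFF): lossy JPEG would corrupt
    the LBP codes stored in the blue channel.
    """
    path = Path(path)
    if img.color_space == "reconstructed" and path.suffix.lower() in {".jpg", ".jpeg"}:
        raise ValueError("reconstructed images must be written losslessly (PNG/TIFF)")
    Image.fromarray(img.pixels.astype(np.uint8)).save(path)
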