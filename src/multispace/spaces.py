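"""Multispace image reconstruction.

An H&E micrograph is mapped to a *reconstructed* 3-channel image whose
channels encode complementary structural information:

* R — Sobel gradient magnitude (sensitive to nucleus boundaries),
* G — a sliding-window GLCM texture statistic (sensitive to nucleus regions),
* B — local binary pattern codes (highlights nucleus centres).

The pipeline is: gray-world white balance → luminance grayscale → the three
texture maps, stacked as channels.  Every operator pads with replicated
borders so outputs keep the input size, and every output stays in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ColorImage, DegenerateInputError, GrayImage

GLCM_STATISTICS = ("contrast", "energy", "homogeneity")


@dataclass(frozen=True)
class SpaceParams:
    """Free parameters of the GLCM and LBP maps.

    glcm_levels : gray-level quantization bins (pixel v → floor(v·levels/256)).
    glcm_window : odd side length of the neighborhood around each pixel.
    glcm_offset : (row, col) displacement of the cooccurring pixel pair.
    glcm_statistic : which scalar of the normalized symmetric cooccurrence
        matrix becomes the pixel value: contrast Σ P(i,j)(i−j)², energy
        Σ P(i,j)², or homogeneity Σ P(i,j)/(1+|i−j|).
    lbp_radius, lbp_points : fixed at (1, 8) — the classic 8-neighbor code.
    """

    glcm_levels: int = 8
    glcm_window: int = 7
    glcm_offset: tuple[int, int] = (0, 1)
    glcm_statistic: str = "contrast"
    lbp_radius: int = 1
    lbp_points: int = 8

    def __post_init__(self) -> None:
        if self.glcm_levels < 2 or self.glcm_levels > 256:
            raise ValueError("glcm_levels must be in [2, 256]")
        if self.glcm_window < 3 or self.glcm_window % 2 == 0:
            raise ValueError("glcm_window must be an odd integer >= 3")
        if self.glcm_offset == (0, 0):
            raise ValueError("glcm_offset must be nonzero")
        if abs(self.glcm_offset[0]) >= self.glcm_window or abs(self.glcm_offset[1]) >= self.glcm_window:
            raise ValueError("glcm_offset must fit inside the window")
        if self.glcm_statistic not in GLCM_STATISTICS:
            raise ValueError(f"glcm_statistic must be one of {GLCM_STATISTICS}")
        if (self.lbp_radius, self.lbp_points) != (1, 8):
            raise ValueError("only the classic 8-neighbor radius-1 LBP is supported")


def white_balance(img: ColorImage) -> ColorImage:
    """Gray-world white balance: scale each channel so its mean equals the
    mean of the three channel means; clip to [0, 255]."""
    if img.color_space != "rgb":
        raise ValueError("white_balance expects an RGB image")
    pixels = img.pixels.astype(np.float64)
    channel_means = pixels.mean(axis=(0, 1))
    if np.any(channel_means == 0):
        raise DegenerateInputError("gray-world correction undefined for an all-zero channel")
    scale = channel_means.mean() / channel_means
    balanced = np.clip(np.rint(pixels * scale), 0, 255).astype(np.int64)
    return ColorImage(balanced, color_space="rgb")


def to_grayscale(img: ColorImage) -> GrayImage:
    """Luminance grayscale 0.299 R + 0.587 G + 0.114 B, rounded."""
    if img.color_space != "rgb":
        raise ValueError("to_grayscale expects an RGB image")
    weights = np.array([0.299, 0.587, 0.114])
    gray = np.rint(img.pixels.astype(np.float64) @ weights)
    return GrayImage(np.clip(gray, 0, 255).astype(np.int64))


def gradient_magnitude(img: GrayImage) -> np.ndarray:
    """Raw Sobel gradient magnitude √(Gx²+Gy²) with replicated borders."""
    x = img.pixels.astype(np.float64)
    gx = ndimage.sobel(x, axis=1, mode="nearest")
    gy = ndimage.sobel(x, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def _rescale_to_255(raw: np.ndarray) -> np.ndarray:
    """Max-normalize a nonnegative map to [0, 255]; an all-zero map stays zero."""
    peak = raw.max()
    if peak <= 0:
        return np.zeros(raw.shape, dtype=np.int64)
    return np.rint(raw * (255.0 / peak)).astype(np.int64)


def gradient_image(img: GrayImage) -> GrayImage:
    """Sobel gradient-magnitude map, max-normalized to [0, 255]."""
    if img.height < 3 or img.width < 3:
        raise ValueError("gradient_image needs at least a 3x3 image")
    return GrayImage(_rescale_to_255(gradient_magnitude(img)))


def _box_sum(m: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum of every h×w box of m (valid placements only), via integral image."""
    c = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.float64)
    c[1:, 1:] = m.cumsum(axis=0).cumsum(axis=1)
    return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]


def glcm_statistic_map(img: GrayImage, p: SpaceParams | None = None) -> np.ndarray:
    """Raw per-pixel GLCM statistic over a sliding window.

    For each pixel, the symmetric normalized cooccurrence matrix of its
    ``glcm_window`` neighborhood at ``glcm_offset`` is summarized by the
    configured statistic.  Replicate padding keeps every window full, so the
    pair count per window is the constant (w−|dr|)·(w−|dc|).
    """
    p = p or SpaceParams()
    h_img, w_img = img.pixels.shape
    w = p.glcm_window
    if h_img < w or w_img < w:
        raise ValueError(f"glcm window {w} larger than image {h_img}x{w_img}")

    levels = p.glcm_levels
    q = (img.pixels.astype(np.int64) * levels) // 256

    dr, dc = p.glcm_offset
    # The symmetric matrix is identical for offset d and −d; canonicalize to dr >= 0.
    if dr < 0 or (dr == 0 and dc < 0):
        dr, dc = -dr, -dc

    half = w // 2
    padded = np.pad(q, half, mode="edge")
    hp, wp = padded.shape
    c_lo, c_hi = max(0, -dc), wp - max(0, dc)
    first = padded[0 : hp - dr, c_lo:c_hi]
    second = padded[dr:hp, c_lo + dc : c_hi + dc]

    box_h, box_w = w - dr, w - abs(dc)
    n_pairs = float(box_h * box_w)

    if p.glcm_statistic == "energy":
        # Energy is quadratic in the matrix entries, so per-level-pair counts
        # are needed; contrast/homogeneity below are linear and collapse to a
        # single weighted box sum.
        counts = np.empty((levels, levels, h_img, w_img))
        for li in range(levels):
            for lj in range(levels):
                counts[li, lj] = _box_sum(((first == li) & (second == lj)).astype(np.float64), box_h, box_w)
        sym = (counts + counts.transpose(1, 0, 2, 3)) / (2.0 * n_pairs)
        return (sym**2).sum(axis=(0, 1))

    if p.glcm_statistic == "contrast":
        weights = (first - second).astype(np.float64) ** 2
    else:  # homogeneity
        weights = 1.0 / (1.0 + np.abs(first - second))
    return _box_sum(weights, box_h, box_w) / n_pairs


def glcm_image(img: GrayImage, p: SpaceParams | None = None) -> GrayImage:
    """Sliding-window GLCM statistic map, max-normalized to [0, 255]."""
    return GrayImage(_rescale_to_255(glcm_statistic_map(img, p)))


# Neighbor offsets clockwise from the top-left corner; the first offset
# contributes the most significant bit of the 8-bit code.
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_image(img: GrayImage) -> GrayImage:
    """Classic 8-neighbor radius-1 LBP codes.

    Bit b is set when the neighbor is >= the center; bits run clockwise from
    the top-left neighbor (most significant bit first).  Codes natively span
    [0, 255], so no rescaling is applied.
    """
    if img.height < 3 or img.width < 3:
        raise ValueError("lbp_image needs at least a 3x3 image")
    x = img.pixels.astype(np.int64)
    padded = np.pad(x, 1, mode="edge")
    h, w = x.shape
    code = np.zeros((h, w), dtype=np.int64)
    for k, (dy, dx) in enumerate(_LBP_OFFSETS):
        neighbor = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        code |= (neighbor >= x).astype(np.int64) << (7 - k)
    return GrayImage(code)


def reconstruct(img: ColorImage, p: SpaceParams | None = None) -> ColorImage:
    """White-balance, grayscale, then stack gradient/GLCM/LBP maps as R/G/B."""
    p = p or SpaceParams()
    gray = to_grayscale(white_balance(img))
    channels = np.stack(
        [gradient_image(gray).pixels, glcm_image(gray, p).pixels, lbp_image(gray).pixels],
        axis=2,
    )
    return ColorImage(channels, color_space="reconstructed")
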