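"""Patch tiling, majority voting and probability atlases.

A 1388×1040 micrograph tiles into a 21×16 grid of 336 non-overlapping 64×64
patches; the right/bottom remainders are discarded.  Patch predictions are
aggregated to an image label by majority vote, and per-patch probabilities
for the predicted class can be rendered as a probability atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ColorImage

PATCH_SIZE = 64


@dataclass(frozen=True)
class PatchGrid:
    """Row-major grid of non-overlapping square patches cut from one image.

    ``patches`` has shape (n_rows·n_cols, s, s, 3); ``origins`` holds each
    patch's top-left (row_px, col_px), both multiples of the patch size.
    """

    patch_size: int
    n_rows: int
    n_cols: int
    patches: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        n = self.n_rows * self.n_cols
        if self.patches.shape != (n, self.patch_size, self.patch_size, 3):
            raise ValueError("patch array shape inconsistent with grid dimensions")
        if self.origins.shape != (n, 2):
            raise ValueError("origin array shape inconsistent with grid dimensions")

    def __len__(self) -> int:
        return self.n_rows * self.n_cols


def tile_image(img: ColorImage, patch_size: int = PATCH_SIZE) -> PatchGrid:
    """Cut an image into non-overlapping patches anchored at the top-left.

    The W mod patch_size right margin and H mod patch_size bottom margin are
    dropped, which is the only layout giving 21×16 = 336 patches on 1388×1040.
    """
    h, w = img.pixels.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"image {h}x{w} smaller than one {patch_size}px patch")
    n_rows, n_cols = h // patch_size, w // patch_size
    cropped = img.pixels[: n_rows * patch_size, : n_cols * patch_size]
    patches = (
        cropped.reshape(n_rows, patch_size, n_cols, patch_size, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(n_rows * n_cols, patch_size, patch_size, 3)
    )
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    origins = np.stack([rows.ravel(), cols.ravel()], axis=1) * patch_size
    return PatchGrid(patch_size, n_rows, n_cols, patches, origins)


def assemble(grid: PatchGrid) -> np.ndarray:
    """Reassemble the patches at their origins (inverse of the cropped tiling)."""
    h, w = grid.n_rows * grid.patch_size, grid.n_cols * grid.patch_size
    out = np.zeros((h, w, 3), dtype=grid.patches.dtype)
    for patch, (r, c) in zip(grid.patches, grid.origins):
        out[r : r + grid.patch_size, c : c + grid.patch_size] = patch
    return out


def majority_vote(patch_labels) -> int:
    """Modal patch label; ties go to the smallest class id."""
    labels = np.asarray(patch_labels)
    if labels.size == 0:
        raise ValueError("cannot vote on an empty label list")
    return int(np.bincount(labels).argmax())


def probability_atlas(grid: PatchGrid, probs: np.ndarray, image_class: int) -> np.ndarray:
    """n_rows×n_cols matrix of each patch's predicted probability for
    ``image_class`` (row-major, matching the grid layout)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[0] != len(grid):
        raise ValueError(f"{probs.shape[0]} probability vectors for {len(grid)} patches")
    atlas = probs[:, image_class].reshape(grid.n_rows, grid.n_cols)
    if atlas.min() < 0 or atlas.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return atlas


def grid_manifest(grid: PatchGrid, image_id: str) -> pd.DataFrame:
    """Tabular description of the grid: image_id, patch_idx, row_px, col_px."""
    return pd.DataFrame(
        {
            "image_id": image_id,
            "patch_idx": np.arange(len(grid)),
            "row_px": grid.origins[:, 0],
            "col_px": grid.origins[:, 1],
        }
    )


def save_atlas_csv(atlas: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, atlas, delimiter=",", fmt="%.6f")
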