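"""Seeded generators of H&E-like images and backbone-feature fixtures.

The image generator emulates the statistical structure the pipeline assumes
in stained lymphoma micrographs: a pink (eosin) background, purple
(hematoxylin) elliptical nuclei whose density, size and internal texture
differ by class, and a random per-image color cast that exercises the
white-balance step.  Three default profiles mirror the qualitative contrast
between the lymphoma subtypes: CLL-like (many small uniform nuclei),
FL-like (fewer, larger, grainier nuclei) and MCL-like (intermediate).

The feature generator skips the imaging stages entirely and emits paired
class-conditional Gaussian (rgb, reconstructed) 2048-vectors: each class
shifts its mean by ``separation`` on a class-specific coordinate block, and
the two streams use disjoint blocks, so their information is complementary
and fusing them genuinely helps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ColorImage, write_image

CLASS_NAMES = ("cll", "fl", "mcl")


@dataclass(frozen=True)
class ClassProfile:
    """Morphology of one synthetic class at a reference image size."""

    name: str
    density_per_mpx: float  # expected nucleus count per megapixel
    radius_range: tuple[float, float]  # semi-axis range, px
    texture_amplitude: float  # intra-nucleus intensity modulation, gray levels
    graininess: int  # chromatin speckle cell size, px


# Lymphoma tissue is densely packed with lymphocytes: nuclei cover roughly a
# third of the field, so every 64×64 patch contains several.  The profiles
# differ in the morphology pathologists actually use: CLL-like fields are
# crowded small uniform cells, FL-like fields have fewer, larger, grainier
# nuclei, MCL-like fields sit in between.
DEFAULT_PROFILES = (
    ClassProfile("cll", density_per_mpx=3800.0, radius_range=(4.0, 6.5), texture_amplitude=10.0, graininess=2),
    ClassProfile("fl", density_per_mpx=1500.0, radius_range=(7.0, 11.0), texture_amplitude=45.0, graininess=6),
    ClassProfile("mcl", density_per_mpx=2400.0, radius_range=(5.5, 8.5), texture_amplitude=25.0, graininess=4),
)


@dataclass(frozen=True)
class SynthConfig:
    image_size: tuple[int, int] = (1388, 1040)  # (W, H), the micrograph geometry
    n_per_class: int = 4
    profiles: tuple[ClassProfile, ...] = DEFAULT_PROFILES
    background_rgb: tuple[int, int, int] = (232, 180, 208)  # eosin pink
    nucleus_rgb: tuple[int, int, int] = (96, 62, 138)  # hematoxylin purple
    background_jitter: float = 6.0
    color_cast: float = 0.12  # per-channel multiplicative cast, U(1−c, 1+c)
    seed: int = 0
    max_place_attempts: int = 200  # rejection-sampling tries per nucleus

    def __post_init__(self) -> None:
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("profile names must be distinct")
        if self.n_per_class < 0 or self.image_size[0] < 3 or self.image_size[1] < 3:
            raise ValueError("invalid size configuration")


def _nucleus_count(profile: ClassProfile, image_size: tuple[int, int]) -> int:
    return int(round(profile.density_per_mpx * image_size[0] * image_size[1] / 1e6))


def _place_nuclei(rng: np.random.Generator, profile: ClassProfile, w: int, h: int, max_attempts: int):
    """Non-overlapping centers/radii by rejection sampling.

    A uniform grid of cells (side = one max diameter) limits the overlap
    check to the 3×3 neighborhood, so dense fields with thousands of nuclei
    place in linear time.
    """
    count = _nucleus_count(profile, (w, h))
    lo, hi = profile.radius_range
    cell = 2.0 * hi
    grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(count):
        placed = False
        for _ in range(max_attempts):
            r = rng.uniform(lo, hi)
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            gx, gy = int(cx // cell), int(cy // cell)
            ok = True
            for nx in range(gx - 1, gx + 2):
                for ny in range(gy - 1, gy + 2):
                    for x, y, rr in grid.get((nx, ny), ()):
                        if (cx - x) ** 2 + (cy - y) ** 2 <= (r + rr) ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gx, gy), []).append((cx, cy, r))
                centers.append((cx, cy))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {count} non-overlapping nuclei for profile {profile.name!r}"
            )
    return centers, radii


def _render_image(rng: np.random.Generator, profile: ClassProfile, cfg: SynthConfig):
    w, h = cfg.image_size
    bg = np.asarray(cfg.background_rgb, dtype=np.float64)
    img = bg + rng.normal(0.0, cfg.background_jitter, size=(h, w, 3))

    centers, radii = _place_nuclei(rng, profile, w, h, cfg.max_place_attempts)
    nucleus = np.asarray(cfg.nucleus_rgb, dtype=np.float64)
    for (cx, cy), r in zip(centers, radii):
        # Random-orientation ellipse with mild eccentricity.
        a = r
        b = r * rng.uniform(0.65, 1.0)
        theta = rng.uniform(0, np.pi)
        x0, x1 = int(max(0, cx - r - 1)), int(min(w, cx + r + 2))
        y0, y1 = int(max(0, cy - r - 1)), int(min(h, cy + r + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not mask.any():
            continue
        # Chromatin texture: coarse speckle at the profile's grain size.
        grain = max(1, profile.graininess)
        gh = (y1 - y0 + grain - 1) // grain
        gw = (x1 - x0 + grain - 1) // grain
        speckle = rng.normal(0.0, profile.texture_amplitude, size=(gh, gw))
        speckle = np.kron(speckle, np.ones((grain, grain)))[: y1 - y0, : x1 - x0]
        region = img[y0:y1, x0:x1]
        region[mask] = nucleus + speckle[mask, None]
        img[y0:y1, x0:x1] = region

    cast = rng.uniform(1.0 - cfg.color_cast, 1.0 + cfg.color_cast, size=3)
    img = np.clip(np.rint(img * cast), 0, 255).astype(np.int64)
    return ColorImage(img, color_space="rgb"), len(centers)


def generate_dataset(cfg: SynthConfig):
    """Generate the seeded 3-class image set.

    Returns (images, labels, manifest) where manifest is a DataFrame with
    columns image_id, class_name, class_id, seed, n_nuclei.
    """
    rng = np.random.default_rng(cfg.seed)
    images: list[ColorImage] = []
    labels: list[int] = []
    rows = []
    for class_id, profile in enumerate(cfg.profiles):
        for j in range(cfg.n_per_class):
            img, n_placed = _render_image(rng, profile, cfg)
            image_id = f"{profile.name}_{j:03d}"
            images.append(img)
            labels.append(class_id)
            rows.append(
                {"image_id": image_id, "class_name": profile.name, "class_id": class_id,
                 "seed": cfg.seed, "n_nuclei": n_placed}
            )
    return images, np.asarray(labels), pd.DataFrame(rows)


def write_dataset(cfg: SynthConfig, out_dir: str | Path):
    """Generate and write PNGs plus manifest.csv; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, _, manifest = generate_dataset(cfg)
    for img, image_id in zip(images, manifest["image_id"]):
        write_image(img, out_dir / f"{image_id}.png")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_feature_fixture(
    n_per_class: int = 100,
    separation: float = 5.0,
    dim: int = 2048,
    seed: int = 0,
    n_classes: int = 3,
    step_dim: int = 32,
    block_cols: int = 5,
):
    """Paired (rgb, reconstructed) class-conditional Gaussian features.

    Viewing each 2048-vector as the selector's T×D feature matrix
    (T = dim/step_dim rows of ``step_dim``), class k's mean is shifted by
    ``separation`` on a class-specific block of matrix *columns* — rgb
    classes on columns [k·w, (k+1)·w), reconstructed classes on the disjoint
    range starting at column step_dim/2.  A column block touches every
    timestep, mirroring how convolutional features spread class information
    across the whole vector rather than concentrating it in one row; the two
    streams' informative coordinates are disjoint, so fusing them genuinely
    adds information.  Unit-variance Gaussian noise everywhere.

    Returns (rgb, rec, labels) with n_classes·n_per_class rows in class order.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if dim % step_dim != 0:
        raise ValueError("dim must be a multiple of step_dim")
    if 2 * n_classes * block_cols > step_dim:
        raise ValueError("step_dim too small for disjoint informative column blocks")
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    rgb = rng.normal(0.0, 1.0, size=(n, dim))
    rec = rng.normal(0.0, 1.0, size=(n, dim))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    t_steps = dim // step_dim
    row_starts = np.arange(t_steps) * step_dim
    for k in range(n_classes):
        rows = labels == k
        cols_rgb = np.arange(k * block_cols, (k + 1) * block_cols)
        cols_rec = cols_rgb + step_dim // 2
        rgb[np.ix_(rows, (row_starts[:, None] + cols_rgb[None, :]).ravel())] += separation
        rec[np.ix_(rows, (row_starts[:, None] + cols_rec[None, :]).ravel())] += separation
    return rgb, rec, labels
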