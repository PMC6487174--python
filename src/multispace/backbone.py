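"""VGG-16-style convolutional feature extractor.

Maps a 64×64×3 patch to a 2048-dimensional feature vector: five blocks of
(2, 2, 3, 3, 3) 3×3 same-padded convolutions with (64, 128, 256, 512, 512)
filters, each block followed by 2×2 max-pooling, so a 64×64 input ends at
2×2×512 which flattens to 2048.  The stock fully connected layers are
dropped — the flattened final pooled maps *are* the features.

The network is a fixed (untrained) extractor.  Weights come either from a
``.npz`` file (pluggable pretrained weights) or from a seeded He-normal
initialization; there is no training path, so the forward pass is written
directly in numpy via im2col + BLAS matmul.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: (filters, conv layers) per block — the standard VGG-16 convolutional trunk.
VGG16_BLOCKS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

FEATURE_DIM = 2048


class PretrainedWeightsUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    """Configuration of the feature extractor.

    weights_source : "seeded_random" (He-normal init from ``seed``),
        "imagenet_pretrained" (requires ``weights_path`` pointing to a .npz
        of conv kernels/biases), and inputs are scaled to [0, 1] either way.
    batch_size : internal chunk size for the im2col forward pass; it bounds
        memory only and does not affect the output.
    """

    input_size: int = 64
    weights_source: str = "seeded_random"
    seed: int = 0
    weights_path: str | None = None
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.weights_source not in ("seeded_random", "imagenet_pretrained"):
            raise ValueError(f"unknown weights_source {self.weights_source!r}")
        if self.input_size % 2**5 != 0 or self.input_size <= 0:
            raise ValueError("input_size must be a positive multiple of 32 (five 2x2 pools)")


def expected_shape_trace(input_size: int = 64) -> list[tuple[str, tuple[int, int, int]]]:
    """Per-layer output shapes (H, W, C) of the architecture, for auditing."""
    trace: list[tuple[str, tuple[int, int, int]]] = [("input", (input_size, input_size, 3))]
    size, conv_idx = input_size, 0
    for block, (filters, n_layers) in enumerate(VGG16_BLOCKS, start=1):
        for _ in range(n_layers):
            conv_idx += 1
            trace.append((f"conv{conv_idx}", (size, size, filters)))
        size //= 2
        trace.append((f"max_pool{block}", (size, size, filters)))
    return trace


@dataclass
class Backbone:
    config: BackboneConfig
    weights: list[np.ndarray] = field(repr=False)  # each (3, 3, C_in, C_out), float32
    biases: list[np.ndarray] = field(repr=False)  # each (C_out,), float32

    @property
    def feature_dim(self) -> int:
        size = self.config.input_size // 2 ** len(VGG16_BLOCKS)
        return size * size * VGG16_BLOCKS[-1][0]


def _layer_channels() -> list[tuple[int, int]]:
    pairs, c_in = [], 3
    for filters, n_layers in VGG16_BLOCKS:
        for _ in range(n_layers):
            pairs.append((c_in, filters))
            c_in = filters
    return pairs


def build_backbone(cfg: BackboneConfig) -> Backbone:
    """Instantiate the extractor with seeded-random or file-loaded weights."""
    if cfg.weights_source == "imagenet_pretrained":
        if cfg.weights_path is None or not Path(cfg.weights_path).exists():
            raise PretrainedWeightsUnavailableError(
                "pretrained weights are not bundled; supply weights_path pointing to a "
                ".npz of conv kernels (w0..w12) and biases (b0..b12), or use "
                "weights_source='seeded_random' for fully offline operation"
            )
        data = np.load(cfg.weights_path)
        weights = [np.asarray(data[f"w{i}"], dtype=np.float32) for i in range(13)]
        biases = [np.asarray(data[f"b{i}"], dtype=np.float32) for i in range(13)]
    else:
        rng = np.random.default_rng(cfg.seed)
        weights, biases = [], []
        for c_in, c_out in _layer_channels():
            std = np.sqrt(2.0 / (9 * c_in))  # He init: fan_in = 3·3·C_in
            weights.append(rng.normal(0.0, std, size=(3, 3, c_in, c_out)).astype(np.float32))
            biases.append(np.zeros(c_out, dtype=np.float32))
    for (c_in, c_out), w in zip(_layer_channels(), weights):
        if w.shape != (3, 3, c_in, c_out):
            raise ValueError(f"conv kernel shape {w.shape} != {(3, 3, c_in, c_out)}")
    return Backbone(cfg, weights, biases)


def _conv3x3_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3×3 convolution + ReLU on an (N, H, W, C) batch."""
    n, h, wid, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wid, 9 * c)
    kernel = w.transpose(0, 1, 2, 3).reshape(9 * c, -1)
    out = cols @ kernel + b
    np.maximum(out, 0.0, out=out)
    return out.reshape(n, h, wid, -1)


def _max_pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


def _forward(backbone: Backbone, batch: np.ndarray) -> np.ndarray:
    x = batch
    layer = 0
    for _, n_layers in VGG16_BLOCKS:
        for _ in range(n_layers):
            x = _conv3x3_relu(x, backbone.weights[layer], backbone.biases[layer])
            layer += 1
        x = _max_pool2(x)
    return x.reshape(x.shape[0], -1)


def extract_features(backbone: Backbone, patches: np.ndarray) -> np.ndarray:
    """Map a batch of patches to feature vectors.

    patches : (N, s, s, 3) integer rasters in [0, 255] (or a single patch
        (s, s, 3)); s must equal the configured input size.

    Returns an (N, feature_dim) float32 array.  Patches are processed in
    fixed-size chunks, so a patch's features never depend on its batch
    neighbors.
    """
    patches = np.asarray(patches)
    single = patches.ndim == 3
    if single:
        patches = patches[None]
    s = backbone.config.input_size
    if patches.ndim != 4 or patches.shape[1:] != (s, s, 3):
        raise ValueError(f"expected patches of shape (N, {s}, {s}, 3), got {patches.shape}")
    scaled = patches.astype(np.float32) / np.float32(255.0)
    chunks = [
        _forward(backbone, scaled[i : i + backbone.config.batch_size])
        for i in range(0, len(scaled), backbone.config.batch_size)
    ]
    feats = np.concatenate(chunks, axis=0)
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite features")
    return feats[0] if single else feats


def concat_features(rgb: np.ndarray, rec: np.ndarray) -> np.ndarray:
    """Concatenate the RGB-stream and reconstruction-stream features
    (RGB first), 2048 + 2048 → 4096.  Works on single vectors or batches."""
    rgb, rec = np.asarray(rgb), np.asarray(rec)
    if rgb.shape != rec.shape or rgb.shape[-1] != FEATURE_DIM:
        raise ValueError(f"both streams must have trailing dimension {FEATURE_DIM}")
    return np.concatenate([rgb, rec], axis=-1)
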