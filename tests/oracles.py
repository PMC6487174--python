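"""Independent brute-force oracles used by the tests.

Each oracle is a deliberately slow, explicit double-loop (or step-by-step)
re-derivation of an operator, sharing no code with the implementation it
checks.
"""

import numpy as np


def sobel_magnitude_oracle(pixels: np.ndarray) -> np.ndarray:
    """Explicit 3×3 Sobel convolution with replicate padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    padded = np.pad(pixels.astype(float), 1, mode="edge")
    h, w = pixels.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            gx = (kx * win).sum()
            gy = (ky * win).sum()
            out[i, j] = np.hypot(gx, gy)
    return out


def glcm_stat_oracle(pixels: np.ndarray, levels: int, window: int, offset: tuple, stat: str) -> np.ndarray:
    """Pair-counting GLCM statistic per pixel: quantize, pad, then for every
    window enumerate all in-window pixel pairs at the offset, symmetrize,
    normalize and reduce."""
    q = (pixels.astype(np.int64) * levels) // 256
    half = window // 2
    padded = np.pad(q, half, mode="edge")
    dr, dc = offset
    h, w = pixels.shape
    out = np.zeros((h, w))
    ii, jj = np.indices((levels, levels))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + window, j : j + window]
            counts = np.zeros((levels, levels))
            for r in range(window):
                for c in range(window):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < window and 0 <= c2 < window:
                        counts[win[r, c], win[r2, c2]] += 1
            sym = counts + counts.T
            p = sym / sym.sum()
            if stat == "contrast":
                out[i, j] = (p * (ii - jj) ** 2).sum()
            elif stat == "energy":
                out[i, j] = (p**2).sum()
            else:
                out[i, j] = (p / (1.0 + np.abs(ii - jj))).sum()
    return out


def lbp_oracle(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel 8-bit code, neighbors clockwise from top-left, MSB first,
    comparison neighbor >= center, replicate borders."""
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    padded = np.pad(pixels.astype(np.int64), 1, mode="edge")
    h, w = pixels.shape
    out = np.zeros((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            code = 0
            for k, (dy, dx) in enumerate(offsets):
                if padded[1 + i + dy, 1 + j + dx] >= pixels[i, j]:
                    code |= 1 << (7 - k)
            out[i, j] = code
    return out


def lstm_oracle(params: dict, seq: np.ndarray) -> np.ndarray:
    """Step-by-step gate equations for a single sequence (T, D) -> (H,).

    i = σ(z_i), f = σ(z_f), g = tanh(z_g), o = σ(z_o);
    c ← f·c + i·g; h ← o·tanh(c); returns the final h.
    """
    h_dim = params["Wh"].shape[0]
    sigma = lambda v: 1.0 / (1.0 + np.exp(-v))
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    for t in range(seq.shape[0]):
        z = seq[t] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = sigma(z[:h_dim])
        f = sigma(z[h_dim : 2 * h_dim])
        g = np.tanh(z[2 * h_dim : 3 * h_dim])
        o = sigma(z[3 * h_dim :])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


def confusion_matrix_oracle(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    for p, t in zip(pred, truth):
        m[t, p] += 1
    return m
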