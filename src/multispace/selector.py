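"""Dual-stream LSTM feature selection and softmax classification.

Each stream (RGB features and reconstructed-image features) reshapes its
2048-dim backbone vector into a 64×32 sequence and feeds it through its own
LSTM; the final 32-dim hidden state is the *selected* feature vector — the
forget gate discards redundant coordinates, the input gate admits useful
ones.  The two 32-dim vectors are cascaded into a 64-dim vector.  Three
linear+softmax heads produce per-stream probabilities a, b and the fused
probabilities used at inference.

Training minimizes the combined cross-entropy
    L = −Σ yᵢ log aᵢ − Σ yᵢ log bᵢ + (fused cross-entropy)
by plain stochastic gradient descent with backprop through time.  The fused
head's term keeps the cascade classifier trained jointly; either per-stream
term alone can still drive the LSTMs if the other saturates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EPS = 1e-12  # floor inside logs


@dataclass(frozen=True)
class SelectorConfig:
    """seq_len·step_dim must equal the backbone feature dimension; hidden is
    the selected-feature size (32 per stream, 64 after the cascade)."""

    seq_len: int = 64
    step_dim: int = 32
    hidden: int = 32
    n_classes: int = 3
    learning_rate: float = 0.2
    iterations: int = 250  # full passes over the training set
    batch_size: int = 32
    seed: int = 0
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if self.seq_len <= 0 or self.step_dim <= 0:
            raise ValueError("seq_len and step_dim must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def feature_dim(self) -> int:
        return self.seq_len * self.step_dim


@dataclass(frozen=True)
class ClassProbabilities:
    """Per-sample softmax outputs: a (RGB stream), b (reconstruction stream),
    fused (cascade head).  Each row is a probability simplex."""

    a: np.ndarray
    b: np.ndarray
    fused: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("fused", self.fused)):
            arr = np.atleast_2d(np.asarray(v, dtype=np.float64))
            if np.any(arr < 0) or np.any(np.abs(arr.sum(axis=-1) - 1.0) > 1e-6):
                raise ValueError(f"{name} is not a valid probability simplex")


@dataclass(frozen=True)
class SelectedFeatures:
    rgb32: np.ndarray
    rec32: np.ndarray

    @property
    def fused64(self) -> np.ndarray:
        return np.concatenate([self.rgb32, self.rec32], axis=-1)


def to_sequence(v: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    """Row-major reshape of a feature vector (or batch) into T×D timesteps."""
    v = np.asarray(v)
    if v.shape[-1] != cfg.feature_dim:
        raise ValueError(f"feature length {v.shape[-1]} != seq_len*step_dim = {cfg.feature_dim}")
    return v.reshape(*v.shape[:-1], cfg.seq_len, cfg.step_dim)


def _init_lstm(rng: np.random.Generator, d: int, h: int) -> dict[str, np.ndarray]:
    scale_x, scale_h = 1.0 / np.sqrt(d), 1.0 / np.sqrt(h)
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget-gate bias, standard stabilizer
    return {
        "Wx": rng.uniform(-scale_x, scale_x, size=(d, 4 * h)),
        "Wh": rng.uniform(-scale_h, scale_h, size=(h, 4 * h)),
        "b": b,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(params: dict[str, np.ndarray], seq: np.ndarray):
    """Run the recurrence over an (N, T, D) batch; gate order is i, f, g, o.

    Returns the final hidden state (N, H) and the cache needed for BPTT.
    """
    n, t_steps, _ = seq.shape
    h_dim = params["Wh"].shape[0]
    h = np.zeros((n, h_dim))
    c = np.zeros((n, h_dim))
    cache = []
    for t in range(t_steps):
        x_t = seq[:, t, :]
        z = x_t @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim : 2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim :])
        c_next = f * c + i * g
        h_next = o * np.tanh(c_next)
        cache.append((x_t, h, c, i, f, g, o, c_next))
        h, c = h_next, c_next
    return h, cache


def _lstm_backward(params, cache, dh_last):
    """Backprop through time given the loss gradient at the final hidden state."""
    h_dim = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh, dc = dh_last, np.zeros_like(dh_last)
    dseq = []
    for x_t, h_prev, c_prev, i, f, g, o, c_next in reversed(cache):
        tc = np.tanh(c_next)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di, df, dg = dc * g, dc * c_prev, dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
        )
        grads["Wx"] += x_t.T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dseq.append(dz @ params["Wx"].T)
        dh = dz @ params["Wh"].T
        dc = dc * f
    return grads, np.stack(dseq[::-1], axis=1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def combined_loss(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> float:
    """−Σ yᵢ log aᵢ − Σ yᵢ log bᵢ for one-hot y (mean over a batch)."""
    a, b, y = np.atleast_2d(a), np.atleast_2d(b), np.atleast_2d(y)
    la = -(y * np.log(np.maximum(a, EPS))).sum(axis=-1)
    lb = -(y * np.log(np.maximum(b, EPS))).sum(axis=-1)
    return float((la + lb).mean())


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


@dataclass
class SelectorModel:
    """Trained dual-stream selector: two LSTMs plus three softmax heads.

    ``norm`` holds the per-coordinate standardization (mean/std per stream)
    fitted on the training features; backbone activations are all-positive
    with a large shared mean, and centering/scaling them is what lets the
    recurrence see between-sample variation.
    """

    config: SelectorConfig
    lstm_rgb: dict[str, np.ndarray] = field(repr=False)
    lstm_rec: dict[str, np.ndarray] = field(repr=False)
    heads: dict[str, np.ndarray] = field(repr=False)  # Wa, ba, Wb, bb, Wf, bf
    loss_trace: list[float] = field(default_factory=list, repr=False)
    norm: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def normalize(self, rgb: np.ndarray, rec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.norm:
            return rgb, rec
        return (
            (rgb - self.norm["mu_rgb"]) / self.norm["sd_rgb"],
            (rec - self.norm["mu_rec"]) / self.norm["sd_rec"],
        )

    def save(self, path: str | Path) -> None:
        arrays = {f"rgb_{k}": v for k, v in self.lstm_rgb.items()}
        arrays.update({f"rec_{k}": v for k, v in self.lstm_rec.items()})
        arrays.update({f"head_{k}": v for k, v in self.heads.items()})
        arrays.update({f"norm_{k}": v for k, v in self.norm.items()})
        arrays["loss_trace"] = np.asarray(self.loss_trace)
        cfg = self.config
        arrays["config"] = np.array(
            [cfg.seq_len, cfg.step_dim, cfg.hidden, cfg.n_classes, cfg.iterations, cfg.batch_size, cfg.seed]
        )
        arrays["config_floats"] = np.array([cfg.learning_rate, cfg.grad_clip])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SelectorModel":
        data = np.load(path)
        ints = data["config"].astype(int)
        floats = data["config_floats"]
        cfg = SelectorConfig(
            seq_len=int(ints[0]), step_dim=int(ints[1]), hidden=int(ints[2]),
            n_classes=int(ints[3]), learning_rate=float(floats[0]), iterations=int(ints[4]),
            batch_size=int(ints[5]), seed=int(ints[6]), grad_clip=float(floats[1]),
        )
        pick = lambda prefix: {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
        return cls(cfg, pick("rgb_"), pick("rec_"), pick("head_"), list(data["loss_trace"]), pick("norm_"))


def _init_model(cfg: SelectorConfig, rng: np.random.Generator) -> SelectorModel:
    h, k = cfg.hidden, cfg.n_classes
    scale = 1.0 / np.sqrt(h)
    heads = {
        "Wa": rng.uniform(-scale, scale, size=(h, k)),
        "ba": np.zeros(k),
        "Wb": rng.uniform(-scale, scale, size=(h, k)),
        "bb": np.zeros(k),
        "Wf": rng.uniform(-scale / np.sqrt(2), scale / np.sqrt(2), size=(2 * h, k)),
        "bf": np.zeros(k),
    }
    return SelectorModel(cfg, _init_lstm(rng, cfg.step_dim, h), _init_lstm(rng, cfg.step_dim, h), heads)


def lstm_select(seq: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Selected features: the final hidden state after consuming all T rows."""
    if not params or "Wx" not in params:
        raise ValueError("LSTM stream has no weights; train or seed the model first")
    seq = np.asarray(seq, dtype=np.float64)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    if seq.shape[-1] != params["Wx"].shape[0]:
        raise ValueError(f"step dimension {seq.shape[-1]} != {params['Wx'].shape[0]}")
    h, _ = _lstm_forward(params, seq)
    return h[0] if single else h


def select_features(model: SelectorModel, rgb: np.ndarray, rec: np.ndarray) -> SelectedFeatures:
    cfg = model.config
    rgb, rec = model.normalize(np.asarray(rgb, dtype=np.float64), np.asarray(rec, dtype=np.float64))
    return SelectedFeatures(
        rgb32=lstm_select(to_sequence(rgb, cfg), model.lstm_rgb),
        rec32=lstm_select(to_sequence(rec, cfg), model.lstm_rec),
    )


def classify(model: SelectorModel, f: SelectedFeatures) -> ClassProbabilities:
    """Apply the three linear+softmax heads to selected features."""
    heads = model.heads
    if not heads:
        raise ValueError("model heads are untrained")
    return ClassProbabilities(
        a=softmax(f.rgb32 @ heads["Wa"] + heads["ba"]),
        b=softmax(f.rec32 @ heads["Wb"] + heads["bb"]),
        fused=softmax(f.fused64 @ heads["Wf"] + heads["bf"]),
    )


def _clip(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def train_selector(
    rgb: np.ndarray, rec: np.ndarray, labels: np.ndarray, cfg: SelectorConfig | None = None
) -> SelectorModel:
    """Train both LSTM streams and all heads jointly by SGD.

    rgb, rec : (N, seq_len·step_dim) paired feature matrices.
    labels : (N,) integer class ids; every class in [0, n_classes) must appear.

    Returns the model with a per-epoch mean-loss trace.
    """
    cfg = cfg or SelectorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if rgb.shape != rec.shape or rgb.shape[0] != labels.shape[0]:
        raise ValueError("rgb, rec and labels must be aligned")
    present = np.unique(labels)
    missing = sorted(set(range(cfg.n_classes)) - set(present.tolist()))
    if missing:
        raise ValueError(f"classes {missing} absent from the training set")

    rng = np.random.default_rng(cfg.seed)
    model = _init_model(cfg, rng)
    model.norm = {
        "mu_rgb": rgb.mean(axis=0),
        "sd_rgb": rgb.std(axis=0) + 1e-8,
        "mu_rec": rec.mean(axis=0),
        "sd_rec": rec.std(axis=0) + 1e-8,
    }
    rgb, rec = model.normalize(rgb, rec)
    n = rgb.shape[0]
    y_all = one_hot(labels, cfg.n_classes)
    seq_rgb = to_sequence(rgb, cfg)
    seq_rec = to_sequence(rec, cfg)
    lr = cfg.learning_rate

    for _ in range(cfg.iterations):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb_rgb, xb_rec, yb = seq_rgb[idx], seq_rec[idx], y_all[idx]
            m = len(idx)

            h_rgb, cache_rgb = _lstm_forward(model.lstm_rgb, xb_rgb)
            h_rec, cache_rec = _lstm_forward(model.lstm_rec, xb_rec)
            fused = np.concatenate([h_rgb, h_rec], axis=1)
            heads = model.heads
            a = softmax(h_rgb @ heads["Wa"] + heads["ba"])
            b = softmax(h_rec @ heads["Wb"] + heads["bb"])
            p = softmax(fused @ heads["Wf"] + heads["bf"])

            fused_ce = float(-(yb * np.log(np.maximum(p, EPS))).sum(axis=-1).mean())
            loss = combined_loss(a, b, yb) + fused_ce
            epoch_loss += loss * m

            # Softmax + cross-entropy gradients (mean over the minibatch).
            da, db, dp = (a - yb) / m, (b - yb) / m, (p - yb) / m
            head_grads = {
                "Wa": h_rgb.T @ da, "ba": da.sum(axis=0),
                "Wb": h_rec.T @ db, "bb": db.sum(axis=0),
                "Wf": fused.T @ dp, "bf": dp.sum(axis=0),
            }
            dh_rgb = da @ heads["Wa"].T + dp @ heads["Wf"][: cfg.hidden].T
            dh_rec = db @ heads["Wb"].T + dp @ heads["Wf"][cfg.hidden :].T
            g_rgb, _ = _lstm_backward(model.lstm_rgb, cache_rgb, dh_rgb)
            g_rec, _ = _lstm_backward(model.lstm_rec, cache_rec, dh_rec)

            _clip(g_rgb, cfg.grad_clip)
            _clip(g_rec, cfg.grad_clip)
            _clip(head_grads, cfg.grad_clip)
            for k, g in g_rgb.items():
                model.lstm_rgb[k] -= lr * g
            for k, g in g_rec.items():
                model.lstm_rec[k] -= lr * g
            for k, g in head_grads.items():
                model.heads[k] -= lr * g
        model.loss_trace.append(epoch_loss / n)
    return model


def predict_patches(model: SelectorModel, rgb: np.ndarray, rec: np.ndarray):
    """Per-patch probabilities from all heads plus hard fused labels.

    The hard label is the argmax of the fused probabilities; exact ties go
    to the smallest class id.
    """
    feats = select_features(model, np.atleast_2d(rgb), np.atleast_2d(rec))
    probs = classify(model, feats)
    labels = np.argmax(np.atleast_2d(probs.fused), axis=-1)
    return probs, labels
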