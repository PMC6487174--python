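"""Accuracy, per-class sensitivity/specificity, and k-fold cross-validation.

ACC is the mean of the correct-prediction indicator.  For class c,
SEN(c) = correctly-predicted-c / total-c and SPE(c) = non-c predicted
non-c / total non-c.  Metrics are kept as fractions internally; multiply by
100 only at presentation.

Cross-validation folds are assigned at the *image* level: all patches of an
image share a fold, so near-identical neighboring patches never leak between
train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tiling import majority_vote


def _check_labels(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be equal-length non-empty label vectors")
    return pred, truth


def accuracy(pred, truth) -> float:
    pred, truth = _check_labels(pred, truth)
    return float((pred == truth).mean())


def sensitivity(pred, truth, c: int) -> float:
    pred, truth = _check_labels(pred, truth)
    mask = truth == c
    if not mask.any():
        raise ValueError(f"sensitivity undefined: class {c} absent from truth")
    return float((pred[mask] == c).mean())


def specificity(pred, truth, c: int) -> float:
    pred, truth = _check_labels(pred, truth)
    mask = truth != c
    if not mask.any():
        raise ValueError(f"specificity undefined: no non-{c} samples in truth")
    return float((pred[mask] != c).mean())


@dataclass
class EvaluationReport:
    """ACC plus per-class SEN/SPE, optionally with fold-wise mean ± std."""

    acc: float
    sen: dict[int, float]
    spe: dict[int, float]
    level: str = "patch"  # patch | image
    fold_mean: dict[str, float] = field(default_factory=dict)
    fold_std: dict[str, float] = field(default_factory=dict)
    n_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "acc": self.acc,
            "sen": {str(k): v for k, v in self.sen.items()},
            "spe": {str(k): v for k, v in self.spe.items()},
            "fold_mean": dict(self.fold_mean),
            "fold_std": dict(self.fold_std),
            "n_folds": self.n_folds,
        }

    def to_table(self, class_names: list[str] | None = None) -> pd.DataFrame:
        """Rows ACC / SEN(c) / SPE(c) with 'mean ± std' cells when folds exist."""
        classes = sorted(self.sen)
        names = class_names or [str(c) for c in classes]
        rows = [("ACC", "overall", self.acc, "acc")]
        rows += [("SEN", names[i], self.sen[c], f"sen_{c}") for i, c in enumerate(classes)]
        rows += [("SPE", names[i], self.spe[c], f"spe_{c}") for i, c in enumerate(classes)]
        records = []
        for index, cls, value, key in rows:
            if self.n_folds and key in self.fold_mean:
                cell = f"{self.fold_mean[key]:.4f} ± {self.fold_std[key]:.3f}"
            else:
                cell = f"{value:.4f}"
            records.append({"index": index, "class": cls, "value": cell})
        return pd.DataFrame(records)


def evaluate_labels(pred, truth, level: str = "patch") -> EvaluationReport:
    """Full report at a single level (no folds)."""
    pred, truth = _check_labels(pred, truth)
    classes = sorted(np.unique(truth).tolist())
    sen = {c: sensitivity(pred, truth, c) for c in classes}
    spe = {c: specificity(pred, truth, c) for c in classes if (truth != c).any()}
    return EvaluationReport(acc=accuracy(pred, truth), sen=sen, spe=spe, level=level)


def evaluate_images(patch_pred: pd.DataFrame, image_truth: dict[str, int]) -> EvaluationReport:
    """Aggregate patch predictions to image labels by majority vote, then score.

    patch_pred : DataFrame with columns image_id, label (one row per patch).
    image_truth : image_id → true class id.
    """
    votes, truths = [], []
    for image_id, true_label in image_truth.items():
        labels = patch_pred.loc[patch_pred["image_id"] == image_id, "label"].to_numpy()
        if labels.size == 0:
            raise ValueError(f"image {image_id!r} has no patch predictions")
        votes.append(majority_vote(labels))
        truths.append(true_label)
    return evaluate_labels(np.asarray(votes), np.asarray(truths), level="image")


def make_image_folds(image_labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold assignment over images (indices into image_labels)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(image_labels):
        idx = rng.permutation(np.flatnonzero(image_labels == c))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def cross_validate(
    rgb: np.ndarray,
    rec: np.ndarray,
    patch_labels: np.ndarray,
    patch_image_ids: np.ndarray,
    image_truth: dict[str, int],
    k: int,
    selector_cfg,
    seed: int,
) -> dict[str, EvaluationReport]:
    """Image-level stratified k-fold CV of the train→predict→vote pipeline.

    Trains a fresh selector per fold on all patches of the training images
    and evaluates on the held-out images at both patch and image level.
    Returns {"patch": report, "image": report} with fold-wise mean ± std.
    """
    from .selector import predict_patches, train_selector

    image_ids = np.asarray(sorted(image_truth))
    image_labels = np.asarray([image_truth[i] for i in image_ids])
    patch_image_ids = np.asarray(patch_image_ids)
    folds = make_image_folds(image_labels, k, seed)

    per_fold: dict[str, list[dict[str, float]]] = {"patch": [], "image": []}
    all_pred: dict[str, list[np.ndarray]] = {"patch": [], "image": []}
    all_true: dict[str, list[np.ndarray]] = {"patch": [], "image": []}
    classes = sorted(set(image_truth.values()))

    for fold_idx, test_img_idx in enumerate(folds):
        test_ids = set(image_ids[test_img_idx].tolist())
        test_mask = np.isin(patch_image_ids, list(test_ids))
        train_labels = patch_labels[~test_mask]
        missing = sorted(set(classes) - set(np.unique(train_labels).tolist()))
        if missing:
            raise ValueError(f"fold {fold_idx}: classes {missing} missing from the training split")

        model = train_selector(rgb[~test_mask], rec[~test_mask], train_labels, selector_cfg)
        _, pred = predict_patches(model, rgb[test_mask], rec[test_mask])

        patch_rep = evaluate_labels(pred, patch_labels[test_mask], level="patch")
        pred_df = pd.DataFrame({"image_id": patch_image_ids[test_mask], "label": pred})
        truth_fold = {i: image_truth[i] for i in sorted(test_ids)}
        image_rep = evaluate_images(pred_df, truth_fold)

        img_pred = np.asarray([majority_vote(pred_df.loc[pred_df["image_id"] == i, "label"].to_numpy()) for i in sorted(test_ids)])
        img_true = np.asarray([truth_fold[i] for i in sorted(test_ids)])
        all_pred["patch"].append(pred)
        all_true["patch"].append(patch_labels[test_mask])
        all_pred["image"].append(img_pred)
        all_true["image"].append(img_true)

        for level, rep in (("patch", patch_rep), ("image", image_rep)):
            metrics = {"acc": rep.acc}
            metrics.update({f"sen_{c}": v for c, v in rep.sen.items()})
            metrics.update({f"spe_{c}": v for c, v in rep.spe.items()})
            per_fold[level].append(metrics)

    reports = {}
    for level in ("patch", "image"):
        pooled_pred = np.concatenate(all_pred[level])
        pooled_true = np.concatenate(all_true[level])
        rep = evaluate_labels(pooled_pred, pooled_true, level=level)
        keys = sorted({key for fold in per_fold[level] for key in fold})
        rep.fold_mean = {key: float(np.mean([f[key] for f in per_fold[level] if key in f])) for key in keys}
        rep.fold_std = {key: float(np.std([f[key] for f in per_fold[level] if key in f])) for key in keys}
        rep.n_folds = k
        reports[level] = rep
    return reports
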