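"""End-to-end pipeline: synth → reconstruct → tile → extract → CV (train,
predict, vote, evaluate), with file-based stage handoff.

Every stage writes its artifacts under the run directory (PNG images,
CSV tables) so any stage can be rerun standalone on prior outputs; with
``resume=True`` only stages whose outputs are missing are executed.  The run
log records the config hash and all derived stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbone import BackboneConfig, build_backbone, extract_features
from .evaluation import EvaluationReport, cross_validate
from .images import ColorImage, read_image, write_image
from .selector import SelectorConfig
from .spaces import SpaceParams, reconstruct
from .synthetic import SynthConfig, generate_dataset
from .tiling import grid_manifest, probability_atlas, save_atlas_csv, tile_image


@dataclass(frozen=True)
class PipelineConfig:
    """Composite configuration; ``seed`` is propagated to every stochastic
    stage (distinct derived seeds per stage, all below 2³¹)."""

    synth: SynthConfig = field(default_factory=lambda: SynthConfig(image_size=(192, 128), n_per_class=4))
    space: SpaceParams = field(default_factory=SpaceParams)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    selector: SelectorConfig = field(default_factory=lambda: SelectorConfig(iterations=40))
    patch_size: int = 64
    cv_folds: int = 2
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        base = int(seed) % (2**31 - 10)
        return replace(
            self,
            seed=base,
            synth=replace(self.synth, seed=base),
            backbone=replace(self.backbone, seed=base + 1),
            selector=replace(self.selector, seed=base + 2),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_dict(data: dict) -> PipelineConfig:
    from .synthetic import ClassProfile, DEFAULT_PROFILES

    synth_kwargs = dict(data.get("synth", {}))
    if "image_size" in synth_kwargs:
        synth_kwargs["image_size"] = tuple(synth_kwargs["image_size"])
    if "profiles" in synth_kwargs:
        synth_kwargs["profiles"] = tuple(
            ClassProfile(**{**p, "radius_range": tuple(p["radius_range"])}) for p in synth_kwargs["profiles"]
        )
    space_kwargs = dict(data.get("space", {}))
    if "glcm_offset" in space_kwargs:
        space_kwargs["glcm_offset"] = tuple(space_kwargs["glcm_offset"])
    cfg = PipelineConfig(
        synth=SynthConfig(**synth_kwargs),
        space=SpaceParams(**space_kwargs),
        backbone=BackboneConfig(**data.get("backbone", {})),
        selector=SelectorConfig(**data.get("selector", {})),
        patch_size=int(data.get("patch_size", 64)),
        cv_folds=int(data.get("cv_folds", 2)),
        seed=int(data.get("seed", 0)),
    )
    return cfg.with_seed(cfg.seed)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _write_features_csv(path: Path, image_ids, patch_idx, feats: np.ndarray, config_hash: str) -> None:
    df = pd.DataFrame(feats, columns=[f"f{i:04d}" for i in range(feats.shape[1])])
    df.insert(0, "patch_idx", patch_idx)
    df.insert(0, "image_id", image_ids)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.8e")


def read_features_csv(path: str | Path):
    df = pd.read_csv(path, comment="#")
    cols = [c for c in df.columns if c.startswith("f")]
    return df["image_id"].to_numpy(), df["patch_idx"].to_numpy(), df[cols].to_numpy(dtype=np.float64)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, resume: bool = False) -> dict[str, EvaluationReport]:
    """Execute the full flow and return {"patch": report, "image": report}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}}

    def _stage(name, outputs, fn):
        outputs = [Path(p) for p in outputs]
        if resume and outputs and all(p.exists() for p in outputs):
            log["stages"][name] = "skipped (resume)"
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, str(exc)) from exc
        log["stages"][name] = f"{time.perf_counter() - t0:.2f}s"

    images_dir = out_dir / "images"
    recon_dir = out_dir / "reconstructed"
    manifest_path = images_dir / "manifest.csv"

    def do_synth():
        images_dir.mkdir(parents=True, exist_ok=True)
        images, _, manifest = generate_dataset(cfg.synth)
        for img, image_id in zip(images, manifest["image_id"]):
            write_image(img, images_dir / f"{image_id}.png")
        manifest.to_csv(manifest_path, index=False)

    _stage("synth", [manifest_path], do_synth)
    manifest = pd.read_csv(manifest_path)
    image_ids = manifest["image_id"].tolist()

    def do_reconstruct():
        recon_dir.mkdir(parents=True, exist_ok=True)
        for image_id in image_ids:
            img = read_image(images_dir / f"{image_id}.png")
            write_image(reconstruct(img, cfg.space), recon_dir / f"{image_id}.png")

    _stage("reconstruct", [recon_dir / f"{i}.png" for i in image_ids], do_reconstruct)

    patches_path = out_dir / "patches.csv"

    def do_tile():
        frames = []
        for image_id in image_ids:
            grid = tile_image(read_image(images_dir / f"{image_id}.png"), cfg.patch_size)
            frames.append(grid_manifest(grid, image_id))
        with open(patches_path, "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)

    _stage("tile", [patches_path], do_tile)

    feat_paths = {s: out_dir / f"features_{s}.csv" for s in ("rgb", "rec")}

    def do_extract():
        bb = build_backbone(cfg.backbone)
        for stream, src_dir in (("rgb", images_dir), ("rec", recon_dir)):
            ids, idxs, rows = [], [], []
            for image_id in image_ids:
                space = "rgb" if stream == "rgb" else "reconstructed"
                grid = tile_image(read_image(src_dir / f"{image_id}.png", color_space=space), cfg.patch_size)
                rows.append(extract_features(bb, grid.patches))
                ids.extend([image_id] * len(grid))
                idxs.extend(range(len(grid)))
            _write_features_csv(feat_paths[stream], ids, idxs, np.concatenate(rows), chash)

    _stage("extract", list(feat_paths.values()), do_extract)

    report_path = out_dir / "report.json"
    preds_path = out_dir / "predictions.csv"
    reports: dict[str, EvaluationReport] = {}

    def do_evaluate():
        ids_rgb, idx_rgb, rgb = read_features_csv(feat_paths["rgb"])
        ids_rec, idx_rec, rec = read_features_csv(feat_paths["rec"])
        if not (np.array_equal(ids_rgb, ids_rec) and np.array_equal(idx_rgb, idx_rec)):
            raise ValueError("rgb/rec feature tables are misaligned")
        truth = dict(zip(manifest["image_id"], manifest["class_id"]))
        patch_labels = np.asarray([truth[i] for i in ids_rgb])
        result = cross_validate(
            rgb, rec, patch_labels, ids_rgb, truth, cfg.cv_folds, cfg.selector, cfg.seed + 3
        )
        reports.update(result)
        with open(report_path, "w") as fh:
            json.dump(
                {"config_hash": chash, **{lvl: rep.to_dict() for lvl, rep in result.items()}},
                fh, indent=2, sort_keys=True,
            )
        for lvl, rep in result.items():
            rep.to_table([p.name for p in cfg.synth.profiles]).to_csv(out_dir / f"report_{lvl}.csv", index=False)
        _write_predictions_and_atlases(cfg, out_dir, rgb, rec, patch_labels, ids_rgb, idx_rgb, truth, preds_path, chash)

    _stage("evaluate", [report_path, preds_path], do_evaluate)

    if not reports and report_path.exists():  # resume path: reload
        with open(report_path) as fh:
            saved = json.load(fh)
        for lvl in ("patch", "image"):
            d = saved[lvl]
            reports[lvl] = EvaluationReport(
                acc=d["acc"], sen={int(k): v for k, v in d["sen"].items()},
                spe={int(k): v for k, v in d["spe"].items()}, level=lvl,
                fold_mean=d["fold_mean"], fold_std=d["fold_std"], n_folds=d["n_folds"],
            )

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return reports


def _write_predictions_and_atlases(cfg, out_dir, rgb, rec, patch_labels, ids, idxs, truth, preds_path, chash):
    """Fit one model on everything and write per-patch probabilities plus a
    probability atlas per image (illustrative artifacts; the CV report above
    is the honest performance estimate)."""
    from .selector import predict_patches, train_selector
    from .tiling import PATCH_SIZE

    model = train_selector(rgb, rec, patch_labels, cfg.selector)
    probs, labels = predict_patches(model, rgb, rec)
    classes = sorted(set(truth.values()))
    frame = {"image_id": ids, "patch_idx": idxs}
    for tag, arr in (("a", probs.a), ("b", probs.b), ("p", probs.fused)):
        for c in classes:
            frame[f"{tag}_{c}"] = arr[:, c]
    frame["label"] = labels
    df = pd.DataFrame(frame)
    with open(preds_path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")

    atlas_dir = out_dir / "atlases"
    atlas_dir.mkdir(exist_ok=True)
    images_dir = out_dir / "images"
    for image_id, cls in truth.items():
        mask = df["image_id"] == image_id
        grid = tile_image(read_image(images_dir / f"{image_id}.png"), cfg.patch_size)
        atlas = probability_atlas(grid, df.loc[mask, [f"p_{c}" for c in classes]].to_numpy(), cls)
        save_atlas_csv(atlas, atlas_dir / f"{image_id}.csv")
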