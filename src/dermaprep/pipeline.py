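"""End-to-end orchestration: synth -> preprocess -> segment -> features ->
train -> eval -> explain, driven by a single YAML config.

Every artifact directory is stamped with the config hash and seed; a
completed stage (matching stamp) is skipped on re-run, and all randomness
flows from the config seed, so re-running a finished pipeline is a no-op
and two fresh runs with the same config produce byte-identical metrics.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field
from PIL import Image as PILImage

from dermaprep import classify, explain, features, preprocess, segment, synthgen
from dermaprep.backbone import TinyCNN

logger = logging.getLogger("dermaprep")

__all__ = ["RunConfig", "load_config", "run_pipeline", "make_report"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthStage(_Strict):
    n_melanoma: int = 30
    n_non_melanoma: int = 150
    with_hair: bool = True
    vignette: bool = False


class HairStage(_Strict):
    canny_low: int = 50
    canny_high: int = 150
    bright_cutoff: int = 200
    close_kernel: int = 3
    erode_kernel: int = 3
    hough_threshold: int = 20
    min_line_len: int = 10
    max_line_len: int = 200
    max_line_gap: int = 5
    dilate_radius: int = 2
    inpaint_window: int = 11


class PreprocessStage(_Strict):
    median_filter_window: int = 3
    corner_black_cutoff: int = 10
    hair: HairStage = Field(default_factory=HairStage)

    def to_config(self) -> preprocess.PreprocessConfig:
        return preprocess.PreprocessConfig(
            median_filter_window=self.median_filter_window,
            corner_black_cutoff=self.corner_black_cutoff,
            hair=preprocess.HairRemovalParams(**self.hair.model_dump()),
        )


class TrainStage(_Strict):
    lr: float = 1e-2  # from-scratch reference CNN; fine-tuning would use 1e-4
    batch_size: int = 32
    epochs: int = 30
    dropout: float = 0.5
    early_stop_patience: int = 5
    lr_decay_factor: float = 0.9
    lr_decay_every: int = 10
    weight_decay: float = 1e-5
    use_class_weights: bool = True
    augment: bool = False

    def to_config(self, seed: int) -> classify.TrainConfig:
        return classify.TrainConfig(
            lr=self.lr,
            batch_size=self.batch_size,
            epochs=self.epochs,
            dropout=self.dropout,
            early_stop_patience=self.early_stop_patience,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_every=self.lr_decay_every,
            weight_decay=self.weight_decay,
            seed=seed,
            augment=classify.AugmentConfig() if self.augment else None,
        )


class AblationStage(_Strict):
    enabled: bool = False
    seeds: list[int] = Field(default_factory=lambda: [0])


class RunConfig(_Strict):
    seed: int = 42
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    threshold_policy: str = "youden"
    synth: SynthStage = Field(default_factory=SynthStage)
    preprocess: PreprocessStage = Field(default_factory=PreprocessStage)
    train: TrainStage = Field(default_factory=TrainStage)
    ablation: AblationStage = Field(default_factory=AblationStage)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/logging excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _stamp(stage_dir: Path, cfg: RunConfig) -> Path:
    return stage_dir / f".done-{cfg.config_hash()}-{cfg.seed}"


def _stage_done(stage_dir: Path, cfg: RunConfig) -> bool:
    return _stamp(stage_dir, cfg).exists()


def _mark_done(stage_dir: Path, cfg: RunConfig) -> None:
    _stamp(stage_dir, cfg).touch()


def _log(stage: str, cfg: RunConfig, **extra) -> None:
    logger.info(json.dumps({"stage": stage, "seed": cfg.seed,
                            "config_hash": cfg.config_hash(), **extra}))


def _load_labels(data_dir: Path) -> list[tuple[str, int]]:
    rows = []
    with open(data_dir / "labels.csv") as fh:
        for row in csv.DictReader(fh):
            rows.append((row["filename"], int(row["label"])))
    return rows


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Raises on any stage failure (after writing a structured log entry);
    completed stages with a matching config stamp are skipped.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    data_dir = out / "data"
    if not _stage_done(data_dir, cfg):
        synthgen.generate_dataset(
            (cfg.synth.n_melanoma, cfg.synth.n_non_melanoma),
            seed=cfg.seed,
            out_dir=data_dir,
            vignette=cfg.synth.vignette,
            with_hair=cfg.synth.with_hair,
        )
        _mark_done(data_dir, cfg)
    _log("synth", cfg, n=cfg.synth.n_melanoma + cfg.synth.n_non_melanoma)

    labels = _load_labels(data_dir)
    pre_dir = out / "preproc"
    pcfg = cfg.preprocess.to_config()
    if not _stage_done(pre_dir, cfg):
        pre_dir.mkdir(exist_ok=True)
        for name, _ in labels:
            img = np.asarray(PILImage.open(data_dir / name).convert("RGB"))
            PILImage.fromarray(preprocess.preprocess_pipeline(img, pcfg)).save(
                pre_dir / name
            )
        _mark_done(pre_dir, cfg)
    _log("preprocess", cfg)

    seg_dir = out / "seg"
    if not _stage_done(seg_dir, cfg):
        seg_dir.mkdir(exist_ok=True)
        with open(seg_dir / "bboxes.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "x", "y", "w", "h"])
            for name, _ in labels:
                img = np.asarray(PILImage.open(pre_dir / name))
                try:
                    res = segment.segment_lesion(img)
                except ValueError:
                    writer.writerow([name, "", "", "", ""])
                    continue
                PILImage.fromarray(res.mask.astype(np.uint8) * 255).save(
                    seg_dir / f"mask_{name}"
                )
                writer.writerow([name, *res.bbox])
        _mark_done(seg_dir, cfg)
    _log("segment", cfg)

    feat_path = out / "features.csv"
    if not feat_path.exists() or not _stage_done(out, cfg):
        with open(feat_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["filename", "contrast", "correlation", "energy",
                 "homogeneity", "area", "perimeter", "aspect"]
            )
            for name, _ in labels:
                img = np.asarray(PILImage.open(pre_dir / name))
                gray = preprocess.to_grayscale(img)
                tex = features.glcm_features(gray)
                try:
                    res = segment.segment_lesion(img)
                    shape = features.shape_features(res.largest_contour, res.bbox)
                except ValueError:
                    shape = (0.0, 0.0, 1.0)
                writer.writerow([name, *tex, *shape])
    _log("features", cfg)

    # train / eval
    metrics_path = out / "metrics.json"
    model_dir = out / "model"
    if not _stage_done(model_dir, cfg):
        model_dir.mkdir(exist_ok=True)
        items = [(str(pre_dir / name), lbl) for name, lbl in labels]
        dataset = classify.LabeledDataset(items)
        train_ds, val_ds, test_ds = classify.stratified_split(dataset, seed=cfg.seed)
        weights = (
            classify.compute_class_weights(dataset.class_counts())
            if cfg.train.use_class_weights
            else None
        )
        backbone = TinyCNN(seed=cfg.seed)
        tcfg = cfg.train.to_config(cfg.seed)
        backbone, history = classify.train_classifier(
            train_ds, val_ds, backbone, tcfg, weights
        )
        np.savez(model_dir / "tinycnn.npz", **backbone.get_state())
        val_probs, _ = backbone.forward(backbone.prepare(val_ds.images()))
        threshold = classify.select_threshold(
            val_probs, val_ds.labels, policy=cfg.threshold_policy
        )
        test_probs, _ = backbone.forward(backbone.prepare(test_ds.images()))
        m = classify.evaluate(test_probs, test_ds.labels, threshold)
        order = np.argsort(-test_probs, kind="stable")
        with open(out / "roc.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "fpr", "tpr"])
            y = test_ds.labels[order]
            n_pos = max(int(y.sum()), 1)
            n_neg = max(int((1 - y).sum()), 1)
            tp = fp = 0
            for i in order:
                if test_ds.labels[i] == 1:
                    tp += 1
                else:
                    fp += 1
                writer.writerow(
                    [f"{test_probs[i]:.6f}", f"{fp / n_neg:.6f}", f"{tp / n_pos:.6f}"]
                )
        payload = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "threshold": round(float(threshold), 6),
            "epochs_run": history["stopped_epoch"],
            "best_epoch": history["best_epoch"],
            "metrics": {
                k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in m.as_dict().items()
            },
        }
        metrics_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        _mark_done(model_dir, cfg)
    _log("train_eval", cfg)

    # explain: overlays for a few test-like images
    exp_dir = out / "explain"
    if not _stage_done(exp_dir, cfg):
        exp_dir.mkdir(exist_ok=True)
        state = dict(np.load(model_dir / "tinycnn.npz"))
        backbone = TinyCNN(seed=cfg.seed)
        backbone.set_state(state)
        for name, _ in labels[: min(6, len(labels))]:
            img = np.asarray(PILImage.open(pre_dir / name))
            cam = explain.grad_cam(backbone, img, class_index=1)
            PILImage.fromarray(explain.overlay(img, cam, alpha=0.4)).save(
                exp_dir / f"cam_{name}"
            )
        _mark_done(exp_dir, cfg)
    _log("explain", cfg)

    if cfg.ablation.enabled:
        abl_path = out / "ablation.csv"
        if not abl_path.exists():
            items = [(str(pre_dir / name), lbl) for name, lbl in labels]
            dataset = classify.LabeledDataset(items)
            report = classify.ablation_weighted_vs_unweighted(
                dataset,
                backbone_factory=lambda s: TinyCNN(seed=s),
                cfg=cfg.train.to_config(cfg.seed),
                seeds=cfg.ablation.seeds,
            )
            with open(abl_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["arm", "class", "precision", "recall", "f1", "auc"])
                for arm in ("weighted", "unweighted"):
                    for cls in ("melanoma", "non_melanoma"):
                        row = report[f"mean_{arm}_{cls}"]
                        writer.writerow(
                            [arm, cls] + [f"{row[m]:.6f}" for m in
                                          ("precision", "recall", "f1", "auc")]
                        )
        _log("ablation", cfg)

    return out


def make_report(run_dir: str | Path) -> Path:
    """Render a Markdown report (metric table, ablation rows, ROC sidecar)."""
    run = Path(run_dir)
    missing = [
        str(p) for p in (run / "metrics.json", run / "roc.csv") if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    payload = json.loads((run / "metrics.json").read_text())
    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{payload['config_hash']}`",
        f"- seed: {payload['seed']}",
        f"- decision threshold: {payload['threshold']}",
        "",
        "## Test metrics",
        "",
        "| metric | value |",
        "| --- | --- |",
    ]
    for k, v in sorted(payload["metrics"].items()):
        lines.append(f"| {k} | {v} |")
    abl = run / "ablation.csv"
    if abl.exists():
        lines += ["", "## Class-weighting ablation", ""]
        with open(abl) as fh:
            rows = list(csv.reader(fh))
        lines.append("| " + " | ".join(rows[0]) + " |")
        lines.append("|" + "---|" * len(rows[0]))
        for row in rows[1:]:
            lines.append("| " + " | ".join(row) + " |")
    lines += ["", "ROC coordinates: see `roc.csv`.", ""]
    report = run / "report.md"
    report.write_text("\n".join(lines))
    return report
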