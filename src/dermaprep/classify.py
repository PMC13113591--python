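"""Class-imbalance-aware binary classification scaffolding.

Melanoma screening data are strongly imbalanced (the study composition
this emulates is 200 melanoma vs. 1000 non-melanoma). The loss is a
weighted binary cross-entropy with inverse-frequency class weights

    w_c = N / (C * n_c)

so a 200/1000 split gives w_mel = 3.0 and w_nmsc = 0.6; with balanced
classes all weights are 1 and the loss reduces to plain BCE. Melanoma is
the positive class in every derived metric. AUC is computed as the
Mann-Whitney rank statistic P(score+ > score-) + 0.5 P(tie), which equals
trapezoidal integration of the ROC curve.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Mapping, Sequence

import numpy as np
from skimage import transform as sk_transform

from dermaprep.backbone import Adam, TinyCNN

__all__ = [
    "ClassWeightSpec",
    "LabeledDataset",
    "AugmentConfig",
    "TrainConfig",
    "Metrics",
    "EarlyStopper",
    "compute_class_weights",
    "weighted_bce",
    "stratified_split",
    "augment",
    "train_classifier",
    "evaluate",
    "roc_auc",
    "select_threshold",
    "ablation_weighted_vs_unweighted",
]

_EPS = 1e-7


@dataclass(frozen=True)
class ClassWeightSpec:
    """Inverse-frequency class weights w_c = N / (C * n_c)."""

    N: int
    C: int
    n_c: dict[Hashable, int]
    w_c: dict[Hashable, float]

    def weight_of(self, label: Hashable) -> float:
        return self.w_c[label]


@dataclass
class LabeledDataset:
    """Pairs of (image or image ref, binary label); 1 = melanoma."""

    items: list[tuple[object, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lbl for _, lbl in self.items], dtype=int)

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {1: int((labels == 1).sum()), 0: int((labels == 0).sum())}

    def images(self) -> list[np.ndarray]:
        out = []
        for ref, _ in self.items:
            if isinstance(ref, np.ndarray):
                out.append(ref)
            else:
                from PIL import Image as PILImage

                out.append(np.asarray(PILImage.open(ref).convert("RGB")))
        return out


def compute_class_weights(n_c: Mapping[Hashable, int]) -> ClassWeightSpec:
    """Exact inverse-frequency weights from per-class sample counts.

    >>> compute_class_weights({"MEL": 200, "NMSC": 1000}).w_c
    {'MEL': 3.0, 'NMSC': 0.6}
    """
    if not n_c:
        raise ValueError("need at least one class")
    if any(v < 1 for v in n_c.values()):
        raise ValueError("every class count must be >= 1")
    N = sum(n_c.values())
    C = len(n_c)
    weights = {k: float(Fraction(N, C * v)) for k, v in n_c.items()}
    return ClassWeightSpec(N=N, C=C, n_c=dict(n_c), w_c=weights)


def _sample_weights(
    y: np.ndarray, w: ClassWeightSpec | Mapping[Hashable, float] | None
) -> np.ndarray:
    if w is None:
        return np.ones(len(y))
    mapping = w.w_c if isinstance(w, ClassWeightSpec) else w
    return np.array([mapping[int(yi)] for yi in y], dtype=float)


def weighted_bce(
    y: Sequence[int] | np.ndarray,
    y_hat: Sequence[float] | np.ndarray,
    w: ClassWeightSpec | Mapping[Hashable, float] | None = None,
) -> float:
    """Weighted binary cross-entropy; unit weights give plain BCE.

    L = -(1/N) sum_i w_{y_i} [y_i log p_i + (1 - y_i) log(1 - p_i)],
    with predictions clipped to [1e-7, 1 - 1e-7].
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), _EPS, 1.0 - _EPS)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have the same length")
    sw = _sample_weights(y.astype(int), w)
    terms = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-(sw * terms).mean())


def stratified_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Deterministic per-class shuffle-and-slice into train/val/test.

    Per class, round(f_val * n) samples go to validation and
    round(f_test * n) to test (round-half-to-even), the remainder to
    train, so every split preserves the global class ratio.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    _, f_val, f_test = fractions
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    labels = dataset.labels
    for cls in sorted(set(labels.tolist())):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 3:
            raise ValueError(f"class {cls} has fewer than 3 samples")
        idx = idx[rng.permutation(idx.size)]
        n_val = round(f_val * idx.size)
        n_test = round(f_test * idx.size)
        val.extend(dataset.items[i] for i in idx[:n_val])
        test.extend(dataset.items[i] for i in idx[n_val : n_val + n_test])
        train.extend(dataset.items[i] for i in idx[n_val + n_test :])
    return LabeledDataset(train), LabeledDataset(val), LabeledDataset(test)


@dataclass(frozen=True)
class AugmentConfig:
    """Training-split augmentation: rotation -> flips -> zoom -> brightness."""

    rotation_deg: float = 20.0
    hflip: bool = True
    vflip: bool = True
    zoom_range: tuple[float, float] = (0.9, 1.1)
    brightness_range: tuple[float, float] = (0.8, 1.2)


def _zoom(img: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError("zoom factor must be positive")
    if factor == 1.0:
        return img
    h, w = img.shape[:2]
    if factor > 1.0:  # zoom in: central crop, resize back
        ch, cw = max(int(round(h / factor)), 1), max(int(round(w / factor)), 1)
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        crop = img[r0 : r0 + ch, c0 : c0 + cw]
        out = sk_transform.resize(
            crop.astype(np.float64), (h, w) + img.shape[2:], order=1,
            mode="edge", anti_aliasing=False, preserve_range=True,
        )
        return np.clip(out, 0, 255).round().astype(img.dtype)
    # zoom out: shrink, pad with edge values
    sh, sw = max(int(round(h * factor)), 1), max(int(round(w * factor)), 1)
    small = sk_transform.resize(
        img.astype(np.float64), (sh, sw) + img.shape[2:], order=1,
        mode="edge", anti_aliasing=True, preserve_range=True,
    )
    small = np.clip(small, 0, 255).round().astype(img.dtype)
    pr, pc = h - sh, w - sw
    pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)) + ((0, 0),) * (img.ndim - 2)
    return np.pad(small, pad, mode="edge")


def augment(img: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Seeded augmentation of one training image; dims are unchanged.

    With rotation 0, flips off, zoom (1, 1) and brightness (1, 1) this is
    the identity.
    """
    rng = np.random.default_rng(seed)
    out = img
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if angle != 0.0:
        rot = sk_transform.rotate(
            out.astype(np.float64), angle, mode="edge", order=1, preserve_range=True
        )
        out = np.clip(rot, 0, 255).round().astype(img.dtype)
    if cfg.hflip and rng.uniform() < 0.5:
        out = out[:, ::-1]
    if cfg.vflip and rng.uniform() < 0.5:
        out = out[::-1]
    factor = rng.uniform(*cfg.zoom_range)
    out = _zoom(out, factor)
    bright = rng.uniform(*cfg.brightness_range)
    if bright != 1.0:
        out = np.clip(out.astype(np.float64) * bright, 0, 255).round().astype(img.dtype)
    return np.ascontiguousarray(out)


@dataclass
class TrainConfig:
    """Training configuration (Adam, early stopping, step LR decay)."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 50
    dropout: float = 0.5
    early_stop_patience: int = 5
    lr_decay_factor: float = 0.9
    lr_decay_every: int = 10
    seed: int = 42
    augment: AugmentConfig | None = None


class EarlyStopper:
    """Stop when the monitored loss has not improved for `patience`
    consecutive epochs."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.stale = 0
        self.best_epoch = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    """Step-decayed learning rate for 1-based epoch numbers."""
    return cfg.lr * cfg.lr_decay_factor ** ((epoch - 1) // cfg.lr_decay_every)


def train_classifier(
    train: LabeledDataset,
    val: LabeledDataset,
    backbone: TinyCNN,
    cfg: TrainConfig | None = None,
    weights: ClassWeightSpec | Mapping[Hashable, float] | None = None,
) -> tuple[TinyCNN, dict]:
    """Minimize weighted BCE with Adam; return best-val-loss checkpoint.

    Per-epoch history records train/val loss, train accuracy and the
    learning rate actually applied. Early stopping monitors validation
    loss with the configured patience; the returned backbone carries the
    parameters of the best validation epoch.
    """
    cfg = cfg or TrainConfig()
    train_refs = set(id(r) for r, _ in train.items)
    if any(id(r) in train_refs for r, _ in val.items):
        raise ValueError("train and validation splits must be disjoint")
    rng = np.random.default_rng(cfg.seed)
    backbone.dropout = cfg.dropout
    opt = Adam(
        backbone,
        lr=cfg.lr,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    y_train = train.labels.astype(float)
    y_val = val.labels.astype(float)
    raw_train = train.images()
    x_train = backbone.prepare(raw_train) if cfg.augment is None else None
    x_val = backbone.prepare(val.images())
    sw_train = _sample_weights(train.labels, weights)

    stopper = EarlyStopper(cfg.early_stop_patience)
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "lr": [], "train_acc": []}
    best_state = backbone.get_state()
    n = len(train)
    for epoch in range(1, cfg.epochs + 1):
        lr = _epoch_lr(cfg, epoch)
        opt.lr = lr
        order = rng.permutation(n)
        if cfg.augment is not None:
            aug_seeds = rng.integers(0, 2**31 - 1, size=n)
            epoch_imgs = [
                augment(raw_train[i], cfg.augment, int(aug_seeds[i])) for i in range(n)
            ]
            x_epoch = backbone.prepare(epoch_imgs)
        else:
            x_epoch = x_train
        epoch_losses, epoch_correct = [], 0
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb, yb, wb = x_epoch[idx], y_train[idx], sw_train[idx]
            probs, _ = backbone.forward(xb, train=True, rng=rng)
            p = np.clip(probs, _EPS, 1.0 - _EPS)
            loss = float(-(wb * (yb * np.log(p) + (1 - yb) * np.log(1 - p))).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr}, batch start {b0})"
                )
            dlogits = wb * (p - yb) / len(yb)
            grads = backbone.backward(dlogits)
            opt.step(grads)
            epoch_losses.append(loss)
            epoch_correct += int(((probs >= 0.5) == (yb >= 0.5)).sum())
        val_probs, _ = backbone.forward(x_val, train=False)
        val_loss = weighted_bce(y_val, val_probs, weights)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        history["train_acc"].append(epoch_correct / n)
        improved = val_loss < stopper.best
        should_stop = stopper.update(val_loss, epoch)
        if improved:
            best_state = backbone.get_state()
        if should_stop:
            break
    backbone.set_state(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = len(history["val_loss"])
    return backbone, history


@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
        }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney rank statistic.

    P(score+ > score-) + 0.5 * P(tie); equal to trapezoidal integration
    of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> Metrics:
    """Confusion counts at `threshold` (positive = score >= threshold)
    plus accuracy/precision/recall/F1 and threshold-free AUC.

    With single-class labels the AUC is undefined and reported as None.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    try:
        auc = roc_auc(scores, labels)
    except ValueError:
        auc = None
    return Metrics(tp, fp, tn, fn, acc, prec, rec, f1, auc)


def select_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    policy: str = "youden",
    specificity: float | None = None,
) -> float:
    """Pick a decision threshold from validation scores.

    ``youden`` maximizes TPR - FPR (ties resolved toward the lower
    threshold, favouring sensitivity). ``max_sensitivity_at_specificity``
    returns the lowest threshold whose specificity reaches the target,
    which maximizes recall among those thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required to select a threshold")
    uniq = np.unique(scores)
    candidates = [float(uniq[0]) - 1e-6]
    candidates += [float((a + b) / 2.0) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates.append(float(uniq[-1]) + 1e-6)
    if neg.max() < pos.min():  # perfectly separated: midpoint of the gap
        gap_mid = float((neg.max() + pos.min()) / 2.0)
        if policy == "youden":
            return gap_mid
    if policy == "youden":
        best_t, best_j = None, -np.inf
        for t in candidates:
            tpr = float((pos >= t).mean())
            fpr = float((neg >= t).mean())
            j = tpr - fpr
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        return float(best_t)
    if policy == "max_sensitivity_at_specificity":
        if specificity is None:
            raise ValueError("specificity target required for this policy")
        feasible = [
            t for t in candidates if float((neg < t).mean()) >= specificity - 1e-12
        ]
        if not feasible:
            achievable = float((neg < candidates[-1]).mean())
            raise ValueError(
                f"specificity {specificity} unattainable; achievable range "
                f"is [0, {achievable}]"
            )
        return float(min(feasible))
    raise ValueError(f"unknown policy: {policy!r}")


def _per_class_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    mel = evaluate(scores, labels, threshold)
    nonmel = evaluate(1.0 - scores, 1 - labels, 1.0 - threshold + 1e-12)
    return {
        "melanoma": {
            "precision": mel.precision, "recall": mel.recall,
            "f1": mel.f1, "auc": mel.auc,
        },
        "non_melanoma": {
            "precision": nonmel.precision, "recall": nonmel.recall,
            "f1": nonmel.f1, "auc": nonmel.auc,
        },
    }


def ablation_weighted_vs_unweighted(
    dataset: LabeledDataset,
    backbone_factory,
    cfg: TrainConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> dict:
    """Paired comparison of inverse-frequency vs. unit class weights.

    For each seed the dataset is stratified-split and two identically
    initialized models are trained, one with w_c = N/(C n_c) and one with
    all-ones weights; per-class precision/recall/F1/AUC on the test split
    are reported per arm, plus cross-seed means.
    """
    cfg = cfg or TrainConfig()
    counts = dataset.class_counts()
    ratio = max(counts.values()) / max(min(counts.values()), 1)
    weights = compute_class_weights(counts)
    runs = []
    for seed in seeds:
        train, val, test = stratified_split(dataset, seed=seed)
        y_test = test.labels
        x_test = None
        arms = {}
        for arm, w in (("weighted", weights), ("unweighted", {0: 1.0, 1: 1.0})):
            run_cfg = dataclasses.replace(cfg, seed=int(seed))
            backbone = backbone_factory(int(seed))
            backbone, history = train_classifier(train, val, backbone, run_cfg, w)
            if x_test is None:
                x_test = backbone.prepare(test.images())
            probs, _ = backbone.forward(x_test, train=False)
            arms[arm] = _per_class_metrics(probs, y_test, 0.5)
            arms[arm]["epochs_run"] = history["stopped_epoch"]
        runs.append({"seed": int(seed), **arms})
    report = {
        "class_counts": counts,
        "imbalance_ratio": ratio,
        "weights": {str(k): v for k, v in weights.w_c.items()},
        "seeds": [int(s) for s in seeds],
        "runs": runs,
    }
    for arm in ("weighted", "unweighted"):
        for cls in ("melanoma", "non_melanoma"):
            report[f"mean_{arm}_{cls}"] = {
                m: float(np.mean([r[arm][cls][m] for r in runs if r[arm][cls][m] is not None]))
                for m in ("precision", "recall", "f1", "auc")
            }
    return report
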