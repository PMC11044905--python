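"""Classification harness: fine-tuning, metrics, cross-validation, ablations.

Protocol: samples are split 8:2 into train and inference sets realized as
5 stratified folds (each fold in turn is the 20% inference set); training
uses Adam at learning rate 0.001 and halts when the monitored accuracy
stops improving (early stopping with configurable patience). Metrics are
accuracy, the 3x3 confusion matrix and per-class precision/recall/F1.
Traditional baselines (decision tree, 25-tree random forest, 5-NN) are
evaluated under the identical fold protocol on pooled-and-flattened image
features.

The trainable model is the numpy :class:`~nirsgait.nn.ToyCNN`; the named
backbone architectures participate through head adaptation and parameter
accounting (:mod:`nirsgait.architectures`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from . import imaging
from .architectures import adapt_head
from .nn import Adam, ToyCNN, softmax_cross_entropy

LABELS = ("STW", "DTW", "STA")

CONDITION_PAIRS = (("STW", "DTW"), ("STW", "STA"), ("DTW", "STA"))


@dataclass
class ModelSpec:
    architecture: str = "toy_cnn"
    pretrained: bool = False
    n_classes: int = 3
    covariate_fusion: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 16
    max_epochs: int = 60
    patience: int = 10  # epochs without improvement before stopping
    folds: int = 5
    seed: int = 0
    normalize: bool = True  # per-channel z-score with training-split stats
    head_only: bool = False  # fine-tune only the classifier head
    # early-stopping monitor: 0 monitors training accuracy (the protocol's
    # literal reading, uses the full training split); > 0 carves an inner
    # stratified validation split of this fraction out of the training data.
    # The inference fold is never used for model selection.
    val_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class BaselineConfig:
    rf_trees: int = 25
    knn_k: int = 5
    feature_mode: str = "pooled"  # "pooled" (3x16x28 averages) | "flat"

    def __post_init__(self) -> None:
        if self.rf_trees < 1 or self.knn_k < 1:
            raise ValueError("n_trees and k must be >= 1")


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray  # rows = true, columns = predicted
    labels: tuple
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined: tuple = ()  # classes whose precision had a zero denominator

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "undefined": list(self.undefined),
        }


@dataclass
class CVReport:
    train_acc: np.ndarray  # per fold
    infer_acc: np.ndarray
    fold_reports: list
    fold_assignment: np.ndarray  # fold index of each sample

    @property
    def train_mean(self) -> float:
        return float(self.train_acc.mean())

    @property
    def train_sd(self) -> float:
        return float(self.train_acc.std(ddof=1))

    @property
    def infer_mean(self) -> float:
        return float(self.infer_acc.mean())

    @property
    def infer_sd(self) -> float:
        return float(self.infer_acc.std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "train_acc": self.train_acc.tolist(),
            "infer_acc": self.infer_acc.tolist(),
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "infer_mean": self.infer_mean,
            "infer_sd": self.infer_sd,
        }


def evaluate(y_true: np.ndarray, y_pred: np.ndarray, labels: tuple = LABELS) -> EvalReport:
    """Multi-class metrics from labels (precision_c = diagonal / column sum)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty set")
    k = len(labels)
    index = {c: i for i, c in enumerate(labels)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    col = conf.sum(axis=0)
    row = conf.sum(axis=1)
    diag = np.diag(conf).astype(float)
    undefined = tuple(labels[i] for i in range(k) if col[i] == 0)
    precision = np.divide(diag, col, out=np.zeros(k), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros(k), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(k), where=pr > 0)
    accuracy = diag.sum() / conf.sum()
    # conservation invariants, checked on every call
    assert conf.sum() == y_true.size
    assert np.isclose(accuracy, np.trace(conf) / conf.sum())
    return EvalReport(float(accuracy), conf, tuple(labels), precision, recall, f1, undefined)


# ---------------------------------------------------------------------------
# fine-tuning


def finetune(
    model: ToyCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cov_train: np.ndarray | None = None,
    cov_val: np.ndarray | None = None,
) -> dict:
    """Train with Adam + early stopping; returns the per-epoch history.

    ``y`` are integer class indices. The monitored accuracy is the
    validation accuracy when a validation set is given, else the training
    accuracy. Training stops once the monitor has not improved for more
    than ``patience`` consecutive epochs (patience 0 stops at the first
    non-improving epoch); the best-epoch weights are restored.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels must cover at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.lr)
    head_keys = ("W3", "b3")
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_monitor, best_weights, best_epoch, since_best = -np.inf, model.get_weights(), -1, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            cov = cov_train[idx] if cov_train is not None else None
            logits, cache = model.forward(x_train[idx], cov)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            grads = model.backward(cache, dlogits)
            if cfg.head_only:
                grads = {k: v for k, v in grads.items() if k in head_keys}
            opt.step(model.params, grads)
            losses.append(loss)
        train_acc = float((model.predict(x_train, cov_train) == y_train).mean())
        if x_val is not None:
            val_acc = float((model.predict(x_val, cov_val) == np.asarray(y_val)).mean())
        else:
            val_acc = np.nan
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        monitor = val_acc if x_val is not None else train_acc
        if monitor > best_monitor:
            best_monitor, best_weights, best_epoch, since_best = (
                monitor, model.get_weights(), epoch, 0,
            )
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["n_epochs"] = len(history["train_loss"])
    return history


# ---------------------------------------------------------------------------
# dataset helpers


def encode_labels(labels: np.ndarray, classes: tuple) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    return np.asarray([index[l] for l in labels], dtype=int)


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = images.mean(axis=(0, 2, 3), keepdims=True)
    sd = images.std(axis=(0, 2, 3), keepdims=True)
    return mean, np.where(sd > 0, sd, 1.0)


def normalize_images(images: np.ndarray, stats: tuple) -> np.ndarray:
    mean, sd = stats
    return ((images - mean) / sd).astype(np.float32)


def covariates_from_meta(meta: list) -> np.ndarray:
    """(gender, cognitive score) per sample; gender coded F=0, M=1."""
    rows = []
    for m in meta:
        rows.append([1.0 if m.get("gender") == "M" else 0.0,
                     float(m.get("cognitive_score", 0.0))])
    return np.asarray(rows)


def _standardize_covs(train: np.ndarray, other: np.ndarray) -> tuple:
    mean, sd = train.mean(axis=0), train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (other - mean) / sd


# ---------------------------------------------------------------------------
# cross-validation


def _fit_eval_fold(images, y, classes, train_idx, test_idx, spec, cfg, covs):
    # the early-stopping monitor is an inner validation split carved out of
    # the training data — never the inference fold, whose accuracy would
    # otherwise be inflated by best-epoch selection
    if cfg.val_fraction > 0 and len(train_idx) >= 5 * len(classes):
        fit_idx, mon_idx = train_test_split(
            train_idx, test_size=cfg.val_fraction, random_state=cfg.seed,
            stratify=y[train_idx],
        )
    else:
        fit_idx, mon_idx = train_idx, None
    x_fit, x_test = images[fit_idx], images[test_idx]
    if cfg.normalize:
        stats = channel_stats(x_fit)
        x_fit = normalize_images(x_fit, stats)
        x_test = normalize_images(x_test, stats)
    cov_fit = cov_mon = cov_test = None
    if spec.covariate_fusion:
        cov_fit, cov_test = _standardize_covs(covs[fit_idx], covs[test_idx])
    model = adapt_head(
        spec.architecture, n_classes=len(classes), pretrained=spec.pretrained,
        covariate_fusion=spec.covariate_fusion, seed=cfg.seed,
    )
    if not isinstance(model, ToyCNN):
        raise ValueError(
            f"architecture {spec.architecture!r} is accounting-only; "
            "train with 'toy_cnn'"
        )
    x_mon = y_mon = None
    if mon_idx is not None:
        x_mon = images[mon_idx]
        if cfg.normalize:
            x_mon = normalize_images(x_mon, stats)
        y_mon = y[mon_idx]
        if spec.covariate_fusion:
            _, cov_mon = _standardize_covs(covs[fit_idx], covs[mon_idx])
    history = finetune(
        model, x_fit, y[fit_idx], cfg, x_mon, y_mon, cov_fit, cov_mon
    )
    train_acc = history["train_acc"][history["best_epoch"]]
    pred = model.predict(x_test, cov_test)
    report = evaluate(
        [classes[i] for i in y[test_idx]], [classes[i] for i in pred], classes
    )
    return train_acc, report


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
    meta: list | None = None,
) -> CVReport:
    """Stratified k-fold CV: each fold is the 20% inference set (8:2 split)."""
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    if len(images) < cfg.folds:
        raise ValueError("dataset smaller than the number of folds")
    classes = tuple(c for c in LABELS if c in set(labels)) or tuple(np.unique(labels))
    y = encode_labels(labels, classes)
    covs = covariates_from_meta(meta) if (spec.covariate_fusion and meta) else None
    if spec.covariate_fusion and covs is None:
        raise ValueError("covariate_fusion requires sample metadata")
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    assignment = np.empty(len(images), dtype=int)
    train_accs, infer_accs, reports = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(images, y)):
        assignment[test_idx] = fold
        train_acc, report = _fit_eval_fold(
            images, y, classes, train_idx, test_idx, spec, cfg, covs
        )
        train_accs.append(train_acc)
        infer_accs.append(report.accuracy)
        reports.append(report)
    return CVReport(
        np.asarray(train_accs), np.asarray(infer_accs), reports, assignment
    )


# ---------------------------------------------------------------------------
# traditional baselines


def pooled_features(images: np.ndarray, cfg: BaselineConfig | None = None) -> np.ndarray:
    """Flatten images for the traditional models.

    Default: average-pool each 3x224x224 image to 3x16x28 (voxel-resolution
    rows, 8x time pooling) and flatten to 1344 features.
    """
    cfg = cfg or BaselineConfig()
    n = len(images)
    if cfg.feature_mode == "flat":
        return images.reshape(n, -1)
    x = images.reshape(n, 3, 16, 14, 28, 8).mean(axis=(3, 5))
    return x.reshape(n, -1)


def _baseline_models(cfg: BaselineConfig, seed: int) -> dict:
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=cfg.knn_k),
    }


def train_baselines(
    images: np.ndarray,
    labels: np.ndarray,
    cfg: BaselineConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """Cross-validate the three traditional baselines; returns per-model CVReport."""
    cfg = cfg or BaselineConfig()
    train_cfg = train_cfg or TrainConfig()
    labels = np.asarray(labels)
    classes = tuple(c for c in LABELS if c in set(labels)) or tuple(np.unique(labels))
    y = encode_labels(labels, classes)
    feats = pooled_features(images, cfg)
    skf = StratifiedKFold(
        n_splits=train_cfg.folds, shuffle=True, random_state=train_cfg.seed
    )
    out = {}
    for name in _baseline_models(cfg, train_cfg.seed):
        train_accs, infer_accs, reports = [], [], []
        assignment = np.empty(len(images), dtype=int)
        for fold, (tr, te) in enumerate(skf.split(feats, y)):
            model = _baseline_models(cfg, train_cfg.seed)[name]
            model.fit(feats[tr], y[tr])
            assignment[te] = fold
            train_accs.append(float(model.score(feats[tr], y[tr])))
            pred = model.predict(feats[te])
            report = evaluate(
                [classes[i] for i in y[te]], [classes[i] for i in pred], classes
            )
            infer_accs.append(report.accuracy)
            reports.append(report)
        out[name] = CVReport(
            np.asarray(train_accs), np.asarray(infer_accs), reports, assignment
        )
    return out


# ---------------------------------------------------------------------------
# pairwise and ablations


def pairwise_classify(
    images: np.ndarray,
    labels: np.ndarray,
    pair: tuple,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
    meta: list | None = None,
) -> CVReport:
    """Two-way CV on the samples of one condition pair."""
    if tuple(sorted(pair)) not in {tuple(sorted(p)) for p in CONDITION_PAIRS}:
        raise ValueError(f"unknown condition pair {pair!r}")
    labels = np.asarray(labels)
    mask = np.isin(labels, pair)
    if len(set(labels[mask])) < 2:
        raise ValueError("both classes of the pair must be present")
    spec = replace(spec or ModelSpec(), n_classes=2)
    sub_meta = [m for m, keep in zip(meta, mask) if keep] if meta else None
    return cross_validate(images[mask], labels[mask], spec, cfg, sub_meta)


ABLATION_AXES = (
    "channel", "hemisphere", "third_kind", "pretraining", "time_mode", "resize_config",
)


def ablation_suite(
    epochs: list,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
    axes: tuple = ("channel",),
    base_resize: imaging.ResizeConfig | None = None,
    third: str = "diff",
) -> pd.DataFrame:
    """Re-encode the epochs per ablation variant and cross-validate each.

    Axes: ``channel`` (zero one of HbO2/Hb/third), ``hemisphere`` (zero
    voxels 1-8 or 9-16), ``third_kind`` (diff vs sum), ``pretraining``
    (both settings logged), ``time_mode`` (zero-padding vs interpolation),
    ``resize_config`` (the 5 row-resize configurations). Every variant
    reports mean +/- sd inference accuracy under the same fold protocol.
    """
    if not axes:
        raise ValueError("ablation axes must be non-empty")
    unknown = set(axes) - set(ABLATION_AXES)
    if unknown:
        raise ValueError(f"unknown ablation axes {sorted(unknown)}")
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    base = base_resize or imaging.ResizeConfig()

    variants: list[tuple[str, str, dict]] = [("full", "full", {})]
    for axis in axes:
        if axis == "channel":
            variants += [("channel", f"drop_{c}", {"drop": c}) for c in imaging.CHANNEL_NAMES]
        elif axis == "hemisphere":
            variants += [("hemisphere", f"drop_{h}", {"drop": h}) for h in ("left", "right")]
        elif axis == "third_kind":
            variants += [("third_kind", "sum", {"third": "sum"})]
        elif axis == "pretraining":
            variants += [("pretraining", "pretrained", {"pretrained": True}),
                         ("pretraining", "fresh", {"pretrained": False})]
        elif axis == "time_mode":
            variants += [(
                "time_mode", "interpolate",
                {"resize": replace(base, time_mode="interpolate")},
            )]
        elif axis == "resize_config":
            variants += [("resize_config", rc.name, {"resize": rc})
                         for rc in imaging.SWEEP_CONFIGS]

    rows = []
    for axis, name, opts in variants:
        resize = opts.get("resize", base)
        images, labels, meta, rejected = imaging.make_dataset(
            epochs, resize, third=opts.get("third", third), drop=opts.get("drop"),
        )
        run_spec = replace(spec, pretrained=opts.get("pretrained", spec.pretrained))
        report = cross_validate(images, labels, run_spec, cfg, meta)
        rows.append(
            {
                "axis": axis,
                "variant": name,
                "infer_mean": report.infer_mean,
                "infer_sd": report.infer_sd,
                "train_mean": report.train_mean,
                "n_samples": len(images),
                "n_rejected": rejected,
                "resize": resize.name,
                "third": opts.get("third", third),
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)
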