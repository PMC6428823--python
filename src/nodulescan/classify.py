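"""SVM nodule/non-nodule classification and the evaluation protocol.

Covers stratified train/test splitting, RBF-SVM training with train-only
feature standardization, confusion matrices, the percentage metrics
(accuracy, sensitivity, specificity), stratified k-fold cross-validation and
ROC curves.  The nodule class is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "LabeledDataset",
    "SplitSpec",
    "ConfusionMatrix",
    "SvmParams",
    "SvmModel",
    "split_dataset",
    "train_svm",
    "predict",
    "confusion",
    "metrics",
    "round_half_up",
    "kfold_cv",
    "roc_points",
    "roc_auc",
]

POSITIVE_LABEL = "nodule"
NEGATIVE_LABEL = "non_nodule"


@dataclass
class LabeledDataset:
    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # values in {nodule, non_nodule}
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be 2D with one label per row")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")
        bad = set(np.unique(self.labels)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if self.ids is None:
            self.ids = np.arange(len(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.features[idx], self.labels[idx], np.asarray(self.ids)[idx])


@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(data: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic stratified split; class balance preserved within
    rounding.  Train size is floor(n * train_fraction)."""
    idx = np.arange(len(data))
    stratify = data.labels if spec.stratified else None
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=stratify,
        shuffle=True,
    )
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split produced an empty partition")
    return data.subset(train_idx), data.subset(test_idx)


@dataclass
class SvmParams:
    kernel: str = "rbf"
    c: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)


@dataclass
class SvmModel:
    """Fitted SVM plus the train-set standardization it was fitted under."""

    svc: SVC
    feature_mean: np.ndarray
    feature_std: np.ndarray
    params: SvmParams = field(default_factory=SvmParams)

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_std


def train_svm(train: LabeledDataset, params: SvmParams | None = None, seed: int = 0) -> SvmModel:
    """Fit a maximum-margin classifier on z-scored features.

    Standardization statistics come from the training set only and are
    stored with the model, so test features are never leaked into them.
    """
    params = params or SvmParams()
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    mean = train.features.mean(axis=0)
    std = train.features.std(axis=0)
    std[std == 0] = 1.0
    y = (train.labels == POSITIVE_LABEL).astype(int)
    svc = SVC(kernel=params.kernel, C=params.c, gamma=params.gamma, random_state=seed)
    svc.fit((train.features - mean) / std, y)
    return SvmModel(svc=svc, feature_mean=mean, feature_std=std, params=params)


def predict(model: SvmModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus signed decision scores (positive score -> nodule)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != len(model.feature_mean):
        raise ValueError("feature dimension mismatch with the trained model")
    scores = model.svc.decision_function(model.standardize(features))
    labels = np.where(scores > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return labels, scores


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_labels, true_labels) -> ConfusionMatrix:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(pred) != len(true) or len(pred) == 0:
        raise ValueError("label arrays must be nonempty and equal length")
    pos_p, pos_t = pred == POSITIVE_LABEL, true == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(pos_p & pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), the reporting convention."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics(cm: ConfusionMatrix, printed_sensitivity_variant: bool = False) -> dict[str, float]:
    """Percentage accuracy, sensitivity and specificity of a 2x2 matrix.

    Sensitivity is TP/(TP+FN); ``printed_sensitivity_variant`` switches to
    TP/(TP+FP), a nonstandard variant kept only for emulation.  Undefined
    ratios (zero denominators) come back as NaN.
    """

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    sens_den = cm.tp + (cm.fp if printed_sensitivity_variant else cm.fn)
    return {
        "accuracy": pct(cm.tp + cm.tn, cm.total),
        "sensitivity": pct(cm.tp, sens_den),
        "specificity": pct(cm.tn, cm.tn + cm.fp),
    }


def kfold_cv(
    data: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    params: SvmParams | None = None,
) -> dict:
    """Stratified k-fold cross-validation; every sample is tested once.

    Returns per-fold metric dicts plus mean and std per metric.
    """
    counts = [np.sum(data.labels == lab) for lab in (POSITIVE_LABEL, NEGATIVE_LABEL)]
    if k < 2 or k > min(counts):
        raise ValueError(f"k must be in [2, {min(counts)}]")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        model = train_svm(data.subset(train_idx), params=params, seed=seed)
        test = data.subset(test_idx)
        pred, _ = predict(model, test.features)
        folds.append(metrics(confusion(pred, test.labels)))
    keys = folds[0].keys()
    return {
        "folds": folds,
        "mean": {key: float(np.mean([f[key] for f in folds])) for key in keys},
        "std": {key: float(np.std([f[key] for f in folds])) for key in keys},
    }


def roc_points(scores, true_labels) -> np.ndarray:
    """(FPR, TPR) pairs swept over the unique scores, monotone from (0, 0)
    to (1, 1)."""
    true = np.asarray(true_labels)
    y = (true == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def roc_auc(scores, true_labels) -> float:
    pts = roc_points(scores, true_labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
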