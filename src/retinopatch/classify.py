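"""Cubic-SVM classification and the two validation protocols.

The classifier is a one-vs-one support vector machine with a third-degree
polynomial kernel

    K(u, v) = (coef0 + u.v / s)^3,

inputs standardized inside the model.  Validation follows two protocols:
a single stratified 80:20 hold-out split, and stratified 10-fold
cross-validation whose out-of-fold predictions are pooled into one confusion
matrix.  Both produce the same six-metric panel: accuracy, unweighted average
recall (UAR), unweighted average precision (UAP), macro F1, Cohen's kappa,
and the geometric mean of class-wise recalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ContractError, ParameterError

METRIC_NAMES = ("accuracy", "uar", "uap", "macro_f1", "kappa", "gmean")


@dataclass
class SvmConfig:
    """Configuration of the polynomial-kernel SVM.

    ``kernel_scale="auto"`` resolves to the number of features, so that with
    standardized inputs the scaled inner product u.v/s has unit order of
    magnitude regardless of dimensionality.  Degree 3 is the published model;
    other degrees are accepted but are a deliberate departure.
    """

    kernel_degree: int = 3
    box_constraint: float = 1.0
    kernel_scale: Union[float, str] = "auto"
    coef0: float = 1.0
    standardize_inputs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_degree < 1:
            raise ParameterError("kernel_degree must be a positive integer")
        if self.box_constraint <= 0:
            raise ParameterError("box_constraint must be positive")
        if self.kernel_scale != "auto" and (
            not isinstance(self.kernel_scale, (int, float)) or self.kernel_scale <= 0
        ):
            raise ParameterError("kernel_scale must be positive or 'auto'")


@dataclass
class EvalReport:
    """Confusion matrix plus the six-metric panel for one validation run."""

    confusion: np.ndarray
    metrics: Dict[str, float]
    protocol: str  # cv10 | holdout8020
    seed: int
    classes: np.ndarray
    per_fold_confusions: Optional[List[np.ndarray]] = None
    config: dict = field(default_factory=dict)

    def metrics_percent(self, ndigits: int = 2) -> Dict[str, float]:
        return {k: round(100.0 * v, ndigits) for k, v in self.metrics.items()}

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "seed": self.seed,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "metrics_percent": self.metrics_percent(),
            "config": self.config,
        }
        if self.per_fold_confusions is not None:
            out["per_fold_confusions"] = [c.tolist() for c in self.per_fold_confusions]
        return out


# ---------------------------------------------------------------------------
# metric panel
# ---------------------------------------------------------------------------

def metrics_from_confusion(cm: np.ndarray) -> Dict[str, float]:
    """Compute the six-metric panel from a C x C confusion matrix.

    Rows are true classes, columns predicted.  Per-class recall (precision)
    with an empty row (column) is defined as 0; a zero recall makes the
    geometric mean 0 (no smoothing).  Kappa is 1 for a perfect single-cell
    matrix (chance agreement 1).
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ContractError("confusion matrix must be square")
    if not np.issubdtype(cm.dtype, np.integer):
        if not np.all(np.equal(np.mod(cm, 1), 0)):
            raise ContractError("confusion matrix entries must be integers")
        cm = cm.astype(np.int64)
    if np.any(cm < 0):
        raise ContractError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ContractError("confusion matrix is empty")

    c = cm.shape[0]
    diag = np.diag(cm).astype(np.float64)
    rowsum = cm.sum(axis=1).astype(np.float64)
    colsum = cm.sum(axis=0).astype(np.float64)

    recall = np.divide(diag, rowsum, out=np.zeros(c), where=rowsum > 0)
    precision = np.divide(diag, colsum, out=np.zeros(c), where=colsum > 0)
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum, out=np.zeros(c), where=pr_sum > 0)

    accuracy = float(diag.sum() / total)
    p_e = float((rowsum * colsum).sum() / total**2)
    kappa = 1.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)

    return {
        "accuracy": accuracy,
        "uar": float(recall.mean()),
        "uap": float(precision.mean()),
        "macro_f1": float(f1.mean()),
        "kappa": float(kappa),
        "gmean": float(np.prod(recall) ** (1.0 / c)),
    }


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


# ---------------------------------------------------------------------------
# training and validation
# ---------------------------------------------------------------------------

def _check_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ContractError("X must be a 2-D matrix")
    if y.shape[0] != X.shape[0]:
        raise ContractError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if not np.all(np.isfinite(X)):
        raise ContractError("X contains non-finite values")
    if np.unique(y).size < 2:
        raise ContractError("training needs at least 2 classes")
    return X, y


def train_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig) -> Pipeline:
    """Fit the one-vs-one polynomial-kernel SVM (optionally standardized)."""
    X, y = _check_xy(X, y)
    scale = X.shape[1] if cfg.kernel_scale == "auto" else float(cfg.kernel_scale)
    svc = SVC(
        kernel="poly",
        degree=cfg.kernel_degree,
        C=cfg.box_constraint,
        gamma=1.0 / scale,
        coef0=cfg.coef0,
        random_state=cfg.seed,
    )
    steps = []
    if cfg.standardize_inputs:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", svc))
    model = Pipeline(steps)
    model.fit(X, y)
    return model


def evaluate_holdout(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SvmConfig,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> EvalReport:
    """Single stratified hold-out split; metrics on the held-out fraction."""
    X, y = _check_xy(X, y)
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise ContractError(
            f"classes {small.tolist()} have fewer than 2 samples; cannot stratify"
        )
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=1.0 - train_fraction,
        stratify=y,
        random_state=seed,
    )
    model = train_svm(X[idx_train], y[idx_train], cfg)
    y_pred = model.predict(X[idx_test])
    cm = _confusion(y[idx_test], y_pred, classes)
    return EvalReport(
        confusion=cm,
        metrics=metrics_from_confusion(cm),
        protocol="holdout8020",
        seed=seed,
        classes=classes,
        config={"svm": vars(cfg).copy(), "train_fraction": train_fraction},
    )


def evaluate_cv10(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SvmConfig,
    seed: int = 0,
    n_folds: int = 10,
) -> EvalReport:
    """Stratified 10-fold CV; out-of-fold predictions pooled into one matrix."""
    X, y = _check_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < n_folds]
    if small.size:
        raise ContractError(
            f"classes {small.tolist()} have fewer than {n_folds} samples; "
            f"{n_folds}-fold stratification degenerates"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_fold = []
    for idx_train, idx_test in skf.split(X, y):
        model = train_svm(X[idx_train], y[idx_train], cfg)
        y_pred = model.predict(X[idx_test])
        fold_cm = _confusion(y[idx_test], y_pred, classes)
        per_fold.append(fold_cm)
        pooled += fold_cm
    return EvalReport(
        confusion=pooled,
        metrics=metrics_from_confusion(pooled),
        protocol="cv10",
        seed=seed,
        classes=classes,
        per_fold_confusions=per_fold,
        config={"svm": vars(cfg).copy(), "n_folds": n_folds},
    )
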