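"""End-to-end orchestration: resize -> patch -> embed -> normalize -> NCA ->
top-k -> cubic SVM -> validation.

Two normalization/selection policies are first-class because they change
results and must never be conflated:

``paper_faithful``
    Min-max normalization and NCA are fit on the full dataset before any
    validation split, then the selected columns are evaluated under both
    protocols.  This mirrors a pipeline that selects features once on all
    data; its scores are optimistic because selection has seen the test rows.
``leakage_safe``
    Min-max and NCA are re-fit inside every training partition; the held-out
    rows only ever pass through transforms learned without them.

Every artifact a run writes embeds the configuration hash so outputs can be
matched to the exact settings that produced them.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .backends import get_backend
from .classify import (
    EvalReport,
    SvmConfig,
    _confusion,
    evaluate_cv10,
    evaluate_holdout,
    metrics_from_confusion,
    train_svm,
)
from .errors import ConfigError, ContractError, InputError
from .features import FeatureMatrix, build_feature_matrix
from .imaging import load_image
from .nca import (
    NcaParams,
    fit_nca,
    minmax_apply,
    minmax_fit,
    select_top_k,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

MODES = ("paper_faithful", "leakage_safe")
PROTOCOLS = ("holdout8020", "cv10")


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    images_dir: Optional[str] = None
    labels_csv: Optional[str] = None
    workdir: str = "runs/run"
    backend: str = "stub"
    backend_options: dict = field(default_factory=dict)
    k: int = 500
    mode: str = "paper_faithful"
    protocols: List[str] = field(default_factory=lambda: list(PROTOCOLS))
    synth: Optional[dict] = None  # SynthSpec kwargs; used when images_dir is unset
    nca: dict = field(default_factory=dict)  # NcaParams kwargs
    svm: dict = field(default_factory=dict)  # SvmConfig kwargs
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        for p in self.protocols:
            if p not in PROTOCOLS:
                raise ConfigError(f"unknown protocol {p!r}; choose from {PROTOCOLS}")
        if self.k < 1:
            raise ConfigError("k must be positive")
        if self.images_dir is None and self.synth is None:
            raise ConfigError("provide either images_dir+labels_csv or a synth block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config keys in {path}: {exc}") from exc

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_labels_csv(path) -> pd.DataFrame:
    """Read the two-column ``filename,label`` UTF-8 table (header required)."""
    try:
        df = pd.read_csv(path, dtype={"filename": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read labels table {path}: {exc}") from exc
    missing = {"filename", "label"} - set(df.columns)
    if missing:
        raise InputError(
            f"labels table {path} lacks required columns {sorted(missing)}"
        )
    return df


def load_dataset(images_dir, labels_csv) -> tuple:
    """Load all labelled images of a directory per its labels table."""
    images_dir = Path(images_dir)
    df = read_labels_csv(labels_csv)
    images, labels = [], []
    for row in df.itertuples(index=False):
        img = load_image(images_dir / row.filename)
        img.label = row.label
        images.append(img)
        labels.append(row.label)
    if not images:
        raise InputError(f"labels table {labels_csv} lists no images")
    return images, np.asarray(labels)


# ---------------------------------------------------------------------------
# normalization + selection policies
# ---------------------------------------------------------------------------

def select_features_full(
    fm: FeatureMatrix, k: int, nca_params: NcaParams
) -> tuple:
    """paper_faithful policy: normalize + NCA + top-k on the full matrix.

    Returns ``(selected_matrix, selection_result, nca_weights)``.
    """
    mm = minmax_fit(fm.values)
    Xn = minmax_apply(mm, fm.values)
    weights = fit_nca(Xn, fm.labels, nca_params)
    sel = select_top_k(weights, k=k)
    return Xn[:, sel.indices], sel, weights


def _fit_transform_select(X_train, y_train, X_test, k, nca_params):
    mm = minmax_fit(X_train)
    weights = fit_nca(minmax_apply(mm, X_train), y_train, nca_params)
    sel = select_top_k(weights, k=k)
    return (
        minmax_apply(mm, X_train)[:, sel.indices],
        minmax_apply(mm, X_test)[:, sel.indices],
        sel,
    )


def evaluate_holdout_leakage_safe(
    fm: FeatureMatrix, k, nca_params, svm_cfg: SvmConfig, seed: int = 0,
    train_fraction: float = 0.8,
) -> EvalReport:
    """Hold-out protocol with min-max + NCA fit on the training rows only."""
    y = fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ContractError("every class needs >= 2 samples to stratify")
    idx_tr, idx_te = train_test_split(
        np.arange(len(y)), test_size=1.0 - train_fraction,
        stratify=y, random_state=seed,
    )
    X_tr, X_te, _ = _fit_transform_select(
        fm.values[idx_tr], y[idx_tr], fm.values[idx_te], k, nca_params
    )
    model = train_svm(X_tr, y[idx_tr], svm_cfg)
    cm = _confusion(y[idx_te], model.predict(X_te), classes)
    return EvalReport(
        confusion=cm, metrics=metrics_from_confusion(cm),
        protocol="holdout8020", seed=seed, classes=classes,
        config={"mode": "leakage_safe", "k": k},
    )


def evaluate_cv10_leakage_safe(
    fm: FeatureMatrix, k, nca_params, svm_cfg: SvmConfig, seed: int = 0,
    n_folds: int = 10,
) -> EvalReport:
    """10-fold CV with min-max + NCA re-fit inside every training partition."""
    y = fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < n_folds):
        raise ContractError(f"every class needs >= {n_folds} samples for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_fold = []
    for idx_tr, idx_te in skf.split(fm.values, y):
        X_tr, X_te, _ = _fit_transform_select(
            fm.values[idx_tr], y[idx_tr], fm.values[idx_te], k, nca_params
        )
        model = train_svm(X_tr, y[idx_tr], svm_cfg)
        fold_cm = _confusion(y[idx_te], model.predict(X_te), classes)
        per_fold.append(fold_cm)
        pooled += fold_cm
    return EvalReport(
        confusion=pooled, metrics=metrics_from_confusion(pooled),
        protocol="cv10", seed=seed, classes=classes,
        per_fold_confusions=per_fold,
        config={"mode": "leakage_safe", "k": k},
    )


# ---------------------------------------------------------------------------
# one-shot run
# ---------------------------------------------------------------------------

def _write_json(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
    tmp.rename(path)


def _write_confusion_csv(path: Path, report: EvalReport) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + [str(c) for c in report.classes])
        for cls, row in zip(report.classes, report.confusion):
            writer.writerow([str(cls)] + [int(v) for v in row])


def run(config: RunConfig) -> Dict[str, EvalReport]:
    """Execute the full pipeline and write all artifacts under the workdir.

    Returns one :class:`EvalReport` per requested protocol.  Artifacts:
    ``features.npz``, ``selection.json`` (paper_faithful mode), and one
    ``report_<protocol>.json`` + confusion CSV per protocol, all embedding
    the configuration hash.
    """
    t0 = time.time()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if config.images_dir is not None:
        images, labels = load_dataset(config.images_dir, config.labels_csv)
    else:
        from .synth import SynthSpec, generate_images

        images, labels = generate_images(SynthSpec(**config.synth))
    logger.info("loaded %d images [%.1fs]", len(images), time.time() - t0)

    backend = get_backend(config.backend, **config.backend_options)
    fm = build_feature_matrix(backend, images, labels=labels)
    fm.backend_meta["config_hash"] = chash
    fm.save(workdir / "features.npz")
    logger.info(
        "extracted %dx%d features [%.1fs]",
        fm.n_samples, fm.n_features, time.time() - t0,
    )

    nca_params = NcaParams(**config.nca)
    svm_cfg = SvmConfig(**config.svm)
    reports: Dict[str, EvalReport] = {}

    if config.mode == "paper_faithful":
        Xs, sel, weights = select_features_full(fm, config.k, nca_params)
        _write_json(
            workdir / "selection.json",
            {
                "indices": sel.indices.tolist(),
                "weights": sel.weights_at_selection.tolist(),
                "k": sel.k,
                "nca_params": asdict(nca_params),
                "nca_converged": weights.converged,
                "objective_trace": weights.objective_trace,
                "mode": config.mode,
                "config_hash": chash,
            },
        )
        logger.info("selected %d features [%.1fs]", sel.k, time.time() - t0)
        for protocol in config.protocols:
            if protocol == "holdout8020":
                rep = evaluate_holdout(Xs, fm.labels, svm_cfg, seed=config.split_seed)
            else:
                rep = evaluate_cv10(Xs, fm.labels, svm_cfg, seed=config.split_seed)
            reports[protocol] = rep
    else:
        for protocol in config.protocols:
            if protocol == "holdout8020":
                rep = evaluate_holdout_leakage_safe(
                    fm, config.k, nca_params, svm_cfg, seed=config.split_seed
                )
            else:
                rep = evaluate_cv10_leakage_safe(
                    fm, config.k, nca_params, svm_cfg, seed=config.split_seed
                )
            reports[protocol] = rep

    for protocol, rep in reports.items():
        payload = rep.to_dict()
        payload["config_hash"] = chash
        payload["mode"] = config.mode
        _write_json(workdir / f"report_{protocol}.json", payload)
        _write_confusion_csv(workdir / f"confusion_{protocol}.csv", rep)
        logger.info(
            "%s: %s [%.1fs]",
            protocol, rep.metrics_percent(), time.time() - t0,
        )
    return reports
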