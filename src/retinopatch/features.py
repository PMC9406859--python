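"""Deep-feature extraction and the concatenated feature matrix.

Each of the nine inputs of a :class:`~retinopatch.imaging.PatchSet` (the
resized main image and patches P1..P8) is embedded into ``fc_dim + pool_dim``
features; the nine per-input vectors are concatenated in the fixed order
``main, P1..P8`` (fc features before pool features within each block), giving
``D = 9 * (fc_dim + pool_dim)`` columns — 26,280 with the default DenseNet201
dimensions (9 x (1000 + 1920)).

Every column carries a provenance record (source input, layer, within-layer
index) so any selected feature can be traced back to the image region and
backend layer it came from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .backends import EmbeddingBackend
from .errors import ContractError, InputError, ParameterError
from .imaging import FundusImage, PatchSet, prepare_patchset

logger = logging.getLogger(__name__)

#: canonical order of the nine embedding inputs
INPUT_ORDER = ("main", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")


def extract_input_features(backend: EmbeddingBackend, img: np.ndarray) -> np.ndarray:
    """Embed one input and return the concatenation ``[fc | pool]``.

    Length is ``fc_dim + pool_dim`` (2920 with DenseNet201 dimensions).
    """
    fc, pool = backend.embed(img)
    if fc.shape != (backend.fc_dim,) or pool.shape != (backend.pool_dim,):
        raise ContractError(
            f"backend {backend.name!r} returned vectors of shapes "
            f"{fc.shape}/{pool.shape}, expected ({backend.fc_dim},)/({backend.pool_dim},)"
        )
    return np.concatenate([fc, pool])


def extract_patchset_features(backend: EmbeddingBackend, ps: PatchSet) -> np.ndarray:
    """Concatenate per-input features over main, P1..P8.

    Length is ``9 * (fc_dim + pool_dim)`` — 26,280 with default dimensions.
    """
    blocks = [extract_input_features(backend, px) for _, px in ps.inputs()]
    return np.concatenate(blocks)


def column_provenance(backend: EmbeddingBackend) -> List[tuple]:
    """Per-column ``(source_input, layer, within_layer_index)`` triples."""
    prov = []
    for source in INPUT_ORDER:
        prov.extend((source, "fc", i) for i in range(backend.fc_dim))
        prov.extend((source, "pool", i) for i in range(backend.pool_dim))
    return prov


@dataclass
class FeatureMatrix:
    """N x D matrix of concatenated deep features with column provenance."""

    values: np.ndarray
    labels: np.ndarray
    provenance: list = field(default_factory=list)
    backend_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ContractError("feature matrix must be 2-dimensional")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ContractError(
                f"{self.values.shape[0]} feature rows but {self.labels.shape[0]} labels"
            )
        if self.provenance and len(self.provenance) != self.values.shape[1]:
            raise ContractError(
                f"provenance covers {len(self.provenance)} columns, "
                f"matrix has {self.values.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        """Persist losslessly as a compressed npz (arrays X, y + JSON meta)."""
        path = Path(path)
        meta = {
            "backend": self.backend_meta,
            "provenance": [list(p) for p in self.provenance],
        }
        np.savez_compressed(
            path,
            X=self.values,
            y=self.labels,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        path = Path(path)
        try:
            with np.load(path, allow_pickle=False) as npz:
                X = npz["X"]
                y = npz["y"]
                meta = json.loads(str(npz["meta"]))
        except (OSError, KeyError, ValueError) as exc:
            raise InputError(f"cannot read feature archive {path}: {exc}") from exc
        return cls(
            values=X,
            labels=y,
            provenance=[tuple(p) for p in meta.get("provenance", [])],
            backend_meta=meta.get("backend", {}),
        )


def build_feature_matrix(
    backend: EmbeddingBackend,
    images: Sequence[FundusImage],
    labels: Optional[Sequence] = None,
    on_error: str = "abort",
    interpolation: str = "bilinear",
) -> FeatureMatrix:
    """Run resize -> patch division -> embedding for every image.

    Row ``k`` holds the 9-block concatenated features of image ``k``.  With
    ``on_error="abort"`` (default) any failing image aborts the run with a
    summary of all per-image errors; ``"skip"`` logs and drops failures.
    """
    if len(images) == 0:
        raise ParameterError("build_feature_matrix needs at least one image")
    if on_error not in ("abort", "skip"):
        raise ParameterError(f"on_error must be 'abort' or 'skip', got {on_error!r}")
    if labels is None:
        labels = [img.label for img in images]
    if len(labels) != len(images):
        raise ContractError(f"{len(images)} images but {len(labels)} labels")

    rows, kept_labels, failures = [], [], []
    for k, (img, lab) in enumerate(zip(images, labels)):
        try:
            ps = prepare_patchset(img, interpolation=interpolation)
            rows.append(extract_patchset_features(backend, ps))
            kept_labels.append(lab)
        except Exception as exc:  # collected and re-raised as a summary
            failures.append((k, img.source_id, str(exc)))
            if on_error == "skip":
                logger.warning("skipping image %d (%s): %s", k, img.source_id, exc)
    if failures and on_error == "abort":
        summary = "; ".join(f"#{k} {sid!r}: {msg}" for k, sid, msg in failures[:5])
        raise InputError(
            f"{len(failures)} of {len(images)} images failed extraction: {summary}"
        )
    if not rows:
        raise InputError("all images failed extraction")
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=np.asarray(kept_labels),
        provenance=column_provenance(backend),
        backend_meta={
            "name": backend.name,
            "fc_dim": backend.fc_dim,
            "pool_dim": backend.pool_dim,
            "input_side": backend.input_side,
        },
    )
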