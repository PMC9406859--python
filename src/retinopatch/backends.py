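"""Embedding backends: pluggable frozen feature extractors.

A backend turns one image (the resized main image or a single patch) into two
feature vectors: the activations of a 1000-way classification layer ("fc") and
of a global-average-pool layer ("pool").  The production backend is a
pretrained DenseNet201 read at its ``fc1000`` (pre-softmax logits) and
``avg_pool`` (1920-unit) layers; it needs torch/torchvision at runtime.  The
stub backend is a seeded fixed random linear projection used for fast,
fully deterministic offline testing.

Every backend resizes its input internally to a square ``input_side`` and
applies its own channel normalization; callers pass raw uint8 (or float)
3-channel arrays of any rectangular shape.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import BackendUnavailableError, ContractError, ParameterError


class EmbeddingBackend:
    """Interface of a frozen feature extractor.

    Attributes
    ----------
    name : str
    input_side : int
        Side of the square input the backend expects internally.
    fc_dim : int
        Width of the classification-layer feature vector (1000 for DenseNet201).
    pool_dim : int
        Width of the global-average-pool vector (1920 for DenseNet201).
    """

    name: str = "abstract"
    input_side: int = 0
    fc_dim: int = 0
    pool_dim: int = 0

    def embed(self, img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Return ``(fc_vector, pool_vector)`` for one 3-channel image."""
        raise NotImplementedError

    def _check_input(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ContractError(
                f"backend {self.name!r} requires rows x cols x 3 input, "
                f"got shape {img.shape}"
            )
        return img


class StubBackend(EmbeddingBackend):
    """Deterministic test backend: a fixed random linear projection.

    The image is converted to grayscale, downsampled to ``input_side`` squared
    (32 x 32 by default), scaled to [0, 1], flattened, and multiplied by two
    frozen random matrices drawn once from ``seed``.  No bias: the all-zero
    image maps to all-zero features, and embedding is exactly linear in the
    downsampled intensities, which preserves the class separability of the
    synthetic generator.
    """

    name = "stub"

    def __init__(
        self,
        fc_dim: int = 1000,
        pool_dim: int = 1920,
        input_side: int = 32,
        seed: int = 0,
    ) -> None:
        if fc_dim < 1 or pool_dim < 1 or input_side < 1:
            raise ParameterError("stub backend dimensions must be positive")
        self.fc_dim = int(fc_dim)
        self.pool_dim = int(pool_dim)
        self.input_side = int(input_side)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        d_in = self.input_side * self.input_side
        scale = 1.0 / np.sqrt(d_in)
        self._w_fc = rng.standard_normal((self.fc_dim, d_in)) * scale
        self._w_pool = rng.standard_normal((self.pool_dim, d_in)) * scale

    def embed(self, img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        img = self._check_input(img)
        gray = np.asarray(img, dtype=np.float64).mean(axis=2) / 255.0
        if gray.shape != (self.input_side, self.input_side):
            gray = _sk_resize(
                gray,
                (self.input_side, self.input_side),
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            )
        v = gray.ravel()
        return self._w_fc @ v, self._w_pool @ v


class DenseNet201Backend(EmbeddingBackend):
    """Pretrained DenseNet201 read at its fc1000 and avg_pool layers.

    The "fc" vector is the 1000-way classification layer's pre-softmax
    activations (logits); the "pool" vector is the 1920-unit global average
    pool that feeds it.  Inputs are resized to 224 x 224, scaled to [0, 1] and
    standardized with the ImageNet channel statistics the pretrained weights
    assume.  Requires the optional ``densenet`` extra (torch + torchvision).
    """

    name = "densenet201"
    input_side = 224
    fc_dim = 1000
    pool_dim = 1920

    _IMAGENET_MEAN = (0.485, 0.456, 0.406)
    _IMAGENET_STD = (0.229, 0.224, 0.225)

    def __init__(self, device: str = "cpu") -> None:
        try:
            import torch
            from torchvision.models import DenseNet201_Weights, densenet201
        except ImportError as exc:
            raise BackendUnavailableError(
                "the densenet201 backend needs torch and torchvision; "
                "install them with: pip install 'retinopatch[densenet]'"
            ) from exc
        self._torch = torch
        self._device = device
        self._model = densenet201(weights=DenseNet201_Weights.IMAGENET1K_V1)
        self._model.eval().to(device)

    def embed(self, img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        img = self._check_input(img)
        torch = self._torch
        x = np.asarray(img, dtype=np.float32) / 255.0
        x = _sk_resize(
            x, (self.input_side, self.input_side), order=1,
            preserve_range=True, anti_aliasing=False,
        )
        x = (x - np.asarray(self._IMAGENET_MEAN)) / np.asarray(self._IMAGENET_STD)
        t = torch.from_numpy(np.ascontiguousarray(x.transpose(2, 0, 1))[None]).float()
        with torch.no_grad():
            feats = self._model.features(t.to(self._device))
            feats = torch.nn.functional.relu(feats)
            pool = torch.nn.functional.adaptive_avg_pool2d(feats, 1).flatten(1)
            fc = self._model.classifier(pool)
        return (
            fc.cpu().numpy().ravel().astype(np.float64),
            pool.cpu().numpy().ravel().astype(np.float64),
        )


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Instantiate a backend by name: ``"stub"`` or ``"densenet201"``."""
    if name == "stub":
        return StubBackend(**kwargs)
    if name == "densenet201":
        return DenseNet201Backend(**kwargs)
    raise ParameterError(f"unknown backend {name!r} (choose stub or densenet201)")
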