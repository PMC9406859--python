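"""Min-max normalization, regularized NCA feature weighting, top-k selection.

Neighborhood component analysis (NCA) for feature selection learns one
nonnegative weight per feature by maximizing the expected leave-one-out
classification accuracy of a stochastic nearest-neighbor rule.  With a
weighted L1 distance

    d_w(x_i, x_j) = sum_l  w_l^2 |x_il - x_jl|,

sample i picks reference j with probability

    p_ij = exp(-d_w(x_i, x_j) / sigma) / sum_{k != i} exp(-d_w(x_i, x_k) / sigma),
    p_ii = 0,

and the regularized objective to maximize is

    F(w) = (1/n) sum_i p_i  -  lambda * sum_l w_l^2,
    p_i  = sum_j [y_i = y_j] p_ij.

The analytic gradient is

    dF/dw_l = (2 w_l / sigma) (1/n) sum_i [ p_i sum_j p_ij |x_il - x_jl|
              - sum_j [y_i = y_j] p_ij |x_il - x_jl| ]  -  2 lambda w_l.

Features irrelevant to the labels are driven to zero by the penalty;
discriminative features earn large weights, and the top-k indices by weight
form the selected subset.  Softmax rows are stabilized by subtracting the
row-wise maximum of the negated scaled distances before exponentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ContractError, NumericalError, ParameterError

logger = logging.getLogger(__name__)

# feature-chunk size for the gradient's |x_il - x_jl| accumulation on wide
# matrices; bounds peak memory at ~batch^2 * chunk doubles
_FEATURE_CHUNK = 2048


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class MinMaxModel:
    """Per-feature minimum and maximum learned on a fit partition."""

    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def n_features(self) -> int:
        return self.minimum.shape[0]


def minmax_fit(X: np.ndarray) -> MinMaxModel:
    """Learn per-feature min and max from the fit partition."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ContractError("minmax_fit needs a nonempty 2-D matrix")
    return MinMaxModel(minimum=X.min(axis=0), maximum=X.max(axis=0))


def minmax_apply(model: MinMaxModel, X: np.ndarray) -> np.ndarray:
    """Apply ``(x - min) / (max - min)`` per feature.

    Constant features (max == min on the fit partition) map to 0.  Values
    outside [0, 1] are possible when applying to unseen data and are kept.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ContractError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"model expects {model.n_features}"
        )
    span = model.maximum - model.minimum
    out = np.zeros_like(X)
    nonconst = span > 0
    out[:, nonconst] = (X[:, nonconst] - model.minimum[nonconst]) / span[nonconst]
    return out


# ---------------------------------------------------------------------------
# NCA objective / gradient
# ---------------------------------------------------------------------------

@dataclass
class NcaParams:
    """Hyperparameters of the regularized NCA fit.

    ``lam`` is the L2 penalty on the weights (``None`` resolves to 1/n at fit
    time), ``sigma`` the kernel width of the softmax-over-distances neighbor
    model.  ``sigma="auto"`` resolves, at the start of a fit, to the mean
    off-diagonal weighted distance at the initial weights: with many features
    the raw L1 distances grow linearly in D and a unit kernel width would
    saturate the softmax to a hard nearest-neighbor rule with vanishing
    gradients; scaling by the mean distance keeps the exponent of order one
    at any dimensionality.  The optimizer is seeded mini-batch gradient
    ascent from w = 1.
    """

    lam: Optional[float] = None
    sigma: object = 1.0  # positive float, or "auto"
    learning_rate: float = 0.1
    batch_size: int = 32
    max_epochs: int = 100
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ParameterError("lambda must be nonnegative")
        if self.sigma != "auto" and (
            not isinstance(self.sigma, (int, float)) or self.sigma <= 0
        ):
            raise ParameterError("sigma must be positive or 'auto'")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.batch_size < 2:
            raise ParameterError("batch_size must be at least 2")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be at least 1")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")

    def resolve_lam(self, n: int) -> float:
        return (1.0 / n) if self.lam is None else float(self.lam)

    def resolve_sigma(self, Xn: np.ndarray, w: np.ndarray) -> float:
        """Concrete kernel width; ``"auto"`` -> mean off-diagonal distance."""
        if self.sigma != "auto":
            return float(self.sigma)
        dist = _pairwise_weighted_l1(Xn, w * w)
        n = dist.shape[0]
        mean_off = dist.sum() / (n * (n - 1))
        return float(mean_off) if mean_off > 0 else 1.0


@dataclass
class NcaWeights:
    """Fitted nonnegative per-feature weights with fit diagnostics."""

    w: np.ndarray
    objective_trace: List[float] = field(default_factory=list)
    converged: bool = False
    params: Optional[NcaParams] = None


@dataclass
class SelectionResult:
    """Top-k column indices ordered by descending weight."""

    indices: np.ndarray
    k: int
    weights_at_selection: np.ndarray


def _check_instance(Xn: np.ndarray, y: np.ndarray) -> None:
    if Xn.ndim != 2 or Xn.shape[0] < 2:
        raise ContractError("NCA needs a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(Xn)):
        raise ContractError("NCA input matrix contains non-finite values")
    if y.shape[0] != Xn.shape[0]:
        raise ContractError(f"{Xn.shape[0]} rows but {y.shape[0]} labels")
    if np.unique(y).size < 2:
        raise ContractError("NCA needs at least 2 classes")


def _pairwise_weighted_l1(X: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """n x n matrix of sum_l w2_l |x_il - x_jl|.

    Because the weights are nonnegative, w2_l |x_il - x_jl| equals
    |w2_l x_il - w2_l x_jl|, so the weighted L1 distance is a plain cityblock
    distance on the column-scaled matrix — computed in C without any
    n x n x D temporary.
    """
    return cdist(X * w2, X * w2, metric="cityblock")


def _reference_probabilities(dist: np.ndarray, sigma: float) -> np.ndarray:
    """Row-stochastic p_ij with p_ii = 0, stabilized per row."""
    logits = -dist / sigma
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


def nca_objective(
    Xn: np.ndarray, y: np.ndarray, w: np.ndarray, params: NcaParams
) -> float:
    """Regularized expected leave-one-out accuracy F(w)."""
    Xn = np.asarray(Xn, dtype=np.float64)
    y = np.asarray(y)
    w = np.asarray(w, dtype=np.float64)
    _check_instance(Xn, y)
    n = Xn.shape[0]
    lam = params.resolve_lam(n)
    sigma = params.resolve_sigma(Xn, w)
    P = _reference_probabilities(_pairwise_weighted_l1(Xn, w * w), sigma)
    same = (y[:, None] == y[None, :])
    p_i = (P * same).sum(axis=1)
    if np.any(p_i == 0):
        logger.debug("some rows have zero same-class neighbor mass (singleton class?)")
    return float(p_i.mean() - lam * np.dot(w, w))


def nca_gradient(
    Xn: np.ndarray, y: np.ndarray, w: np.ndarray, params: NcaParams
) -> np.ndarray:
    """Analytic gradient of :func:`nca_objective` with respect to w."""
    Xn = np.asarray(Xn, dtype=np.float64)
    y = np.asarray(y)
    w = np.asarray(w, dtype=np.float64)
    _check_instance(Xn, y)
    n, d = Xn.shape
    lam = params.resolve_lam(n)
    sigma = params.resolve_sigma(Xn, w)
    w2 = w * w
    dist = _pairwise_weighted_l1(Xn, w2)
    P = _reference_probabilities(dist, sigma)
    same = (y[:, None] == y[None, :])
    p_i = (P * same).sum(axis=1)
    # A_ij = (p_i - [y_i = y_j]) * p_ij ; grad_l = (2 w_l / (sigma n)) sum_ij A_ij |x_il - x_jl|
    A = (p_i[:, None] - same) * P
    grad = np.zeros(d)
    for lo in range(0, d, _FEATURE_CHUNK):
        hi = min(lo + _FEATURE_CHUNK, d)
        block = np.abs(Xn[:, None, lo:hi] - Xn[None, :, lo:hi])
        grad[lo:hi] = np.einsum("ij,ijl->l", A, block)
    grad *= 2.0 * w / (sigma * n)
    grad -= 2.0 * lam * w
    return grad


def fit_nca(Xn: np.ndarray, y: np.ndarray, params: NcaParams) -> NcaWeights:
    """Mini-batch gradient ascent on F(w) from w = 1, clipping w at 0.

    Rows are shuffled each epoch with the seeded generator; the learning rate
    decays as ``lr / (1 + epoch)``.  The fit stops early when the full-data
    objective improves by less than ``tolerance`` between epochs.  A
    ``sigma="auto"`` kernel width is resolved once, at the initial weights,
    so a single fixed objective is optimized throughout; the resolved value
    is stored in the returned diagnostics.
    """
    Xn = np.asarray(Xn, dtype=np.float64)
    y = np.asarray(y)
    _check_instance(Xn, y)
    n, d = Xn.shape
    rng = np.random.default_rng(params.seed)
    w = np.ones(d)
    if params.sigma == "auto":
        from dataclasses import replace

        params = replace(params, sigma=params.resolve_sigma(Xn, w))
    trace = [nca_objective(Xn, y, w, params)]
    converged = False
    for epoch in range(params.max_epochs):
        lr = params.learning_rate / (1.0 + epoch)
        order = rng.permutation(n)
        for lo in range(0, n, params.batch_size):
            idx = order[lo : lo + params.batch_size]
            if idx.size < 2 or np.unique(y[idx]).size < 2:
                continue  # a batch with one row or one class carries no signal
            g = nca_gradient(Xn[idx], y[idx], w, params)
            w = np.maximum(w + lr * g, 0.0)
        obj = nca_objective(Xn, y, w, params)
        if not np.isfinite(obj):
            raise NumericalError(
                f"NCA objective became non-finite at epoch {epoch}; "
                "try a smaller learning_rate"
            )
        trace.append(obj)
        if abs(trace[-1] - trace[-2]) < params.tolerance:
            converged = True
            break
    return NcaWeights(w=w, objective_trace=trace, converged=converged, params=params)


def select_top_k(weights: NcaWeights, k: int = 500) -> SelectionResult:
    """Indices of the k largest weights, ties broken by ascending index."""
    w = np.asarray(weights.w, dtype=np.float64)
    d = w.shape[0]
    if not (1 <= k <= d):
        raise ParameterError(f"k must be in [1, {d}], got {k}")
    # stable sort on -w keeps original (ascending-index) order within ties
    order = np.argsort(-w, kind="stable")[:k]
    return SelectionResult(indices=order, k=k, weights_at_selection=w[order])
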