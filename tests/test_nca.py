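"""Min-max normalization and the regularized NCA feature selector.

The objective and gradient are checked against two independent oracles: a
literal double-loop enumeration of the neighbor probabilities, and central
finite differences.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from retinopatch import (
    ContractError,
    NcaParams,
    NcaWeights,
    ParameterError,
    fit_nca,
    generate_planted_matrix,
    minmax_apply,
    minmax_fit,
    nca_gradient,
    nca_objective,
    select_top_k,
)
from retinopatch.synth import PlantedMatrixSpec


# ---------------------------------------------------------------------------
# independent oracle: literal enumeration of the neighbor model
# ---------------------------------------------------------------------------

def brute_force_objective(X, y, w, lam, sigma):
    n, d = X.shape
    total = 0.0
    for i in range(n):
        weights = []
        for j in range(n):
            if j == i:
                weights.append(0.0)
                continue
            dist = sum(w[l] ** 2 * abs(X[i, l] - X[j, l]) for l in range(d))
            weights.append(math.exp(-dist / sigma))
        z = sum(weights)
        p_i = sum(
            weights[j] / z for j in range(n) if j != i and y[j] == y[i]
        )
        total += p_i
    return total / n - lam * sum(v**2 for v in w)


class TestMinMax:
    def test_endpoints_of_the_formula(self):
        X = np.array([[0.0], [5.0], [10.0]])
        model = minmax_fit(X)
        np.testing.assert_allclose(minmax_apply(model, X).ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[3.0], [3.0], [3.0]])
        np.testing.assert_array_equal(minmax_apply(minmax_fit(X), X), 0.0)

    def test_unseen_data_interpolates_without_clipping(self):
        model = minmax_fit(np.array([[0.0, 2.0], [4.0, 6.0]]))
        np.testing.assert_allclose(
            minmax_apply(model, np.array([[2.0, 4.0]])).ravel(), [0.5, 0.5]
        )
        out = minmax_apply(model, np.array([[8.0, -2.0]])).ravel()
        np.testing.assert_allclose(out, [2.0, -1.0])  # outside [0,1] allowed

    def test_dimension_mismatch_rejected(self):
        model = minmax_fit(np.zeros((2, 3)))
        with pytest.raises(ContractError):
            minmax_apply(model, np.zeros((2, 4)))


class TestObjective:
    def test_zero_weights_give_uniform_neighbor_probabilities(self):
        # n=4, two balanced classes: each sample has 1 same-class neighbor of
        # 3, so F = 1/3 regardless of lambda (penalty vanishes at w=0)
        X = np.random.default_rng(0).normal(size=(4, 3))
        y = np.array([0, 0, 1, 1])
        for lam in (0.0, 5.0):
            params = NcaParams(lam=lam, seed=0)
            val = nca_objective(X, y, np.zeros(3), params)
            assert val == pytest.approx(1.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        y = rng.integers(0, 2, size=6)
        y[0], y[1] = 0, 1  # ensure two classes
        w = rng.uniform(0.2, 1.5, size=3)
        params = NcaParams(lam=0.3, sigma=0.8, seed=0)
        ours = nca_objective(X, y, w, params)
        oracle = brute_force_objective(X, y, w, lam=0.3, sigma=0.8)
        assert ours == pytest.approx(oracle, rel=1e-10)


class TestGradient:
    def test_zero_weights_give_zero_gradient(self):
        X = np.random.default_rng(3).normal(size=(5, 4))
        y = np.array([0, 1, 0, 1, 0])
        g = nca_gradient(X, y, np.zeros(4), NcaParams(lam=1.0, seed=0))
        np.testing.assert_array_equal(g, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        y = np.array([0, 0, 1, 1, 0, 1])
        w = rng.uniform(0.3, 1.2, size=3)
        params = NcaParams(lam=0.2, sigma=1.0, seed=0)
        g = nca_gradient(X, y, w, params)
        h = 1e-5
        fd = np.empty_like(g)
        for l in range(3):
            wp, wm = w.copy(), w.copy()
            wp[l] += h
            wm[l] -= h
            fd[l] = (
                nca_objective(X, y, wp, params) - nca_objective(X, y, wm, params)
            ) / (2 * h)
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-8)
        assert rel.max() < 1e-4

    def test_huge_penalty_dominates_informative_data(self):
        X, y, _ = generate_planted_matrix(
            PlantedMatrixSpec(n=30, D=5, n_informative=3, effect_size=2.0, seed=0)
        )
        w = np.full(5, 0.7)
        g = nca_gradient(X, y, w, NcaParams(lam=1e3, sigma=1.0, seed=0))
        assert np.all(g < 0)


class TestFit:
    def test_informative_features_outweigh_noise_on_planted_data(self):
        X, y, informative = generate_planted_matrix(PlantedMatrixSpec(seed=7))
        Xn = minmax_apply(minmax_fit(X), X)
        weights = fit_nca(Xn, y, NcaParams(seed=7))
        mask = np.zeros(50, dtype=bool)
        mask[informative] = True
        assert weights.w[mask].mean() > weights.w[~mask].mean()
        assert np.all(weights.w >= 0)
        assert np.all(np.isfinite(weights.objective_trace))

    def test_trace_final_value_not_below_initial(self):
        X, y, _ = generate_planted_matrix(PlantedMatrixSpec(seed=3))
        Xn = minmax_apply(minmax_fit(X), X)
        weights = fit_nca(Xn, y, NcaParams(seed=3, max_epochs=30))
        assert weights.objective_trace[-1] >= weights.objective_trace[0]

    def test_permuted_labels_shrink_weights(self):
        X, y, _ = generate_planted_matrix(
            PlantedMatrixSpec(n=60, D=20, n_informative=5, effect_size=2.0, seed=5)
        )
        rng = np.random.default_rng(0)
        y_null = rng.permutation(y)
        Xn = minmax_apply(minmax_fit(X), X)
        weights = fit_nca(Xn, y_null, NcaParams(seed=5, max_epochs=30))
        assert np.sum(weights.w**2) < 20.0  # below the all-ones initialization

    def test_identical_seed_gives_bitwise_identical_weights(self):
        X, y, _ = generate_planted_matrix(
            PlantedMatrixSpec(n=50, D=10, n_informative=3, seed=2)
        )
        Xn = minmax_apply(minmax_fit(X), X)
        w1 = fit_nca(Xn, y, NcaParams(seed=11, max_epochs=5))
        w2 = fit_nca(Xn, y, NcaParams(seed=11, max_epochs=5))
        np.testing.assert_array_equal(w1.w, w2.w)
        assert w1.objective_trace == w2.objective_trace

    def test_column_permutation_equivariance(self):
        X, y, _ = generate_planted_matrix(
            PlantedMatrixSpec(n=40, D=8, n_informative=3, seed=4)
        )
        Xn = minmax_apply(minmax_fit(X), X)
        perm = np.random.default_rng(9).permutation(8)
        w_orig = fit_nca(Xn, y, NcaParams(seed=1, max_epochs=10)).w
        w_perm = fit_nca(Xn[:, perm], y, NcaParams(seed=1, max_epochs=10)).w
        np.testing.assert_allclose(w_perm, w_orig[perm], rtol=1e-8, atol=1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ContractError):
            fit_nca(X, np.zeros(10, dtype=int), NcaParams(seed=0))

    def test_auto_sigma_resolved_and_recorded(self):
        X, y, _ = generate_planted_matrix(
            PlantedMatrixSpec(n=30, D=6, n_informative=3, seed=8)
        )
        Xn = minmax_apply(minmax_fit(X), X)
        weights = fit_nca(Xn, y, NcaParams(seed=0, sigma="auto", max_epochs=3))
        assert isinstance(weights.params.sigma, float)
        assert weights.params.sigma > 0

    @pytest.mark.parametrize(
    "bad", [dict(sigma=-1), dict(learning_rate=0), dict(batch_size=1),
            dict(max_epochs=0), dict(tolerance=0), dict(lam=-0.1)]
    )
    def test_invalid_hyperparameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            NcaParams(seed=0, **bad)


class TestSelectTopK:
    def test_descending_weights(self):
        w = NcaWeights(w=np.array([0.1, 0.9, 0.5]))
        sel = select_top_k(w, k=2)
        assert sel.indices.tolist() == [1, 2]

    def test_ties_broken_by_ascending_index(self):
        sel = select_top_k(NcaWeights(w=np.ones(5)), k=3)
        assert sel.indices.tolist() == [0, 1, 2]

    def test_k_equals_d_returns_full_ordering(self):
        w = np.array([0.3, 0.7, 0.1, 0.7])
        sel = select_top_k(NcaWeights(w=w), k=4)
        assert sel.indices.tolist() == [1, 3, 0, 2]

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ParameterError):
            select_top_k(NcaWeights(w=np.ones(5)), k=k)

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=30),
           st.data())
    def test_selection_is_unique_and_sorted_by_weight(self, ws, data):
        w = np.array(ws)
        k = data.draw(st.integers(1, len(ws)))
        sel = select_top_k(NcaWeights(w=w), k=k)
        assert len(set(sel.indices.tolist())) == k
        picked = w[sel.indices]
        assert np.all(np.diff(picked) <= 0)
        # nothing outside the selection beats anything inside it
        if k < len(ws):
            rest = np.delete(w, sel.indices)
            assert rest.max() <= picked.min() + 1e-12
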