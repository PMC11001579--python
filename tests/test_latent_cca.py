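"""Sparse CCA solver, component assignment, clustering, and comparisons."""

import numpy as np
import pytest
from scipy.linalg import eigh

from neuroforage.latent_cca import (
    SparseCCA,
    assign_components,
    cluster_neurons_by_reconstruction,
    component_vs_single_unit,
    fit_scca,
)


def classical_cca_correlations(X, Y, k):
    """Generalized-eigenproblem oracle for canonical correlations."""
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    w = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    return np.sqrt(np.clip(w[:k], 0, 1))


class TestSolver:
    def test_matches_generalized_eigenproblem_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X = rng.normal(size=(200, 5))
            Y = rng.normal(size=(200, 8)) + 0.5 * X @ rng.normal(size=(5, 8))
            model = SparseCCA(n_components=5, fullness=1.0, reg=0.0).fit(X, Y)
            oracle = classical_cca_correlations(X, Y, 5)
            assert np.allclose(model.correlations_, oracle, atol=1e-8)

    def test_identical_spaces_give_unit_correlations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        model = SparseCCA(n_components=4, fullness=1.0, reg=0.0).fit(X, X.copy())
        assert np.allclose(model.correlations_, 1.0, atol=1e-8)

    def test_independent_spaces_have_low_heldout_correlation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(600, 6))
        Y = rng.normal(size=(600, 6))
        folds = np.repeat(np.arange(6), 100)
        res = fit_scca(X, Y, n_components=3, fullness=1.0, fold_ids=folds)
        assert np.abs(res.heldout_correlations).mean() < 0.15

    def test_sparsity_monotone_in_fullness(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 20))
        Y = 0.7 * X @ rng.normal(size=(20, 10)) + rng.normal(size=(300, 10))
        nnz = []
        for f in (1.0, 0.6, 0.3, 0.15):
            m = SparseCCA(n_components=3, fullness=f).fit(X, Y)
            nnz.append(m.n_active_task_columns().sum())
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_invariant_to_affine_recombination_of_units(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 5))
        Y = 0.5 * X @ rng.normal(size=(5, 7)) + rng.normal(size=(400, 7))
        A = rng.normal(size=(7, 7)) + 3 * np.eye(7)  # invertible mix
        m1 = SparseCCA(n_components=4, fullness=1.0, reg=0.0).fit(X, Y)
        m2 = SparseCCA(n_components=4, fullness=1.0, reg=0.0).fit(X, Y @ A)
        assert np.allclose(m1.correlations_, m2.correlations_, atol=1e-6)

    def test_components_ordered_descending(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 8))
        Y = 0.6 * X @ rng.normal(size=(8, 9)) + rng.normal(size=(300, 9))
        m = SparseCCA(n_components=6, fullness=0.5).fit(X, Y)
        assert np.all(np.diff(m.correlations_) <= 1e-12)

    def test_invalid_fullness_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(ValueError):
            SparseCCA(fullness=0.0).fit(X, X)


class TestAssignment:
    def test_planted_single_variable_components(self):
        groups = {"waiting_time": np.array([0, 1]),
                  "reward_ratio": np.array([2, 3]),
                  "press": np.array([4, 5])}

        class Fake:
            x_weights_whitened_ = np.array([
                # k0 loads on reward_ratio, k1 on waiting_time, k2 on press
                [0.0, 0.9, 0.1],
                [0.1, 0.8, 0.0],
                [1.0, 0.0, 0.1],
                [0.8, 0.1, 0.0],
                [0.0, 0.0, 0.9],
                [0.1, 0.0, 0.7],
            ])

        out = assign_components(Fake(), groups,
                                variables=("waiting_time", "reward_ratio"))
        assert out == {"waiting_time": 1, "reward_ratio": 0}

    def test_tie_breaks_to_lower_index(self):
        groups = {"a": np.array([0]), "b": np.array([1])}

        class Fake:
            x_weights_whitened_ = np.array([[0.5, 0.5], [0.5, 0.5]])

        out = assign_components(Fake(), groups, variables=("a",))
        assert out["a"] == 0

    def test_zero_weight_variable_unassigned(self):
        groups = {"a": np.array([0]), "b": np.array([1])}

        class Fake:
            x_weights_whitened_ = np.array([[0.0, 0.0], [1.0, 0.5]])

        out = assign_components(Fake(), groups, variables=("a", "b"))
        assert out["a"] is None and out["b"] in (0, 1)


class TestClustering:
    def _planted(self, rng, n=400, per_family=6):
        latent1 = rng.normal(size=n)
        latent2 = rng.normal(size=n)
        X = np.column_stack([latent1, latent2, rng.normal(size=n)])
        Y = np.column_stack(
            [latent1 * rng.uniform(0.8, 1.2) + 0.3 * rng.normal(size=n)
             for _ in range(per_family)]
            + [latent2 * rng.uniform(0.8, 1.2) + 0.3 * rng.normal(size=n)
               for _ in range(per_family)])
        return X, Y

    def test_two_planted_families_recovered(self, rng):
        X, Y = self._planted(rng)
        clusters = cluster_neurons_by_reconstruction(Y, X, min_size=5)
        assert len(clusters) == 2
        sets = [set(c) for c in clusters]
        assert set(range(6)) in sets and set(range(6, 12)) in sets

    def test_identical_units_form_single_cluster(self, rng):
        n = 300
        latent = rng.normal(size=n)
        X = latent[:, None]
        Y = np.tile(latent[:, None], (1, 8))
        clusters = cluster_neurons_by_reconstruction(Y, X, min_size=5)
        assert len(clusters) == 1 and len(clusters[0]) == 8

    def test_min_size_larger_than_population(self, rng):
        X, Y = self._planted(rng)
        assert cluster_neurons_by_reconstruction(Y, X, min_size=50) == []


class TestComponentVsSingleUnit:
    def test_distributed_latent_favors_component(self, rng):
        """A latent spread over 24 noisy units is read out better by the
        canonical component than by the best single unit."""
        n = 1200
        latent = rng.normal(size=n)
        X = np.column_stack([latent + 0.1 * rng.normal(size=n),
                             rng.normal(size=(n, 3)).T.reshape(3, n).T.mean(1)])
        Y = np.column_stack([latent * rng.uniform(0.5, 1.0)
                             + 1.5 * rng.normal(size=n) for _ in range(24)])
        groups = {"waiting_time": np.array([0]), "other": np.array([1])}
        folds = np.repeat(np.arange(6), n // 6)
        out = component_vs_single_unit(X, Y, groups, {"waiting_time": latent},
                                       folds, n_components=2, fullness=1.0)
        row = out.iloc[0]
        assert row["r_component"] > row["r_single_unit"]
        assert row["r_component"] > 0.6

    def test_permuted_target_near_zero(self, rng):
        n = 600
        latent = rng.normal(size=n)
        X = np.column_stack([latent, rng.normal(size=n)])
        Y = np.column_stack([latent + rng.normal(size=n) for _ in range(8)])
        groups = {"waiting_time": np.array([0]), "other": np.array([1])}
        folds = np.repeat(np.arange(4), n // 4)
        shuffled = rng.permutation(latent)
        out = component_vs_single_unit(X, Y, groups, {"waiting_time": shuffled},
                                       folds, n_components=2, fullness=1.0)
        assert abs(out.iloc[0]["r_component"]) < 0.15
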