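import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from tdafold.errors import DegenerateFactorError, InvalidArgumentError
from tdafold.factorize import (
    cophenetic_rank_selection,
    nmf_fit,
    normalize_factors,
    rank_selection_rss,
    transform,
)
from tdafold.synthetic import planted_block_matrix, planted_factor_matrix


def best_permutation_cosine(W, W_true):
    a = W / np.linalg.norm(W, axis=0)
    b = W_true / np.linalg.norm(W_true, axis=0)
    C = a.T @ b
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci].mean()


class TestNmfFit:
    def test_exact_planted_factors_fit_to_numerical_floor(self):
        rng = np.random.default_rng(0)
        V = rng.gamma(2.0, 1.0, (80, 3)) @ rng.gamma(2.0, 1.0, (3, 150))
        model = nmf_fit(V, 3, seed=1, max_iter=4000, tol=1e-14)
        rel = model.objective / np.linalg.norm(V)
        assert rel < 1e-3

    def test_rank_one_direction_recovered(self):
        rng = np.random.default_rng(2)
        w = rng.gamma(2.0, 1.0, 60)
        h = rng.gamma(2.0, 1.0, 100)
        V = np.outer(w, h)
        model = nmf_fit(V, 1, seed=0)
        cos = float(model.W[:, 0] @ w / (np.linalg.norm(model.W) * np.linalg.norm(w)))
        assert cos > 0.999

    @pytest.mark.parametrize("seed", [0, 1])
    def test_objective_never_increases(self, seed):
        V, _, _ = planted_factor_matrix(60, 80, rank=4, noise=0.1, seed=seed)
        model = nmf_fit(V, 4, seed=seed, max_iter=300)
        h = model.objective_history
        assert np.all(np.diff(h) <= 1e-9 * h[0])

    def test_unit_norm_basis_columns(self):
        V, _, _ = planted_factor_matrix(40, 60, rank=3, noise=0.1, seed=3)
        model = nmf_fit(V, 3, seed=0)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-9)

    def test_seed_determinism(self):
        V, _, _ = planted_factor_matrix(40, 60, rank=3, noise=0.1, seed=4)
        m1 = nmf_fit(V, 3, seed=11)
        m2 = nmf_fit(V, 3, seed=11)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.H, m2.H)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nmf_fit(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_agrees_with_sklearn_objective(self):
        # independent cross-check: our Frobenius optimum is no worse than
        # sklearn's multiplicative-update NMF by more than a few percent
        from sklearn.decomposition import NMF

        V, _, _ = planted_factor_matrix(60, 90, rank=4, noise=0.05, seed=5)
        ours = nmf_fit(V, 4, seed=0, max_iter=3000, tol=1e-10).objective
        sk = NMF(4, solver="mu", init="random", random_state=0, max_iter=3000, tol=1e-10)
        sk.fit(V.T)
        theirs = np.linalg.norm(V.T - sk.transform(V.T) @ sk.components_)
        assert ours <= 1.05 * theirs


class TestNormalizeFactors:
    def test_rescales_column_and_row_inversely(self):
        W = np.array([[2.0, 0.0], [0.0, 1.0]])
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        Wn, Hn = normalize_factors(W, H)
        assert np.allclose(Wn[:, 0], [1.0, 0.0])
        assert np.allclose(Hn[0], [2.0, 4.0])

    def test_identity_on_normalized_input(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        H = np.ones((2, 3))
        Wn, Hn = normalize_factors(W, H)
        assert np.array_equal(Wn, W) and np.array_equal(Hn, H)

    def test_reconstruction_preserved_exactly(self):
        rng = np.random.default_rng(0)
        W = rng.random((10, 4)) + 0.1
        H = rng.random((4, 7))
        Wn, Hn = normalize_factors(W, H)
        assert np.allclose(Wn @ Hn, W @ H, atol=1e-12)

    def test_zero_column_rejected_with_column_named(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateFactorError, match="1"):
            normalize_factors(W, np.ones((2, 3)))


class TestParameterRecovery:
    def test_planted_basis_recovered_at_scale(self):
        # smaller replica of the headline recovery experiment for speed
        cosines = []
        for seed in range(3):
            V, W_true, _ = planted_factor_matrix(150, 400, rank=5, noise=0.05, seed=seed)
            model = nmf_fit(V, 5, seed=seed + 100, max_iter=1500)
            cosines.append(best_permutation_cosine(model.W, W_true))
        assert np.mean(cosines) >= 0.95


class TestRankSelectionRss:
    @pytest.mark.parametrize("seed", range(3))
    def test_planted_rank_found_at_inflection(self, seed):
        V, _, _ = planted_factor_matrix(80, 250, rank=4, noise=0.05, seed=seed)
        report = rank_selection_rss(V, list(range(2, 9)), n_subsample=250, seed=seed)
        assert report.selected_rank_rss == 4

    def test_pure_noise_reports_no_inflection(self):
        V = np.random.default_rng(0).random((80, 250))
        report = rank_selection_rss(V, list(range(2, 9)), n_subsample=250, seed=1)
        assert report.selected_rank_rss is None

    def test_rss_non_increasing_in_rank(self):
        V, _, _ = planted_factor_matrix(60, 200, rank=4, noise=0.1, seed=7)
        report = rank_selection_rss(V, [2, 3, 4, 5, 6], n_subsample=200, seed=2)
        rss = [report.rss[L] for L in sorted(report.rss)]
        scale = rss[0]
        assert all(b <= a + 1e-6 * scale for a, b in zip(rss, rss[1:]))

    def test_oversized_subsample_clamped_with_warning(self):
        V, _, _ = planted_factor_matrix(30, 50, rank=2, noise=0.1, seed=0)
        with pytest.warns(UserWarning, match="exceeds"):
            rank_selection_rss(V, [2, 3], n_subsample=500, seed=0)


class TestCopheneticRankSelection:
    def test_perfectly_stable_clustering_scores_one(self):
        # two well-separated blocks cluster identically in every run
        rng = np.random.default_rng(0)
        a = np.zeros((40, 30))
        a[:20, :15] = rng.gamma(2, 1, (20, 15)) + 5
        a[20:, 15:] = rng.gamma(2, 1, (20, 15)) + 5
        report = cophenetic_rank_selection(a, [2], n_runs=5, n_subsample=30, seed=0)
        assert report.cophenetic[2] == pytest.approx(1.0)

    def test_coefficients_within_unit_interval(self):
        V, _ = planted_block_matrix(seed=1, samples_per_block=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cophenetic_rank_selection(V, [3, 4, 5], n_runs=5, seed=1)
        assert all(0.0 <= v <= 1.0 for v in report.cophenetic.values())

    def test_requires_multiple_runs(self):
        with pytest.raises(InvalidArgumentError):
            cophenetic_rank_selection(np.ones((4, 4)), [2], n_runs=1)


class TestTransform:
    def test_training_columns_reproduce_training_scores(self):
        V, _, _ = planted_factor_matrix(60, 120, rank=4, noise=0.05, seed=9)
        model = nmf_fit(V, 4, seed=0, max_iter=3000, tol=1e-9)
        H_new = transform(model, V)
        denom = np.linalg.norm(model.H)
        assert np.linalg.norm(H_new - model.H) / denom < 0.05

    def test_zero_column_maps_to_zero_scores(self):
        V, _, _ = planted_factor_matrix(40, 50, rank=3, noise=0.05, seed=2)
        model = nmf_fit(V, 3, seed=0)
        H_new = transform(model, np.zeros((40, 2)))
        assert np.all(H_new < 1e-6)

    def test_scores_always_non_negative(self):
        V, _, _ = planted_factor_matrix(40, 50, rank=3, noise=0.3, seed=3)
        model = nmf_fit(V, 3, seed=0)
        assert np.all(transform(model, V) >= 0)

    def test_dimension_mismatch_rejected(self):
        V, _, _ = planted_factor_matrix(40, 50, rank=3, noise=0.1, seed=4)
        model = nmf_fit(V, 3, seed=0)
        with pytest.raises(InvalidArgumentError):
            transform(model, np.ones((39, 5)))
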