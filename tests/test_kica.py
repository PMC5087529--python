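"""PCA reduction, the kernel ICA contrast, and source recovery."""

import numpy as np
import pytest

from ecg_mdfx import kica
from ecg_mdfx.kica import (amari_index, centered_gram, kica_contrast, kica_fit,
                           pca_fit, pca_transform, project_beats, rbf_kernel)


class TestPCA:
    def test_rank_two_data_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(200, 2)) @ basis
        model = pca_fit(X, n_components=2)
        assert model.cumulative_contribution == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        model = pca_fit(X, n_components=8)
        scores = pca_transform(X, model)
        recon = scores @ model.eigenvectors + model.mean_vector
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_known_factor_variances_recovered(self):
        rng = np.random.default_rng(2)
        n, d = 1000, 12
        factors = rng.normal(size=(n, 3)) * np.array([5.0, 3.0, 1.5])
        load, _ = np.linalg.qr(rng.normal(size=(d, 3)))
        X = factors @ load.T + 1e-3 * rng.normal(size=(n, d))
        # independent oracle: brute-force eigendecomposition of the covariance
        evals_oracle = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1][:3]
        model = pca_fit(X, n_components=3)
        np.testing.assert_allclose(model.eigenvalues, evals_oracle, rtol=1e-8)
        np.testing.assert_allclose(
            np.sqrt(evals_oracle), [5.0, 3.0, 1.5], rtol=0.1)

    def test_scores_covariance_matches_eigenvalues(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 10)) * np.linspace(3, 0.5, 10)
        model = pca_fit(X, n_components=4)
        scores = pca_transform(X, model)
        cov = np.cov(scores.T, ddof=1)
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues), atol=1e-6)

    def test_transform_of_mean_is_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 6)) + 5.0
        model = pca_fit(X, n_components=3)
        out = pca_transform(model.mean_vector[None, :], model)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residual_equals_discarded_variance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 8)) * np.linspace(4, 0.3, 8)
        model = pca_fit(X, n_components=3)
        scores = pca_transform(X, model)
        recon = scores @ model.eigenvectors + model.mean_vector
        resid = float(np.sum((X - recon) ** 2))
        all_evals = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
        expected = float(all_evals[3:].sum()) * (len(X) - 1)
        assert resid == pytest.approx(expected, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.ones((10, 5)), n_components=2)


class TestKernel:
    def test_rbf_values(self):
        assert rbf_kernel([1.0, 0.0], [1.0, 0.0], 1.0) == 1.0
        u, v = np.array([1.0, 1.0]), np.array([0.0, 0.0])  # ||u-v||^2 = 2
        assert rbf_kernel(u, v, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-9)
        d1 = rbf_kernel([0.0], [1.0], 1.0)
        d2 = rbf_kernel([0.0], [2.0], 1.0)
        assert d2 < d1 < 1.0

    def test_rbf_invalid_sigma(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)

    def test_centered_gram_of_constant_is_zero(self):
        G = centered_gram(np.full(5, 2.0), 1.0)
        np.testing.assert_allclose(G, 0.0, atol=1e-12)

    def test_centered_gram_row_sums_vanish(self):
        x = np.random.default_rng(0).normal(size=40)
        G = centered_gram(x, 1.0)
        assert np.max(np.abs(G.sum(axis=1))) < 1e-8
        np.testing.assert_allclose(G, G.T, atol=1e-12)

    def test_centered_gram_hand_computed(self):
        x = np.array([0.0, 1.0, 2.0])
        K = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                K[i, j] = np.exp(-((x[i] - x[j]) ** 2) / 2.0)
        H = np.eye(3) - np.ones((3, 3)) / 3.0
        np.testing.assert_allclose(centered_gram(x, 1.0), H @ K @ H, atol=1e-12)


class TestContrast:
    def test_independent_sources_have_small_contrast(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(2000, 2))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        c = kica_contrast(np.eye(2), Z)
        assert 0.0 <= c < 0.05

    def test_duplicated_source_has_large_contrast(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=500)
        Z_ind = np.column_stack([z, rng.normal(size=500)])
        Z_dup = np.column_stack([z, z + 1e-6 * rng.normal(size=500)])
        c_ind = kica_contrast(np.eye(2), Z_ind)
        c_dup = kica_contrast(np.eye(2), Z_dup)
        assert c_dup > c_ind
        assert c_dup > 0.5

    def test_contrast_nonnegative_for_random_rotations(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(150, 3))
        for _ in range(5):
            W, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            assert kica_contrast(W, Z) >= 0.0

    def test_contrast_invariant_to_permutation_and_sign(self):
        rng = np.random.default_rng(3)
        Z = np.column_stack([rng.uniform(-1, 1, 200), rng.laplace(size=200),
                             rng.normal(size=200)])
        W, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = kica_contrast(W, Z)
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        D = np.diag([1.0, -1.0, -1.0])
        assert kica_contrast(P @ W, Z) == pytest.approx(base, abs=1e-6)
        assert kica_contrast(D @ W, Z) == pytest.approx(base, abs=1e-6)


class TestFit:
    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5)) @ rng.normal(size=(5, 5))
        model = kica_fit(X, p=5, seed=0, max_sweeps=1, contrast_subsample=100)
        Z = (X - model.mean) @ model.whitener
        np.testing.assert_allclose(np.cov(Z.T, ddof=1), np.eye(5), atol=1e-6)

    def test_already_independent_input_keeps_identity(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.uniform(-2, 2, 600),
                             rng.laplace(size=600),
                             np.sign(rng.normal(size=600))])
        model = kica_fit(X, p=3, seed=0, n_restarts=1)
        # unmixing o mixing should be near a permutation: here mixing = I
        B = model.W @ model.whitener.T
        assert amari_index(B) < 0.1

    def test_three_source_blind_recovery(self):
        rng = np.random.default_rng(42)
        n = 1000
        S = np.column_stack([
            rng.uniform(-1.7, 1.7, n),
            rng.laplace(0, 1, n),
            np.sign(rng.normal(size=n)) * rng.uniform(0.5, 1.5, n),
        ])
        A = rng.normal(size=(3, 3))
        X = S @ A.T
        model = kica_fit(X, p=3, seed=1, n_restarts=2)
        B = model.W @ model.whitener.T
        assert amari_index(B @ A) < 0.1
        assert model.contrast_value >= 0.0

    def test_same_seed_same_result(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4)) ** 3
        m1 = kica_fit(X, p=4, seed=7, max_sweeps=1)
        m2 = kica_fit(X, p=4, seed=7, max_sweeps=1)
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_input_validation(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            kica_fit(X, p=1)
        with pytest.raises(ValueError):
            kica_fit(X[:3], p=3)


class TestProjection:
    def test_orthogonal_rows_give_unit_vectors(self):
        rng = np.random.default_rng(0)
        S, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        S = S.T  # 4 x 10, orthonormal rows
        for j in range(4):
            coeffs = project_beats(S[j][None, :], S)[0]
            np.testing.assert_allclose(coeffs, np.eye(4)[j], atol=1e-10)

    def test_zero_beat_gives_zero_coefficients(self):
        S = np.random.default_rng(1).normal(size=(4, 10))
        np.testing.assert_allclose(project_beats(np.zeros((1, 10)), S), 0.0)

    def test_projection_is_least_squares(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(4, 10))
        x = rng.normal(size=(1, 10))
        A = project_beats(x, S)
        # independent oracle: explicit least-squares solve
        coef_lsq, *_ = np.linalg.lstsq(S.T, x[0], rcond=None)
        np.testing.assert_allclose(A[0], coef_lsq, atol=1e-8)
        resid = x[0] - A[0] @ S
        np.testing.assert_allclose(S @ resid, 0.0, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            project_beats(np.zeros((1, 9)), np.zeros((4, 10)))


def test_end_to_end_mixture_recovery():
    """Beats built from 4 independent base signals: the PCA->KICA->projection
    chain recovers each beat's mixing coefficients up to permutation/scale."""
    rng = np.random.default_rng(0)
    n, length, p = 500, 250, 4
    t = np.linspace(0, 1, length)
    bases = np.vstack([
        np.sin(2 * np.pi * 3 * t),
        np.sign(np.sin(2 * np.pi * 7 * t)),
        np.exp(-((t - 0.3) ** 2) / 0.005),
        t - 0.5,
    ])
    coeffs_true = np.column_stack([
        rng.uniform(0.5, 2.0, n),
        rng.laplace(1.0, 0.3, n),
        rng.uniform(-1.5, 1.5, n),
        np.sign(rng.normal(size=n)) * rng.uniform(0.5, 1.0, n),
    ])
    X = coeffs_true @ bases + 1e-3 * rng.normal(size=(n, length))
    pca = pca_fit(X, n_components=p)
    scores = pca_transform(X, pca)
    model = kica_fit(scores, p=p, seed=3, n_restarts=2, pca_model=pca)
    A = project_beats(X, model.S)
    assert A.shape == (n, p)
    # each true coefficient series must be captured by some recovered column
    used = set()
    for j in range(p):
        corr = [abs(np.corrcoef(coeffs_true[:, j], A[:, k])[0, 1])
                for k in range(p)]
        k = int(np.argmax(corr))
        assert corr[k] > 0.95
        used.add(k)
    assert len(used) == p
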