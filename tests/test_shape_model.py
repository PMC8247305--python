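"""Procrustes alignment, PCA shape basis, and the sparse lasso projection."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from wrinklefind.shape_model import (
    apply_similarity,
    build_shape_pca,
    lasso_objective,
    params_from_shape,
    procrustes_align,
    shape_from_params,
    similarity_transform,
    sparse_shape_projection,
)


def _ellipse(n=20, rx=3.0, ry=1.5):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([rx * np.cos(t), ry * np.sin(t)], axis=1)


def _random_similarity(rng):
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.5, 2.0)
    rot = scale * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    return rot, rng.uniform(-10, 10, size=2)


class TestProcrustes:
    def test_identical_copies_mean_is_normalized_copy(self):
        shape = _ellipse()
        aligned, mean = procrustes_align([shape.copy() for _ in range(4)])
        a_mat, t = similarity_transform(shape, mean)
        assert np.allclose(apply_similarity(shape, a_mat, t), mean, atol=1e-9)
        for al in aligned:
            assert np.allclose(al, mean, atol=1e-9)

    def test_similarity_copies_align_exactly(self, rng):
        shape = _ellipse()
        rot, t = _random_similarity(rng)
        aligned, _ = procrustes_align([shape, shape @ rot.T + t])
        assert np.abs(aligned[0] - aligned[1]).max() < 1e-6

    def test_noisy_ellipses_recover_generator(self, rng):
        clean = _ellipse()
        shapes = [clean + rng.normal(0, 0.05, clean.shape) for _ in range(3)]
        _, mean = procrustes_align(shapes)
        a_mat, t = similarity_transform(clean, mean)
        back = apply_similarity(clean, a_mat, t)
        # compare in the original pixel scale of the generator
        scale = np.linalg.norm(a_mat[:, 0])
        rms = np.sqrt(((back - mean) ** 2).sum(axis=1).mean()) / scale
        assert rms < 0.5

    def test_mean_invariant_under_common_similarity(self, rng):
        shapes = [_ellipse() + rng.normal(0, 0.1, (20, 2)) for _ in range(5)]
        rot, t = _random_similarity(rng)
        _, mean_a = procrustes_align(shapes)
        _, mean_b = procrustes_align([s @ rot.T + t for s in shapes])
        a_mat, tt = similarity_transform(mean_b, mean_a)
        assert np.abs(apply_similarity(mean_b, a_mat, tt) - mean_a).max() < 1e-6

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            procrustes_align([np.zeros((5, 2)), np.ones((5, 2))])


class TestShapePCA:
    def test_identical_shapes_zero_components(self):
        model = build_shape_pca([_ellipse()] * 4)
        assert model.n_components == 0
        assert model.eigenvalues.size == 0

    def test_single_direction_of_variation_is_rank_one(self):
        base = _ellipse()
        direction = np.zeros_like(base)
        direction[0] = (1.0, 0.5)
        shapes = [base + t * direction for t in (-1.0, 0.0, 1.0, 2.0)]
        model = build_shape_pca(shapes, variance_kept=1.0)
        assert model.n_components == 1

    def test_matches_dense_eigendecomposition(self, rng):
        shapes = [rng.standard_normal((10, 2)) for _ in range(8)]
        model = build_shape_pca(shapes, variance_kept=1.0)
        x = np.stack([s.ravel() for s in shapes])
        cov = np.cov(x, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        k = model.n_components
        assert np.allclose(model.eigenvalues, vals[:k], atol=1e-8)
        for j in range(k):  # eigenvectors defined up to sign
            dot = abs(model.basis[:, j] @ vecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_basis_orthonormal_and_spectrum_sorted(self, rng):
        shapes = [rng.standard_normal((10, 2)) for _ in range(8)]
        model = build_shape_pca(shapes, variance_kept=0.98)
        gram = model.basis.T @ model.basis
        assert np.abs(gram - np.eye(model.n_components)).max() < 1e-8
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= 0)

    def test_invalid_variance_kept(self):
        with pytest.raises(ValueError):
            build_shape_pca([_ellipse()] * 3, variance_kept=1.5)


class TestShapeSynthesis:
    @pytest.fixture()
    def model(self, rng):
        shapes = [_ellipse() + rng.normal(0, 0.3, (20, 2)) for _ in range(10)]
        return build_shape_pca(shapes, variance_kept=1.0)

    def test_zero_params_return_mean(self, model):
        assert np.allclose(shape_from_params(model, np.zeros(model.n_components)),
                           model.mean_shape)

    def test_linearity_along_first_mode(self, model):
        e1 = np.zeros(model.n_components)
        e1[0] = 1.0
        s1 = shape_from_params(model, e1)
        s2 = shape_from_params(model, 2 * e1)
        assert np.allclose(s2 - model.mean_shape, 2 * (s1 - model.mean_shape))

    def test_round_trip_in_span(self, model, rng):
        p = rng.standard_normal(model.n_components)
        shape = shape_from_params(model, p)
        assert np.abs(params_from_shape(model, shape) - p).max() < 1e-10
        again = shape_from_params(model, params_from_shape(model, shape))
        assert np.abs(again - shape).max() < 1e-8

    def test_out_of_span_projection_residual_orthogonal(self, model, rng):
        shape = model.mean_shape + rng.standard_normal(model.mean_shape.shape)
        p = params_from_shape(model, shape)
        recon = shape_from_params(model, p)
        residual = (shape - recon).ravel()
        assert np.abs(model.basis.T @ residual).max() < 1e-8


class TestSparseProjection:
    def test_orthonormal_dictionary_lambda_zero_is_least_squares(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((8, 5)))
        vec = rng.standard_normal(8)
        s, recon = sparse_shape_projection(vec, q, lam=0.0)
        assert np.allclose(s, q.T @ vec, atol=1e-10)
        assert np.allclose(recon, q @ q.T @ vec, atol=1e-10)

    def test_atom_recovery(self, rng):
        w = rng.standard_normal((12, 5))
        w /= np.linalg.norm(w, axis=0)
        s, _ = sparse_shape_projection(w[:, 2], w, lam=1e-8)
        assert s[2] == pytest.approx(1.0, abs=1e-3)
        assert np.abs(np.delete(s, 2)).max() < 1e-3

    @pytest.mark.parametrize("lam", [1e-6, 0.01, 0.1])
    def test_objective_matches_sklearn_coordinate_descent(self, rng, lam):
        w = rng.standard_normal((8, 5))
        vec = rng.standard_normal(8)
        s, _ = sparse_shape_projection(vec, w, lam=lam, max_sweeps=5000)
        # sklearn solves (1/2n)||y - Xw||^2 + alpha ||w||_1
        ref = Lasso(alpha=lam / len(vec), fit_intercept=False, tol=1e-12,
                    max_iter=100000).fit(w, vec)
        ours = lasso_objective(vec, w, s, lam)
        theirs = lasso_objective(vec, w, ref.coef_, lam)
        assert ours <= theirs + 1e-6

    def test_objective_non_increasing_over_sweeps(self, rng):
        w = rng.standard_normal((10, 6))
        vec = rng.standard_normal(10)
        objs = [
            lasso_objective(vec, w, sparse_shape_projection(
                vec, w, lam=0.05, max_sweeps=k)[0], 0.05)
            for k in range(1, 8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            sparse_shape_projection(np.ones(4), np.zeros((4, 0)), 0.1)
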