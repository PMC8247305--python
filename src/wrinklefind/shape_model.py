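"""Statistical shape modeling of landmark configurations.

Shapes are ordered 2-D point sets (88 full-face points or 20 wrinkle-only
points), handled as ``(n, 2)`` arrays and flattened to vectors
``x = (x1, y1, ..., xn, yn)`` for linear algebra.  The model is the classic
point-distribution model: generalized Procrustes alignment removes
similarity transforms, PCA of the aligned shapes yields an orthonormal basis
``E`` so that any shape is synthesized as ``s = mean + E p`` and analyzed as
``p = E^T (s - mean)``.

A small L1-regularized projection onto a dictionary of training wrinkle
shapes (lasso, solved by coordinate descent) is included: it snaps a noisy
ridge-derived wrinkle polyline onto the span of plausible training wrinkle
structures before it seeds the appearance-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeModel",
    "similarity_transform",
    "apply_similarity",
    "procrustes_align",
    "build_shape_pca",
    "shape_from_params",
    "params_from_shape",
    "sparse_shape_projection",
    "lasso_objective",
]


@dataclass(frozen=True)
class ShapeModel:
    """Procrustes mean, orthonormal PCA basis and eigenvalue spectrum."""

    mean_shape: np.ndarray  # (n, 2)
    basis: np.ndarray  # (2n, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), non-negative, non-increasing

    @property
    def n_points(self) -> int:
        return len(self.mean_shape)

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


def _as_shape(shape: np.ndarray) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    if shape.ndim != 2 or shape.shape[1] != 2:
        raise ValueError("a shape must be an (n, 2) array")
    return shape


def similarity_transform(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares similarity (scale * rotation, translation) mapping src -> dst.

    Returns ``(A, t)`` with ``dst ~= src @ A.T + t`` (Umeyama's method without
    reflection).
    """
    src, dst = _as_shape(src), _as_shape(dst)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same number of points")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs**2).sum()
    if var_s <= 0:
        raise ValueError("degenerate source shape (all points identical)")
    cov = xd.T @ xs
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.array([1.0, d])
    rot = u @ np.diag(diag) @ vt
    scale = (s * diag).sum() / var_s
    a_mat = scale * rot
    t = mu_d - mu_s @ a_mat.T
    return a_mat, t


def apply_similarity(shape: np.ndarray, a_mat: np.ndarray, t: np.ndarray) -> np.ndarray:
    return _as_shape(shape) @ np.asarray(a_mat).T + np.asarray(t)


def _normalize(shape: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    centered = shape - shape.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size <= 0:
        raise ValueError("degenerate shape (all points identical)")
    return centered / size


def procrustes_align(
    shapes: list[np.ndarray], tol: float = 1e-7, max_iter: int = 100
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment.

    Iterates: align every shape to the current mean by a similarity
    transform, recompute the mean, renormalize it (unit centroid size,
    centered at the origin), until the mean moves less than ``tol`` or
    ``max_iter`` rounds.  Returns the aligned shapes and the mean shape.
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    shapes = [_as_shape(s) for s in shapes]
    n_pts = {len(s) for s in shapes}
    if len(n_pts) != 1:
        raise ValueError("all shapes must have the same number of points")
    mean = _normalize(shapes[0])
    aligned = list(shapes)
    for _ in range(max_iter):
        aligned = [apply_similarity(s, *similarity_transform(s, mean)) for s in shapes]
        new_mean = _normalize(np.mean(aligned, axis=0))
        moved = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if moved < tol:
            break
    aligned = [apply_similarity(s, *similarity_transform(s, mean)) for s in shapes]
    return aligned, mean


def build_shape_pca(aligned: list[np.ndarray], variance_kept: float = 0.98) -> ShapeModel:
    """PCA of aligned shapes via the sample covariance (divisor n-1).

    Keeps the smallest number of leading components whose cumulative variance
    reaches ``variance_kept``; identical shapes yield zero components.
    """
    if not 0.0 < variance_kept <= 1.0:
        raise ValueError("variance_kept must be in (0, 1]")
    if len(aligned) < 2:
        raise ValueError("need at least two shapes")
    x_mat = np.stack([_as_shape(s).ravel() for s in aligned])
    mean_vec = x_mat.mean(axis=0)
    centered = x_mat - mean_vec
    cov = centered.T @ centered / (len(aligned) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # variance below a tiny fraction of the raw coordinate energy is roundoff
    floor = 1e-12 * float((x_mat**2).mean())
    eigvals[eigvals < floor] = 0.0
    total = eigvals.sum()
    if total <= 0:
        k = 0
    else:
        k = int(np.searchsorted(np.cumsum(eigvals) / total, variance_kept) + 1)
        k = min(k, len(aligned) - 1, len(mean_vec))
    return ShapeModel(
        mean_shape=mean_vec.reshape(-1, 2),
        basis=eigvecs[:, :k],
        eigenvalues=eigvals[:k],
    )


def shape_from_params(model: ShapeModel, p: np.ndarray) -> np.ndarray:
    """Linear shape synthesis ``s = mean + E p``."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.shape != (model.n_components,):
        raise ValueError(f"expected {model.n_components} parameters, got {p.shape}")
    vec = model.mean_shape.ravel() + model.basis @ p
    return vec.reshape(-1, 2)


def params_from_shape(model: ShapeModel, shape: np.ndarray) -> np.ndarray:
    """Orthogonal projection ``p = E^T (s - mean)``."""
    shape = _as_shape(shape)
    if len(shape) != model.n_points:
        raise ValueError(
            f"shape has {len(shape)} points, model expects {model.n_points}"
        )
    return model.basis.T @ (shape.ravel() - model.mean_shape.ravel())


def lasso_objective(vec: np.ndarray, w_mat: np.ndarray, s: np.ndarray, lam: float) -> float:
    """The coordinate-descent objective 0.5 * ||vec - W s||^2 + lam * ||s||_1."""
    resid = vec - w_mat @ s
    return 0.5 * float(resid @ resid) + lam * float(np.abs(s).sum())


def sparse_shape_projection(
    shape_vec: np.ndarray,
    dictionary: np.ndarray,
    lam: float = 1e-6,
    max_sweeps: int = 1000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-regularized projection of a shape vector onto a shape dictionary.

    Solves ``min_s 0.5 * ||vec - W s||^2 + lam * ||s||_1`` by cyclic
    coordinate descent with soft thresholding and returns ``(s, W s)``.
    The objective is non-increasing across sweeps; iteration stops when a
    full sweep improves it by less than ``tol``.
    """
    vec = np.asarray(shape_vec, dtype=float).ravel()
    w_mat = np.asarray(dictionary, dtype=float)
    if w_mat.ndim != 2 or w_mat.shape[1] == 0:
        raise ValueError("dictionary must be a (dim, n_atoms) matrix with atoms")
    if w_mat.shape[0] != vec.shape[0]:
        raise ValueError("dictionary rows must match the shape vector dimension")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n_atoms = w_mat.shape[1]
    col_sq = (w_mat**2).sum(axis=0)
    s = np.zeros(n_atoms)
    resid = vec.copy()  # vec - W s
    obj = lasso_objective(vec, w_mat, s, lam)
    for _ in range(max_sweeps):
        for j in range(n_atoms):
            if col_sq[j] <= 0:
                continue
            wj = w_mat[:, j]
            rho = wj @ resid + col_sq[j] * s[j]
            new_sj = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new_sj != s[j]:
                resid -= wj * (new_sj - s[j])
                s[j] = new_sj
        new_obj = lasso_objective(vec, w_mat, s, lam)
        if obj - new_obj < tol:
            obj = new_obj
            break
        obj = new_obj
    return s, w_mat @ s
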