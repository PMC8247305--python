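"""Appearance model and fixed-Jacobian steepest-descent fitting.

The appearance model couples a point-distribution shape model with a texture
model: training images are warped (piecewise-affine, over a Delaunay
triangulation of the mean shape) into a shape-free reference frame, sampled
on the pixel lattice inside the mesh, photometrically normalized to zero
mean / unit variance, and summarized by PCA.

Fitting minimizes the texture residual ``dg = g_image - g_model`` over a
combined parameter vector ``p = (a, b, tx, ty, q_1..q_k)``: four similarity
pose parameters (the image shape is ``M(a, b) s_ref + t`` with
``M = [[1+a, -b], [b, 1+a]]``) composed with the shape-model coordinates
``s_ref = s0 + E q``.  The parameter update is the classic fixed-Jacobian
steepest-descent step

    dp = (J^T J)^(-1) J^T dg,      p_k = p_(k-1) - alpha * dp,

with J estimated once at training time by numeric perturbation of each
parameter around the ground-truth fits, and a step-halving line search over
alpha in {1, 1/2, 1/4, 1/8} that accepts the first step that decreases the
error.  The shape offset ``s0`` defaults to the model mean; passing a
per-image initial shape instead is exactly the "unique mean shape" variant
used by the wrinkle pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .shape_model import (
    ShapeModel,
    build_shape_pca,
    procrustes_align,
    similarity_transform,
)

__all__ = [
    "ReferenceFrame",
    "AppearanceModel",
    "FitResult",
    "MeshDegenerateError",
    "sample_texture",
    "build_appearance_model",
    "fit",
]

_RIDGE_EPS = 1e-8  # Tikhonov damping of J^T J against rank deficiency
_ALPHAS = (1.0, 0.5, 0.25, 0.125)


class MeshDegenerateError(RuntimeError):
    """Raised when a shape flips or collapses triangles of the model mesh."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Triangulated mean shape with its interior pixel lattice.

    Every reference pixel stores the triangle it falls in and its barycentric
    coordinates; warping to an image is then a barycentric combination of the
    target shape's triangle vertices.
    """

    points: np.ndarray  # (n, 2) reference-frame landmark coordinates
    simplices: np.ndarray  # (n_tri, 3) vertex indices
    pixel_tri: np.ndarray  # (n_pix,) triangle index per reference pixel
    barycentric: np.ndarray  # (n_pix, 3)
    pixel_coords: np.ndarray  # (n_pix, 2) (x, y), for rendering/debugging

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_tri)


@dataclass(frozen=True)
class AppearanceModel:
    shape_model: ShapeModel  # in reference-frame coordinates
    frame: ReferenceFrame
    texture_mean: np.ndarray  # (n_pix,)
    texture_basis: np.ndarray  # (n_pix, kt), orthonormal columns
    texture_eigenvalues: np.ndarray
    jacobian: np.ndarray  # (n_pix, 4 + k)
    _update_matrix: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        jac = self.jacobian
        jtj = jac.T @ jac + _RIDGE_EPS * np.eye(jac.shape[1])
        object.__setattr__(self, "_update_matrix", np.linalg.solve(jtj, jac.T))

    @property
    def n_params(self) -> int:
        return 4 + self.shape_model.n_components

    def predict_displacement(self, residual: np.ndarray) -> np.ndarray:
        """dp = (J^T J + eps I)^(-1) J^T dg."""
        return self._update_matrix @ residual


@dataclass
class FitResult:
    final_shape: np.ndarray  # (n, 2) image coordinates
    final_params: np.ndarray  # (4 + k,)
    error_trace: list[float]
    iterations: int
    converged: bool
    init_mode: str = ""
    fallback: bool = False


# --- pose ------------------------------------------------------------------


def _pose_matrix(pose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b, tx, ty = pose
    return np.array([[1.0 + a, -b], [b, 1.0 + a]]), np.array([tx, ty])


def _pose_apply(pose: np.ndarray, shape_ref: np.ndarray) -> np.ndarray:
    m, t = _pose_matrix(pose)
    return shape_ref @ m.T + t


def _pose_from_similarity(a_mat: np.ndarray, t: np.ndarray) -> np.ndarray:
    # a_mat is scale*rotation: [[c, -s], [s, c]]
    return np.array([a_mat[0, 0] - 1.0, a_mat[1, 0], t[0], t[1]])


def _pose_invert_points(pose: np.ndarray, shape_img: np.ndarray) -> np.ndarray:
    m, t = _pose_matrix(pose)
    return (shape_img - t) @ np.linalg.inv(m).T


# --- reference frame and texture sampling ----------------------------------


def _build_reference_frame(mean_shape: np.ndarray, margin: float = 2.0) -> ReferenceFrame:
    """Delaunay-triangulate the mean shape and index its interior pixels."""
    points = mean_shape - mean_shape.min(axis=0) + margin
    tri = Delaunay(points)
    x_max, y_max = points.max(axis=0) + margin
    xx, yy = np.meshgrid(np.arange(int(np.ceil(x_max))), np.arange(int(np.ceil(y_max))))
    lattice = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    simplex = tri.find_simplex(lattice)
    inside = simplex >= 0
    lattice, simplex = lattice[inside], simplex[inside]
    trans = tri.transform[simplex]  # (n_pix, 3, 2): affine to barycentric
    bary2 = np.einsum("pij,pj->pi", trans[:, :2, :], lattice - trans[:, 2, :])
    bary = np.concatenate([bary2, 1.0 - bary2.sum(axis=1, keepdims=True)], axis=1)
    return ReferenceFrame(
        points=points,
        simplices=tri.simplices.copy(),
        pixel_tri=simplex,
        barycentric=bary,
        pixel_coords=lattice,
    )


def _triangle_areas(shape: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v = shape[simplices]
    return 0.5 * (
        (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1])
        - (v[:, 2, 0] - v[:, 0, 0]) * (v[:, 1, 1] - v[:, 0, 1])
    )


def _warp_positions(frame: ReferenceFrame, shape: np.ndarray) -> np.ndarray:
    verts = shape[frame.simplices[frame.pixel_tri]]  # (n_pix, 3, 2)
    return np.einsum("pi,pij->pj", frame.barycentric, verts)


def _normalize_texture(raw: np.ndarray) -> np.ndarray:
    mu = raw.mean()
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros_like(raw)
    return (raw - mu) / sd


def sample_texture(
    image: np.ndarray, shape: np.ndarray, model: AppearanceModel
) -> np.ndarray:
    """Warp the image region under ``shape`` into the reference frame.

    Returns the photometrically normalized (zero mean, unit variance) texture
    vector over the reference pixels.  Raises :class:`MeshDegenerateError`
    when the shape flips or collapses mesh triangles (the caller treats this
    as a failed step).
    """
    shape = np.asarray(shape, dtype=float)
    if shape.shape != model.frame.points.shape:
        raise ValueError("shape point count does not match the model")
    ref_area = _triangle_areas(model.frame.points, model.frame.simplices)
    img_area = _triangle_areas(shape, model.frame.simplices)
    if np.any(img_area * ref_area <= 0):
        raise MeshDegenerateError("shape flips or collapses mesh triangles")
    pos = _warp_positions(model.frame, shape)
    raw = map_coordinates(
        np.asarray(image, dtype=float), [pos[:, 1], pos[:, 0]], order=1, mode="nearest"
    )
    return _normalize_texture(raw)


# --- training ---------------------------------------------------------------

#: Default parameter perturbations used to estimate the fixed Jacobian:
#: per shape mode +-0.25 and +-0.5 standard deviations, +-2 px translation,
#: +-5 % scale and +-5 degrees rotation.
DEFAULT_PERTURBATIONS = {
    "shape_sigma": (0.25, 0.5),
    "translate_px": 2.0,
    "scale": 0.05,
    "rotate_deg": 5.0,
}


def _texture_pca(textures: np.ndarray, variance_kept: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = textures.mean(axis=0)
    centered = textures - mean
    # thin SVD: n_samples << n_pixels
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / max(len(textures) - 1, 1)
    # textures are unit-variance; variance below 1e-12 of that is roundoff
    eigvals[eigvals < 1e-12] = 0.0
    total = eigvals.sum()
    if total <= 0:
        k = 0
    else:
        k = int(np.searchsorted(np.cumsum(eigvals) / total, variance_kept) + 1)
        k = min(k, len(textures) - 1)
    return mean, vt[:k].T, eigvals[:k]


def build_appearance_model(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    variance_kept: float = 0.98,
    texture_variance_kept: float = 0.95,
    jacobian_perturbations: dict | None = None,
    texture_scale: float = 0.5,
) -> AppearanceModel:
    """Train shape, texture and fixed-Jacobian models from (image, shape) pairs.

    The reference frame is the Procrustes mean shape rescaled to
    ``texture_scale`` times the mean training centroid size (a half-resolution
    texture by default, which quarters the sampling cost at no measurable
    accuracy loss on smooth skin).  The Jacobian column for parameter ``j``
    averages ``(g(p + delta e_j) - g(p)) / delta`` over all training images
    and the configured displacements; texture-model components are projected
    out of it so the update reacts to residuals the texture model cannot
    explain.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three training pairs")
    pert = dict(DEFAULT_PERTURBATIONS, **(jacobian_perturbations or {}))
    shapes = [np.asarray(s, dtype=float) for _, s in pairs]
    aligned, _ = procrustes_align(shapes)
    sizes = [
        np.sqrt(((s - s.mean(axis=0)) ** 2).sum()) for s in shapes
    ]
    ref_scale = texture_scale * float(np.mean(sizes))
    scaled = [s * ref_scale for s in aligned]
    shape_pca = build_shape_pca(scaled, variance_kept=variance_kept)
    frame = _build_reference_frame(shape_pca.mean_shape)
    offset = frame.points - shape_pca.mean_shape  # constant translation
    shape_model = ShapeModel(
        mean_shape=shape_pca.mean_shape + offset,
        basis=shape_pca.basis,
        eigenvalues=shape_pca.eigenvalues,
    )
    model_stub = AppearanceModel(
        shape_model=shape_model,
        frame=frame,
        texture_mean=np.zeros(frame.n_pixels),
        texture_basis=np.zeros((frame.n_pixels, 0)),
        texture_eigenvalues=np.zeros(0),
        jacobian=np.zeros((frame.n_pixels, 1)),
    )
    textures = np.stack(
        [sample_texture(img, shp, model_stub) for img, shp in pairs]
    )
    tex_mean, tex_basis, tex_eigvals = _texture_pca(textures, texture_variance_kept)

    # fixed Jacobian by numeric perturbation around each ground-truth fit
    n_shape = shape_model.n_components
    n_params = 4 + n_shape
    mean_ref = shape_model.mean_shape
    jac = np.zeros((frame.n_pixels, n_params))
    counts = np.zeros(n_params)
    rot = np.deg2rad(pert["rotate_deg"])
    pose_deltas = {
        0: (pert["scale"], -pert["scale"]),
        1: (np.sin(rot), -np.sin(rot)),
        2: (pert["translate_px"], -pert["translate_px"]),
        3: (pert["translate_px"], -pert["translate_px"]),
    }
    for (img, _), gt in zip(pairs, shapes):
        a_mat, t = similarity_transform(mean_ref, gt)
        pose0 = _pose_from_similarity(a_mat, t)
        s0 = _pose_invert_points(pose0, gt)
        g0 = sample_texture(img, gt, model_stub)
        for j in range(4):
            for delta in pose_deltas[j]:
                pose = pose0.copy()
                pose[j] += delta
                try:
                    g = sample_texture(img, _pose_apply(pose, s0), model_stub)
                except MeshDegenerateError:
                    continue
                jac[:, j] += (g - g0) / delta
                counts[j] += 1
        for mode in range(n_shape):
            sigma = np.sqrt(max(shape_model.eigenvalues[mode], 1e-12))
            for mag in pert["shape_sigma"]:
                for sign in (1.0, -1.0):
                    delta = sign * mag * sigma
                    disp = (shape_model.basis[:, mode] * delta).reshape(-1, 2)
                    try:
                        g = sample_texture(img, _pose_apply(pose0, s0 + disp), model_stub)
                    except MeshDegenerateError:
                        continue
                    jac[:, 4 + mode] += (g - g0) / delta
                    counts[4 + mode] += 1
    counts[counts == 0] = 1.0
    jac /= counts
    if tex_basis.shape[1]:
        jac = jac - tex_basis @ (tex_basis.T @ jac)
    return AppearanceModel(
        shape_model=shape_model,
        frame=frame,
        texture_mean=tex_mean,
        texture_basis=tex_basis,
        texture_eigenvalues=tex_eigvals,
        jacobian=jac,
    )


# --- fitting ----------------------------------------------------------------


def _model_texture(model: AppearanceModel, g_image: np.ndarray) -> np.ndarray:
    """Best texture-model reconstruction of a sampled texture."""
    c = model.texture_basis.T @ (g_image - model.texture_mean)
    return model.texture_mean + model.texture_basis @ c


def _shape_at(model: AppearanceModel, params: np.ndarray, s0: np.ndarray) -> np.ndarray:
    pose, q = params[:4], params[4:]
    ref = s0 + (model.shape_model.basis @ q).reshape(-1, 2)
    return _pose_apply(pose, ref)


def fit(
    model: AppearanceModel,
    image: np.ndarray,
    init_shape: np.ndarray,
    max_iterations: int = 30,
    min_improvement: float = 1e-3,
    shape_offset: str = "init",
) -> FitResult:
    """Fixed-Jacobian steepest-descent fit from an initial shape estimate.

    Each iteration samples the image under the current shape, reconstructs it
    with the texture model, predicts a parameter displacement from the
    residual and retries it with step sizes alpha in {1, 1/2, 1/4, 1/8},
    accepting the first step whose error is below the current error.  The
    fit stops when no step size improves the error (relative improvements
    below ``min_improvement`` count as no improvement, a floating-point
    guard) or after ``max_iterations``.

    ``shape_offset="init"`` uses the initial shape itself as the shape-model
    offset (the per-image "unique mean shape" variant); ``"mean"`` uses the
    trained mean shape, i.e. the initial shape only sets the starting pose
    and shape parameters.
    """
    image = np.asarray(image, dtype=float)
    init_shape = np.asarray(init_shape, dtype=float)
    h, w = image.shape
    if (
        init_shape.min() < -0.5
        or init_shape[:, 0].max() > w - 0.5
        or init_shape[:, 1].max() > h - 0.5
    ):
        raise ValueError("initial shape lies outside the image")
    sm = model.shape_model
    a_mat, t = similarity_transform(sm.mean_shape, init_shape)
    pose0 = _pose_from_similarity(a_mat, t)
    init_ref = _pose_invert_points(pose0, init_shape)
    if shape_offset == "init":
        s0 = init_ref
        q0 = np.zeros(sm.n_components)
    elif shape_offset == "mean":
        s0 = sm.mean_shape
        q0 = sm.basis.T @ (init_ref - sm.mean_shape).ravel()
    else:
        raise ValueError("shape_offset must be 'init' or 'mean'")
    params = np.concatenate([pose0, q0])

    current_shape = _shape_at(model, params, s0)
    g_image = sample_texture(image, current_shape, model)
    residual = g_image - _model_texture(model, g_image)
    error = float(residual @ residual)
    trace = [error]
    iterations = 0
    converged = False
    for _ in range(max_iterations):
        iterations += 1
        dp = model.predict_displacement(residual)
        accepted = False
        for alpha in _ALPHAS:
            trial = params - alpha * dp
            try:
                trial_shape = _shape_at(model, trial, s0)
                g_try = sample_texture(image, trial_shape, model)
            except (MeshDegenerateError, ValueError):
                continue
            resid_try = g_try - _model_texture(model, g_try)
            err_try = float(resid_try @ resid_try)
            if err_try < error * (1.0 - min_improvement):
                params, current_shape = trial, trial_shape
                g_image, residual, error = g_try, resid_try, err_try
                trace.append(error)
                accepted = True
                break
        if not accepted:
            converged = True
            break
    return FitResult(
        final_shape=current_shape,
        final_params=params,
        error_trace=trace,
        iterations=iterations,
        converged=converged,
    )
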