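"""End-to-end nasolabial wrinkle detector.

The full pipeline, per input image with known face landmarks:

1. preprocess: grayscale, Gaussian blur + histogram equalization, cheek mask;
2. Hessian ridge detection: principal-eigenvalue response, Otsu binarization
   inside the (eroded) cheek mask, skeletonization into polylines;
3. line filtering: discard lines shorter than the line length threshold
   (LLT, default 100 px) or with total turning above the line angle
   threshold (LAT, default pi radians - distorted lines that reverse
   direction);
4. unique initial shape: the winning ridge line, resampled to 20 points and
   optionally regularized by a sparse (lasso) projection onto the training
   wrinkle shapes;
5. appearance-model fit seeded with that per-image initial shape.

A generic-mean-shape baseline (the plain appearance-model fit whose initial
wrinkle is the single trained mean shape positioned by the face landmarks)
is available for comparison via ``init_mode="generic_mean"``.  If ridge
detection produces no usable line, the detector falls back to that generic
mean shape and flags the result.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import aam_core, hessian_ridge, preprocess
from .aam_core import AppearanceModel, FitResult, ReferenceFrame
from .hessian_ridge import RidgePolyline
from .shape_model import (
    ShapeModel,
    apply_similarity,
    build_shape_pca,
    procrustes_align,
    similarity_transform,
    sparse_shape_projection,
)
from .template import N_FACE_POINTS, N_WRINKLE_POINTS

__all__ = [
    "DetectorConfig",
    "DetectorModels",
    "train_detector",
    "filter_lines",
    "select_wrinkle_line",
    "resample_to_shape",
    "build_initial_shape",
    "detect",
    "save_detector",
    "load_detector",
    "NoCandidateLineError",
]


class NoCandidateLineError(RuntimeError):
    """No filtered ridge line lies in the requested cheek region."""


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and hyperparameters of the detector."""

    llt: float = 100.0  # line length threshold, px
    lat: float = float(np.pi)  # line angle threshold, radians of total turning
    n_wrinkle_points: int = N_WRINKLE_POINTS
    hessian_sigma: float = 2.0
    lambda_sparse: float = 1e-6
    init_mode: str = "unique_shape"  # or "generic_mean"
    max_iterations: int = 30
    smoothing_sigma: float = 1.5
    equalize: str = "none"  # "global"/"clahe" equalization before ridge detection
    binarize_method: str = "otsu"
    binarize_param: float | None = None
    mask_margin: float = 4.0
    prune_below: float = 12.0
    side: str = "left"
    sparse_projection: bool = True
    variance_kept: float = 0.98
    texture_variance_kept: float = 0.95

    def __post_init__(self) -> None:
        if self.llt <= 0:
            raise ValueError("llt must be positive")
        if not 0 < self.lat <= 2 * np.pi:
            raise ValueError("lat must be in (0, 2*pi]")
        if self.n_wrinkle_points < 2:
            raise ValueError("n_wrinkle_points must be >= 2")
        if self.init_mode not in ("unique_shape", "generic_mean"):
            raise ValueError("init_mode must be 'unique_shape' or 'generic_mean'")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class DetectorModels:
    """Everything trained: appearance model, wrinkle shape model, dictionary."""

    appearance: AppearanceModel
    wrinkle_model: ShapeModel
    wrinkle_dictionary: np.ndarray  # (2 * n_wrinkle, n_train) aligned shapes
    config: DetectorConfig


def train_detector(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: DetectorConfig | None = None,
) -> DetectorModels:
    """Train all models from (grayscale image, 88-point shape) pairs."""
    config = config or DetectorConfig()
    appearance = aam_core.build_appearance_model(
        pairs,
        variance_kept=config.variance_kept,
        texture_variance_kept=config.texture_variance_kept,
    )
    wrinkles = [np.asarray(s)[N_FACE_POINTS:] for _, s in pairs]
    aligned, _ = procrustes_align(wrinkles)
    wrinkle_model = build_shape_pca(aligned, variance_kept=config.variance_kept)
    dictionary = np.stack([s.ravel() for s in aligned], axis=1)
    return DetectorModels(
        appearance=appearance,
        wrinkle_model=wrinkle_model,
        wrinkle_dictionary=dictionary,
        config=config,
    )


def filter_lines(
    lines: list[RidgePolyline], llt: float, lat: float
) -> list[RidgePolyline]:
    """Keep lines with ``arc_length >= llt`` and ``total_turning < lat``.

    Short lines are noise; lines whose direction turns by more than the angle
    threshold (pi: a full reversal) are distorted non-wrinkle structures.
    Input order is preserved and lines are not mutated.
    """
    if llt <= 0 or not 0 < lat <= 2 * np.pi:
        raise ValueError("invalid thresholds")
    return [
        ln for ln in lines if ln.arc_length >= llt and ln.total_turning < lat
    ]


def _side_region(face_landmarks: np.ndarray, side: str) -> tuple[np.ndarray, float]:
    region = preprocess.default_regions()["cheek"]
    midline_x = float(np.mean(face_landmarks[27:31, 0]))  # nose bridge, 0-based 27..30
    return region, midline_x


def select_wrinkle_line(
    lines: list[RidgePolyline],
    face_landmarks: np.ndarray,
    side: str = "left",
    image_shape: tuple[int, int] | None = None,
) -> RidgePolyline:
    """Pick the best candidate on one cheek side.

    Candidates whose centroid lies in the cheek work region on the requested
    side of the face midline (nose bridge) are scored by
    ``arc_length * mean_response``; the argmax wins.  Raises
    :class:`NoCandidateLineError` if no candidate qualifies (callers fall
    back to the generic mean shape).
    """
    if not lines:
        raise NoCandidateLineError("no candidate lines")
    region, midline_x = _side_region(face_landmarks, side)
    if image_shape is None:
        extent = np.concatenate([face_landmarks] + [ln.points for ln in lines])
        image_shape = (
            int(np.ceil(extent[:, 1].max())) + 2,
            int(np.ceil(extent[:, 0].max())) + 2,
        )
    mask = preprocess.cheek_mask(face_landmarks, region, image_shape)
    best, best_score = None, -np.inf
    for ln in lines:
        cx, cy = ln.points.mean(axis=0)
        on_side = cx < midline_x if side == "left" else cx > midline_x
        ix, iy = int(round(cx)), int(round(cy))
        in_region = (
            0 <= iy < image_shape[0] and 0 <= ix < image_shape[1] and mask[iy, ix]
        )
        if not (on_side and in_region):
            continue
        response = ln.mean_response if np.isfinite(ln.mean_response) else 1.0
        score = ln.arc_length * response
        if score > best_score:
            best, best_score = ln, score
    if best is None:
        raise NoCandidateLineError(f"no candidate line on the {side} cheek")
    return best


def resample_to_shape(line: RidgePolyline, n: int) -> np.ndarray:
    """``n`` points at equal arc-length spacing along the line, endpoints included."""
    return hessian_ridge.resample_polyline(line.points, n)


def _generic_mean_wrinkle(
    models: DetectorModels, face_landmarks: np.ndarray
) -> np.ndarray:
    """The trained mean wrinkle shape positioned by the face landmarks."""
    mean88 = models.appearance.shape_model.mean_shape
    a_mat, t = similarity_transform(mean88[:N_FACE_POINTS], face_landmarks)
    return apply_similarity(mean88[N_FACE_POINTS:], a_mat, t)


def _sparse_regularize(
    wrinkle: np.ndarray, models: DetectorModels, lam: float
) -> np.ndarray:
    """Replace a raw ridge-derived shape with its sparse reconstruction over
    the aligned training wrinkle structures."""
    mean = models.wrinkle_model.mean_shape
    a_mat, t = similarity_transform(wrinkle, mean)
    vec = apply_similarity(wrinkle, a_mat, t).ravel()
    _, recon = sparse_shape_projection(vec, models.wrinkle_dictionary, lam)
    back_a = np.linalg.inv(a_mat)
    return (recon.reshape(-1, 2) - t) @ back_a.T


def build_initial_shape(
    image: np.ndarray,
    face_landmarks: np.ndarray,
    config: DetectorConfig,
    models: DetectorModels,
) -> tuple[np.ndarray, bool]:
    """Per-image unique initial wrinkle shape from Hessian ridge detection.

    Returns ``(wrinkle_shape, used_fallback)``.  Never raises for missing
    ridges: any failure falls back to the generic mean wrinkle shape
    positioned by the face landmarks, with the flag set.
    """
    face_landmarks = np.asarray(face_landmarks, dtype=float)
    full = np.concatenate(
        [face_landmarks, _generic_mean_wrinkle(models, face_landmarks)]
    )
    try:
        gray = preprocess.to_grayscale(image)
        region = preprocess.default_regions()["cheek"]
        mask = preprocess.cheek_mask(full, region, gray.shape)
        mask = preprocess.erode_mask(mask, config.mask_margin)
        eq = preprocess.smooth_and_equalize(
            gray, config.smoothing_sigma, mask=mask, method=config.equalize
        )
        fld = hessian_ridge.hessian_at_scale(eq, config.hessian_sigma)
        resp = hessian_ridge.ridge_response(fld, "dark_ridge")
        binary = hessian_ridge.binarize_response(
            resp, mask, method=config.binarize_method, param=config.binarize_param
        )
        lines = hessian_ridge.extract_lines(
            binary, response=resp, prune_below=config.prune_below
        )
        lines = filter_lines(lines, config.llt, config.lat)
        line = select_wrinkle_line(
            lines, face_landmarks, side=config.side, image_shape=gray.shape
        )
        # orient nose end first (toward the nose wing landmark)
        wing = face_landmarks[31] if config.side == "left" else face_landmarks[35]
        pts = line.points
        if np.linalg.norm(pts[-1] - wing) < np.linalg.norm(pts[0] - wing):
            line = RidgePolyline(points=pts[::-1].copy(), mean_response=line.mean_response)
        shape = resample_to_shape(line, config.n_wrinkle_points)
        if config.sparse_projection and models.wrinkle_dictionary.shape[1] > 0:
            shape = _sparse_regularize(shape, models, config.lambda_sparse)
        return shape, False
    except (NoCandidateLineError, ValueError):
        return _generic_mean_wrinkle(models, face_landmarks), True


def detect(
    image: np.ndarray,
    face_landmarks: np.ndarray | None,
    models: DetectorModels,
    config: DetectorConfig | None = None,
) -> FitResult:
    """Localize the nasolabial wrinkle line in one image.

    ``init_mode="unique_shape"`` seeds the appearance-model fit with the
    per-image ridge-derived wrinkle shape (used as the shape-model offset -
    the modified fitting variant); ``"generic_mean"`` runs the baseline fit
    from the single trained mean shape.
    """
    config = config or models.config
    if face_landmarks is None:
        raise ValueError(
            "face landmarks are required (supply them from file or a landmarker)"
        )
    face_landmarks = np.asarray(face_landmarks, dtype=float)
    if len(face_landmarks) != N_FACE_POINTS:
        raise ValueError(f"expected {N_FACE_POINTS} face landmarks")
    gray = preprocess.to_grayscale(image)
    fallback = False
    if config.init_mode == "unique_shape":
        wrinkle, fallback = build_initial_shape(gray, face_landmarks, config, models)
        offset = "init"
    else:
        wrinkle = _generic_mean_wrinkle(models, face_landmarks)
        offset = "mean"
    init_full = np.concatenate([face_landmarks, wrinkle])
    result = aam_core.fit(
        models.appearance,
        gray,
        init_full,
        max_iterations=config.max_iterations,
        shape_offset=offset,
    )
    result.init_mode = config.init_mode
    result.fallback = fallback
    return result


# --- model persistence ------------------------------------------------------


def save_detector(path: str | Path, models: DetectorModels) -> None:
    """Serialize trained models to a single NPZ archive."""
    app = models.appearance
    np.savez_compressed(
        path,
        config_json=np.array(json.dumps(asdict(models.config))),
        sm_mean=app.shape_model.mean_shape,
        sm_basis=app.shape_model.basis,
        sm_eigvals=app.shape_model.eigenvalues,
        frame_points=app.frame.points,
        frame_simplices=app.frame.simplices,
        frame_pixel_tri=app.frame.pixel_tri,
        frame_bary=app.frame.barycentric,
        frame_pixel_coords=app.frame.pixel_coords,
        texture_mean=app.texture_mean,
        texture_basis=app.texture_basis,
        texture_eigvals=app.texture_eigenvalues,
        jacobian=app.jacobian,
        wr_mean=models.wrinkle_model.mean_shape,
        wr_basis=models.wrinkle_model.basis,
        wr_eigvals=models.wrinkle_model.eigenvalues,
        wr_dictionary=models.wrinkle_dictionary,
    )


def load_detector(path: str | Path) -> DetectorModels:
    with np.load(path, allow_pickle=False) as data:
        config = DetectorConfig(**json.loads(str(data["config_json"])))
        frame = ReferenceFrame(
            points=data["frame_points"],
            simplices=data["frame_simplices"],
            pixel_tri=data["frame_pixel_tri"],
            barycentric=data["frame_bary"],
            pixel_coords=data["frame_pixel_coords"],
        )
        appearance = AppearanceModel(
            shape_model=ShapeModel(
                mean_shape=data["sm_mean"],
                basis=data["sm_basis"],
                eigenvalues=data["sm_eigvals"],
            ),
            frame=frame,
            texture_mean=data["texture_mean"],
            texture_basis=data["texture_basis"],
            texture_eigenvalues=data["texture_eigvals"],
            jacobian=data["jacobian"],
        )
        wrinkle_model = ShapeModel(
            mean_shape=data["wr_mean"],
            basis=data["wr_basis"],
            eigenvalues=data["wr_eigvals"],
        )
        return DetectorModels(
            appearance=appearance,
            wrinkle_model=wrinkle_model,
            wrinkle_dictionary=data["wr_dictionary"],
            config=config,
        )
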