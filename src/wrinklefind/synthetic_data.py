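"""Deterministic generator of face-like fixture images with known wrinkle truth.

Real nasolabial-wrinkle datasets are access restricted, so every test and
experiment in this package runs on synthetic faces: an elliptical "skin"
region on a darker background, soft facial features (eyes, brows, nose,
mouth) that anchor the appearance model, a linear illumination gradient,
band-limited skin noise, and a single dark curvilinear valley - the wrinkle -
rendered with a Gaussian cross-profile along a spline through a few control
points on the left cheek.

Each fixture carries its ground truth: the 88 landmarks (68 template face
points scaled to the face ellipse plus 20 points sampled at uniform arc
length along the wrinkle centerline) and the dense wrinkle centerline itself.

Generation is bit-deterministic: the same :class:`FixtureSpec` always
produces the same image and landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.interpolate import CubicSpline

from . import pts as pts_io
from .hessian_ridge import RidgePolyline, resample_polyline
from .template import (
    DEFAULT_WRINKLE_CONTROL_NORM,
    FACE_TEMPLATE_68,
    N_WRINKLE_POINTS,
)

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic face fixture.

    ``wrinkle_control_points`` are pixel (x, y) coordinates of 3-5 spline
    control points; the rendered valley passes through all of them.  Depth
    and intensities are on the [0, 1] image scale, widths in pixels.
    """

    image_height: int = 545
    image_width: int = 520
    face_center: tuple[float, float] = (260.0, 270.0)
    face_axes: tuple[float, float] = (210.0, 240.0)
    wrinkle_control_points: tuple[tuple[float, float], ...] = tuple(
        (260.0 + 210.0 * nx, 270.0 + 240.0 * ny)
        for nx, ny in DEFAULT_WRINKLE_CONTROL_NORM
    )
    wrinkle_depth: float = 0.25
    wrinkle_width: float = 2.5
    noise_std: float = 0.02
    illumination_gradient: float = 2e-4
    seed: int = 0


@dataclass
class Fixture:
    """A rendered face image with its ground-truth landmarks and wrinkle line."""

    image: np.ndarray  # (H, W) float in [0, 1]
    landmarks: np.ndarray  # (88, 2) (x, y)
    wrinkle_truth: RidgePolyline
    spec: FixtureSpec


# Soft facial features drawn as anisotropic Gaussian blobs:
# (center_x, center_y, sigma_x, sigma_y, depth) in normalized face coords.
_FEATURE_BLOBS = (
    (-0.42, -0.38, 0.09, 0.05, 0.25),  # left eye
    (0.42, -0.38, 0.09, 0.05, 0.25),  # right eye
    (-0.435, -0.565, 0.16, 0.025, 0.18),  # left brow
    (0.435, -0.565, 0.16, 0.025, 0.18),  # right brow
    (0.0, -0.05, 0.05, 0.18, 0.10),  # nose shading
    (0.0, 0.52, 0.22, 0.05, 0.15),  # mouth
)

_SKIN_LEVEL = 0.72
_BACKGROUND_LEVEL = 0.35


def _dense_wrinkle_curve(control: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Natural cubic spline through the control points, resampled at ``step`` px."""
    control = np.asarray(control, dtype=float)
    if len(control) < 3 or len(control) > 5:
        raise ValueError("wrinkle needs 3-5 control points")
    chord = np.linalg.norm(np.diff(control, axis=0), axis=1)
    if np.any(chord <= 0):
        raise ValueError("wrinkle control points must be distinct")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, control, axis=0, bc_type="natural")
    dense_t = np.linspace(0.0, t[-1], max(int(np.ceil(t[-1] / 0.1)), 32))
    dense = spline(dense_t)
    n = max(int(round(t[-1] / step)) + 1, 8)
    return resample_polyline(dense, n)


def _ellipse_radius2(points: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    cx, cy = spec.face_center
    ax, ay = spec.face_axes
    return ((points[:, 0] - cx) / ax) ** 2 + ((points[:, 1] - cy) / ay) ** 2


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Render one synthetic face fixture from its spec.

    Raises ``ValueError`` if the wrinkle curve is not strictly inside the face
    ellipse or the spec is otherwise invalid.
    """
    if spec.wrinkle_depth < 0:
        raise ValueError("wrinkle_depth must be >= 0 (valley darker than skin)")
    if spec.wrinkle_width <= 0:
        raise ValueError("wrinkle_width must be positive")
    if spec.noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    h, w = spec.image_height, spec.image_width
    curve = _dense_wrinkle_curve(np.asarray(spec.wrinkle_control_points))
    if np.any(_ellipse_radius2(curve, spec) >= 1.0):
        raise ValueError("wrinkle curve must lie strictly inside the face ellipse")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = spec.face_center
    ax, ay = spec.face_axes
    nx = (xx - cx) / ax
    ny = (yy - cy) / ay
    inside = nx**2 + ny**2 <= 1.0

    base = np.where(inside, _SKIN_LEVEL, _BACKGROUND_LEVEL)
    for fx, fy, sx, sy, depth in _FEATURE_BLOBS:
        base = base - depth * np.exp(
            -((nx - fx) ** 2) / (2 * sx**2) - ((ny - fy) ** 2) / (2 * sy**2)
        )
    base = ndimage.gaussian_filter(base, 3.0)
    image = base + spec.illumination_gradient * (xx - cx)

    if spec.wrinkle_depth > 0:
        # exact distance to the rasterized centerline -> Gaussian cross profile
        line_mask = np.ones((h, w), dtype=bool)
        ix = np.clip(np.round(curve[:, 0]).astype(int), 0, w - 1)
        iy = np.clip(np.round(curve[:, 1]).astype(int), 0, h - 1)
        line_mask[iy, ix] = False
        dist = ndimage.distance_transform_edt(line_mask)
        image = image - spec.wrinkle_depth * np.exp(
            -(dist**2) / (2 * spec.wrinkle_width**2)
        )

    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 0.8)
        noise *= spec.noise_std / noise.std()
        image = image + noise

    image = np.clip(image, 0.0, 1.0)

    face_pts = np.stack(
        [cx + ax * FACE_TEMPLATE_68[:, 0], cy + ay * FACE_TEMPLATE_68[:, 1]], axis=1
    )
    wrinkle_pts = resample_polyline(curve, N_WRINKLE_POINTS)
    landmarks = np.concatenate([face_pts, wrinkle_pts])
    return Fixture(
        image=image,
        landmarks=landmarks,
        wrinkle_truth=RidgePolyline(points=curve),
        spec=spec,
    )


def _randomized_spec(base: FixtureSpec, rng: np.random.Generator, seed: int) -> FixtureSpec:
    """Jitter the face geometry, wrinkle shape and photometry of ``base``.

    Emulates person-to-person variation: the face ellipse varies in position
    and (independently per axis) in size, and the wrinkle varies in position,
    curvature, depth and width within the cheek.  Wrinkle control points are
    carried in the normalized face frame so they follow the face.
    """
    ax, ay = base.face_axes
    cx, cy = base.face_center
    control = np.asarray(base.wrinkle_control_points, dtype=float)
    norm = (control - (cx, cy)) / (ax, ay)
    jitter = np.zeros_like(norm)
    # the whole fold shifts laterally within the cheek (distance from the
    # mouth varies strongly between persons); endpoints additionally move a
    # little and interior control points more (curvature variety)
    jitter += [rng.uniform(-0.09, 0.01), rng.uniform(-0.02, 0.02)]
    jitter[0] += [rng.uniform(-0.025, 0.025), rng.uniform(-0.01, 0.01)]
    jitter[-1] += [rng.uniform(-0.025, 0.025), rng.uniform(-0.01, 0.01)]
    for i in range(1, len(norm) - 1):
        jitter[i] += [rng.uniform(-0.04, 0.04), rng.uniform(-0.03, 0.03)]
    new_axes = (
        ax * rng.uniform(0.95, 1.05),
        ay * rng.uniform(0.95, 1.05),
    )
    new_center = (cx + rng.uniform(-8.0, 8.0), cy + rng.uniform(-8.0, 8.0))
    new_control = (norm + jitter) * new_axes + new_center
    return replace(
        base,
        face_axes=new_axes,
        face_center=new_center,
        wrinkle_control_points=tuple(map(tuple, new_control)),
        wrinkle_depth=float(rng.uniform(0.18, 0.30)),
        wrinkle_width=float(rng.uniform(2.0, 3.0)),
        seed=seed,
    )


def generate_dataset(
    n: int,
    base_spec: FixtureSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    split: str = "train",
) -> list[Fixture]:
    """Generate ``n`` fixtures with seeded random wrinkle shape, depth and width.

    When ``out_dir`` is given, images (8-bit PNG, round-half-up), PTS landmark
    files and a ``manifest.csv`` are written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else FixtureSpec()
    rng = np.random.default_rng(seed)
    fixtures = []
    for _ in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fixtures.append(generate_fixture(_randomized_spec(base, rng, sub_seed)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, fx in enumerate(fixtures):
            img_name, pts_name = f"{split}_{i:03d}.png", f"{split}_{i:03d}.pts"
            eight_bit = np.floor(fx.image * 255.0 + 0.5).astype(np.uint8)
            Image.fromarray(eight_bit).save(out / img_name)
            pts_io.write_pts(out / pts_name, fx.landmarks)
            rows.append({"image": img_name, "landmarks": pts_name, "split": split})
        pts_io.write_manifest(out / "manifest.csv", rows)
    return fixtures
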