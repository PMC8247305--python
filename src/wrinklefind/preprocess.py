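"""Cheek region-of-interest masking and photometric normalization.

Skin texture is noisy and unevenly lit, so before ridge detection the image
is converted to grayscale, Gaussian-smoothed and histogram-equalized, and
all processing is restricted to the cheek area.  Regions are defined as
polygons over the 88 facial landmarks: a coarse cheek quadrilateral that
covers cheek, nose and mouth, from which the nose and mouth polygons are
masked out, plus finer left/right cheek polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import exposure
from skimage.color import rgb2gray
from skimage.draw import polygon2mask

from . import template

__all__ = [
    "RegionSpec",
    "default_regions",
    "to_grayscale",
    "smooth_and_equalize",
    "cheek_mask",
    "erode_mask",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named landmark-polygon region.

    ``boundary_indices`` are ordered 1-based landmark indices whose resolved
    points form the masking polygon; ``exclusions`` lists polygons (same
    convention) that are cut out of it.
    """

    name: str
    boundary_indices: tuple[int, ...]
    exclusions: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for idx in list(self.boundary_indices) + [
            i for poly in self.exclusions for i in poly
        ]:
            if not 1 <= idx <= template.N_LANDMARKS:
                raise ValueError(f"landmark index {idx} outside 1..{template.N_LANDMARKS}")
        if len(self.boundary_indices) < 3:
            raise ValueError("a region polygon needs at least 3 boundary indices")


def default_regions() -> dict[str, RegionSpec]:
    """The package's default cheek region definitions."""
    return {
        "cheek": RegionSpec(
            "cheek",
            template.CHEEK_BOUNDARY,
            exclusions=(template.NOSE_POLYGON, template.MOUTH_POLYGON),
        ),
        "cheek_left": RegionSpec("cheek_left", template.CHEEK_LEFT_BOUNDARY),
        "cheek_right": RegionSpec("cheek_right", template.CHEEK_RIGHT_BOUNDARY),
    }


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale conversion; grayscale input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return rgb2gray(image)
    raise ValueError(f"expected 1- or 3-channel image, got shape {image.shape}")


def smooth_and_equalize(
    gray: np.ndarray,
    sigma: float = 1.5,
    mask: np.ndarray | None = None,
    method: str = "global",
) -> np.ndarray:
    """Gaussian blur followed by histogram equalization, output in [0, 1].

    With a mask, the equalization mapping is computed from the masked pixels
    only (the cheek work area).  ``method`` is ``"global"``, ``"clahe"`` or
    ``"none"`` (smoothing only; see the methods note on why equalization can
    hurt valley contrast when the wrinkle covers few pixels).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    gray = np.asarray(gray, dtype=float)
    smoothed = ndimage.gaussian_filter(gray, sigma) if sigma > 0 else gray
    if method == "none":
        return np.clip(smoothed, 0.0, 1.0)
    if method == "global":
        eq = exposure.equalize_hist(smoothed, mask=mask)
    elif method == "clahe":
        rescaled = exposure.rescale_intensity(smoothed, out_range=(0.0, 1.0))
        eq = exposure.equalize_adapthist(rescaled)
    else:
        raise ValueError(f"unknown equalization method: {method!r}")
    return np.clip(eq, 0.0, 1.0)


def _resolve(landmarks: np.ndarray, indices: tuple[int, ...]) -> np.ndarray:
    landmarks = np.asarray(landmarks, dtype=float)
    out = []
    for idx in indices:
        if idx > len(landmarks):
            raise ValueError(f"landmark index {idx} missing (only {len(landmarks)} points)")
        pt = landmarks[idx - 1]
        if not np.all(np.isfinite(pt)):
            raise ValueError(f"landmark index {idx} is not finite")
        out.append(pt)
    return np.asarray(out)


def _fill_polygon(points_xy: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    # polygon2mask wants (row, col) = (y, x)
    return polygon2mask(image_shape, points_xy[:, ::-1])


def cheek_mask(
    landmarks: np.ndarray,
    region: RegionSpec,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of the region polygon, with exclusion polygons cut out.

    A degenerate (self-intersecting or zero-area) boundary polygon yields an
    empty mask and a warning.
    """
    boundary = _resolve(landmarks, region.boundary_indices)
    poly = Polygon(boundary)
    if (not poly.is_valid) or poly.area <= 0:
        warnings.warn(
            f"region {region.name!r}: degenerate boundary polygon, returning empty mask",
            stacklevel=2,
        )
        return np.zeros(image_shape, dtype=bool)
    mask = _fill_polygon(boundary, image_shape)
    for excl in region.exclusions:
        pts = _resolve(landmarks, excl)
        if Polygon(pts).area > 0:
            mask &= ~_fill_polygon(pts, image_shape)
    return mask


def erode_mask(mask: np.ndarray, margin: float) -> np.ndarray:
    """Shrink a mask by ``margin`` pixels (Euclidean), guarding ridge filters
    against responses leaking in from the region boundary."""
    if margin <= 0:
        return mask
    return ndimage.distance_transform_edt(mask) > margin
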