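"""Canonical 68-point face template and named landmark index groups.

The package works with 88 ordered landmarks per face: indices 1-68 (1-based)
are face feature points, indices 69-88 trace the nasolabial wrinkle line from
its nose end to its chin end.  The 68 face points follow the common
jaw / brows / nose / eyes / mouth grouping:

    1-17   jawline, left ear level around the chin to right ear level
    18-27  eyebrows (left 18-22, right 23-27)
    28-31  nose bridge, top to tip
    32-36  nose bottom, left wing to right wing
    37-48  eyes (left 37-42, right 43-48)
    49-60  outer lip (49 left corner, 55 right corner)
    61-68  inner lip (61 left corner, 64 right corner)

Coordinates are stored in a normalized frame: the face is the unit disc
(x right, y down, so positive y is toward the chin).  Mapping to pixels is
``center + point * axes`` for a face ellipse with semi-axes ``axes``.

The exact within-group ordering is a convention of this package; only the
indices used by the cheek region definitions (jawline, nose wings, mouth
corner neighborhoods) carry anatomical meaning.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FACE_TEMPLATE_68",
    "N_FACE_POINTS",
    "N_WRINKLE_POINTS",
    "N_LANDMARKS",
    "CHEEK_BOUNDARY",
    "CHEEK_LEFT_BOUNDARY",
    "CHEEK_RIGHT_BOUNDARY",
    "NOSE_POLYGON",
    "MOUTH_POLYGON",
    "DEFAULT_WRINKLE_CONTROL_NORM",
]

N_FACE_POINTS = 68
N_WRINKLE_POINTS = 20
N_LANDMARKS = N_FACE_POINTS + N_WRINKLE_POINTS


def _jawline() -> np.ndarray:
    # 17 points on the face ellipse from left ear level (194 deg) around the
    # chin (90 deg) to right ear level (-14 deg), 13 deg apart.
    phi = np.deg2rad(194.0 - 13.0 * np.arange(17))
    return np.stack([np.cos(phi), np.sin(phi)], axis=1)


def _template() -> np.ndarray:
    jaw = _jawline()
    brows = np.array(
        [
            (-0.65, -0.52), (-0.54, -0.57), (-0.43, -0.60), (-0.32, -0.57), (-0.22, -0.53),
            (0.22, -0.53), (0.32, -0.57), (0.43, -0.60), (0.54, -0.57), (0.65, -0.52),
        ]
    )
    nose_bridge = np.array([(0.0, -0.35), (0.0, -0.20), (0.0, -0.05), (0.0, 0.10)])
    nose_bottom = np.array(
        [(-0.18, 0.22), (-0.09, 0.235), (0.0, 0.245), (0.09, 0.235), (0.18, 0.22)]
    )
    eyes = np.array(
        [
            (-0.53, -0.38), (-0.475, -0.425), (-0.365, -0.425), (-0.31, -0.38),
            (-0.365, -0.335), (-0.475, -0.335),
            (0.31, -0.38), (0.365, -0.425), (0.475, -0.425), (0.53, -0.38),
            (0.475, -0.335), (0.365, -0.335),
        ]
    )
    outer_lip = np.array(
        [
            (-0.34, 0.52), (-0.24, 0.47), (-0.17, 0.44), (0.0, 0.42), (0.21, 0.445),
            (0.24, 0.47), (0.34, 0.52), (0.24, 0.58), (0.12, 0.615), (0.0, 0.625),
            (-0.12, 0.615), (-0.24, 0.58),
        ]
    )
    inner_lip = np.array(
        [
            (-0.28, 0.52), (-0.14, 0.49), (0.0, 0.48), (0.28, 0.52),
            (0.18, 0.545), (0.06, 0.555), (-0.06, 0.555), (-0.18, 0.545),
        ]
    )
    return np.concatenate([jaw, brows, nose_bridge, nose_bottom, eyes, outer_lip, inner_lip])


#: (68, 2) array of normalized face-template coordinates.
FACE_TEMPLATE_68 = _template()

# Cheek region borders as ordered 1-based landmark indices.  The coarse
# "cheek" quadrilateral covers the cheek, nose and mouth area; the nose and
# mouth polygons are masked out of it.  The left/right polygons trace each
# cheek between the jawline and the nose-lip line.
CHEEK_BOUNDARY = (2, 5, 11, 14)
CHEEK_LEFT_BOUNDARY = (1, 2, 3, 4, 5, 6, 7, 31, 32, 50, 49)
CHEEK_RIGHT_BOUNDARY = (15, 14, 13, 12, 11, 35, 53, 54, 64)
NOSE_POLYGON = (28, 32, 33, 34, 35, 36)
MOUTH_POLYGON = tuple(range(49, 61))

#: Default wrinkle spline control points in normalized face coordinates,
#: running from the nose end down toward the chin on the left cheek.
DEFAULT_WRINKLE_CONTROL_NORM = ((-0.26, 0.19), (-0.38, 0.43), (-0.45, 0.65))
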