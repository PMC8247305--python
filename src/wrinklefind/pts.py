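"""Reading and writing landmark annotation files in the PTS text format.

The format is the plain-text dialect used by most facial landmark datasets::

    version: 1
    n_points: 88
    {
    x1 y1
    ...
    }

PTS files store 1-based pixel coordinates; the package works with 0-based
``(x, y)`` coordinates internally, so 1.0 is subtracted on read and added on
write.  Coordinates are written with ``repr`` so that a write/read cycle is
bit-exact.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_pts", "write_pts", "write_manifest", "read_manifest"]


def read_pts(path: str | os.PathLike) -> np.ndarray:
    """Read a PTS landmark file into an ``(n, 2)`` float array of 0-based (x, y)."""
    lines = Path(path).read_text().splitlines()
    n_points = None
    coords: list[tuple[float, float]] = []
    in_block = False
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("version:"):
            continue
        if line.startswith("n_points:"):
            n_points = int(line.split(":", 1)[1])
            continue
        if line == "{":
            in_block = True
            continue
        if line == "}":
            in_block = False
            continue
        if in_block:
            x, y = line.split()
            coords.append((float(x), float(y)))
    points = np.asarray(coords, dtype=float)
    if n_points is not None and len(points) != n_points:
        raise ValueError(
            f"{path}: header declares {n_points} points but {len(points)} were read"
        )
    return points - 1.0


def write_pts(path: str | os.PathLike, points: np.ndarray) -> None:
    """Write an ``(n, 2)`` array of 0-based (x, y) coordinates as a PTS file."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    out = ["version: 1", f"n_points: {len(points)}", "{"]
    for x, y in points + 1.0:
        out.append(f"{float(x)!r} {float(y)!r}")
    out.append("}")
    Path(path).write_text("\n".join(out) + "\n")


def write_manifest(path: str | os.PathLike, rows: list[dict]) -> None:
    """Write a dataset manifest CSV with ``image``, ``landmarks``, ``split`` columns."""
    pd.DataFrame(rows, columns=["image", "landmarks", "split"]).to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
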