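"""Contour extraction and Hausdorff-distance scoring.

Segmentation quality is judged by comparing the level line of the final
segmentation function against a reference contour with the Hausdorff
distance

    d_H(C1, C2) = max{ h(C1, C2), h(C2, C1) },
    h(C1, C2) = max_{a in C1} min_{b in C2} ||a - b||,

computed between finite point sets in unit-square coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .grid import GridSpec, grid_for_image


@dataclass
class ContourSet:
    """Finite point set in domain coordinates with provenance."""

    points: np.ndarray  # (K, 2) columns (x, y)
    level: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0 or pts.shape[1] != 2:
            raise ValueError("contour must be a nonempty (K, 2) point set")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def extract_contour(
    u: np.ndarray,
    level: float,
    grid: GridSpec | None = None,
    keep: str = "longest",
    source: str = "",
) -> ContourSet:
    """Sub-cell level line of a scalar field (marching squares).

    Crossing points are located by linear interpolation along cell edges and
    returned in domain coordinates.  ``keep="longest"`` (default) returns the
    longest connected curve — the object contour — while ``keep="all"``
    concatenates every curve.  The level must lie strictly between the field
    minimum and maximum.
    """
    u = np.asarray(u, dtype=float)
    if grid is None:
        grid = grid_for_image(u)
    if not (u.min() < level < u.max()):
        raise ValueError(
            f"level {level:g} outside field range [{u.min():g}, {u.max():g}]"
        )
    curves = measure.find_contours(u, level)
    if not curves:
        raise ValueError(f"field never crosses level {level:g}")
    if keep == "longest":
        curves = [max(curves, key=len)]
    elif keep != "all":
        raise ValueError("keep must be 'longest' or 'all'")
    rc = np.vstack(curves)  # (row, col) = (y index, x index), sub-cell
    pts = np.column_stack([(rc[:, 1] + 0.5) * grid.hx, (rc[:, 0] + 0.5) * grid.hy])
    return ContourSet(points=pts, level=level, source=source)


def _as_points(c) -> np.ndarray:
    pts = c.points if isinstance(c, ContourSet) else np.atleast_2d(np.asarray(c, float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point set contains non-finite coordinates")
    return pts


def directed_hausdorff(c1, c2) -> float:
    """One-sided distance ``h(C1, C2) = max_a min_b ||a - b||``."""
    p1, p2 = _as_points(c1), _as_points(c2)
    d, _ = cKDTree(p2).query(p1)
    return float(np.max(d))


def hausdorff_distance(c1, c2) -> float:
    """Symmetric Hausdorff distance between two finite point sets."""
    return max(directed_hausdorff(c1, c2), directed_hausdorff(c2, c1))
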