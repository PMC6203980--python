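"""Polygon geometry primitives shared across the pipeline.

Conventions
-----------
Contours are ``(N, 2)`` float arrays of ``(row, col)`` vertices at pixel
centers, implicitly closed (the last vertex connects back to the first).
Signed quantities use the mathematical plane ``x = col``, ``y = row``;
"counter-clockwise" means positive signed shoelace area in that frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely import Polygon, minimum_bounding_radius

from .errors import GeometryError

__all__ = [
    "shoelace_area",
    "polygon_centroid",
    "equivalent_ellipse_axes",
    "min_enclosing_circle_radius",
    "convex_hull",
    "resample_closed",
    "cross_section_geometry",
]


def _xy(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or len(c) < 3:
        raise GeometryError("contour must be an (N>=3, 2) vertex array")
    return c[:, 1], c[:, 0]  # x = col, y = row


def signed_area(contour: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise orientation."""
    x, y = _xy(contour)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def shoelace_area(contour: np.ndarray) -> float:
    """Absolute polygon area in px^2 by the shoelace formula."""
    return abs(signed_area(contour))


def polygon_centroid(contour: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple closed polygon, returned as (row, col)."""
    x, y = _xy(contour)
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12:
        raise GeometryError("zero-area contour has no centroid")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return (cy, cx)


def equivalent_ellipse_axes(contour: np.ndarray) -> tuple[float, float]:
    """Major/minor full axis lengths (px) of the moment-equivalent ellipse.

    The ellipse with the same area and second central moments as the
    polygon; for a true ellipse this recovers 2a and 2b exactly.
    """
    x, y = _xy(contour)
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12:
        raise GeometryError("zero-area contour")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    # second moments about the origin (standard closed-polygon formulas)
    ixx = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    iyy = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    ixy = float(np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross)) / 24.0
    s = np.sign(a)
    # normalized central second moments (covariance of the uniform lamina)
    uxx = s * iyy / abs(a) - cx * cx
    uyy = s * ixx / abs(a) - cy * cy
    uxy = s * ixy / abs(a) - cx * cy
    cov = np.array([[uxx, uxy], [uxy, uyy]])
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 0.0, None)
    minor, major = 4.0 * np.sqrt(evals)  # full axis lengths
    return float(major), float(minor)


def min_enclosing_circle_radius(contour: np.ndarray) -> float:
    """Radius (px) of the minimum circle enclosing the contour vertices."""
    c = np.asarray(contour, dtype=float)
    poly = Polygon(c[:, ::-1])  # shapely wants (x, y)
    if not poly.is_valid or poly.area == 0:
        poly = poly.convex_hull
    return float(minimum_bounding_radius(poly))


def convex_hull(contour: np.ndarray) -> np.ndarray:
    """Convex hull of the contour vertices, counter-clockwise, as (row, col).

    Raises
    ------
    GeometryError
        If the input points are collinear (hull is degenerate).
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need at least 3 vertices")
    try:
        hull = ConvexHull(pts[:, ::-1])  # qhull in (x, y)
    except QhullError as exc:
        raise GeometryError(f"degenerate (collinear) contour: {exc}") from exc
    xy = pts[:, ::-1][hull.vertices]  # qhull returns CCW order in (x, y)
    out = xy[:, ::-1].copy()
    if signed_area(out) < 0:
        out = out[::-1]
    return out


def resample_closed(contour: np.ndarray, k: int) -> np.ndarray:
    """Resample a closed contour at ``k`` equal arc-length stations."""
    c = np.asarray(contour, dtype=float)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    closed = np.vstack([c, c[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("zero-perimeter contour")
    stations = np.linspace(0.0, total, k, endpoint=False)
    rows = np.interp(stations, s, closed[:, 0])
    cols = np.interp(stations, s, closed[:, 1])
    return np.column_stack([rows, cols])


def cross_section_geometry(
    contour: np.ndarray, pixel_size_mm: float
) -> dict[str, float | tuple[float, float]]:
    """Section-level geometry of a closed stalk contour.

    Returns a dict with keys ``PAD``, ``AAD`` (moment-equivalent ellipse
    axes, mm), ``CCR`` (minimum enclosing circle radius, mm), ``SA``
    (shoelace area, mm^2), ``AR`` (PAD/AAD) and ``centroid`` (row, col in px).
    """
    area_px = shoelace_area(contour)
    if area_px <= 0:
        raise GeometryError("degenerate contour with zero area")
    major, minor = equivalent_ellipse_axes(contour)
    if minor <= 0:
        raise GeometryError("degenerate contour with zero minor axis")
    ccr = min_enclosing_circle_radius(contour)
    return {
        "PAD": major * pixel_size_mm,
        "AAD": minor * pixel_size_mm,
        "CCR": ccr * pixel_size_mm,
        "SA": area_px * pixel_size_mm**2,
        "AR": major / minor,
        "centroid": polygon_centroid(contour),
    }
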