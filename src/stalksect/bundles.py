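"""Vascular bundle detection and three-step contour refinement.

Bundles appear as compact bright blobs inside the epidermis inner
boundary.  Raw candidates come from fixed or adaptive (local-mean)
thresholding; each candidate is then

1. validated against distance-dependent area and solidity thresholds
   (laxer at the periphery so small rind bundles are not deleted by the
   minimum-area control),
2. replaced by its convex hull, and
3. fitted with a closed periodic interpolating cubic spline through K
   equal-arc-length control points — the editable final shape whose
   sampled polygon provides the bundle's centroid and area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline
from shapely import LineString, Point, Polygon
from skimage.filters import threshold_local
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk, opening

from .config import BundleConfig
from .errors import InputError
from .geometry import convex_hull, polygon_centroid, resample_closed, shoelace_area
from .image import SliceImage
from .layers import LayerMap, layer_of_point
from .segment import StalkSection


@dataclass
class ClosedSpline:
    """Closed periodic cubic through K control points on the contour."""

    control_points: np.ndarray
    sampled_polygon: np.ndarray


@dataclass
class VascularBundle:
    uid: int
    raw_contour: np.ndarray
    hull_contour: np.ndarray
    spline_contour: ClosedSpline
    centroid: tuple[float, float]
    area_mm2: float
    layer_id: int
    size_class: str = "medium"
    raw_area_mm2: float = 0.0
    hull_area_mm2: float = 0.0
    inner_contours: list[np.ndarray] = field(default_factory=list)


def threshold_bundles(
    img: SliceImage, section: StalkSection, cfg: BundleConfig | None = None
) -> list[np.ndarray]:
    """Bright connected components strictly inside the epidermis inner
    boundary, each as a closed outer contour; border-touching components
    are excluded."""
    cfg = cfg or BundleConfig()
    px = img.pixels
    if section.epidermis is not None and section.interior_distance is not None:
        interior = section.interior_distance > section.epidermis.thickness_px
    elif section.interior_distance is not None:
        interior = section.interior_distance > 1
    else:
        interior = ndi.binary_erosion(section.mask)

    if cfg.threshold_mode == "fixed":
        bright = px > cfg.fixed_threshold
    else:
        # fill the exterior with the interior median so local means near the
        # section boundary are not dragged toward the dark background
        work = px.astype(float)
        if interior.any():
            work[~interior] = np.median(work[interior])
        thr = threshold_local(
            work,
            block_size=cfg.adaptive_window_px,
            method="mean",
            offset=-cfg.adaptive_offset,
        )
        bright = px.astype(float) > thr
    cand = opening(bright & interior, disk(1))

    lbl = label(cand)
    h, w = cand.shape
    contours: list[np.ndarray] = []
    for p in regionprops(lbl):
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue  # touches the image border
        sub = np.pad(p.image, 1)
        cs = find_contours(sub.astype(float), 0.5)
        if not cs:
            continue
        contour = max(cs, key=len)
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        if len(contour) < 3:
            continue
        contour = contour + np.array([r0 - 1, c0 - 1], dtype=float)
        contours.append(contour)
    return contours


def normalized_centroid_distance(
    point: tuple[float, float], section: StalkSection
) -> float:
    """Distance of ``point`` from the section centroid, normalized by the
    boundary distance along the same ray: 0 at the centroid, 1 on the
    boundary."""
    c = np.asarray(section.centroid, dtype=float)
    p = np.asarray(point, dtype=float)
    v = p - c
    r = float(np.linalg.norm(v))
    if r < 1e-9:
        return 0.0
    u = v / r
    h, w = (
        section.mask.shape
        if section.mask is not None
        else (int(p[0]) + 1, int(p[1]) + 1)
    )
    reach = 2.0 * (h + w)
    ray = LineString([c[::-1], (c + u * reach)[::-1]])  # shapely (x, y)
    boundary = Polygon(section.outer_contour[:, ::-1]).exterior
    hit = ray.intersection(boundary)
    if hit.is_empty:
        return 1.0
    # distance from the centroid to the nearest boundary crossing along the ray
    rho = hit.distance(Point(c[::-1]))
    if rho <= 0:
        return 1.0
    return float(min(r / rho, 1.0))


def validate_candidates(
    cands: list[np.ndarray],
    section: StalkSection,
    cfg: BundleConfig | None = None,
) -> list[np.ndarray]:
    """Keep candidates passing the distance-dependent area and solidity
    thresholds (linear interpolation between center and periphery)."""
    cfg = cfg or BundleConfig()
    kept = []
    for contour in cands:
        area = shoelace_area(contour)
        if area <= 0:
            continue
        try:
            hull = convex_hull(contour)
        except Exception:
            continue
        hull_area = shoelace_area(hull)
        solidity = area / hull_area if hull_area > 0 else 0.0
        d = normalized_centroid_distance(polygon_centroid(contour), section)
        a_min = cfg.a_center_px + (cfg.a_periph_px - cfg.a_center_px) * d
        s_min = cfg.s_center + (cfg.s_periph - cfg.s_center) * d
        if area >= a_min and solidity >= s_min:
            kept.append(contour)
    return kept


def hull_contour(contour: np.ndarray) -> np.ndarray:
    """Convex hull of a closed contour, counter-clockwise vertices."""
    return convex_hull(contour)


def fit_spline(contour: np.ndarray, k: int = 12) -> ClosedSpline:
    """Fit a closed periodic interpolating cubic through ``k`` equal
    arc-length control points and densely sample it (16k points)."""
    if k < 4:
        raise InputError("spline needs at least 4 control points")
    cp = resample_closed(contour, k)
    closed = np.vstack([cp, cp[:1]])
    t = np.arange(k + 1, dtype=float)
    spl = CubicSpline(t, closed, bc_type="periodic")
    ts = np.linspace(0.0, float(k), 16 * k, endpoint=False)
    sampled = spl(ts)
    return ClosedSpline(control_points=cp, sampled_polygon=sampled)


def evaluate_spline(control_points: np.ndarray, samples_per_node: int = 16) -> np.ndarray:
    """Re-evaluate a closed periodic cubic from (possibly edited) control
    points; returns the dense sampled polygon."""
    cp = np.asarray(control_points, dtype=float)
    k = len(cp)
    closed = np.vstack([cp, cp[:1]])
    t = np.arange(k + 1, dtype=float)
    spl = CubicSpline(t, closed, bc_type="periodic")
    ts = np.linspace(0.0, float(k), samples_per_node * k, endpoint=False)
    return spl(ts)


def detect_bundles(
    img: SliceImage,
    section: StalkSection,
    layers: LayerMap,
    cfg: BundleConfig | None = None,
) -> list[VascularBundle]:
    """Full per-slice bundle pipeline: threshold -> validate -> hull ->
    spline; uids in raster-scan order of centroids; size classes are
    per-slice area terciles (descriptive only)."""
    cfg = cfg or BundleConfig()
    px2 = img.pixel_size_mm**2
    cands = threshold_bundles(img, section, cfg)
    kept = validate_candidates(cands, section, cfg)
    records = []
    for contour in kept:
        hull = convex_hull(contour)
        spline = fit_spline(hull, cfg.spline_nodes)
        area_px = shoelace_area(spline.sampled_polygon)
        if area_px <= 0:
            continue
        centroid = polygon_centroid(spline.sampled_polygon)
        records.append(
            {
                "raw": contour,
                "hull": hull,
                "spline": spline,
                "centroid": centroid,
                "area_px": area_px,
                "raw_area_px": shoelace_area(contour),
                "hull_area_px": shoelace_area(hull),
            }
        )
    # deterministic uid assignment: raster-scan order of centroids
    records.sort(key=lambda r: (r["centroid"][0], r["centroid"][1]))
    areas = np.array([r["area_px"] for r in records])
    if len(areas) >= 3:
        lo, hi = np.quantile(areas, [1 / 3, 2 / 3])
    else:
        lo = hi = None
    bundles = []
    for uid, r in enumerate(records):
        if lo is None:
            size_class = "medium"
        elif r["area_px"] <= lo:
            size_class = "small"
        elif r["area_px"] <= hi:
            size_class = "medium"
        else:
            size_class = "large"
        bundles.append(
            VascularBundle(
                uid=uid,
                raw_contour=r["raw"],
                hull_contour=r["hull"],
                spline_contour=r["spline"],
                centroid=r["centroid"],
                area_mm2=r["area_px"] * px2,
                layer_id=layer_of_point(layers, r["centroid"]),
                size_class=size_class,
                raw_area_mm2=r["raw_area_px"] * px2,
                hull_area_mm2=r["hull_area_px"] * px2,
            )
        )
    return bundles
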