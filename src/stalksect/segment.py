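"""Stalk section segmentation and epidermis ring extraction.

The stalk is the single dominant bright connected region of a micro-CT
cross-section slice.  Segmentation is threshold-based (Otsu by default)
followed by morphological closing and hole filling, so pith lacunae and
dark vessel lumina end up inside the mask.  The epidermis is the bright
outermost ring; its average thickness is found by peeling the mask inward
in 1-px shells until the peeled shell's mean intensity drops below a
configured fraction of the outermost shell's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import closing, disk

from .config import SegmentationConfig
from .errors import SegmentationError
from .geometry import cross_section_geometry
from .image import SliceImage


@dataclass
class EpidermisRing:
    """Outer/inner boundary of the epidermis and its mean thickness."""

    outer_boundary: np.ndarray
    inner_boundary: np.ndarray
    mean_thickness_mm: float
    thickness_px: float = 0.0


@dataclass
class StalkSection:
    """Segmented stalk cross-section with section-level geometry.

    ``mask`` covers the epidermis outer boundary and everything inside it.
    PAD/AAD are the moment-equivalent ellipse axes of the outer contour,
    CCR the minimum enclosing circle radius, SA the shoelace polygon area,
    AR = PAD/AAD >= 1.  All lengths mm, areas mm^2.
    """

    mask: np.ndarray | None
    outer_contour: np.ndarray
    centroid: tuple[float, float]
    PAD: float
    AAD: float
    CCR: float
    SA: float
    AR: float
    pixel_size_mm: float
    epidermis: EpidermisRing | None = None
    interior_distance: np.ndarray | None = field(default=None, repr=False)

    @property
    def area_px(self) -> float:
        return self.SA / self.pixel_size_mm**2


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no boundary contour")
    contour = max(contours, key=len)
    return contour[:-1] if np.allclose(contour[0], contour[-1]) else contour


def segment_stalk(
    img: SliceImage, cfg: SegmentationConfig | None = None
) -> StalkSection:
    """Segment the stalk section from the background.

    Thresholds the image (Otsu or fixed), applies morphological closing,
    keeps the largest connected component, and fills interior holes.

    Raises
    ------
    SegmentationError
        If no foreground component reaches ``cfg.min_section_area_px``.

    Warns if a second component comes within 10% of the largest's area
    (possible multi-stalk image); the largest is kept.
    """
    cfg = cfg or SegmentationConfig()
    px = img.pixels
    if cfg.threshold_method == "otsu":
        if px.min() == px.max():
            raise SegmentationError("flat image: no foreground/background contrast")
        thr = threshold_otsu(px)
    else:
        thr = cfg.fixed_threshold
    fg = px > thr
    if cfg.closing_radius_px > 0:
        fg = closing(fg, disk(cfg.closing_radius_px))
    lbl = label(fg)
    props = regionprops(lbl)
    props = [p for p in props if p.area >= cfg.min_section_area_px]
    if not props:
        raise SegmentationError(
            f"no foreground component with area >= {cfg.min_section_area_px} px"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area >= 0.9 * props[0].area:
        warnings.warn(
            "ambiguous segmentation: second component within 10% of the "
            "largest; keeping the largest",
            stacklevel=2,
        )
    mask = ndi.binary_fill_holes(lbl == props[0].label)
    contour = _outer_contour(mask)
    geom = cross_section_geometry(contour, img.pixel_size_mm)
    section = StalkSection(
        mask=mask,
        outer_contour=contour,
        centroid=geom["centroid"],
        PAD=geom["PAD"],
        AAD=geom["AAD"],
        CCR=geom["CCR"],
        SA=geom["SA"],
        AR=geom["AR"],
        pixel_size_mm=img.pixel_size_mm,
    )
    section.interior_distance = ndi.distance_transform_edt(mask)
    return section


def detect_epidermis(
    section: StalkSection,
    img: SliceImage,
    cfg: SegmentationConfig | None = None,
    max_thickness_px: int = 60,
) -> EpidermisRing:
    """Locate the epidermis inner boundary and estimate mean thickness.

    The mask is peeled inward in 1-px distance shells; the inner boundary
    sits at the first shell whose mean intensity falls below
    ``cfg.epidermis_drop_fraction`` times the outermost shell's mean.
    Mean thickness is averaged over outer-boundary samples as the distance
    to the nearest inner-boundary vertex.
    """
    cfg = cfg or SegmentationConfig()
    if section.mask is None:
        raise SegmentationError("section mask required for epidermis detection")
    dist = section.interior_distance
    if dist is None:
        dist = ndi.distance_transform_edt(section.mask)
    px = img.pixels.astype(float)

    shell0 = (dist > 0) & (dist <= 1)
    ref = px[shell0].mean() if shell0.any() else 0.0
    t = None
    for k in range(2, max_thickness_px + 1):
        shell = (dist > k - 1) & (dist <= k)
        if not shell.any():
            break
        if px[shell].mean() < cfg.epidermis_drop_fraction * ref:
            t = k - 1
            break
    if t is None:
        t = 1
        warnings.warn(
            "no epidermis intensity drop-off found; thickness clamped to 1 px",
            stacklevel=2,
        )
    inner_mask = dist > t
    if not inner_mask.any():
        t = 1
        inner_mask = dist > 1
        warnings.warn("thin epidermis: thickness clamped to 1 px", stacklevel=2)
    inner = _outer_contour(inner_mask)

    # mean thickness sampled along the outer boundary
    outer = section.outer_contour
    sample = outer[:: max(1, len(outer) // 256)]
    d2 = np.linalg.norm(sample[:, None, :] - inner[None, :, :], axis=2)
    mean_t_px = float(d2.min(axis=1).mean())
    if mean_t_px < 1:
        warnings.warn("thin epidermis: thickness clamped to 1 px", stacklevel=2)
        mean_t_px = 1.0
    ring = EpidermisRing(
        outer_boundary=outer,
        inner_boundary=inner,
        mean_thickness_mm=mean_t_px * img.pixel_size_mm,
        thickness_px=float(t),
    )
    section.epidermis = ring
    return ring
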