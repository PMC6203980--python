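"""Synthetic cross-section phantoms with exact ground truth.

A phantom emulates the gross radiographic anatomy of a maize stalk
internode slice: an elliptical section with a bright epidermis ring, small
bright vascular bundles densely packed in the rind (the outer equal-area
band), larger bundles sparsely scattered through the pith, a darker
parenchyma background, and additive Gaussian noise.  Every bundle's
center, radius, pixel-count area and owner layer are recorded, together
with the trait vector those quantities imply, so each pipeline stage can
be checked against exact ground truth without real CT data.

Default geometry and intensities (semi-axes 280 x 230 px, 12 px epidermis,
70 rind + 50 pith bundles, intensity set 20/90/220/180, noise sd 3) are
chosen so that Otsu separates section from background and local-mean
thresholding separates bundles from parenchyma, with bundle packing still
feasible in the rind band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from skimage.measure import find_contours

from scipy import ndimage as ndi

from .config import RunConfig
from .errors import InputError, PackingError
from .geometry import cross_section_geometry
from .image import SliceImage
from .layers import LayerMap, equal_area_layers
from .segment import StalkSection
from .traits import TRAIT_NAMES, TraitVector

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "generate_cohort"]


@dataclass
class PhantomSpec:
    section_axes_px: tuple[float, float] = (280.0, 230.0)  # (a=col, b=row) semi-axes
    epidermis_thickness_px: float = 12.0
    n_rind_bundles: int = 70
    n_pith_bundles: int = 50
    rind_bundle_radius_px: tuple[float, float] = (4.0, 6.0)
    pith_bundle_radius_px: tuple[float, float] = (7.0, 11.0)
    intensities: tuple[int, int, int, int] = (20, 90, 220, 180)  # bg, paren, epi, bundle
    noise_sd: float = 3.0
    min_gap_px: float = 3.0
    margin_px: int = 20
    pixel_size_mm: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        bg, paren, epi, bundle = self.intensities
        if not (bundle > paren and epi > paren > bg):
            raise InputError(
                "need bundle > parenchyma and epidermis > parenchyma > background"
            )
        a, b = self.section_axes_px
        if min(a, b) <= self.epidermis_thickness_px + max(
            self.rind_bundle_radius_px[1], self.pith_bundle_radius_px[1]
        ):
            raise InputError("section too small for epidermis + bundles")


@dataclass
class GroundTruth:
    """Exact per-bundle and section-level truth for one phantom."""

    bundle_centers: np.ndarray  # (N, 2) float (row, col)
    bundle_radii: np.ndarray
    bundle_layer_ids: np.ndarray
    bundle_areas_px: np.ndarray
    bundle_clear_of_boundary: np.ndarray  # centroid >= 2 px from layer offsets
    section_area_mm2: float
    section_axes_mm: tuple[float, float]
    epidermis_thickness_mm: float
    layer_areas_mm2: list[float]
    traits: TraitVector
    mask: np.ndarray | None = field(default=None, repr=False)


def _clean_section(mask: np.ndarray, pixel_size_mm: float) -> StalkSection:
    contour = max(find_contours(mask.astype(float), 0.5), key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    geom = cross_section_geometry(contour, pixel_size_mm)
    sec = StalkSection(
        mask=mask,
        outer_contour=contour,
        centroid=geom["centroid"],
        PAD=geom["PAD"],
        AAD=geom["AAD"],
        CCR=geom["CCR"],
        SA=geom["SA"],
        AR=geom["AR"],
        pixel_size_mm=pixel_size_mm,
    )
    sec.interior_distance = ndi.distance_transform_edt(mask)
    return sec


def _implied_traits(
    section: StalkSection,
    layers: LayerMap,
    layer_ids: np.ndarray,
    areas_mm2: np.ndarray,
) -> TraitVector:
    counts = [int(np.sum(layer_ids == k)) for k in (1, 2, 3, 4)]
    areas = [float(areas_mm2[layer_ids == k].sum()) for k in (1, 2, 3, 4)]
    vb = sum(counts)
    ta = sum(areas)
    la = layers.layer_areas_mm2
    return TraitVector(
        PAD=section.PAD, AAD=section.AAD, CCR=section.CCR, SA=section.SA,
        VB=vb, PVB=counts[0], CVB_2=counts[1], CVB_3=counts[2], CVB_4=counts[3],
        PA=areas[0], CA_2=areas[1], CA_3=areas[2], CA_4=areas[3],
        PAR=areas[0] / la[0], CAR_2=areas[1] / la[1],
        CAR_3=areas[2] / la[2], CAR_4=areas[3] / la[3],
        MA=ta / vb if vb else 0.0, TA=ta, Rsection=ta / section.SA,
        AR=section.AR,
    )


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[SliceImage, GroundTruth]:
    """Render one phantom slice and its exact ground truth.

    Deterministic for a given ``spec.seed``.  Bundle centers are drawn by
    rejection sampling on the pixel grid (at most 10^4 attempts each);
    infeasible packing raises :class:`PackingError`.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    a, b = spec.section_axes_px
    m = spec.margin_px
    h = int(2 * b) + 2 * m
    w = int(2 * a) + 2 * m
    cy, cx = h / 2.0, w / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    mask = ((rr - cy) / b) ** 2 + ((cc - cx) / a) ** 2 <= 1.0

    section = _clean_section(mask, spec.pixel_size_mm)
    dist = section.interior_distance
    layers = equal_area_layers(section, 4)
    labels = layers.label_raster
    t_epi = spec.epidermis_thickness_px

    bg, paren, epi, bundle_val = spec.intensities
    canvas = np.full((h, w), float(bg))
    canvas[mask] = float(paren)
    canvas[(dist > 0) & (dist <= t_epi)] = float(epi)

    centers: list[tuple[int, int]] = []
    radii: list[float] = []
    layer_ids: list[int] = []

    def _place(n: int, r_range: tuple[float, float], region: np.ndarray, kind: str):
        idx = np.flatnonzero(region.ravel())
        if len(idx) == 0:
            raise PackingError(f"no admissible {kind} centers; section too small")
        for _ in range(n):
            r = float(rng.uniform(*r_range))
            placed = False
            for _attempt in range(10_000):
                flat = int(rng.choice(idx))
                pr, pc = divmod(flat, w)
                if dist[pr, pc] < t_epi + r + spec.min_gap_px:
                    continue
                ok = True
                for (qr, qc), qrad in zip(centers, radii):
                    if (pr - qr) ** 2 + (pc - qc) ** 2 < (
                        r + qrad + spec.min_gap_px
                    ) ** 2:
                        ok = False
                        break
                if ok:
                    centers.append((pr, pc))
                    radii.append(r)
                    layer_ids.append(int(labels[pr, pc]))
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place {kind} bundle of radius {r:.1f} px with "
                    f"min_gap {spec.min_gap_px} px after 10000 attempts"
                )

    rind_region = labels == 1
    pith_region = labels >= 2
    _place(spec.n_rind_bundles, spec.rind_bundle_radius_px, rind_region, "rind")
    _place(spec.n_pith_bundles, spec.pith_bundle_radius_px, pith_region, "pith")

    areas_px = []
    for (pr, pc), r in zip(centers, radii):
        ri = int(np.ceil(r))
        sl = (slice(pr - ri, pr + ri + 1), slice(pc - ri, pc + ri + 1))
        local_r, local_c = np.mgrid[sl]
        disk = (local_r - pr) ** 2 + (local_c - pc) ** 2 <= r * r
        canvas[sl][disk] = float(bundle_val)
        areas_px.append(int(disk.sum()))

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    img = SliceImage(
        pixels=pixels,
        pixel_size_mm=spec.pixel_size_mm,
        source_id=f"phantom_{spec.seed:05d}",
    )

    centers_arr = np.array(centers, dtype=float)
    offsets = np.asarray(layers.offsets_px)
    center_depths = dist[tuple(np.array(centers, dtype=int).T)]
    clear = np.min(np.abs(center_depths[:, None] - offsets[None, :]), axis=1) >= 2.0
    px2 = spec.pixel_size_mm**2
    areas_mm2 = np.asarray(areas_px, dtype=float) * px2
    gt = GroundTruth(
        bundle_centers=centers_arr,
        bundle_radii=np.asarray(radii),
        bundle_layer_ids=np.asarray(layer_ids, dtype=int),
        bundle_areas_px=np.asarray(areas_px, dtype=int),
        bundle_clear_of_boundary=clear,
        section_area_mm2=section.SA,
        section_axes_mm=(2 * a * spec.pixel_size_mm, 2 * b * spec.pixel_size_mm),
        epidermis_thickness_mm=t_epi * spec.pixel_size_mm,
        layer_areas_mm2=list(layers.layer_areas_mm2),
        traits=_implied_traits(section, layers, np.asarray(layer_ids), areas_mm2),
        mask=mask,
    )
    return img, gt


def ground_truth_to_dict(gt: GroundTruth) -> dict[str, Any]:
    """JSON-ready form of a GroundTruth (mask omitted)."""
    return {
        "bundle_centers": gt.bundle_centers.tolist(),
        "bundle_radii": gt.bundle_radii.tolist(),
        "bundle_layer_ids": gt.bundle_layer_ids.tolist(),
        "bundle_areas_px": gt.bundle_areas_px.tolist(),
        "bundle_clear_of_boundary": gt.bundle_clear_of_boundary.tolist(),
        "section_area_mm2": gt.section_area_mm2,
        "section_axes_mm": list(gt.section_axes_mm),
        "epidermis_thickness_mm": gt.epidermis_thickness_mm,
        "layer_areas_mm2": gt.layer_areas_mm2,
        "traits": gt.traits.as_dict(),
    }


def generate_cohort(
    spec_a: PhantomSpec,
    spec_b: PhantomSpec,
    n_per_group: int,
    mech_model: dict[str, Any],
    seed: int = 0,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Simulate a two-variety study: run the full pipeline on phantoms from
    two specs and attach a bending-strength column.

    ``mech_model`` has keys ``intercept`` (float), ``coefs`` (trait -> slope)
    and ``noise_sd`` (float); BS is the stated linear function of the
    *measured* traits plus Gaussian noise, enabling regression-recovery
    experiments with a known generative model.

    Plant-to-plant size variability is emulated by jittering each sample's
    section semi-axes independently by up to +/-8% around the spec values,
    so section-level traits (PAD, AAD, CCR, SA, AR) vary across the cohort
    as they do across real stalks.
    """
    from .pipeline import analyze_slice  # deferred: avoids import cycle

    if n_per_group < 2:
        raise InputError("n_per_group must be >= 2")
    coefs = dict(mech_model.get("coefs", {}))
    unknown = [t for t in coefs if t not in TRAIT_NAMES]
    if unknown:
        raise InputError(f"mech_model references unknown traits: {unknown}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, spec in (("A", spec_a), ("B", spec_b)):
        for i in range(n_per_group):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            a, b = spec.section_axes_px
            jitter = rng.uniform(-0.08, 0.08, size=2)
            sp = PhantomSpec(
                **{
                    **spec.__dict__,
                    "section_axes_px": (a * (1 + jitter[0]), b * (1 + jitter[1])),
                    "seed": sub_seed,
                }
            )
            img, _ = generate_phantom(sp)
            img.source_id = f"{group}_{i:03d}"
            result = analyze_slice(img, cfg)
            row = {"source_id": img.source_id, "group": group}
            row.update(result.traits.as_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    bs = float(mech_model.get("intercept", 0.0)) + sum(
        c * df[t].to_numpy(dtype=float) for t, c in coefs.items()
    )
    noise_sd = float(mech_model.get("noise_sd", 0.0))
    if noise_sd > 0:
        bs = bs + rng.normal(0.0, noise_sd, len(df))
    df["BS"] = bs
    return df
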