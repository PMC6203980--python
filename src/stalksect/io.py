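"""Slice image loading, batch discovery, and result serialization.

Per-slice results are stored as versioned JSON: contours as vertex lists,
traits as a named map.  The format is inspectable and diff-able; rasters
(section mask, layer labels) are not stored — everything downstream of
segmentation is carried by contours and scalars, and spline polygons are
re-evaluated deterministically from their control points on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .bundles import ClosedSpline, VascularBundle, evaluate_spline
from .errors import FormatError, InputError
from .image import SliceImage
from .layers import LayerMap
from .segment import EpidermisRing, StalkSection
from .traits import TRAIT_NAMES, TraitVector

SCHEMA_VERSION = 1

# Rec. 601 luma weights for RGB -> gray collapse
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SliceResult:
    """Integrated analysis result for one slice."""

    source_id: str
    section: StalkSection
    layers: LayerMap
    bundles: list[VascularBundle]
    traits: TraitVector
    config_digest: str = ""


def discover_images(directory: str | Path, pattern: str = "*.png") -> list[Path]:
    """Deterministic (lexicographic) list of files matching ``pattern``."""
    d = Path(directory)
    if not d.is_dir():
        raise InputError(f"not a directory: {d}")
    return sorted(p for p in d.glob(pattern) if p.is_file())


def load_slice(path: str | Path, pixel_size_mm: float, source_id: str | None = None) -> SliceImage:
    """Read an 8-bit BMP/PNG/TIFF raster; RGB collapses to Rec. 601 luma."""
    path = Path(path)
    if pixel_size_mm <= 0:
        raise InputError("pixel_size_mm must be positive")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim}")
    if arr.dtype != np.uint8:
        if arr.max() > 255 or arr.min() < 0:
            raise FormatError("expected 8-bit intensities in [0, 255]")
        arr = arr.astype(np.uint8)
    return SliceImage(
        pixels=arr,
        pixel_size_mm=pixel_size_mm,
        source_id=source_id if source_id is not None else path.stem,
    )


def _contour_out(c: np.ndarray) -> list[list[float]]:
    return np.asarray(c, dtype=float).tolist()


def _contour_in(c: list) -> np.ndarray:
    return np.asarray(c, dtype=float)


def save_result(result: SliceResult, path: str | Path) -> None:
    """Write a SliceResult as versioned JSON (documented schema)."""
    sec = result.section
    epi = sec.epidermis
    doc = {
        "schema_version": SCHEMA_VERSION,
        "source_id": result.source_id,
        "config_digest": result.config_digest,
        "section": {
            "pixel_size_mm": sec.pixel_size_mm,
            "outer_contour": _contour_out(sec.outer_contour),
            "centroid": list(sec.centroid),
            "PAD": sec.PAD,
            "AAD": sec.AAD,
            "CCR": sec.CCR,
            "SA": sec.SA,
            "AR": sec.AR,
            "epidermis": None
            if epi is None
            else {
                "outer_boundary": _contour_out(epi.outer_boundary),
                "inner_boundary": _contour_out(epi.inner_boundary),
                "mean_thickness_mm": epi.mean_thickness_mm,
                "thickness_px": epi.thickness_px,
            },
        },
        "layers": {
            "n_layers": result.layers.n_layers,
            "scheme": result.layers.scheme,
            "offsets_px": result.layers.offsets_px,
            "max_depth_px": result.layers.max_depth_px,
            "layer_areas_mm2": result.layers.layer_areas_mm2,
            "boundary_contours": [
                _contour_out(c) for c in result.layers.boundary_contours
            ],
        },
        "bundles": [
            {
                "uid": b.uid,
                "raw_contour": _contour_out(b.raw_contour),
                "hull_contour": _contour_out(b.hull_contour),
                "spline_control_points": _contour_out(
                    b.spline_contour.control_points
                ),
                "centroid": list(b.centroid),
                "area_mm2": b.area_mm2,
                "raw_area_mm2": b.raw_area_mm2,
                "hull_area_mm2": b.hull_area_mm2,
                "layer_id": b.layer_id,
                "size_class": b.size_class,
            }
            for b in result.bundles
        ],
        "traits": result.traits.as_dict(),
    }
    Path(path).write_text(json.dumps(doc))


def load_result(path: str | Path) -> SliceResult:
    """Load a SliceResult written by :func:`save_result`.

    Rasters are not reconstructed (``mask``/``label_raster`` are None);
    spline polygons are re-evaluated from their control points, which is
    exact because the evaluation is deterministic.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable result file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"result schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    s = doc["section"]
    epi = None
    if s.get("epidermis"):
        e = s["epidermis"]
        epi = EpidermisRing(
            outer_boundary=_contour_in(e["outer_boundary"]),
            inner_boundary=_contour_in(e["inner_boundary"]),
            mean_thickness_mm=e["mean_thickness_mm"],
            thickness_px=e["thickness_px"],
        )
    section = StalkSection(
        mask=None,
        outer_contour=_contour_in(s["outer_contour"]),
        centroid=tuple(s["centroid"]),
        PAD=s["PAD"],
        AAD=s["AAD"],
        CCR=s["CCR"],
        SA=s["SA"],
        AR=s["AR"],
        pixel_size_mm=s["pixel_size_mm"],
        epidermis=epi,
    )
    lay = doc["layers"]
    layers = LayerMap(
        n_layers=lay["n_layers"],
        label_raster=None,
        boundary_contours=[_contour_in(c) for c in lay["boundary_contours"]],
        layer_areas_mm2=list(lay["layer_areas_mm2"]),
        scheme=lay["scheme"],
        offsets_px=list(lay["offsets_px"]),
        max_depth_px=lay["max_depth_px"],
    )
    bundles = []
    for b in doc["bundles"]:
        cp = _contour_in(b["spline_control_points"])
        bundles.append(
            VascularBundle(
                uid=b["uid"],
                raw_contour=_contour_in(b["raw_contour"]),
                hull_contour=_contour_in(b["hull_contour"]),
                spline_contour=ClosedSpline(
                    control_points=cp, sampled_polygon=evaluate_spline(cp)
                ),
                centroid=tuple(b["centroid"]),
                area_mm2=b["area_mm2"],
                layer_id=b["layer_id"],
                size_class=b["size_class"],
                raw_area_mm2=b["raw_area_mm2"],
                hull_area_mm2=b["hull_area_mm2"],
            )
        )
    traits = TraitVector(**doc["traits"])
    return SliceResult(
        source_id=doc["source_id"],
        section=section,
        layers=layers,
        bundles=bundles,
        traits=traits,
        config_digest=doc.get("config_digest", ""),
    )


def write_trait_table(results: list[SliceResult], path: str | Path) -> None:
    """Collect results into a CSV: source_id + the 21 trait columns."""
    if not results:
        raise InputError("no results to tabulate")
    ids = [r.source_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate source_id values: {dupes}")
    rows = []
    for r in results:
        row = {"source_id": r.source_id}
        row.update({k: r.traits.as_dict()[k] for k in TRAIT_NAMES})
        rows.append(row)
    pd.DataFrame(rows, columns=["source_id"] + TRAIT_NAMES).to_csv(
        path, index=False
    )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait table CSV written by :func:`write_trait_table` (extra
    columns such as BS or group labels are preserved)."""
    df = pd.read_csv(path)
    missing = [c for c in ["source_id"] + TRAIT_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"trait table missing columns: {missing}")
    return df
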