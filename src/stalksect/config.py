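"""Pipeline configuration: uniform algorithm parameters for batch runs.

Every analysis result embeds ``config_digest`` — a SHA-256 fingerprint of
the full parameter set — so that trait tables are traceable to the exact
parameters that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

from .errors import InputError


@dataclass
class SegmentationConfig:
    """Stalk/background segmentation and epidermis extraction parameters.

    threshold_method : 'otsu' (parameter-free default) or 'fixed'.
    fixed_threshold : global intensity cut used when threshold_method='fixed'.
    closing_radius_px : disk radius for morphological closing of the mask.
    min_section_area_px : smallest foreground component accepted as a stalk.
    epidermis_drop_fraction : the epidermis inner boundary is placed at the
        first 1-px inward erosion step whose peeled shell has mean intensity
        below this fraction of the outermost shell's mean.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float = 128.0
    closing_radius_px: int = 3
    min_section_area_px: int = 5000
    epidermis_drop_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise InputError(f"unknown threshold_method {self.threshold_method!r}")
        if not 0 < self.epidermis_drop_fraction < 1:
            raise InputError("epidermis_drop_fraction must be in (0, 1)")


@dataclass
class LayerConfig:
    """Concentric layer decomposition parameters."""

    n_layers: int = 4
    layer_scheme: str = "equal_area"  # or 'equidistant'

    def __post_init__(self) -> None:
        if self.layer_scheme not in ("equal_area", "equidistant"):
            raise InputError(f"unknown layer_scheme {self.layer_scheme!r}")
        if self.n_layers < 2:
            raise InputError("n_layers must be >= 2")


@dataclass
class BundleConfig:
    """Vascular bundle detection and refinement parameters.

    The validation thresholds interpolate linearly with the normalized
    distance d of a candidate's centroid from the section centroid
    (d = 0 at the centroid, 1 at the section boundary): a candidate is kept
    iff its area >= a_center_px + (a_periph_px - a_center_px) * d and its
    solidity >= s_center + (s_periph - s_center) * d.  Peripheral thresholds
    are laxer so that the small, densely packed rind bundles survive the
    minimum-area control.
    """

    threshold_mode: str = "adaptive"  # or 'fixed'
    fixed_threshold: float = 140.0
    adaptive_window_px: int = 51
    adaptive_offset: float = 10.0
    a_center_px: float = 80.0
    a_periph_px: float = 30.0
    s_center: float = 0.5
    s_periph: float = 0.4
    spline_nodes: int = 12

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "adaptive"):
            raise InputError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.adaptive_window_px % 2 == 0:
            raise InputError("adaptive_window_px must be odd")
        if self.spline_nodes < 4:
            raise InputError("spline_nodes must be >= 4")


@dataclass
class RunConfig:
    """Uniform parameter set for a batch run."""

    pixel_size_mm: float = 0.01
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    layers: LayerConfig = field(default_factory=LayerConfig)
    bundles: BundleConfig = field(default_factory=BundleConfig)
    n_workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise InputError("pixel_size_mm must be positive")
        if self.n_workers < 1:
            raise InputError("n_workers must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("segmentation", SegmentationConfig),
            ("layers", LayerConfig),
            ("bundles", BundleConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def digest(self) -> str:
        """SHA-256 fingerprint of the canonical JSON form of the config."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
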