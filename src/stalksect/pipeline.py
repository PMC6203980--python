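"""Single-slice analysis pipeline: segmentation -> epidermis -> layers ->
bundles -> traits, under one uniform parameter set."""

from __future__ import annotations

from .bundles import detect_bundles
from .config import RunConfig
from .image import SliceImage
from .io import SliceResult
from .layers import equal_area_layers, equidistant_layers
from .segment import detect_epidermis, segment_stalk
from .traits import compute_traits


def analyze_slice(img: SliceImage, cfg: RunConfig | None = None) -> SliceResult:
    """Run the full anatomical analysis of one calibrated slice image."""
    cfg = cfg or RunConfig(pixel_size_mm=img.pixel_size_mm)
    section = segment_stalk(img, cfg.segmentation)
    detect_epidermis(section, img, cfg.segmentation)
    if cfg.layers.layer_scheme == "equal_area":
        layers = equal_area_layers(section, cfg.layers.n_layers)
    else:
        layers = equidistant_layers(section, cfg.layers.n_layers)
    bundles = detect_bundles(img, section, layers, cfg.bundles)
    traits = compute_traits(section, layers, bundles)
    return SliceResult(
        source_id=img.source_id,
        section=section,
        layers=layers,
        bundles=bundles,
        traits=traits,
        config_digest=cfg.digest(),
    )
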