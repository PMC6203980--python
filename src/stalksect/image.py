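"""Calibrated grayscale slice image container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass
class SliceImage:
    """One calibrated 8-bit cross-section raster.

    Parameters
    ----------
    pixels : (H, W) uint8 array
        Grayscale intensities in [0, 255].
    pixel_size_mm : float
        Isotropic pixel edge length in millimetres; must be supplied by the
        user (scan geometry fixes it at acquisition time, it is never
        guessed from file metadata).
    source_id : str
        Label identifying the slice, typically the file stem.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise InputError("pixels must be a 2-D array with >= 2 rows and columns")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if not self.pixel_size_mm > 0:
            raise InputError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
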