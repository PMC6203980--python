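import numpy as np
import pytest

import stalksect as ss


def make_disk_image(radius=150, intensity=180, background=20, pad=20,
                    pixel_size_mm=0.01):
    """Filled disk of given radius on a dark background."""
    n = 2 * (radius + pad)
    rr, cc = np.mgrid[0:n, 0:n]
    c = n / 2.0
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    px = np.full((n, n), background, dtype=np.uint8)
    px[mask] = intensity
    return ss.SliceImage(pixels=px, pixel_size_mm=pixel_size_mm,
                         source_id="disk"), mask


def make_annulus_image(radius=150, thickness=12, ring=220, interior=90,
                       background=20, pad=20, axes=None):
    """Bright ring of uniform thickness around a darker interior; ``axes``
    switches to an elliptical ring with the given (a, b) semi-axes."""
    if axes is None:
        a = b = radius
    else:
        a, b = axes
    h, w = 2 * (b + pad), 2 * (a + pad)
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    outer = ((rr - cy) / b) ** 2 + ((cc - cx) / a) ** 2 <= 1.0
    inner = ((rr - cy) / (b - thickness)) ** 2 + (
        (cc - cx) / (a - thickness)
    ) ** 2 <= 1.0
    px = np.full((h, w), background, dtype=np.uint8)
    px[outer] = ring
    px[inner] = interior
    return ss.SliceImage(pixels=px, pixel_size_mm=0.01, source_id="annulus")


def random_blob_contour(rng, center=(0.0, 0.0), mean_radius=60.0, n_pts=72,
                        wobble=0.25):
    """Smooth star-shaped closed contour around ``center`` (row, col)."""
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    k = rng.integers(2, 6)
    phase = rng.uniform(0, 2 * np.pi)
    r = mean_radius * (1 + wobble * np.sin(k * theta + phase)
                       + 0.5 * wobble * np.cos((k + 1) * theta))
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.column_stack([rows, cols])


@pytest.fixture(scope="session")
def phantom_and_truth():
    return ss.generate_phantom(ss.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def analyzed(phantom_and_truth):
    img, _ = phantom_and_truth
    return ss.analyze_slice(img)
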