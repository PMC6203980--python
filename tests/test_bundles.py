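"""Bundle detection: thresholding, distance-dependent validation, hull and
spline refinement, and full-pipeline recovery on phantoms."""

import dataclasses

import numpy as np
import pytest

import stalksect as ss
from stalksect.bundles import evaluate_spline, normalized_centroid_distance
from stalksect.geometry import shoelace_area
from tests.conftest import make_disk_image


def blob_image(n_blobs=30, seed=0, radius=8, section_radius=220):
    """Disk-shaped section with ``n_blobs`` disjoint bright blobs inside."""
    img, _ = make_disk_image(radius=section_radius, intensity=90, pad=20)
    px = img.pixels.copy()
    n = px.shape[0]
    rng = np.random.default_rng(seed)
    centers = []
    while len(centers) < n_blobs:
        r, c = rng.uniform(n / 2 - 150, n / 2 + 150, 2)
        if all((r - q[0]) ** 2 + (c - q[1]) ** 2 > (2 * radius + 8) ** 2 for q in centers):
            centers.append((r, c))
    rr, cc = np.mgrid[0:n, 0:n]
    for r, c in centers:
        px[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = 180
    return ss.SliceImage(pixels=px, pixel_size_mm=0.01), centers


class TestThresholdBundles:
    def test_counts_disjoint_blobs(self):
        img, centers = blob_image(30)
        section = ss.segment_stalk(img)
        ss.detect_epidermis(section, img)
        cands = ss.threshold_bundles(img, section)
        assert len(cands) == len(centers)

    def test_uniform_interior_yields_nothing(self):
        img, _ = make_disk_image(radius=200, intensity=90)
        section = ss.segment_stalk(img)
        assert ss.threshold_bundles(img, section) == []

    def test_one_pixel_bridge_merges_under_fixed_threshold(self):
        img, _ = make_disk_image(radius=120, intensity=90, pad=20)
        px = img.pixels.copy()
        n = px.shape[0]
        rr, cc = np.mgrid[0:n, 0:n]
        c0 = n // 2
        px[(rr - c0) ** 2 + (cc - (c0 - 14)) ** 2 <= 8**2] = 180
        px[(rr - c0) ** 2 + (cc - (c0 + 14)) ** 2 <= 8**2] = 180
        px[c0 - 1 : c0 + 2, c0 - 14 : c0 + 15] = 180  # 3-px bridge survives opening
        merged = ss.SliceImage(pixels=px, pixel_size_mm=0.01)
        section = ss.segment_stalk(merged)
        cfg = ss.BundleConfig(threshold_mode="fixed", fixed_threshold=140)
        assert len(ss.threshold_bundles(merged, section, cfg)) == 1


class TestValidateCandidates:
    @staticmethod
    def _square(center, side):
        r, c = center
        h = side / 2.0
        return np.array(
            [[r - h, c - h], [r - h, c + h], [r + h, c + h], [r + h, c - h]]
        )

    def test_distance_dependent_area_threshold(self):
        img, _ = make_disk_image(radius=200, intensity=90, pad=20)
        section = ss.segment_stalk(img)
        cy, cx = section.centroid
        cfg = ss.BundleConfig(a_center_px=40, a_periph_px=8)
        small_far = self._square((cy + 190, cx), side=np.sqrt(10))  # d ~ 0.95
        small_near = self._square((cy + 20, cx), side=np.sqrt(10))  # d ~ 0.1
        assert ss.validate_candidates([small_far], section, cfg) == [small_far]
        assert ss.validate_candidates([small_near], section, cfg) == []

    def test_convex_candidates_pass_any_solidity_threshold(self):
        img, _ = make_disk_image(radius=200, intensity=90, pad=20)
        section = ss.segment_stalk(img)
        cfg = ss.BundleConfig(s_center=0.99, s_periph=0.99, a_center_px=5, a_periph_px=5)
        sq = self._square(section.centroid, side=20)
        assert len(ss.validate_candidates([sq], section, cfg)) == 1

    def test_normalized_distance_limits(self):
        img, _ = make_disk_image(radius=200, intensity=90, pad=20)
        section = ss.segment_stalk(img)
        cy, cx = section.centroid
        assert normalized_centroid_distance((cy, cx), section) == 0.0
        d_edge = normalized_centroid_distance((cy, cx + 199), section)
        assert 0.97 <= d_edge <= 1.0


class TestSpline:
    def test_circle_area_recovery(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        circle = np.column_stack([50 * np.sin(t), 50 * np.cos(t)])
        spl = ss.fit_spline(circle, 8)
        assert shoelace_area(spl.sampled_polygon) == pytest.approx(
            np.pi * 50**2, rel=0.01
        )

    def test_square_corner_behavior(self):
        # K=4 nodes at the corners leave no straight-edge information: the
        # smooth closed interpolant bulges out toward the circumscribed
        # circle (area 800*pi); denser nodes recover the square.
        sq = np.array([[0.0, 0.0], [0.0, 40.0], [40.0, 40.0], [40.0, 0.0]])
        a4 = shoelace_area(ss.fit_spline(sq, 4).sampled_polygon)
        assert 1600 < a4 <= 800 * np.pi * 1.01
        a16 = shoelace_area(ss.fit_spline(sq, 16).sampled_polygon)
        assert a16 == pytest.approx(1600, rel=0.10)

    def test_passes_through_control_points(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        c = np.column_stack([30 * np.sin(t), 45 * np.cos(t)])
        spl = ss.fit_spline(c, 12)
        for p in spl.control_points:
            d = np.linalg.norm(spl.sampled_polygon - p, axis=1).min()
            assert d <= 0.5

    def test_outward_edit_increases_area(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        c = np.column_stack([30 * np.sin(t), 30 * np.cos(t)])
        spl = ss.fit_spline(c, 8)
        base = shoelace_area(spl.sampled_polygon)
        cp = spl.control_points.copy()
        cp[0] *= 1.3  # push one node radially outward
        assert shoelace_area(evaluate_spline(cp)) > base

    def test_too_few_nodes_rejected(self):
        sq = np.array([[0.0, 0.0], [0.0, 4.0], [4.0, 4.0], [4.0, 0.0]])
        with pytest.raises(ss.InputError):
            ss.fit_spline(sq, 3)


class TestDetectBundles:
    def test_phantom_counts_and_layers_exact(self, phantom_and_truth, analyzed):
        _, gt = phantom_and_truth
        t = analyzed.traits
        assert t.VB == gt.traits.VB == 120
        assert (t.PVB, t.CVB_2, t.CVB_3, t.CVB_4) == (
            gt.traits.PVB, gt.traits.CVB_2, gt.traits.CVB_3, gt.traits.CVB_4,
        )

    def test_total_area_within_five_percent(self, phantom_and_truth, analyzed):
        _, gt = phantom_and_truth
        assert analyzed.traits.TA == pytest.approx(gt.traits.TA, rel=0.05)

    def test_hull_never_shrinks_and_spline_stays_close(self, analyzed):
        for b in analyzed.bundles:
            assert b.hull_area_mm2 >= b.raw_area_mm2 * (1 - 1e-9)
            assert abs(b.area_mm2 - b.hull_area_mm2) / b.hull_area_mm2 <= 0.05

    def test_raising_area_thresholds_monotone(self, phantom_and_truth):
        img, _ = phantom_and_truth
        section = ss.segment_stalk(img)
        ss.detect_epidermis(section, img)
        layers = ss.equal_area_layers(section)
        counts = []
        for a in (30, 60, 120):
            cfg = ss.BundleConfig(a_center_px=a * 2.0, a_periph_px=a)
            counts.append(len(ss.detect_bundles(img, section, layers, cfg)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_determinism(self, phantom_and_truth):
        img, _ = phantom_and_truth
        r1 = ss.analyze_slice(img)
        r2 = ss.analyze_slice(img)
        assert [b.uid for b in r1.bundles] == [b.uid for b in r2.bundles]
        assert r1.traits.as_dict() == r2.traits.as_dict()

    def test_empty_interior(self):
        img, _ = make_disk_image(radius=200, intensity=90)
        section = ss.segment_stalk(img)
        with pytest.warns(UserWarning):
            ss.detect_epidermis(section, img)
        layers = ss.equal_area_layers(section)
        bundles = ss.detect_bundles(img, section, layers)
        assert bundles == []
        traits = ss.compute_traits(section, layers, bundles)
        assert traits.VB == 0 and traits.TA == 0.0

    def test_idempotence_on_rerasterized_output(self, analyzed, phantom_and_truth):
        """Re-rasterizing the detected bundles and re-detecting returns the
        same count."""
        img, _ = phantom_and_truth
        px = np.full_like(img.pixels, 20)
        section = analyzed.section
        px[section.mask] = 90
        dist = section.interior_distance
        px[(dist > 0) & (dist <= section.epidermis.thickness_px)] = 220
        from skimage.draw import polygon as draw_polygon

        for b in analyzed.bundles:
            poly = b.spline_contour.sampled_polygon
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=px.shape)
            px[rr, cc] = 180
        re_img = ss.SliceImage(pixels=px, pixel_size_mm=0.01)
        re_res = ss.analyze_slice(re_img)
        assert re_res.traits.VB == analyzed.traits.VB
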