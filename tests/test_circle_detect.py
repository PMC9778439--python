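import numpy as np
import pytest

from lentil_eye.circle_detect import (
    DISCARDED_RADIOMETRIC,
    DISCARDED_RADIUS,
    RETAINED,
    DegenerateGeometryError,
    DetectedCircle,
    DetectorParams,
    EdgeMap,
    circumcircle,
    detect_circles,
    edge_map,
    extract_patch,
    radiometric_filter,
    radius_filter,
)
from lentil_eye.synthetic_scene import SceneSpec, generate_scene

from conftest import grid_oracle


def draw_disc(shape=(128, 128), center=(64, 64), radius=50, fg=180, bg=30):
    """Anti-aliased disc for edge tests (independent of the scene module)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(xx - center[0], yy - center[1])
    alpha = np.clip(radius + 0.5 - d, 0, 1)
    img = bg + alpha * (fg - bg)
    return np.repeat(img[..., None], 3, axis=2).astype(np.uint8)


def match_truth(detections, truth_circles, center_tol=2.0, radius_tol=1.0):
    used, hits = set(), 0
    for cx, cy, r in truth_circles:
        for j, c in enumerate(detections):
            if j in used:
                continue
            if (np.hypot(c.center[0] - cx, c.center[1] - cy) < center_tol
                    and abs(c.radius_px - r) < radius_tol):
                used.add(j)
                hits += 1
                break
    return hits


class TestEdgeMap:
    def test_constant_image_has_no_edges(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        assert edge_map(img).n_pixels == 0

    def test_disc_edges_form_annulus(self):
        img = draw_disc(radius=50)
        em = edge_map(img)
        coords = em.coordinates.astype(float)
        d = np.hypot(coords[:, 0] - 64, coords[:, 1] - 64)
        assert np.mean(np.abs(d - 50) <= 2) >= 0.8

    def test_two_discs_two_loops(self):
        from skimage.measure import label

        img = np.maximum(draw_disc((128, 256), (64, 64), 40),
                         draw_disc((128, 256), (190, 64), 40))
        em = edge_map(img)
        lab = label(em.raster, connectivity=2)
        big = [i for i in range(1, lab.max() + 1) if (lab == i).sum() >= 50]
        assert len(big) == 2

    def test_coordinates_match_raster(self):
        img = draw_disc()
        em = edge_map(img)
        for x, y in em.coordinates[:25]:
            assert em.raster[y, x]


class TestCircumcircle:
    def test_right_triangle(self):
        c = circumcircle((0, 0), (2, 0), (0, 2))
        assert c.center == pytest.approx((1, 1))
        assert c.radius_px == pytest.approx(np.sqrt(2))

    def test_symmetric_case(self):
        c = circumcircle((0, 0), (2, 0), (1, 1))
        assert c.center == pytest.approx((1, 0))
        assert c.radius_px == pytest.approx(1)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            circumcircle((0, 0), (1, 0), (2, 0))


class TestDetectCircles:
    def test_empty_edge_map(self):
        em = EdgeMap(np.zeros((64, 64), dtype=bool))
        assert detect_circles(em, DetectorParams()) == []

    def test_recovers_scene_circles(self, scene10):
        image, truth = scene10
        det = detect_circles(edge_map(image), DetectorParams(rng_seed=0))
        assert match_truth(det, truth.circles) >= 9

    def test_occluded_arc_still_detected(self):
        # pure 270-degree arc: a quarter of the rim is missing
        raster = np.zeros((128, 128), dtype=bool)
        theta = np.linspace(0, 1.5 * np.pi, 2000)
        xs = np.clip(np.round(64 + 50 * np.cos(theta)).astype(int), 0, 127)
        ys = np.clip(np.round(64 + 50 * np.sin(theta)).astype(int), 0, 127)
        raster[ys, xs] = True
        det = detect_circles(EdgeMap(raster), DetectorParams(rng_seed=1))
        assert match_truth(det, [(64, 64, 50)], center_tol=2, radius_tol=1) == 1

    def test_no_false_positives_on_noise(self):
        params = DetectorParams(rng_seed=0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            raster = rng.random((128, 128)) < 0.009
            assert detect_circles(EdgeMap(raster), params) == []

    def test_deterministic(self, scene10):
        image, _ = scene10
        em = edge_map(image)
        d1 = detect_circles(em, DetectorParams(rng_seed=3))
        d2 = detect_circles(em, DetectorParams(rng_seed=3))
        assert [(c.center, c.radius_px) for c in d1] == [
            (c.center, c.radius_px) for c in d2
        ]

    def test_matches_exhaustive_grid_oracle(self):
        img = draw_disc((128, 128), (60, 70), 42)
        em = edge_map(img)
        det = detect_circles(em, DetectorParams(rng_seed=0))
        assert len(det) == 1
        # exhaustive Hough-style search around the truth
        best = grid_oracle(em.coordinates.astype(float), (60, 70), 42)
        c = det[0]
        assert np.hypot(c.center[0] - best[0], c.center[1] - best[1]) <= 0.75
        assert abs(c.radius_px - best[2]) <= 0.75


class TestRadiusFilter:
    def test_outlier_discarded(self):
        # radii where the outlier sits outside mean +/- 2*SD:
        # mu = 55.5, sd = 15.1, |90 - 55.5| = 34.5 > 30.2
        radii = (50, 51, 49, 52, 48, 43, 60, 90)
        mu, sd = np.mean(radii), np.std(radii)
        assert abs(90 - mu) > 2 * sd  # oracle for the expected discard
        circles = [DetectedCircle(center=(0, 0), radius_px=r) for r in radii]
        out = radius_filter(circles, 2.0)
        assert [c.status for c in out] == [RETAINED] * 7 + [DISCARDED_RADIUS]

    def test_lone_gross_outlier_inflates_sigma(self):
        # documented blind spot of the published rule: one huge radius
        # widens the band enough to pass (|200 - 87.5| < 2 * 64.96)
        circles = [DetectedCircle(center=(0, 0), radius_px=r)
                   for r in (50, 51, 49, 200)]
        out = radius_filter(circles, 2.0)
        assert all(c.status == RETAINED for c in out)

    def test_all_equal_retained(self):
        circles = [DetectedCircle(center=(0, 0), radius_px=40) for _ in range(5)]
        assert all(c.status == RETAINED for c in radius_filter(circles, 2.0))

    def test_single_circle_retained(self):
        out = radius_filter([DetectedCircle(center=(0, 0), radius_px=7)], 2.0)
        assert out[0].status == RETAINED

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            radius_filter([], 2.0)

    def test_input_not_mutated(self):
        circles = [DetectedCircle(center=(0, 0), radius_px=r) for r in (5, 100)]
        radius_filter(circles, 0.5)
        assert all(c.status == RETAINED for c in circles)


class TestRadiometricFilter:
    def test_circle_on_bright_disc_retained(self):
        img = draw_disc(radius=40)
        c = radiometric_filter(DetectedCircle(center=(64, 64), radius_px=40), img)
        assert c.background_fraction < 0.05
        assert c.status == RETAINED

    def test_circle_on_background_discarded(self):
        img = draw_disc(radius=20, center=(100, 100))
        c = radiometric_filter(DetectedCircle(center=(25, 25), radius_px=15), img)
        assert c.background_fraction > 0.9
        assert c.status == DISCARDED_RADIOMETRIC

    def test_double_radius_circle_three_quarters_background(self):
        img = draw_disc((256, 256), (128, 128), 60)
        c = radiometric_filter(
            DetectedCircle(center=(128, 128), radius_px=120), img)
        assert c.background_fraction == pytest.approx(0.75, abs=0.03)
        assert c.status == DISCARDED_RADIOMETRIC

    def test_circle_outside_image_raises(self):
        img = draw_disc()
        with pytest.raises(ValueError):
            radiometric_filter(
                DetectedCircle(center=(-500, -500), radius_px=10), img)


class TestExtractPatch:
    def test_central_patch_geometry(self):
        img = draw_disc((256, 256), (128, 128), 50)
        patch = extract_patch(img, DetectedCircle(center=(128, 128), radius_px=50))
        assert patch.pixels.shape[:2] == (100, 100)
        assert patch.mask.sum() / patch.mask.size == pytest.approx(np.pi / 4,
                                                                   abs=0.01)
        assert not patch.clipped

    def test_border_patch_clipped_mask_consistent(self):
        img = draw_disc((100, 100), (10, 50), 20)
        patch = extract_patch(img, DetectedCircle(center=(10, 50), radius_px=20))
        assert patch.clipped
        # analytic: full disc minus the circular segment beyond x < 0
        r, d = 20.0, 10.0
        segment = r * r * np.arccos(d / r) - d * np.sqrt(r * r - d * d)
        expected = np.pi * r * r - segment
        assert patch.mask.sum() == pytest.approx(expected, rel=0.03)

    def test_one_patch_per_retained_circle(self, scene10):
        image, _ = scene10
        det = detect_circles(edge_map(image), DetectorParams(rng_seed=0))
        circles = [DetectedCircle(center=c.center, radius_px=c.radius_px)
                   for c in det]
        patches = [extract_patch(image, c) for c in circles]
        assert len(patches) == len(circles)
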