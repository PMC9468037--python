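import dataclasses

import numpy as np
import pytest

from benthoscan import lasers
from benthoscan import synthetic as syn


def _rgb(r, g, b):
    img = np.zeros((1, 1, 3), dtype=np.uint8)
    img[0, 0] = (r, g, b)
    return img


class TestLaserSignal:
    def test_basic_arithmetic(self):
        assert lasers.laser_signal(_rgb(200, 50, 50), 0.2)[0, 0] == pytest.approx(180.0)

    def test_signed_no_wraparound(self):
        # uint8 arithmetic would wrap; signed math must give -102
        assert lasers.laser_signal(_rgb(0, 255, 255), 0.2)[0, 0] == pytest.approx(-102.0)

    def test_zero_coeff_is_red_channel(self, rendered):
        img, _ = rendered
        assert np.array_equal(lasers.laser_signal(img, 0.0), img[..., 0].astype(float))

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError, match="three channels"):
            lasers.laser_signal(np.zeros((4, 4)), 0.2)

    def test_coeff_out_of_range(self):
        with pytest.raises(ValueError):
            lasers.laser_signal(_rgb(1, 2, 3), 1.5)


class TestTemplate:
    def test_expected_pairwise(self):
        t = lasers.LaserTemplate(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]]), buffer_px=0)
        # pairwise distances 3, 4, 5
        assert t.expected_pairwise_px == pytest.approx(4.0)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            lasers.LaserTemplate(np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]]))

    def test_yaml_roundtrip(self, tmp_path, template):
        path = tmp_path / "template.yaml"
        template.to_yaml(path)
        back = lasers.LaserTemplate.from_yaml(path)
        assert np.allclose(back.annotated_points, template.annotated_points)
        assert back.buffer_px == template.buffer_px


class TestBuildMask:
    def _brute_triangle_count(self, pts, shape):
        # membership oracle: rasterize by sampling every pixel center
        from matplotlib.path import Path as MplPath

        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        path = MplPath(pts)
        inside = path.contains_points(
            np.stack([xx.ravel(), yy.ravel()], axis=1), radius=0.5
        )
        return inside.reshape(h, w)

    def test_zero_buffer_is_filled_triangle(self):
        pts = np.array([[10.0, 5.0], [40.0, 8.0], [20.0, 45.0]])
        t = lasers.LaserTemplate(pts, buffer_px=0)
        mask = lasers.build_mask(t, (50, 50))
        oracle = self._brute_triangle_count(pts, (50, 50))
        # rasterization conventions may differ along edges by < a 1-px band
        assert abs(mask.sum() - oracle.sum()) <= np.ceil(3 * 50)
        # interior certainly included
        assert mask[20, 22]

    def test_buffer_strictly_contains_unbuffered(self):
        pts = np.array([[100.0, 100.0], [300.0, 120.0], [180.0, 350.0]])
        t0 = lasers.LaserTemplate(pts, buffer_px=0)
        t1 = lasers.LaserTemplate(pts, buffer_px=250)
        m0 = lasers.build_mask(t0, (500, 500))
        m1 = lasers.build_mask(t1, (500, 500))
        assert np.all(m1[m0])
        assert m1.sum() > m0.sum()

    def test_edge_point_clipped(self):
        pts = np.array([[0.0, 0.0], [49.0, 0.0], [25.0, 49.0]])
        t = lasers.LaserTemplate(pts, buffer_px=30)
        mask = lasers.build_mask(t, (50, 50))
        assert mask.shape == (50, 50)
        assert mask.any()

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 20.0]])
        t = lasers.LaserTemplate(pts, buffer_px=10)
        with pytest.raises(ValueError, match="degenerate triangle"):
            lasers.build_mask(t, (50, 50))


class TestDetection:
    def test_detects_three_points_near_truth(self, rendered, template):
        img, truth = rendered
        det = lasers.detect_laser_points(img, template)
        assert det.n_found == 3
        # each detected point within 3 px of a true laser point
        for p in det.points:
            d = np.linalg.norm(truth.true_laser_points - p, axis=1).min()
            assert d < 3.0

    def test_lasers_off_gives_zero(self, base_params, template):
        p = dataclasses.replace(base_params, lasers_on=False)
        img, _ = syn.render_image(p)
        det = lasers.detect_laser_points(img, template)
        assert det.n_found == 0
        assert det.flag == "unscaled"

    def test_overlapping_discs_merge(self):
        # two red dots closer than the enforced separation -> at most 2 peaks
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        yy, xx = np.mgrid[0:100, 0:100]
        for cx in (48, 53):
            bump = 250 * np.exp(-((xx - cx) ** 2 + (yy - 50) ** 2) / (2 * 3.5**2))
            img[..., 0] = np.maximum(img[..., 0], bump.astype(np.uint8))
        t = lasers.LaserTemplate(
            np.array([[30.0, 30.0], [70.0, 30.0], [50.0, 70.0]]), buffer_px=30
        )
        det = lasers.detect_laser_points(img, t)
        assert det.n_found <= 2

    def test_brightness_rescale_invariance(self, rendered, template):
        img, _ = rendered
        dimmed = (img.astype(float) * 0.5).astype(np.uint8)
        d1 = lasers.detect_laser_points(img, template)
        d2 = lasers.detect_laser_points(dimmed, template)
        assert d1.n_found == d2.n_found == 3
        assert d2.scale_px_per_cm == pytest.approx(d1.scale_px_per_cm, rel=0.01)

    def test_vignette_does_not_break_detection(self, base_params, template):
        p = dataclasses.replace(base_params, vignette_strength=0.8)
        img, _ = syn.render_image(p)
        det = lasers.detect_laser_points(img, template)
        assert det.n_found == 3


class TestComputeScale:
    def test_equilateral_400px(self):
        pts = _equilateral(400.0)
        det = _detection_from_points(pts)
        assert lasers.compute_scale(det, 40.0) == pytest.approx(10.0)

    def test_equilateral_864px(self):
        det = _detection_from_points(_equilateral(864.0))
        assert lasers.compute_scale(det, 40.0) == pytest.approx(21.6)

    def test_two_points(self):
        det = _detection_from_points(np.array([[0.0, 0.0], [880.0, 0.0]]))
        assert lasers.compute_scale(det, 40.0) == pytest.approx(22.0)

    def test_single_point_unscaled(self):
        det = _detection_from_points(np.array([[5.0, 5.0]]))
        assert det.scale_px_per_cm is None
        assert det.flag == "unscaled"
        with pytest.raises(ValueError, match="unscaled"):
            lasers.compute_scale(det, 40.0)


def _equilateral(side):
    h = side * np.sqrt(3) / 2
    return np.array([[0.0, 0.0], [side, 0.0], [side / 2, h]])


def _detection_from_points(pts):
    from itertools import combinations

    d = [float(np.hypot(*(a - b))) for a, b in combinations(pts, 2)]
    return lasers.LaserDetection(
        points=pts, pairwise_distances=d,
        scale_px_per_cm=lasers.compute_scale_from_distances(d, 40.0),
    )


class TestScaleRecovery:
    def test_median_relative_error_under_2pct(self, template):
        # light version of the survey-wide parameter recovery property
        rng = np.random.default_rng(5)
        errs = []
        for i in range(12):
            p = syn.SceneParams(
                image_width=560, image_height=840, focal_scale=10.8,
                altitude_m=float(rng.uniform(1, 4)),
                seafloor_class="ABCD"[i % 4],
                brightness_jitter=float(rng.uniform(0.7, 1.3)),
                rng_seed=int(rng.integers(1 << 31)),
            )
            img, truth = syn.render_image(p)
            det = lasers.detect_laser_points(img, template)
            assert det.n_found >= 2
            errs.append(
                abs(det.scale_px_per_cm - truth.true_scale_px_per_cm)
                / truth.true_scale_px_per_cm
            )
        assert np.median(errs) < 0.02


def test_detect_survey_csv(small_survey, tmp_path):
    import pandas as pd
    from PIL import Image

    truth = pd.read_csv(small_survey["truth"])
    pts = truth.iloc[0][["laser_x1", "laser_y1", "laser_x2", "laser_y2", "laser_x3", "laser_y3"]]
    template = lasers.LaserTemplate(np.array(pts, dtype=float).reshape(3, 2), buffer_px=60)
    df = lasers.detect_survey(small_survey["images"], template)
    assert len(df) == 16
    assert set(df.columns) == {"image_id", "n_found", "scale_px_per_cm", "flag"}
    ok = df[df["flag"] == "ok"]
    assert len(ok) == 16
    merged = ok.merge(truth, on="image_id")
    rel = (merged["scale_px_per_cm"] - merged["true_scale_px_per_cm"]).abs() / merged["true_scale_px_per_cm"]
    assert rel.median() < 0.02
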