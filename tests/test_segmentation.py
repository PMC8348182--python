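"""HSB conversion, colour-threshold lesion segmentation, eye ROI, vessels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pteryquant as pq
from pteryquant.segmentation import (
    HSBWindow,
    SegmentationError,
    otsu_threshold_from_counts,
)


def _uniform_image(rgb, shape=(40, 60)):
    px = np.zeros((*shape, 3), dtype=np.uint8)
    px[...] = rgb
    return pq.CalibratedImage(px)


@pytest.mark.parametrize(
    "rgb, hsb",
    [
        ((255, 0, 0), (0, 255, 255)),  # pure red
        ((0, 255, 0), (85, 255, 255)),  # pure green: 120 deg * 255/360
        ((128, 128, 128), (0, 0, 128)),  # grey: no saturation
        ((0, 0, 255), (170, 255, 255)),  # pure blue
    ],
)
def test_rgb_to_hsb_anchor_colors(rgb, hsb):
    h, s, b = pq.rgb_to_hsb(np.array([[rgb]], dtype=np.uint8))
    assert (int(h[0, 0]), int(s[0, 0]), int(b[0, 0])) == hsb


def _brute_force_otsu(counts):
    """Exhaustive between-class variance maximization; foreground = value >= t."""
    counts = np.asarray(counts, dtype=float)
    values = np.arange(counts.size, dtype=float)
    total = counts.sum()
    best_t, best_var = 0, -1.0
    for t in range(1, counts.size):
        w0 = counts[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (values[:t] * counts[:t]).sum() / w0
        mu1 = (values[t:] * counts[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


@given(st.lists(st.integers(0, 50), min_size=8, max_size=64).filter(lambda c: sum(c) > 0))
def test_otsu_matches_brute_force_variance_maximization(counts):
    counts = np.asarray(counts)
    if np.count_nonzero(counts) < 2:
        assert otsu_threshold_from_counts(counts) == 0
    else:
        t = otsu_threshold_from_counts(counts)
        t_ref = _brute_force_otsu(counts)
        # both must achieve the maximal between-class variance
        assert _variance_at(counts, t) == pytest.approx(_variance_at(counts, t_ref))


def _variance_at(counts, t):
    counts = np.asarray(counts, dtype=float)
    values = np.arange(counts.size, dtype=float)
    w0, w1 = counts[:t].sum(), counts[t:].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (values[:t] * counts[:t]).sum() / w0
    mu1 = (values[t:] * counts[t:]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


class TestLesion:
    def test_all_black_image_gives_empty_mask(self):
        img = _uniform_image((0, 0, 0))
        roi = np.ones(img.pixels.shape[:2], dtype=bool)
        with pytest.warns(UserWarning):
            mask = pq.segment_lesion(img, eye_roi=roi)
        assert not mask.any()

    def test_everything_in_gate_passes(self):
        # hue 85, S 255, B 200 everywhere inside the ROI
        px = np.zeros((30, 30, 3), dtype=np.uint8)
        px[...] = (0, 200, 0)
        img = pq.CalibratedImage(px)
        roi = np.zeros((30, 30), dtype=bool)
        roi[5:25, 5:25] = True
        mask = pq.segment_lesion(img, eye_roi=roi)
        assert np.array_equal(mask, roi)

    def test_iou_against_ground_truth(self, noisy_scene):
        img, truth = noisy_scene
        roi = pq.segment_eye_roi(img)
        mask = pq.segment_lesion(img, eye_roi=roi)
        inter = (mask & truth.lesion_mask).sum()
        union = (mask | truth.lesion_mask).sum()
        assert inter / union >= 0.90

    def test_mask_inside_eye_roi(self, noisy_scene):
        img, _ = noisy_scene
        roi = pq.segment_eye_roi(img)
        mask = pq.segment_lesion(img, eye_roi=roi)
        assert not (mask & ~roi).any()

    def test_raising_brightness_floor_only_shrinks_mask(self, noisy_scene):
        img, _ = noisy_scene
        roi = pq.segment_eye_roi(img)
        masks = [
            pq.segment_lesion(img, HSBWindow(b_min=b, brightness_method="fixed"), roi)
            for b in (48, 100, 180, 230)
        ]
        for lo, hi in zip(masks[1:], masks[:-1]):
            assert not (lo & ~hi).any()  # each stricter mask is a subset

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            HSBWindow(h_min=120, h_max=50)
        with pytest.raises(ValueError):
            HSBWindow(brightness_method="median")


class TestEyeRoi:
    def test_covers_true_ellipse(self, noisy_scene):
        img, _ = noisy_scene
        roi = pq.segment_eye_roi(img)
        from skimage import draw

        true = np.zeros_like(roi)
        rr, cc = draw.ellipse(120, 160, 75, 100, shape=roi.shape)
        true[rr, cc] = True
        assert (roi & true).sum() / true.sum() >= 0.95

    def test_noiseless_area_matches_analytic_ellipse(self):
        img, _ = pq.generate_eye_image(
            pq.EyeSceneParams(
                image_width=1024, image_height=768, eye_center=(384, 512),
                eye_radii=(300, 400), noise_sd=0, seed=1,
            )
        )
        roi = pq.segment_eye_roi(img)
        assert roi.sum() == pytest.approx(np.pi * 400 * 300, rel=0.02)

    def test_blank_frame_raises(self):
        with pytest.raises(SegmentationError):
            pq.segment_eye_roi(_uniform_image((7, 7, 7)))


class TestVessels:
    def test_vessel_free_eye_is_nearly_empty(self):
        img, truth = pq.generate_eye_image(
            pq.EyeSceneParams(vessel_total_length_px=0, noise_sd=10, seed=5)
        )
        roi = pq.segment_eye_roi(img)
        mask = pq.segment_vessels(img, roi, 50, lesion_mask=truth.lesion_mask)
        assert mask.sum() <= 0.01 * roi.sum()

    def test_known_tree_recovered_within_15pct(self, noisy_scene):
        img, truth = noisy_scene
        roi = pq.segment_eye_roi(img)
        mask = pq.segment_vessels(img, roi, 50, lesion_mask=truth.lesion_mask)
        assert mask.sum() == pytest.approx(truth.true_vessel_px, rel=0.15)

    def test_deterministic(self, noisy_scene):
        img, truth = noisy_scene
        roi = pq.segment_eye_roi(img)
        a = pq.segment_vessels(img, roi, 50, lesion_mask=truth.lesion_mask)
        b = pq.segment_vessels(img, roi, 50, lesion_mask=truth.lesion_mask)
        assert np.array_equal(a, b)
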