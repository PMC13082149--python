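"""Autofocus, fiduciary detection, classification and morphometrics."""

import numpy as np
import pytest
from scipy import ndimage

from wormdart.chip import ChannelGeometry, default_chip_map, channel_boxes
from wormdart.imaging import (
    ChannelCrop,
    FiduciaryError,
    FocusError,
    ZStack,
    best_focus_index,
    classify_channel,
    cross_template,
    detect_fiduciary,
    measure_body,
    motility_fraction,
    segment_worm,
    skeleton_length,
)
from wormdart.synthetic import render_motility_frames, render_well_image


def constant_geometry(width=98.0, height=40.0, length=3000.0):
    return ChannelGeometry("const", ((0.0, width, height), (length, width, height)), length)


class TestBestFocus:
    def test_single_slice(self):
        stack = ZStack(np.random.default_rng(0).random((1, 32, 32)))
        assert best_focus_index(stack) == 0

    def test_blurred_checkerboard_matches_oracle(self):
        rng = np.random.default_rng(1)
        sharp = np.indices((64, 64)).sum(axis=0) % 2 * 1.0
        data = np.stack([
            ndimage.gaussian_filter(sharp, 0.4 * abs(z - 9)) + rng.normal(0, 0.01, sharp.shape)
            for z in range(18)
        ])
        stack = ZStack(data)
        # independent oracle: per-slice variance of the discrete Laplacian
        oracle = int(np.argmax([
            ndimage.laplace(s.astype(float)).var() for s in data
        ]))
        assert best_focus_index(stack) == oracle == 9

    def test_uniform_stack_raises(self):
        with pytest.raises(FocusError):
            best_focus_index(ZStack(np.ones((5, 16, 16))))


class TestFiduciary:
    def test_exact_match_position(self):
        tmpl = cross_template(31, 5)
        img = np.ones((300, 400))
        img[80 : 80 + 31, 120 : 120 + 31] = tmpl
        x, y, score = detect_fiduciary(img, tmpl)
        assert (x, y) == (120, 80)
        assert score == pytest.approx(1.0)

    def test_noisy_within_one_pixel(self):
        tmpl = cross_template(31, 5)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = np.ones((200, 260))
            img[60 : 91, 100 : 131] = tmpl
            img = img + rng.normal(0, 0.05, img.shape)  # 5% of contrast
            x, y, _ = detect_fiduciary(img, tmpl, threshold=0.3)
            hits += abs(x - 100) <= 1 and abs(y - 60) <= 1
        assert hits == 20

    def test_blank_image_raises(self):
        with pytest.raises(FiduciaryError):
            detect_fiduciary(np.ones((100, 100)), cross_template(15, 3))

    def test_well_localization_via_chip_map(self):
        """Detected fiduciary + chip-map spacing pin every channel center."""
        chip = default_chip_map()
        px = 2.0
        img, truth = render_well_image(chip, fiduciary_xy_um=(400.0, 400.0),
                                       pixel_size=px)
        tmpl = cross_template(31, 5, contrast=0.6) * 0.85
        x, y, _ = detect_fiduciary(img, tmpl, threshold=0.5)
        boxes = channel_boxes(chip, (x * px, y * px), (100.0, 400.0))
        for box, cx_true in zip(boxes, truth["channel_centers_x_um"]):
            assert abs(box.center[0] - cx_true) <= px  # within 1 px


class TestClassification:
    def test_labels_against_generator_truth(self, fixture_suite):
        agree = total = 0
        for fx in fixture_suite:
            crop = ChannelCrop(fx["stack"], "c",
                               fx["truth"].axial_origin if fx["truth"] else 200.0,
                               fx["geometry"])
            label, _ = classify_channel(crop)
            want = fx["kind"]
            total += 1
            agree += label == want
        assert agree / total >= 0.95

    def test_blank_crop_is_none(self):
        rng = np.random.default_rng(0)
        stack = ZStack(np.full((5, 400, 120), 0.8) + rng.normal(0, 0.01, (5, 400, 120)))
        label, _ = classify_channel(ChannelCrop(stack, "c", 0.0, constant_geometry()))
        assert label == "none"


class TestSegmentation:
    def test_dice_against_truth(self, one_full_fixture):
        fx = one_full_fixture
        crop = ChannelCrop(fx["stack"], "c", fx["truth"].axial_origin, fx["geometry"])
        mask, flags = segment_worm(crop, fx["truth"].true_best_focus)
        assert not flags.get("segmentation_failed")
        inter = np.logical_and(mask, fx["truth"].mask).sum()
        dice = 2 * inter / (mask.sum() + fx["truth"].mask.sum())
        assert dice >= 0.90

    def test_blank_channel_sets_failed_flag(self):
        rng = np.random.default_rng(3)
        stack = ZStack(np.full((5, 300, 100), 0.8) + rng.normal(0, 0.005, (5, 300, 100)))
        mask, flags = segment_worm(ChannelCrop(stack, "c", 0.0, constant_geometry()), 2)
        assert flags.get("segmentation_failed")
        assert mask.sum() == 0

    def test_two_blobs_keeps_largest_with_flag(self):
        img = np.full((300, 160), 0.8)
        img[40:140, 40:100] = 0.3   # large blob
        img[200:260, 60:110] = 0.3  # smaller blob
        stack = ZStack(np.stack([img] * 5))
        mask, flags = segment_worm(ChannelCrop(stack, "c", 0.0, constant_geometry()), 2)
        assert flags.get("multi_component")
        rows = np.where(mask.any(axis=1))[0]
        assert rows[0] >= 38 and rows[-1] <= 141  # only the large blob kept


class TestMeasureBody:
    def test_rectangle_closed_form(self):
        px = 0.425
        mask = np.zeros((1200, 100), dtype=bool)
        mask[100:1100, 25:75] = True  # 1000 x 50 px
        geo = constant_geometry(height=40.0)
        length, area, volume = measure_body(mask, geo, 0.0, px)
        assert area == pytest.approx(1000 * 50 * px**2)          # 9,031.25 um2
        assert volume == pytest.approx(area * 40.0)              # 361,250 um3
        assert length == pytest.approx(1000 * px, abs=2 * px)    # 425 um

    def test_volume_equals_per_pixel_oracle(self, one_full_fixture):
        from wormdart.chip import height_profile_at
        fx = one_full_fixture
        truth = fx["truth"]
        px = fx["stack"].pixel_size
        _, _, volume = measure_body(truth.mask, fx["geometry"], truth.axial_origin, px)
        # brute force: loop over every mask pixel
        oracle = 0.0
        for (r, c) in np.argwhere(truth.mask):
            s = truth.axial_origin + (r + 0.5) * px
            _, h = height_profile_at(fx["geometry"], s)
            oracle += px**2 * h
        assert volume == pytest.approx(oracle, rel=1e-12)

    def test_semicircular_tube_arc_length(self):
        px = 0.425
        R, r = 200.0 / px, 15.0 / px
        size = int(2 * (R + r) + 10)
        yy, xx = np.mgrid[0:size, 0:size]
        cy = cx = size // 2
        d = np.hypot(yy - cy, xx - cx)
        mask = (np.abs(d - R) <= r) & (yy <= cy)
        length = skeleton_length(mask, px)
        assert length == pytest.approx(np.pi * 200.0, rel=0.03)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            measure_body(np.zeros((10, 10), dtype=bool), constant_geometry(), 0.0, 0.425)

    def test_mask_outside_channel_raises(self):
        mask = np.zeros((400, 50), dtype=bool)
        mask[350:, 10:40] = True
        geo = constant_geometry(length=100.0)  # channel shorter than the crop
        with pytest.raises(ValueError):
            measure_body(mask, geo, 0.0, 0.425)


class TestMotility:
    def test_identical_frames_zero(self):
        frames, _ = render_motility_frames(n_blobs=6, n_moving=0, seed=2)
        assert motility_fraction(frames) == 0.0

    def test_four_of_ten_moving(self):
        frames, moving = render_motility_frames(n_blobs=10, n_moving=4,
                                                shift_px=6.0, seed=5)
        assert motility_fraction(frames, min_displacement_px=5.0) == pytest.approx(0.4)

    def test_empty_frames_raise(self):
        blank = [np.full((100, 100), 0.8)] * 2
        with pytest.raises(ValueError):
            motility_fraction(blank)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            motility_fraction([np.zeros((10, 10))])
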