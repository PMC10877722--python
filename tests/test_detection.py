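"""Tests of ROI cropping, artifact masking, preprocessing and circle detection."""

import numpy as np
import pytest

from cavitrack import (
    DetectionParams,
    GroundTruthBubble,
    ImageSeries,
    RegionOfInterest,
    SyntheticConfig,
    build_artifact_mask,
    crop_to_roi,
    detect_circles,
    detect_series,
    preprocess_frame,
    render_trial,
)


def _series(frames):
    return ImageSeries(frames=np.asarray(frames, dtype=np.uint8),
                       temperature=40.0, frame_rate=1e5)


def _disc_frame(shape=(96, 128), center=(32, 32), radius=5.0, contrast=60.0, bg=150.0):
    cfg = SyntheticConfig(
        image_size=shape, noise_sd=0.0, n_artifacts=0,
        bubble_contrast=contrast, background_level=bg, frames_per_trial=1,
    )
    b = GroundTruthBubble(center=center, radius=radius, first_frame=0, last_frame=0)
    return render_trial(40.0, [b], cfg, np.random.default_rng(0)).frames[0]


class TestCrop:
    def test_full_frame_identity(self):
        s = _series(np.random.default_rng(0).integers(0, 255, (5, 40, 60)))
        out = crop_to_roi(s, RegionOfInterest.full_frame(s.frames.shape))
        assert np.array_equal(out.frames, s.frames)
        assert out.temperature == s.temperature

    def test_crop_shape(self):
        s = _series(np.zeros((3, 128, 256)))
        out = crop_to_roi(s, RegionOfInterest(10, 10, 100, 50))
        assert out.frames.shape == (3, 50, 100)

    def test_crop_then_full_roi_idempotent(self):
        s = _series(np.random.default_rng(1).integers(0, 255, (4, 64, 64)))
        once = crop_to_roi(s, RegionOfInterest(5, 6, 30, 20))
        twice = crop_to_roi(once, RegionOfInterest.full_frame(once.frames.shape))
        assert np.array_equal(once.frames, twice.frames)

    def test_out_of_bounds_rejected(self):
        s = _series(np.zeros((3, 64, 64)))
        with pytest.raises(ValueError):
            crop_to_roi(s, RegionOfInterest(60, 0, 10, 10))

    def test_invalid_roi_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(0, 0, 0, 10)


class TestArtifactMask:
    def test_static_blob_masked_exactly(self):
        cfg = SyntheticConfig(image_size=(64, 96), noise_sd=0.0, n_artifacts=0,
                              frames_per_trial=10)
        artifacts = [((48.0, 32.0), 6.0)]
        series = render_trial(40.0, [], cfg, np.random.default_rng(0), artifacts=artifacts)
        mask = build_artifact_mask(series, 0.98)
        yy, xx = np.mgrid[0:64, 0:96]
        core = (xx - 48) ** 2 + (yy - 32) ** 2 <= 5.0**2  # fully-covered interior
        outside = (xx - 48) ** 2 + (yy - 32) ** 2 > 7.5**2
        assert mask[core].all()
        assert not mask[outside].any()

    def test_uniform_series_has_empty_mask(self):
        s = _series(np.full((10, 32, 32), 120))
        assert not build_artifact_mask(s, 0.999).any()

    def test_deterministic(self):
        frames = np.random.default_rng(2).integers(0, 255, (8, 32, 32))
        s = _series(frames)
        assert np.array_equal(build_artifact_mask(s, 0.9), build_artifact_mask(s, 0.9))

    def test_requires_three_frames(self):
        s = _series(np.zeros((2, 32, 32)))
        with pytest.raises(ValueError):
            build_artifact_mask(s)


class TestPreprocess:
    def test_identity_with_empty_mask_no_smoothing(self):
        params = DetectionParams(smoothing_sigma=0.0)
        frame = np.random.default_rng(3).integers(0, 255, (32, 32)).astype(float)
        out = preprocess_frame(frame, np.zeros_like(frame, dtype=bool), params)
        assert np.array_equal(out, frame)

    def test_artifact_pixels_flattened_to_median(self):
        frame = np.full((40, 40), 100.0)
        frame[10:16, 10:16] = 220.0
        mask = frame > 200
        out = preprocess_frame(frame, mask, DetectionParams(smoothing_sigma=0.0))
        assert np.all(np.abs(out[10:16, 10:16] - np.median(frame)) <= 2.0)

    def test_constant_frame_stays_constant(self):
        frame = np.full((32, 32), 77.0)
        out = preprocess_frame(frame, np.zeros_like(frame, dtype=bool), DetectionParams())
        assert np.allclose(out, 77.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((4, 4)), np.zeros((5, 5), dtype=bool), DetectionParams())


class TestDetectCircles:
    def test_blank_frame_gives_nothing(self):
        assert detect_circles(np.full((64, 64), 100.0), DetectionParams()) == []

    def test_single_disc_round_trip(self):
        frame = _disc_frame(center=(32, 32), radius=5.0)
        dets = detect_circles(frame, DetectionParams())
        assert len(dets) == 1
        (d,) = dets
        assert abs(d.center[0] - 32) <= 1 and abs(d.center[1] - 32) <= 1
        assert abs(d.radius - 5.0) <= 1

    def test_two_separated_discs(self):
        cfg = SyntheticConfig(image_size=(96, 128), noise_sd=0.0, n_artifacts=0,
                              frames_per_trial=1)
        bubbles = [
            GroundTruthBubble(center=(30.0, 30.0), radius=5.0, first_frame=0, last_frame=0),
            GroundTruthBubble(center=(95.0, 60.0), radius=7.0, first_frame=0, last_frame=0),
        ]
        frame = render_trial(40.0, bubbles, cfg, np.random.default_rng(0)).frames[0]
        dets = detect_circles(frame, DetectionParams())
        assert len(dets) == 2
        centres = sorted(d.center for d in dets)
        assert np.hypot(centres[0][0] - 30, centres[0][1] - 30) <= 2
        assert np.hypot(centres[1][0] - 95, centres[1][1] - 60) <= 2

    def test_count_non_increasing_in_sensitivity(self):
        frame = _disc_frame(center=(40, 40), radius=6.0)
        counts = [
            len(detect_circles(frame, DetectionParams(sensitivity=s)))
            for s in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_small_frame_rejected(self):
        with pytest.raises(ValueError):
            detect_circles(np.zeros((10, 10)), DetectionParams(radius_range=(3, 8)))

    def test_precision_recall_one_on_clean_discs(self):
        # noise-free, well-separated, in-range discs: every bubble found,
        # nothing else found (matching tolerance 2 px centre / 2 px radius)
        cfg = SyntheticConfig(image_size=(128, 192), noise_sd=0.0, n_artifacts=0,
                              frames_per_trial=1)
        truth = [
            GroundTruthBubble(center=(30.0, 30.0), radius=3.5, first_frame=0, last_frame=0),
            GroundTruthBubble(center=(100.0, 40.0), radius=5.0, first_frame=0, last_frame=0),
            GroundTruthBubble(center=(60.0, 95.0), radius=8.0, first_frame=0, last_frame=0),
            GroundTruthBubble(center=(150.0, 100.0), radius=6.2, first_frame=0, last_frame=0),
        ]
        frame = render_trial(40.0, truth, cfg, np.random.default_rng(0)).frames[0]
        dets = detect_circles(frame, DetectionParams())
        assert len(dets) == len(truth)
        for b in truth:
            match = [
                d for d in dets
                if np.hypot(d.center[0] - b.center[0], d.center[1] - b.center[1]) <= 2
                and abs(d.radius - b.radius) <= 2
            ]
            assert len(match) == 1


class TestArtifactRejection:
    def test_static_artifact_changes_no_detection(self):
        cfg = SyntheticConfig(image_size=(96, 128), noise_sd=0.0, n_artifacts=0,
                              frames_per_trial=10)
        bubbles = [
            GroundTruthBubble(center=(40.0, 40.0), radius=5.0, first_frame=0, last_frame=9)
        ]
        rng = np.random.default_rng(0)
        plain = render_trial(40.0, bubbles, cfg, rng, artifacts=[])
        with_art = render_trial(
            40.0, bubbles, cfg, rng, artifacts=[((100.0, 70.0), 7.0)]
        )
        d_plain = detect_series(plain)
        d_art = detect_series(with_art)
        for a, b in zip(d_plain, d_art):
            assert [(x.center, x.radius) for x in a] == [(x.center, x.radius) for x in b]

    def test_coordinates_round_trip_through_roi(self):
        cfg = SyntheticConfig(image_size=(96, 128), noise_sd=0.0, n_artifacts=0,
                              frames_per_trial=5)
        bubbles = [
            GroundTruthBubble(center=(60.0, 50.0), radius=5.0, first_frame=0, last_frame=4)
        ]
        series = render_trial(40.0, bubbles, cfg, np.random.default_rng(0))
        roi = RegionOfInterest(20, 15, 100, 70)
        per_frame = detect_series(series, roi=roi)
        for dets in per_frame:
            for d in dets:
                x, y = d.center[0] + roi.x0, d.center[1] + roi.y0
                assert 0 <= x < 128 and 0 <= y < 96
                assert np.hypot(x - 60, y - 50) <= 2
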