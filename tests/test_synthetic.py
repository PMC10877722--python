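"""Tests of the synthetic trial generator: count model, rendering, ground truth."""

import math

import numpy as np
import pytest

from cavitrack import (
    GroundTruthBubble,
    SyntheticConfig,
    TrialRecord,
    generate_dataset,
    mean_count_curve,
    render_trial,
    sample_trial_count,
)
from cavitrack.synthetic import PlacementError, sample_artifacts


class TestMeanCountCurve:
    @pytest.mark.parametrize(
        "temperature,expected",
        [(20.0, 0.12), (30.0, 0.71), (40.0, 6.4), (50.0, 28.0), (60.0, 97.5)],
    )
    def test_exact_at_anchors(self, temperature, expected):
        assert mean_count_curve(temperature) == pytest.approx(expected, rel=1e-12)

    def test_log_linear_midpoint(self):
        # geometric mean of the 20 and 30 degree anchors
        expected = math.exp((math.log(0.12) + math.log(0.71)) / 2.0)
        assert mean_count_curve(25.0) == pytest.approx(expected, rel=1e-12)
        assert mean_count_curve(25.0) == pytest.approx(0.2919, abs=1e-4)

    def test_monotone_increasing_over_span(self):
        temps = np.linspace(20, 60, 81)
        values = [mean_count_curve(t) for t in temps]
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("temperature", [19.9, 60.1, -5.0])
    def test_no_extrapolation(self, temperature):
        with pytest.raises(ValueError):
            mean_count_curve(temperature)

    def test_rejects_nonpositive_anchor_counts(self):
        with pytest.raises(ValueError):
            mean_count_curve(25.0, anchors=[(20.0, 0.0), (30.0, 1.0)])


class TestSampleTrialCount:
    def test_monte_carlo_mean_matches_curve(self):
        # 10,000 draws at 40 degC, theta=5: mean within 3 standard errors of 6.4
        rng = np.random.default_rng(7)
        draws = np.array([sample_trial_count(40.0, 5.0, rng) for _ in range(10_000)])
        mu = 6.4
        se = math.sqrt((mu + mu**2 / 5.0) / len(draws))
        assert abs(draws.mean() - mu) < 3 * se

    def test_determinism(self):
        a = [sample_trial_count(50.0, 5.0, np.random.default_rng(3)) for _ in range(20)]
        b = [sample_trial_count(50.0, 5.0, np.random.default_rng(3)) for _ in range(20)]
        assert a == b

    def test_vanishing_mean_gives_zero(self):
        # as the anchor count approaches zero the draw degenerates to 0
        rng = np.random.default_rng(0)
        anchors = [(20.0, 1e-12), (30.0, 1e-12)]
        assert all(
            sample_trial_count(25.0, 5.0, rng, anchors) == 0 for _ in range(50)
        )

    def test_invalid_dispersion(self):
        with pytest.raises(ValueError):
            sample_trial_count(40.0, 0.0, np.random.default_rng(0))

    def test_calibration_at_all_anchors(self):
        # >= 2000 simulated trials per anchor temperature: empirical mean
        # within 3 standard errors of the calibration-table value
        rng = np.random.default_rng(11)
        n = 2000
        for temp, mu in SyntheticConfig().mean_anchor_table:
            draws = np.array([sample_trial_count(temp, 5.0, rng) for _ in range(n)])
            se = math.sqrt((mu + mu**2 / 5.0) / n)
            assert abs(draws.mean() - mu) < 3 * se, f"anchor {temp}"


class TestRenderTrial:
    def test_default_frame_count(self, rng):
        cfg = SyntheticConfig()
        series = render_trial(40.0, [], cfg, rng)
        assert series.n_frames == 50
        assert series.frames.shape == (50, 128, 256)
        assert series.frames.dtype == np.uint8

    def test_series_duration_is_half_millisecond(self, rng):
        series = render_trial(40.0, [], SyntheticConfig(), rng)
        assert series.duration_s == pytest.approx(0.5e-3)

    def test_zero_bubbles_noise_free_is_flat_plus_artifacts(self):
        cfg = SyntheticConfig(noise_sd=0.0, n_artifacts=0, frames_per_trial=5)
        series = render_trial(40.0, [], cfg, np.random.default_rng(0))
        assert np.all(series.frames == int(cfg.background_level))

    def test_bubble_darker_exactly_during_lifetime(self):
        cfg = SyntheticConfig(noise_sd=0.0, n_artifacts=0)
        bubble = GroundTruthBubble(center=(40.0, 40.0), radius=5.0, first_frame=10, last_frame=20)
        series = render_trial(40.0, [bubble], cfg, np.random.default_rng(0))
        centre_pixel = series.frames[:, 40, 40].astype(float)
        bg = cfg.background_level
        dark = centre_pixel < bg
        expected = np.zeros(cfg.frames_per_trial, dtype=bool)
        expected[10:21] = True
        assert np.array_equal(dark, expected)

    def test_bubble_disc_darker_artifact_brighter_than_background(self):
        cfg = SyntheticConfig(noise_sd=0.0, n_artifacts=0)
        bubble = GroundTruthBubble(center=(60.0, 60.0), radius=6.0, first_frame=0, last_frame=4)
        artifacts = [((200.0, 30.0), 7.0)]
        series = render_trial(40.0, [bubble], cfg, np.random.default_rng(0), artifacts=artifacts)
        frame = series.frames[0].astype(float)
        yy, xx = np.mgrid[0:128, 0:256]
        disc = (xx - 60) ** 2 + (yy - 60) ** 2 <= 5.0**2
        blob = (xx - 200) ** 2 + (yy - 30) ** 2 <= 6.0**2
        assert frame[disc].mean() < cfg.background_level
        assert frame[blob].mean() > cfg.background_level

    def test_artifacts_static_across_frames(self, rng):
        cfg = SyntheticConfig(noise_sd=0.0)
        series = render_trial(40.0, [], cfg, rng)
        assert all(np.array_equal(series.frames[0], f) for f in series.frames[1:])

    def test_out_of_frame_bubble_rejected(self, rng):
        cfg = SyntheticConfig()
        bad = GroundTruthBubble(center=(2.0, 2.0), radius=5.0, first_frame=0, last_frame=3)
        with pytest.raises(PlacementError):
            render_trial(40.0, [bad], cfg, rng)


class TestGenerateDataset:
    def test_default_design_is_45_trials(self):
        trials = generate_dataset(SyntheticConfig(), np.random.default_rng(0))
        assert len(trials) == 45
        temps = [t.record.temperature for t in trials]
        assert sorted(set(temps)) == [20, 25, 30, 35, 40, 45, 50, 55, 60]
        assert all(temps.count(T) == 5 for T in set(temps))

    def test_single_trial_config(self):
        cfg = SyntheticConfig(temperatures=(20.0,), trials_per_temperature=1)
        trials = generate_dataset(cfg, np.random.default_rng(0))
        assert len(trials) == 1

    def test_rendered_default_frame_total(self, small_config):
        # scaled-down render to keep the test fast; the frame *arithmetic*
        # (trials x frames_per_trial) is what matters
        trials = generate_dataset(small_config, np.random.default_rng(1), render=True)
        total = sum(t.series.n_frames for t in trials)
        assert total == len(trials) * small_config.frames_per_trial

    def test_determinism_byte_identical(self, small_config):
        a = generate_dataset(small_config, np.random.default_rng(5), render=True)
        b = generate_dataset(small_config, np.random.default_rng(5), render=True)
        assert [t.record for t in a] == [t.record for t in b]
        assert [t.bubbles for t in a] == [t.bubbles for t in b]
        for ta, tb in zip(a, b):
            assert ta.series.frames.tobytes() == tb.series.frames.tobytes()

    def test_ground_truth_conservation(self, small_config):
        trials = generate_dataset(small_config, np.random.default_rng(2), render=True)
        for t in trials:
            assert len(t.bubbles) == t.record.n_bubbles

    def test_rendered_bubbles_respect_config_ranges(self, small_config):
        trials = generate_dataset(small_config, np.random.default_rng(3), render=True)
        rmin, rmax = small_config.bubble_radius_range
        for t in trials:
            for b in t.bubbles:
                assert rmin <= b.radius <= rmax
                assert 0 <= b.first_frame <= b.last_frame < small_config.frames_per_trial

    def test_concurrent_bubbles_never_overlap(self):
        cfg = SyntheticConfig(temperatures=(60.0,), trials_per_temperature=2)
        trials = generate_dataset(cfg, np.random.default_rng(4), render=True)
        for t in trials:
            for i, a in enumerate(t.bubbles):
                for b in t.bubbles[i + 1 :]:
                    if a.first_frame <= b.last_frame and b.first_frame <= a.last_frame:
                        d = math.hypot(
                            a.center[0] - b.center[0], a.center[1] - b.center[1]
                        )
                        assert d > a.radius + b.radius


def test_trial_record_validation():
    with pytest.raises(ValueError):
        TrialRecord("x", 20.0, -1, "synthetic")
    with pytest.raises(ValueError):
        TrialRecord("x", 20.0, 3, "guessed")


def test_sample_artifacts_respects_count(rng):
    cfg = SyntheticConfig(n_artifacts=4)
    assert len(sample_artifacts(cfg, rng)) == 4
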