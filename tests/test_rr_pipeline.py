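import numpy as np
import pytest

from thermalvitals.errors import (ConfigurationError, DegenerateInputError,
                                  FusionDegenerateWarning, PipelineError,
                                  TrackingLossError)
from thermalvitals.io_core import RectROI, ThermalVideo
from thermalvitals.rr_pipeline import (LagPosterior, ROITrack, RrConfig,
                                       estimator_ac, estimator_amdf,
                                       estimator_map, estimate_rr_series,
                                       fuse_bayes, interval_posterior,
                                       rom_waveform, select_interval,
                                       to_posterior, track_roi)
from thermalvitals.signals import butter_bandpass
from thermalvitals.synthgen import SceneConfig, generate_scene

HAND_WINDOW = np.array([1.0, 2.0, 3.0, 2.0, 1.0])   # w[-2..2]


class TestEstimators:
    def test_hand_case_autocorrelation(self):
        # (1/2)(w0*w-2 + w1*w-1 + w2*w0) = (3 + 4 + 3)/2
        assert estimator_ac(HAND_WINDOW, 2) == pytest.approx(5.0)

    def test_hand_case_amdf(self):
        # mean abs diff = (|3-1| + |2-2| + |1-3|)/2 = 2 -> reciprocal 0.5
        assert estimator_amdf(HAND_WINDOW, 2) == pytest.approx(0.5)

    def test_hand_case_map(self):
        # max(3+1, 2+2, 1+3) = 4
        assert estimator_map(HAND_WINDOW, 2) == pytest.approx(4.0)

    def test_all_zero_window_autocorrelation_zero(self):
        assert estimator_ac(np.zeros(11), 4) == 0.0

    def test_cosine_period_maximal_among_lags(self):
        period = 20
        v = np.arange(-3 * period, 3 * period + 1)
        w = np.cos(2 * np.pi * v / period)
        lags = range(10, 3 * period // 2)
        vals = [estimator_ac(w, m) for m in lags]
        assert list(lags)[int(np.argmax(vals))] == period

    def test_amdf_exact_period_hits_epsilon_cap(self):
        period = 8
        v = np.arange(-period, period + 1)
        w = np.sin(2 * np.pi * v / period)
        assert estimator_amdf(w, period) >= 1e11

    def test_amdf_inverse_homogeneity(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=21)
        assert estimator_amdf(2 * w, 5) == pytest.approx(
            estimator_amdf(w, 5) / 2, rel=1e-9)

    def test_map_two_impulses(self):
        w = np.zeros(21)
        w[10] = 1.0       # center, v=0
        w[10 - 6] = 1.0   # v=-6
        assert estimator_map(w, 6) == pytest.approx(2.0)

    def test_map_monotone_window_rightmost_pairing(self):
        w = np.linspace(0.0, 2.0, 15)   # strictly increasing
        m = 4
        c = w.size // 2
        # brute force over v: pairing (w[v], w[v-m]) maximal at v=m
        vals = [w[c + v] + w[c + v - m] for v in range(m + 1)]
        assert estimator_map(w, m) == pytest.approx(vals[-1])
        assert int(np.argmax(vals)) == m

    def test_insufficient_span_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimator_ac(np.ones(5), 3)

    def test_matches_literal_loop_oracle(self):
        # literal transliterations of the three definitions
        def ac_loop(w, m, c):
            return sum(w[c + v] * w[c + v - m] for v in range(m + 1)) / m

        def amdf_loop(w, m, c):
            s = sum(abs(w[c + v] - w[c + v - m]) for v in range(m + 1)) / m
            return 1.0 / (s + 1e-12)

        def map_loop(w, m, c):
            return max(w[c + v] + w[c + v - m] for v in range(m + 1))

        rng = np.random.default_rng(123)
        for _ in range(100):
            m = int(rng.integers(2, 30))
            w = rng.normal(size=2 * m + 1 + 2 * int(rng.integers(0, 5)))
            c = w.size // 2
            assert estimator_ac(w, m) == pytest.approx(
                ac_loop(w, m, c), abs=1e-10)
            assert estimator_amdf(w, m) == pytest.approx(
                amdf_loop(w, m, c), rel=1e-10)
            assert estimator_map(w, m) == pytest.approx(
                map_loop(w, m, c), abs=1e-10)


class TestPosteriorAndFusion:
    def test_uniform_from_equal_values(self):
        p = to_posterior(np.array([1.0, 1.0, 1.0]), np.array([2, 3, 4]))
        np.testing.assert_allclose(p.probs, 1 / 3)

    def test_shift_normalize_arithmetic(self):
        p = to_posterior(np.array([0.0, 2.0, 6.0]), np.array([2, 3, 4]))
        np.testing.assert_allclose(p.probs, [0.0, 0.25, 0.75])

    def test_normalization_for_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.normal(size=17)
            p = to_posterior(vals, np.arange(17))
            assert p.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(DegenerateInputError):
            to_posterior(np.array([1.0, np.nan]), np.array([2, 3]))

    def test_fuse_uniform_ties_to_smallest_lag(self):
        lags = np.array([5, 6, 7])
        u = LagPosterior(lags, np.full(3, 1 / 3))
        fused, m_hat = fuse_bayes(u, u, u)
        np.testing.assert_allclose(fused.probs, 1 / 3)
        assert m_hat == 5

    def test_uniform_is_identity_element(self):
        lags = np.array([5, 6, 7])
        u = LagPosterior(lags, np.full(3, 1 / 3))
        peaked = LagPosterior(lags, np.array([0.1, 0.8, 0.1]))
        fused, m_hat = fuse_bayes(u, peaked, u)
        np.testing.assert_allclose(fused.probs, peaked.probs)
        assert m_hat == 6

    def test_product_arithmetic(self):
        lags = np.array([5, 6, 7])
        pa = LagPosterior(lags, np.array([0.5, 0.5, 0.0]))
        pb = LagPosterior(lags, np.array([0.0, 0.5, 0.5]))
        pc = LagPosterior(lags, np.full(3, 1 / 3))
        fused, m_hat = fuse_bayes(pa, pb, pc)
        np.testing.assert_allclose(fused.probs, [0.0, 1.0, 0.0])
        assert m_hat == 6

    def test_zero_product_falls_back_with_warning(self):
        lags = np.array([5, 6])
        pa = LagPosterior(lags, np.array([1.0, 0.0]))
        pb = LagPosterior(lags, np.array([0.0, 1.0]))
        pc = LagPosterior(lags, np.array([1.0, 0.0]))
        with pytest.warns(FusionDegenerateWarning):
            fused, m_hat = fuse_bayes(pa, pb, pc)
        assert m_hat == 5
        np.testing.assert_allclose(fused.probs, pa.probs)

    def test_mismatched_grids_rejected(self):
        pa = LagPosterior(np.array([5, 6]), np.array([0.5, 0.5]))
        pb = LagPosterior(np.array([6, 7]), np.array([0.5, 0.5]))
        with pytest.raises(ConfigurationError):
            fuse_bayes(pa, pb, pa)

    def test_select_interval_prefers_fundamental_peak(self):
        lags = np.arange(50, 200)
        probs = np.full(lags.size, 1e-6)
        probs[lags == 80] = 0.40
        probs[lags == 160] = 0.45    # subharmonic slightly stronger
        probs /= probs.sum()
        assert select_interval(LagPosterior(lags, probs)) == 80

    def test_select_interval_unimodal_is_argmax(self):
        lags = np.arange(50, 100)
        probs = np.exp(-0.5 * ((lags - 70) / 3.0) ** 2)
        probs /= probs.sum()
        assert select_interval(LagPosterior(lags, probs)) == 70


def static_video(frame, n=40, fps=50.0):
    return ThermalVideo(np.repeat(frame[None], n, axis=0), fps)


class TestRoiTracking:
    def test_static_video_zero_offsets(self):
        rng = np.random.default_rng(2)
        frame = 22 + 12 * rng.random((40, 40))
        track = track_roi(static_video(frame), RectROI(10, 10, 12, 12))
        np.testing.assert_array_equal(track.offsets, 0)

    def test_integer_shift_recovered_exactly(self):
        rng = np.random.default_rng(3)
        frame = 22 + 12 * rng.random((60, 60))
        frames = np.repeat(frame[None], 30, axis=0).copy()
        frames[10:] = np.roll(frames[10:], (3, -2), axis=(1, 2))
        video = ThermalVideo(frames, 50.0)
        track = track_roi(video, RectROI(20, 20, 14, 14))
        np.testing.assert_array_equal(track.offsets[:10], 0)
        np.testing.assert_array_equal(track.offsets[10:],
                                      np.tile([3, -2], (20, 1)))

    def test_uniform_template_raises(self):
        frame = np.full((40, 40), 25.0)
        with pytest.raises(TrackingLossError):
            track_roi(static_video(frame), RectROI(10, 10, 12, 12))


class TestRomWaveform:
    def test_uniform_rom_constant_trace(self):
        frame = np.full((30, 30), 30.0)
        video = static_video(frame, n=20)
        track = ROITrack(RectROI(5, 5, 12, 12), np.zeros((20, 2), dtype=int))
        trace = rom_waveform(video, track)
        np.testing.assert_allclose(trace.values, 30.0)

    def test_checkerboard_mean_exact(self):
        frame = np.indices((20, 20)).sum(axis=0) % 2
        frame = np.where(frame == 0, 20.0, 40.0)
        video = static_video(frame, n=5)
        track = ROITrack(RectROI(2, 2, 8, 8),
                         np.zeros((5, 2), dtype=int))
        trace = rom_waveform(video, track, RrConfig(rom_frac=1.0))
        np.testing.assert_allclose(trace.values, 30.0)

    def test_generator_modulation_peak_to_peak(self):
        cfg = SceneConfig(rows=64, cols=64, duration=8.0, noise_sd_k=0.0,
                          bcg_amp_px=0.0, nostril_amp_k=0.5, seed=4)
        video, _, _ = generate_scene(cfg)
        nr = cfg.resolved().nostril_roi
        track = ROITrack(nr, np.zeros((video.n_frames, 2), dtype=int))
        trace = rom_waveform(video, track, RrConfig(rom_frac=1.0))
        assert np.ptp(trace.values) == pytest.approx(1.0, rel=0.05)


@pytest.fixture(scope="module")
def rr_scene():
    cfg = SceneConfig(rows=64, cols=64, duration=40.0, rr_bpm=15.0, seed=5)
    video, _, _ = generate_scene(cfg)
    nr = cfg.resolved().nostril_roi
    roi = RectROI(nr.row0 - 4, nr.col0 - 4, nr.height + 8, nr.width + 8)
    return video, roi


class TestEstimateRrSeries:
    def test_recovers_rate_and_lag(self, rr_scene):
        video, roi = rr_scene
        series = estimate_rr_series(video, roi)
        assert len(series) >= 10
        assert np.median(np.abs(series.rates - 15.0)) <= 1.0
        # 15 breaths/min at 50 fps is a 200-sample interval
        m_hats = 60.0 * 50.0 / series.rates
        assert np.median(np.abs(m_hats - 200.0)) <= 5

    def test_posterior_normalized_at_every_center(self, rr_scene):
        video, roi = rr_scene
        cfg = RrConfig()
        m_min, m_max = cfg.lag_range(video.fps)
        track = track_roi(video, roi)
        filt = butter_bandpass(rom_waveform(video, track, cfg),
                               *cfg.band).values
        for center in range(m_max, filt.size - m_max, 200):
            posterior, _ = interval_posterior(filt, center, m_min, m_max)
            assert posterior.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_short_video_degenerate(self):
        cfg = SceneConfig(rows=48, cols=48, duration=10.0, seed=6)
        video, _, _ = generate_scene(cfg)   # 500 frames < 2*500+1
        nr = cfg.resolved().nostril_roi
        with pytest.raises(DegenerateInputError):
            estimate_rr_series(video, nr)

    def test_lag_range_derivation(self):
        m_min, m_max = RrConfig().lag_range(50.0)
        assert m_min == int(np.ceil(50 / 0.85)) == 59
        assert m_max == int(np.floor(50 / 0.1)) == 500
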