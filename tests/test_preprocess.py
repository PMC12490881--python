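"""Filtering, smoothing, resampling, and the median-deviation outlier rule."""

import numpy as np
import pytest

from semgdec.preprocess import (
    OutlierFilterConfig,
    PreprocessConfig,
    filter_semg,
    reject_outlier_samples,
    resample_kinematics,
    semg_filter_response,
    smooth_kinematics,
    zscore,
)
from semgdec.session_io import GestureAnnotation, GestureEvent, KinematicTrack, SemgRecording

FS = 4000.0


def _rec(x):
    return SemgRecording(samples=x, fs=FS)


def _tone(freq, seconds=4.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _steady_rms(x):
    """RMS of the middle half (discard filter transients)."""
    n = len(x)
    return np.sqrt(np.mean(x[n // 4 : 3 * n // 4] ** 2))


class TestFilterSemg:
    def test_constant_offset_removed(self):
        x = np.full((8000, 16), 123.4)
        out = filter_semg(_rec(x), PreprocessConfig(zscore=False))
        assert np.abs(out.samples[2000:-2000]).max() < 1e-6

    @pytest.mark.parametrize("freq", [50.0, 100.0])
    def test_line_tones_suppressed_to_below_one_percent(self, freq):
        x = np.tile(_tone(freq)[:, None], (1, 16))
        out = filter_semg(_rec(x), PreprocessConfig(zscore=False))
        assert _steady_rms(out.samples[:, 0]) <= 0.01 * _steady_rms(x[:, 0])

    def test_150hz_tone_passes_near_unity(self):
        x = np.tile(_tone(150.0)[:, None], (1, 16))
        out = filter_semg(_rec(x), PreprocessConfig(zscore=False))
        ratio = _steady_rms(out.samples[:, 0]) / _steady_rms(x[:, 0])
        assert abs(ratio - 1.0) < 0.05

    def test_highpass_gain_at_cutoff_matches_butterworth(self):
        # Analytic 4th-order Butterworth magnitude at its cutoff is
        # 1/sqrt(2) (-3.01 dB); forward-backward filtering squares it.
        cfg = PreprocessConfig(zscore=False)
        gain = semg_filter_response(cfg, FS, np.array([20.0]))[0]
        analytic = (1 / np.sqrt(2)) ** 2
        assert abs(20 * np.log10(gain) - 20 * np.log10(analytic)) < 0.5

    def test_zscore_statistics(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 3.0, (20000, 16))
        out = filter_semg(_rec(x), PreprocessConfig())
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-9
        assert np.abs(out.samples.std(axis=0) - 1).max() < 1e-9

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, (5000, 4))
        once = zscore(x)
        assert np.allclose(zscore(once), once, atol=1e-12)

    def test_constant_channel_zscored_to_zeros_with_warning(self):
        x = np.ones((100, 3))
        x[:, 1] = np.arange(100)
        with pytest.warns(RuntimeWarning, match="constant"):
            out = zscore(x)
        assert np.all(out[:, 0] == 0)

    def test_prefilter_stage_is_linear(self):
        rng = np.random.default_rng(2)
        cfg = PreprocessConfig(zscore=False)
        x = rng.standard_normal((6000, 16))
        y = rng.standard_normal((6000, 16))
        fx = filter_semg(_rec(x), cfg).samples
        fy = filter_semg(_rec(y), cfg).samples
        fxy = filter_semg(_rec(2.0 * x - 3.0 * y), cfg).samples
        assert np.allclose(fxy, 2.0 * fx - 3.0 * fy, atol=1e-8)

    def test_nonfinite_input_rejected(self):
        x = np.zeros((4000, 16))
        x[5, 5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            filter_semg(_rec(x))

    def test_comb_harmonics_option_extends_notches(self):
        cfg = PreprocessConfig(zscore=False, comb_n_harmonics=10)
        gain150 = semg_filter_response(cfg, FS, np.array([150.0]))[0]
        assert gain150 < 0.01  # 3rd harmonic of 50 Hz now notched


class TestSmoothKinematics:
    def _track(self, x, rate=120.0):
        return KinematicTrack(angles=x, rate=rate)

    def test_constant_preserved(self):
        x = np.full((1000, 16), 37.0)
        out = smooth_kinematics(self._track(x), PreprocessConfig(savgol_window=101, savgol_ref_rate=None))
        assert np.allclose(out.angles, 37.0)

    def test_linear_ramp_preserved_in_interior(self):
        x = np.tile(np.linspace(0, 90, 2000)[:, None], (1, 16))
        out = smooth_kinematics(self._track(x), PreprocessConfig(savgol_window=101, savgol_ref_rate=None))
        assert np.allclose(out.angles[200:-200], x[200:-200], atol=1e-9)

    def test_noise_variance_reduction_matches_moving_average(self):
        # Order-1 Savitzky-Golay over w samples is a plain moving average,
        # so white noise SD shrinks by 1/sqrt(w).
        rng = np.random.default_rng(3)
        sigma = 5.0
        x = rng.normal(0, sigma, (120000, 16))
        cfg = PreprocessConfig(savgol_window=502, savgol_ref_rate=None)
        out = smooth_kinematics(self._track(x), cfg)
        w = cfg.savgol_window_odd
        interior = out.angles[w : -w]
        expected = sigma / np.sqrt(w)
        assert abs(interior.std() - expected) / expected < 0.05

    def test_window_adjusted_to_odd(self):
        assert PreprocessConfig(savgol_window=502).savgol_window_odd == 501
        assert PreprocessConfig(savgol_window=501).savgol_window_odd == 501

    def test_short_track_error_suggests_smaller_window(self):
        x = np.zeros((100, 16))
        with pytest.raises(ValueError, match="smaller"):
            smooth_kinematics(self._track(x), PreprocessConfig(savgol_window=502, savgol_ref_rate=None))


class TestResampleKinematics:
    def test_constant_stays_constant(self):
        x = np.full((120, 16), 12.5)
        out = resample_kinematics(KinematicTrack(angles=x, rate=120.0), 4000.0)
        assert np.allclose(out.angles, 12.5)
        assert out.rate == 4000.0

    def test_ramp_keeps_endpoints(self):
        x = np.tile(np.linspace(0, 90, 121)[:, None], (1, 16))
        out = resample_kinematics(KinematicTrack(angles=x, rate=120.0), 4000.0)
        assert out.angles[0, 0] == pytest.approx(0.0)
        assert out.angles[-1, 0] == pytest.approx(90.0, abs=1.0)
        diffs = np.diff(out.angles[:, 0])
        assert np.all(diffs >= -1e-9)

    def test_down_then_upsample_bounded_error(self):
        # Band-limited signal: 2 Hz sine sampled at 120 Hz; down to 40 Hz
        # and back up should stay within the linear-interpolation bound
        # max|f''| * h^2 / 8 with h = 1/40 s.
        t = np.arange(1200) / 120.0
        f = 2.0
        x = np.tile(np.sin(2 * np.pi * f * t)[:, None], (1, 16))
        track = KinematicTrack(angles=x, rate=120.0)
        down = resample_kinematics(track, 40.0)
        up = resample_kinematics(down, 120.0)
        # Compare strictly inside the span of the 40 Hz samples (the ends
        # are held constant, not interpolated) and allow for the two
        # stacked interpolations.
        n = int(down.times[-1] * 120.0) - 1
        err = np.abs(up.angles[:n, 0] - x[:n, 0]).max()
        bound = (2 * np.pi * f) ** 2 * (1 / 40.0) ** 2 / 8
        assert err <= bound * 1.25

    def test_empty_track_rejected(self):
        track = KinematicTrack.__new__(KinematicTrack)
        track.angles = np.zeros((0, 16))
        track.rate = 120.0
        track.offset = 0.0
        with pytest.raises(ValueError, match="empty"):
            resample_kinematics(track, 4000.0)


def _ann(intervals):
    return GestureAnnotation(
        [
            GestureEvent("g", on, off, i + 1, "static1")
            for i, (on, off) in enumerate(intervals)
        ]
    )


class TestOutlierRule:
    def test_worked_three_sample_example(self):
        # One joint at (10, 12, 40) deg: median 12, third sample deviates
        # 28 >= 15 -> keep 2 of 3.
        rate = 1.0
        x = np.full((3, 16), 5.0)
        x[:, 0] = [10.0, 12.0, 40.0]
        track = KinematicTrack(angles=x, rate=rate)
        report = reject_outlier_samples(track, _ann([(0.0, 3.0)]))
        assert report.keep_mask.tolist() == [True, True, False]
        assert report.removed_fraction[0] == pytest.approx(1 / 3)
        assert report.overall_removed_fraction == pytest.approx(1 / 3)

    def test_tight_cluster_keeps_everything(self):
        rng = np.random.default_rng(0)
        x = 30.0 + rng.uniform(-0.5, 0.5, (100, 16))
        track = KinematicTrack(angles=x, rate=10.0)
        report = reject_outlier_samples(track, _ann([(0.0, 10.0)]))
        assert report.keep_mask.all()

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 360, (50, 16))
        track = KinematicTrack(angles=x, rate=10.0)
        report = reject_outlier_samples(
            track, _ann([(0.0, 5.0)]), OutlierFilterConfig(max_deviation=np.inf)
        )
        assert report.keep_mask.all()

    def test_matches_bruteforce_on_random_intervals(self):
        rng = np.random.default_rng(2)
        x = rng.normal(40, 12, (200, 16))
        track = KinematicTrack(angles=x, rate=20.0)
        intervals = [(0.5, 2.5), (3.0, 5.5), (6.0, 9.9)]
        report = reject_outlier_samples(track, _ann(intervals), OutlierFilterConfig(15.0))
        # brute force, sample by sample
        expected = np.ones(200, dtype=bool)
        for on, off in intervals:
            idx = [i for i in range(200) if on <= i / 20.0 < off]
            med = np.median(x[idx], axis=0)
            for i in idx:
                if np.max(np.abs(x[i] - med)) >= 15.0:
                    expected[i] = False
        assert np.array_equal(report.keep_mask, expected)

    def test_removed_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 20, (300, 16))
        track = KinematicTrack(angles=x, rate=30.0)
        ann = _ann([(0.0, 10.0)])
        fracs = [
            reject_outlier_samples(track, ann, OutlierFilterConfig(th)).overall_removed_fraction
            for th in [5.0, 10.0, 20.0, 40.0, 80.0]
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_interval_rejected(self):
        x = np.zeros((100, 16))
        track = KinematicTrack(angles=x, rate=10.0)
        with pytest.raises(ValueError, match="no kinematic samples"):
            reject_outlier_samples(track, _ann([(5.02, 5.03)]))
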