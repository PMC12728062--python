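"""Filtering, fusion, alignment, cleaning, onset detection and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from aanrehab.preprocess import (
    FilterSpec,
    KalmanState,
    butterworth_filter,
    ekf_attitude,
    emg_condition,
    estimate_lag,
    hampel_clean,
    integrate_gyro,
    kalman_update,
    quality_score,
    resample_align,
    segment_and_window,
    tkeo,
    tkeo_onset,
)
from aanrehab.streams import SignalStream
from aanrehab.synth import TrialSpec, gen_imu_stream


def _stream(x, fs=100.0, modality="emg"):
    return SignalStream(np.asarray(x, dtype=float), fs=fs, modality=modality)


class TestButterworth:
    def test_dc_gain_is_unity(self):
        x = _stream(np.full(500, 3.7))
        for order in (1, 2, 4):
            y = butterworth_filter(x, FilterSpec("lowpass", 5.0, order=order))
            assert np.allclose(y.data, 3.7, atol=1e-8)

    def test_analog_prototype_minus_3db_at_cutoff(self):
        """|H(j w_c)|^2 = 1 / (1 + (w/w_c)^(2n)) gives -3.01 dB at cutoff."""
        for n in (1, 2, 4):
            b, a = signal.butter(n, 1.0, analog=True)
            _, h = signal.freqs(b, a, worN=[1.0])
            assert 20 * np.log10(abs(h[0])) == pytest.approx(-3.0103, abs=1e-3)

    def test_noise_variance_matches_frequency_domain_integral(self, rng):
        """White-noise output variance equals the integral of |H|^2 * S_xx."""
        fs, n = 1000.0, 400_000
        x = _stream(rng.standard_normal(n), fs=fs)
        spec = FilterSpec("lowpass", 5.0, order=2)
        y = butterworth_filter(x, spec, mode="online").data[0][2000:]
        w, h = signal.sosfreqz(spec.sos(fs), worN=20000, fs=fs)
        expected = np.trapezoid(np.abs(h) ** 2, w) / (fs / 2)
        assert y.var() == pytest.approx(expected, rel=0.05)

    def test_cutoff_at_nyquist_rejected(self):
        x = _stream(np.zeros(100), fs=100.0)
        with pytest.raises(ValueError):
            butterworth_filter(x, FilterSpec("lowpass", 50.0))

    def test_all_specs_stable(self):
        """Poles inside the unit circle for every expressible design."""
        for kind, cut in [("lowpass", 3.0), ("lowpass", 40.0),
                          ("bandpass", (20.0, 450.0)), ("notch", 50.0)]:
            for order in (1, 2, 4, 6):
                fs = 1000.0
                sos = FilterSpec(kind, cut, order=order).sos(fs)
                _, poles, _ = signal.sos2zpk(sos)
                assert np.all(np.abs(poles) < 1.0)


class TestEmgCondition:
    def test_pure_mains_tone_suppressed_in_envelope(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs
        tone = _stream(np.sin(2 * np.pi * 50 * t), fs=fs)
        _, env = emg_condition(tone)
        assert np.mean(env.data**2) < 0.01 * np.mean(tone.data**2)

    def test_zero_input_zero_envelope(self):
        _, env = emg_condition(_stream(np.zeros(2000), fs=1000.0))
        assert np.allclose(env.data, 0.0)

    def test_envelope_tracks_modulator(self, rng):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        modulator = 0.5 * (1 + np.sin(2 * np.pi * 0.5 * t))
        carrier = rng.standard_normal(t.size)
        sos = signal.butter(4, [20, 450], btype="bandpass", fs=fs, output="sos")
        carrier = signal.sosfiltfilt(sos, carrier)
        _, env = emg_condition(_stream(carrier * modulator, fs=fs))
        r = np.corrcoef(env.data[0], modulator)[0, 1]
        assert r > 0.9

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            emg_condition(_stream(np.zeros(1000), fs=500.0))


class TestIntegration:
    def test_constant_rate(self):
        omega = _stream(np.full(201, 10.0), fs=100.0, modality="imu_gyro")
        theta = integrate_gyro(omega)
        assert theta.data[0, -1] == pytest.approx(20.0)
        assert theta.data[0, 0] == 0.0

    def test_cosine_integrates_to_sine(self):
        fs = 100.0
        t = np.arange(500) / fs
        omega = _stream(np.cos(t), fs=fs, modality="imu_gyro")
        theta = integrate_gyro(omega).data[0]
        assert np.allclose(theta, np.sin(t), atol=1e-4)  # O(dt^2)


class TestKalman:
    def test_zero_innovation_keeps_prior(self, rng):
        x = rng.standard_normal(4)
        P = np.eye(4) * 0.3
        H = rng.standard_normal((2, 4))
        z = H @ x
        x_post, _, _ = kalman_update(x, P, z, H, np.eye(2) * 0.1)
        assert np.allclose(x_post, x)

    def test_identity_limits(self):
        # R -> inf  =>  K -> 0  =>  posterior = prior
        x, P, H = np.array([1.0, 2.0]), np.eye(2), np.eye(2)
        x_post, _, K = kalman_update(x, P, np.array([5.0, 5.0]), H,
                                     np.eye(2) * 1e12)
        assert np.allclose(K, 0.0, atol=1e-9) and np.allclose(x_post, x)
        # R -> 0  =>  K -> I (H = I)  =>  posterior = measurement
        x_post, _, _ = kalman_update(x, P, np.array([5.0, 6.0]), H,
                                     np.eye(2) * 1e-12)
        assert np.allclose(x_post, [5.0, 6.0], atol=1e-6)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            KalmanState(P=-np.eye(7))

    def test_static_imu_ekf_beats_raw_integration(self):
        """Constant gyro bias: fused roll drift over 60 s is far below the
        drift of direct integration, both vs ground truth 0 degrees."""
        fs, dur = 100.0, 60.0
        n = int(fs * dur)
        rng = np.random.default_rng(0)
        bias = 0.5  # deg/s
        gyro = SignalStream(
            np.vstack([np.full(n, bias), np.zeros(n), np.zeros(n)])
            + 0.05 * rng.standard_normal((3, n)),
            fs=fs, modality="imu_gyro")
        accel = SignalStream(
            np.vstack([np.zeros(n), np.zeros(n), np.full(n, 9.81)])
            + 0.02 * rng.standard_normal((3, n)),
            fs=fs, modality="imu_accel")
        fused, state = ekf_attitude(gyro, accel)
        raw = integrate_gyro(gyro)
        assert abs(fused.data[0, -1]) < 2.0
        assert abs(raw.data[0, -1]) > 25.0
        assert np.linalg.norm(state.quaternion) == pytest.approx(1.0, abs=1e-9)

    def test_ekf_tracks_synthetic_reach(self, clean_patient, one_reach):
        gyro, accel = gen_imu_stream(clean_patient, one_reach, fs=100, rng=0)
        fused, _ = ekf_attitude(gyro, accel)
        truth = integrate_gyro(gyro).data[0]
        rmse = np.sqrt(np.mean((fused.data[0] - truth) ** 2))
        assert rmse < 0.05 * np.ptp(truth)


class TestEstimateLag:
    def test_identical_signals_zero_lag(self, rng):
        x = _stream(rng.standard_normal(500))
        assert estimate_lag(x, x, max_lag=0.5) == 0.0

    @pytest.mark.parametrize("shift", range(-10, 11))
    def test_integer_shifts_exact(self, shift, rng):
        base = rng.standard_normal(600)
        a = _stream(base[50:550])
        b = _stream(base[50 - shift:550 - shift])
        assert estimate_lag(a, b, max_lag=0.2) == pytest.approx(shift / 100.0)

    def test_noisy_delay_within_10ms(self):
        """Delayed copy at SNR 10 dB: |lag - 50 ms| <= 10 ms over 20 seeds."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal(1200)
            sos = signal.butter(2, 20, fs=100, output="sos")
            base = signal.sosfiltfilt(sos, base)
            a = base[100:1100]
            b = base[95:1095]  # delayed by 5 samples at 100 Hz
            snr_amp = np.std(b) / np.sqrt(10)
            b = b + snr_amp * rng.standard_normal(b.size)
            lag = estimate_lag(_stream(a), _stream(b), max_lag=0.3)
            errs.append(abs(lag - 0.05))
        assert max(errs) <= 0.010 + 1e-9

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_lag(_stream(np.ones(100)), _stream(np.arange(100.0)),
                         max_lag=0.1)


class TestResampleAlign:
    def test_linear_ramp_exact(self):
        ramp = _stream(np.arange(1000.0), fs=1000.0)
        (out,) = resample_align([ramp], target_fs=100.0)
        assert np.allclose(np.diff(out.data[0]), 10.0)

    def test_zoh_preserves_step(self):
        step = _stream(np.repeat([0.0, 1.0], 50), fs=100.0)
        (out,) = resample_align([step], target_fs=50.0, hold=[True])
        assert set(np.unique(out.data)) == {0.0, 1.0}
        edge = np.flatnonzero(np.diff(out.data[0]))[0]
        assert abs(edge - 24.5) <= 1.0  # at most one-sample shift

    def test_round_trip_sinusoid_rmse_below_1pct(self):
        fs = 100.0
        t = np.arange(300) / fs
        x = np.sin(2 * np.pi * 5 * t)
        (up,) = resample_align([_stream(x, fs=fs)], target_fs=1000.0)
        (down,) = resample_align([up], target_fs=100.0)
        m = min(down.n_samples, x.size)
        rmse = np.sqrt(np.mean((down.data[0, :m] - x[:m]) ** 2))
        assert rmse < 0.01 * np.sqrt(np.mean(x**2)) + 1e-3

    def test_disjoint_ranges_rejected(self):
        a = _stream(np.zeros(100))
        b = SignalStream(np.zeros(100), fs=100.0, modality="emg", t0=50.0)
        with pytest.raises(ValueError):
            resample_align([a, b])


class TestHampel:
    def test_clean_sinusoid_untouched(self):
        t = np.arange(1000) / 100.0
        x = _stream(np.sin(2 * np.pi * 0.5 * t))
        cleaned, mask = hampel_clean(x)
        assert mask.sum() == 0
        assert quality_score(mask) == 1.0
        assert np.array_equal(cleaned.data, x.data)

    def test_single_spike_replaced(self, rng):
        base = signal.sosfiltfilt(signal.butter(2, 10, fs=100, output="sos"),
                                  rng.standard_normal(500))
        x = base.copy()
        x[250] = 100 * np.abs(base).max()
        cleaned, mask = hampel_clean(_stream(x))
        assert mask[0, 250]
        assert mask.sum() == 1
        assert abs(cleaned.data[0, 250] - base[250]) < 5 * base.std()

    def test_injected_spikes_detected(self, rng):
        """>= 95 % of injected 5 % spikes found, < 1 % false positives."""
        n = 4000
        x = signal.sosfiltfilt(signal.butter(2, 10, fs=100, output="sos"),
                               rng.standard_normal(n))
        idx = rng.choice(n, size=n // 20, replace=False)
        truth = np.zeros(n, dtype=bool)
        truth[idx] = True
        x[idx] += 12 * x.std() * rng.choice([-1, 1], size=idx.size)
        _, mask = hampel_clean(_stream(x), half_window=5, n_mad=4)
        hits = (mask[0] & truth).sum() / truth.sum()
        false_pos = (mask[0] & ~truth).sum() / (~truth).sum()
        assert hits >= 0.95
        assert false_pos < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = signal.sosfiltfilt(signal.butter(2, 10, fs=100, output="sos"),
                               rng.standard_normal(1000))
        x[100] = 50.0
        once, m1 = hampel_clean(_stream(x))
        twice, m2 = hampel_clean(once)
        assert np.array_equal(once.data, twice.data)
        assert m2.sum() == 0

    def test_long_gap_flagged_not_dropped(self, rng):
        x = rng.standard_normal(200)
        x[20:60] = np.nan  # 20 % gap
        with pytest.warns(UserWarning, match="low-quality"):
            cleaned, mask = hampel_clean(_stream(x))
        assert np.isfinite(cleaned.data).all()
        assert quality_score(mask) < 0.9


class TestTkeo:
    def test_constant_signal_zero_energy(self):
        assert np.allclose(tkeo(np.full(100, 2.5)), 0.0)

    def test_sinusoid_constant_energy(self):
        """Psi[A sin(wn)] = A^2 sin^2(w), independent of n."""
        n = np.arange(1000)
        for a, w in [(1.0, 0.3), (2.5, 0.8)]:
            psi = tkeo(a * np.sin(w * n))[1:-1]
            assert np.allclose(psi, a**2 * np.sin(w) ** 2, atol=1e-9)

    def test_burst_onset_within_50ms(self, rng):
        fs = 1000.0
        n = int(4 * fs)
        x = 0.05 * rng.standard_normal(n)
        burst = slice(int(2.0 * fs), int(2.5 * fs))
        x[burst] += 0.5 * rng.standard_normal(burst.stop - burst.start)
        onsets = tkeo_onset(_stream(x, fs=fs), threshold_k=8,
                            min_consecutive=10)
        assert onsets
        assert abs(onsets[0] - 2.0) <= 0.05

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            tkeo(np.array([1.0, 2.0]))


class TestWindowing:
    def _trial(self, t0, t1, tid=0):
        return TrialSpec(trial_id=tid, distance_D=30, width_W=5,
                         duration_T=t1 - t0, t_start=t0, t_end=t1)

    def test_counts_50pct_overlap(self):
        x = _stream(np.zeros(1000))
        (seg,) = segment_and_window(x, [self._trial(0.0, 10.0)],
                                    window_ms=200, overlap=0.5)
        assert seg.n_windows == 99

    def test_counts_zero_overlap(self):
        x = _stream(np.zeros(1000))
        (seg,) = segment_and_window(x, [self._trial(0.0, 10.0)],
                                    window_ms=200, overlap=0.0)
        assert seg.n_windows == 50

    def test_window_longer_than_segment_warns(self):
        x = _stream(np.zeros(1000))
        with pytest.warns(UserWarning):
            (seg,) = segment_and_window(x, [self._trial(0.0, 0.1)],
                                        window_ms=200)
        assert seg.n_windows == 0

    def test_out_of_range_trial_rejected(self):
        x = _stream(np.zeros(100))
        with pytest.raises(ValueError):
            segment_and_window(x, [self._trial(0.0, 2.0)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        start=st.integers(min_value=0, max_value=40),
        length=st.integers(min_value=5, max_value=55),
        window_ms=st.sampled_from([100, 200, 300]),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_windows_never_cross_segment_boundaries(self, start, length,
                                                    window_ms, overlap):
        x = _stream(np.zeros(10_000))
        t0, t1 = start / 10.0, (start + length) / 10.0
        (seg,) = segment_and_window(x, [self._trial(t0, t1)],
                                    window_ms=window_ms, overlap=overlap)
        for w in seg.windows:
            assert seg.start <= w.start < w.end <= seg.end

    def test_coverage_union_spans_segment(self):
        """Windows cover the segment up to at most one trailing partial."""
        x = _stream(np.zeros(1000))
        (seg,) = segment_and_window(x, [self._trial(0.0, 9.73)],
                                    window_ms=200, overlap=0.5)
        covered = np.zeros(seg.end - seg.start, dtype=bool)
        for w in seg.windows:
            covered[w.start - seg.start:w.end - seg.start] = True
        uncovered = (~covered).sum()
        assert uncovered < int(0.2 * x.fs)  # less than one window
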