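"""Feature bank: smoothness oracles, EMG features, couplings, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from aanrehab.features import (
    BaselineNormalizer,
    OnlineFeatureSelector,
    assist_energy,
    cci,
    ema_update,
    emd_delay,
    emg_freq_features,
    emg_time_features,
    fitts_id,
    kinematic_features,
    ldlj,
    mutual_info,
    select_features,
    sparc,
    spectral_slope,
    task_features,
)
from aanrehab.preprocess import TaskSegment
from aanrehab.streams import SignalStream
from aanrehab.synth import TrialSpec, minimum_jerk_velocity


def _angles(theta, fs=100.0):
    return SignalStream(np.asarray(theta, dtype=float), fs=fs, modality="angle")


# --------------------------------------------------------------------------
# Independent brute-force smoothness oracles (kept free of package code)
# --------------------------------------------------------------------------


def sparc_oracle(speed, fs, padlevel=4, fc=20.0, amp_th=0.05):
    """Direct re-derivation: arc length of the normalized speed spectrum."""
    nfft = int(2 ** np.ceil(np.log2(len(speed)) + padlevel))
    freqs = np.arange(nfft) * fs / nfft
    mag = np.abs(np.fft.fft(speed, nfft))
    keep = freqs <= fc
    f_sel, m_sel = freqs[keep], mag[keep] / mag[keep].max()
    idx = np.flatnonzero(m_sel >= amp_th)
    f_sel, m_sel = f_sel[idx[0]:idx[-1] + 1], m_sel[idx[0]:idx[-1] + 1]
    arc = 0.0
    span = f_sel[-1] - f_sel[0]
    for i in range(1, len(f_sel)):
        arc += np.sqrt(((f_sel[i] - f_sel[i - 1]) / span) ** 2
                       + (m_sel[i] - m_sel[i - 1]) ** 2)
    return -arc


def ldlj_oracle(speed, fs):
    """Direct re-derivation: -ln(T^5 / A^2 * sum of squared jerk * dt)."""
    dt = 1.0 / fs
    duration = len(speed) * dt
    peak = max(abs(v) for v in speed)
    vel = np.asarray(speed, dtype=float)
    acc = np.gradient(vel, dt)
    jerk = np.gradient(acc, dt)
    integral = np.trapezoid(jerk**2, dx=dt)
    return -np.log(duration**5 / peak**2 * integral)


class TestSmoothness:
    def test_min_jerk_matches_independent_oracles(self):
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)
        speed = 30 * minimum_jerk_velocity(t, 2.0)
        assert sparc(speed, fs) == pytest.approx(sparc_oracle(speed, fs),
                                                 abs=1e-6)
        assert ldlj(speed, fs) == pytest.approx(ldlj_oracle(speed, fs),
                                                abs=1e-6)

    def test_ldlj_amplitude_invariant(self):
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)
        speed = minimum_jerk_velocity(t, 2.0)
        assert ldlj(3.7 * speed, fs) == pytest.approx(ldlj(speed, fs),
                                                      rel=1e-9)

    def test_jitter_degrades_both_metrics_monotonically(self):
        """SPARC and LDLJ decrease as zero-mean jitter amplitude grows."""
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)
        base = 30 * minimum_jerk_velocity(t, 2.0)
        amp_grid = np.linspace(0.0, 3.0, 10)
        sparc_med, ldlj_med = [], []
        for amp in amp_grid:
            sp, ld = [], []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                jit = amp * signal.sosfiltfilt(
                    signal.butter(2, [4, 12], btype="bandpass", fs=fs,
                                  output="sos"),
                    rng.standard_normal(t.size))
                sp.append(sparc(base + jit, fs))
                ld.append(ldlj(base + jit, fs))
            sparc_med.append(np.median(sp))
            ldlj_med.append(np.median(ld))
        assert all(np.diff(sparc_med) < 0)
        assert all(np.diff(ldlj_med) < 0)


class TestKinematic:
    def test_rom_and_romn(self):
        seg = TaskSegment(trial_id=0, start=0, end=3)
        fv = kinematic_features(seg, _angles([10.0, 45.0, 30.0]), rom_base=70.0)
        assert fv["rom"] == pytest.approx(35.0)
        assert fv["romn"] == pytest.approx(0.5)

    def test_invalid_rom_base(self):
        seg = TaskSegment(trial_id=0, start=0, end=3)
        with pytest.raises(ValueError):
            kinematic_features(seg, _angles([1.0, 2.0, 3.0]), rom_base=0.0)

    def test_clean_reach_has_unit_path_efficiency(self):
        fs = 100.0
        t = np.arange(0, 3.0, 1 / fs)
        from aanrehab.synth import reach_angle_profile

        theta = reach_angle_profile(t, 0.0, 3.0, 50.0)
        seg = TaskSegment(trial_id=0, start=0, end=t.size)
        fv = kinematic_features(seg, _angles(theta), rom_base=60.0)
        assert fv["path_efficiency"] == pytest.approx(1.0, abs=1e-9)


class TestAssistEnergy:
    def test_constant_torque_and_speed(self):
        tq = SignalStream(np.ones(201), fs=100.0, modality="envelope")
        sp = SignalStream(np.ones(201), fs=100.0, modality="envelope")
        assert assist_energy(tq, sp) == pytest.approx(2.0)

    def test_zero_speed_zero_work(self):
        tq = SignalStream(np.ones(100), fs=100.0, modality="envelope")
        sp = SignalStream(np.zeros(100), fs=100.0, modality="envelope")
        assert assist_energy(tq, sp) == 0.0

    def test_quadrature_orthogonality(self):
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)  # two full 1 Hz periods
        tq = SignalStream(np.sin(2 * np.pi * t), fs=fs, modality="envelope")
        sp = SignalStream(np.cos(2 * np.pi * t), fs=fs, modality="envelope")
        assert abs(assist_energy(tq, sp)) < 1e-3


class TestEmgTime:
    def test_constant_signal(self):
        fv = emg_time_features(np.full(50, -2.0))
        assert fv["rms"] == pytest.approx(2.0)
        assert fv["mav"] == pytest.approx(2.0)
        assert fv["wl"] == 0.0 and fv["zc"] == 0

    def test_two_sample_rms(self):
        assert emg_time_features(np.array([3.0, 4.0]))["rms"] == pytest.approx(
            np.sqrt(12.5))

    def test_alternating_signal_zero_crossings(self):
        n = 25
        x = np.resize([1.0, -1.0], n)
        assert emg_time_features(x)["zc"] == n - 1

    def test_deadband_suppresses_small_crossings(self):
        x = np.resize([0.01, -0.01], 40)
        assert emg_time_features(x, deadband=0.1)["zc"] == 0


class TestEmgFreq:
    def test_pure_tone(self):
        fs = 1000.0
        t = np.arange(int(fs)) / fs
        fv = emg_freq_features(np.sin(2 * np.pi * 100 * t), fs)
        res = fs / 128  # Welch bin width
        assert abs(fv["mnf"] - 100.0) < 2 * res
        assert abs(fv["mdf"] - 100.0) < 2 * res

    def test_symmetric_spectrum_mean_at_center(self, rng):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 80 * t) + np.sin(2 * np.pi * 120 * t + 1.0)
        fv = emg_freq_features(x, fs)
        assert fv["mnf"] == pytest.approx(100.0, abs=3.0)

    def test_flat_band_mean_frequency(self, rng):
        """Band-limited white noise on 20-450 Hz: MNF ~ (20+450)/2 = 235 Hz."""
        fs = 1000.0
        sos = signal.butter(8, [20, 450], btype="bandpass", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(int(20 * fs)))
        fv = emg_freq_features(x, fs, nperseg=1024)
        assert fv["mnf"] == pytest.approx(235.0, rel=0.05)

    def test_all_zero_window_masked(self):
        with pytest.warns(UserWarning):
            fv = emg_freq_features(np.zeros(128), 1000.0)
        assert np.isnan(fv["mnf"]) and np.isnan(fv["mdf"])

    def test_spectral_slope_linear_trend(self):
        mnf = np.array([120.0, 110.0, 100.0, 90.0])
        t = np.array([0.0, 1.0, 2.0, 3.0])
        assert spectral_slope(mnf, t) == pytest.approx(-10.0)


class TestCci:
    def test_equal_envelopes(self):
        e = np.array([1.0, 2.0, 3.0])
        assert cci(e, e) == 1.0

    def test_disjoint_supports(self):
        assert cci(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_value(self):
        assert cci(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == 0.5

    def test_negative_rejected_and_degenerate_masked(self):
        with pytest.raises(ValueError):
            cci(np.array([-1.0]), np.array([1.0]))
        assert np.isnan(cci(np.zeros(3), np.zeros(3)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=20),
           st.lists(st.floats(0.0, 10.0), min_size=2, max_size=20),
           st.floats(0.1, 50.0))
    def test_symmetry_and_scale_invariance(self, a, b, k):
        m = min(len(a), len(b))
        a, b = np.array(a[:m]), np.array(b[:m])
        if np.maximum(a, b).sum() == 0:
            return
        assert cci(a, b) == pytest.approx(cci(b, a))
        assert cci(k * a, k * b) == pytest.approx(cci(a, b))
        assert 0.0 <= cci(a, b) <= 1.0


class TestCouplings:
    def test_emd_values(self):
        assert emd_delay(0.5, 0.5) == 0.0
        assert emd_delay(0.10, 0.16) == pytest.approx(0.06)
        assert np.isnan(emd_delay(None, 0.2))
        with pytest.warns(UserWarning):
            assert emd_delay(0.3, 0.2) == pytest.approx(-0.1)

    def test_emd_recovered_from_synthetic_lag(self, rng):
        """A 60 ms built-in EMG-to-motion lag is recovered within 20 ms."""
        from aanrehab.preprocess import tkeo_onset

        fs = 1000.0
        n = int(4 * fs)
        noise = 0.03
        emg = noise * rng.standard_normal(n)
        motion = noise * rng.standard_normal(n)
        emg[int(1.94 * fs):int(2.5 * fs)] += 0.6 * rng.standard_normal(
            int(0.56 * fs))
        motion[int(2.0 * fs):int(2.56 * fs)] += 0.6 * rng.standard_normal(
            int(0.56 * fs))
        e_on = tkeo_onset(SignalStream(emg, fs=fs, modality="emg"))[0]
        m_on = tkeo_onset(SignalStream(motion, fs=fs, modality="emg"))[0]
        assert emd_delay(e_on, m_on) == pytest.approx(0.06, abs=0.02)

    def test_mi_independent_pairs_near_zero(self, rng):
        a, b = rng.random(10_000), rng.random(10_000)
        assert mutual_info(a, b) <= 0.05

    def test_mi_identical_discrete_levels(self, rng):
        x = rng.integers(0, 4, size=4000).astype(float)
        assert mutual_info(x, x, n_bins=4) == pytest.approx(2.0, abs=0.01)

    def test_mi_gaussian_closed_form(self, rng):
        """Bivariate normal rho=0.9: I = -0.5 log2(1-rho^2) ~ 1.198 bits."""
        n, rho = 50_000, 0.9
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        expected = -0.5 * np.log2(1 - rho**2)
        assert mutual_info(xy[:, 0], xy[:, 1]) == pytest.approx(expected,
                                                                rel=0.15)

    def test_mi_degenerate_input(self):
        with pytest.warns(UserWarning):
            assert mutual_info(np.ones(200), np.arange(200.0)) == 0.0


class TestTask:
    def _trial(self, d, w, t):
        return TrialSpec(trial_id=0, distance_D=d, width_W=w, duration_T=t,
                         t_start=0.0, t_end=t)

    def test_fitts_hand_values(self):
        assert fitts_id(5.0, 5.0) == pytest.approx(1.0)
        assert fitts_id(15.0, 5.0) == pytest.approx(2.0)
        fv = task_features([self._trial(15.0, 5.0, 0.5)])
        assert fv["fitts_tp"] == pytest.approx(4.0)

    def test_fitts_monotonicity(self):
        ids_d = [fitts_id(d, 5.0) for d in np.linspace(1, 50, 25)]
        ids_w = [fitts_id(30.0, w) for w in np.linspace(1, 20, 25)]
        assert all(np.diff(ids_d) > 0)
        assert all(np.diff(ids_w) < 0)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            fitts_id(10.0, 0.0)
        with pytest.raises(ValueError):
            task_features([])


class TestNormalize:
    def test_ema_limits_and_recursion(self):
        assert ema_update(0.0, 5.0, alpha=1.0) == 5.0
        mu, hand = 0.0, 0.0
        for x in (1.0, 2.0, 3.0):
            mu = ema_update(mu, x, alpha=0.05)
            hand = 0.05 * x + 0.95 * hand
        assert mu == pytest.approx(hand)
        assert mu == pytest.approx(0.290125)  # alpha sum: 0.05*(3+1.9+0.9025)

    def test_constant_input_converges_geometrically(self):
        mu, c, alpha = 0.0, 4.0, 0.1
        for t in range(1, 30):
            mu = ema_update(mu, c, alpha)
            assert abs(mu - c) == pytest.approx((1 - alpha) ** t * 4.0)

    @pytest.mark.parametrize("mode", ["zscore", "robust", "ratio"])
    def test_round_trip(self, mode, rng):
        X = rng.normal(5.0, 2.0, size=(200, 4))
        norm = BaselineNormalizer(mode=mode).fit(X)
        Z = norm.transform(X)
        assert np.allclose(norm.inverse_transform(Z), X)

    def test_zero_spread_feature_masked(self, rng):
        X = np.column_stack([rng.normal(size=100), np.full(100, 2.0)])
        Z = BaselineNormalizer(mode="zscore").fit(X).transform(X)
        assert np.isfinite(Z[:, 0]).all()
        assert np.isnan(Z[:, 1]).all()


class TestSelection:
    def test_pca_retains_two_real_directions(self, rng):
        """Two strong orthogonal variance directions plus 1 % noise: PCA at
        95 % cumulative variance keeps exactly 2 components."""
        n = 2000
        basis = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        scores = rng.standard_normal((n, 3)) * np.array([10.0, 7.0, 0.3])
        X = scores @ basis.T
        pca = select_features(X, mode="offline")
        assert pca.n_components_ == 2

    def test_duplicate_column_pruned(self, rng):
        x = rng.standard_normal(400)
        X = np.column_stack([x, x, rng.standard_normal(400)])
        y = x + 0.1 * rng.standard_normal(400)
        kept = select_features(X, y, budget=10)
        assert len(set(kept) & {0, 1}) == 1

    def test_budget_enforced_and_tie_break_deterministic(self, rng):
        X = rng.standard_normal((300, 12))
        y = rng.standard_normal(300)  # independent target
        sel1 = OnlineFeatureSelector(budget=5).fit(X, y)
        sel2 = OnlineFeatureSelector(budget=5).fit(X, y)
        assert len(sel1.support_) <= 5
        assert np.array_equal(sel1.support_, sel2.support_)

    def test_invalid_budget(self, rng):
        with pytest.raises(ValueError):
            OnlineFeatureSelector(budget=0).fit(rng.standard_normal((10, 2)),
                                                rng.standard_normal(10))
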