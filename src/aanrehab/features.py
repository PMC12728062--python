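"""Per-window and per-segment feature bank, baseline normalization, selection.

Kinematic features (ROM, velocity statistics, LDLJ and SPARC smoothness, path
efficiency, 4-12 Hz tremor ratio), sEMG time features (RMS, MAV, WL, ZC, SSC,
IEMG) and frequency features (MNF, MDF), cross-modal couplings (co-contraction
index, electromechanical delay, cross-correlation, mutual information), and
Fitts task-level metrics. Features are returned as plain name->value dicts; a
non-finite value means "masked" and downstream stages must skip or downweight
it.

Normalization against individualized baselines (z-score, robust, ratio, with
exponential-moving-average baseline updating) and feature selection (online:
variance filter + mutual-information ranking + correlation pruning; offline:
PCA at >= 95 % cumulative variance) are exposed as scikit-learn style
transformers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import mutual_info_regression
from sklearn.utils.validation import check_is_fitted

from aanrehab.preprocess import TaskSegment
from aanrehab.streams import SignalStream
from aanrehab.synth import TrialSpec

# ---------------------------------------------------------------------------
# Smoothness metrics
# ---------------------------------------------------------------------------


def sparc(speed: np.ndarray, fs: float, padlevel: int = 4, fc: float = 20.0,
          amp_th: float = 0.05) -> float:
    """Spectral arc length of a movement speed profile (negative; 0 = ideal).

    Arc length of the magnitude spectrum normalized by its peak, restricted to
    the adaptive band where the normalized spectrum exceeds ``amp_th`` (within
    0..``fc`` Hz). More negative values indicate a more fragmented, less
    smooth movement.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 4 or not np.isfinite(speed).all():
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(speed.size) + padlevel))
    f = np.arange(nfft) * fs / nfft
    mag = np.abs(np.fft.fft(speed, nfft))
    sel = f <= fc
    f_sel, m_sel = f[sel], mag[sel]
    peak = m_sel.max()
    if peak <= 0:
        return float("nan")
    m_sel = m_sel / peak
    above = np.flatnonzero(m_sel >= amp_th)
    lo, hi = above[0], above[-1] + 1
    f_cut, m_cut = f_sel[lo:hi], m_sel[lo:hi]
    if f_cut.size < 2:
        return 0.0
    df = np.diff(f_cut) / (f_cut[-1] - f_cut[0])
    return float(-np.sum(np.sqrt(df**2 + np.diff(m_cut) ** 2)))


def ldlj(speed: np.ndarray, fs: float) -> float:
    """Log dimensionless jerk of a speed profile (larger = smoother).

    -ln( (T^5 / A^2) * integral of squared jerk ), with T the profile duration
    and A the peak speed. Invariant under amplitude and duration scaling of a
    fixed movement shape.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 5 or not np.isfinite(speed).all():
        return float("nan")
    dt = 1.0 / fs
    duration = speed.size * dt
    peak = np.abs(speed).max()
    if peak <= 0:
        return float("nan")
    jerk = np.gradient(np.gradient(speed, dt), dt)
    integral = np.trapezoid(jerk**2, dx=dt)
    if integral <= 0:
        return float("nan")
    return float(-np.log(duration**5 / peak**2 * integral))


def band_power_ratio(x: np.ndarray, fs: float, low: float = 4.0,
                     high: float = 12.0) -> float:
    """Fraction of Welch spectral power inside [low, high] Hz."""
    x = np.asarray(x, dtype=float)
    nperseg = min(256, x.size)
    f, p = signal.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    total = np.trapezoid(p, f)
    if total <= 0:
        return float("nan")
    band = (f >= low) & (f <= high)
    return float(np.trapezoid(p[band], f[band]) / total)


# ---------------------------------------------------------------------------
# Kinematic / dynamic features
# ---------------------------------------------------------------------------


def kinematic_features(
    segment: TaskSegment,
    angles: SignalStream,
    rom_base: float,
) -> dict[str, float]:
    """Kinematic feature subset for one task segment.

    Uses the first channel of ``angles`` (degrees). Velocity statistics come
    from the differentiated angle; smoothness from the speed profile. Path
    efficiency is the 1-DoF form: peak-to-peak excursion over half the total
    variation, equal to 1 for a clean out-and-back reach. ``target_rmse`` and
    ``endpoint_error`` require a spatial target and are masked (NaN) here;
    the VR task layer fills them when target geometry is known.
    """
    if rom_base <= 0:
        raise ValueError("rom_base must be positive")
    theta = angles.data[0, segment.start : segment.end]
    fs = angles.fs
    if theta.size < 2:
        return {k: float("nan") for k in _KINEMATIC_KEYS}
    rom = float(theta.max() - theta.min())
    if theta.size < 5:  # too short for velocity/smoothness estimates
        out = {k: float("nan") for k in _KINEMATIC_KEYS}
        out.update(rom=rom, romn=rom / rom_base)
        return out
    vel = np.gradient(theta, 1.0 / fs)
    speed = np.abs(vel)
    peak_idx = int(np.argmax(speed))
    tv = float(np.sum(np.abs(np.diff(theta))))
    path_eff = float(np.clip(rom / (tv / 2.0), 0.0, 1.0)) if tv > 0 else float("nan")
    dwell = float(np.mean(speed < 0.1 * speed.max())) if speed.max() > 0 else float("nan")
    return {
        "rom": rom,
        "romn": rom / rom_base,
        "v_mean": float(speed.mean()),
        "v_peak": float(speed.max()),
        "v_sd": float(speed.std()),
        # velocities per unit of calibrated ROM (1/s): comparable across
        # subjects with different movement amplitudes
        "v_mean_n": float(speed.mean()) / rom_base,
        "v_peak_n": float(speed.max()) / rom_base,
        "v_sd_n": float(speed.std()) / rom_base,
        "ttpv": peak_idx / fs,
        "ldlj": ldlj(vel, fs),
        "sparc": sparc(speed, fs),
        "path_efficiency": path_eff,
        "tremor_ratio_4_12": band_power_ratio(theta, fs),
        # velocity-domain variant: differentiation boosts the tremor band
        # relative to the slow voluntary movement, improving sensitivity
        "tremor_ratio_vel": band_power_ratio(vel, fs),
        "dwell_ratio": dwell,
        "target_rmse": float("nan"),
        "endpoint_error": float("nan"),
    }


_KINEMATIC_KEYS = (
    "rom", "romn", "v_mean", "v_peak", "v_sd", "v_mean_n", "v_peak_n",
    "v_sd_n", "ttpv", "ldlj", "sparc", "path_efficiency",
    "tremor_ratio_4_12", "tremor_ratio_vel", "dwell_ratio", "target_rmse",
    "endpoint_error",
)


def assist_energy(torque: SignalStream, speed: SignalStream) -> float:
    """Assistive work E = integral of torque * angular velocity, in joules.

    ``torque`` in N*m and ``speed`` in rad/s, time-aligned at the same rate.
    """
    if torque.fs != speed.fs or torque.n_samples != speed.n_samples:
        raise ValueError("torque and speed streams must be aligned (same fs/length)")
    power = torque.data[0] * speed.data[0]
    return float(np.trapezoid(power, dx=1.0 / torque.fs))


# ---------------------------------------------------------------------------
# sEMG features
# ---------------------------------------------------------------------------


def emg_time_features(window: np.ndarray, deadband: float = 0.0) -> dict[str, float]:
    """Standard sEMG time-domain features of one window.

    RMS, mean absolute value, integrated EMG, waveform length, zero crossings
    and slope sign changes; ZC and SSC apply a noise deadband (an excursion
    must exceed it to count).
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    diff = np.diff(x)
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(diff) > deadband)))
    d1, d2 = diff[:-1], diff[1:]
    ssc = int(np.sum((d1 * d2 < 0) & ((np.abs(d1) > deadband) | (np.abs(d2) > deadband))))
    return {
        "rms": float(np.sqrt(np.mean(x**2))),
        "mav": float(np.mean(np.abs(x))),
        "iemg": float(np.sum(np.abs(x))),
        "wl": float(np.sum(np.abs(diff))),
        "zc": zc,
        "ssc": ssc,
    }


def emg_freq_features(window: np.ndarray, fs: float,
                      nperseg: int = 128) -> dict[str, float]:
    """Mean and median frequency of one sEMG window via Welch periodogram.

    MNF = sum(f P(f)) / sum(P(f)); MDF splits the spectral power in half.
    An all-zero window yields masked (NaN) values.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 64:
        raise ValueError("window must hold at least 64 samples")
    f, p = signal.welch(x, fs=fs, nperseg=min(nperseg, x.size))
    total = p.sum()
    if total <= 0:
        warnings.warn("all-zero window: spectral features masked", stacklevel=2)
        return {"mnf": float("nan"), "mdf": float("nan")}
    mnf = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    mdf = float(np.interp(total / 2.0, cum, f))
    return {"mnf": mnf, "mdf": mdf}


def spectral_slope(mnf_series: np.ndarray, t_centers: np.ndarray) -> float:
    """Linear trend of MNF across a segment's windows, in Hz/s (fatigue index)."""
    mnf_series = np.asarray(mnf_series, dtype=float)
    t_centers = np.asarray(t_centers, dtype=float)
    ok = np.isfinite(mnf_series)
    if ok.sum() < 2:
        return float("nan")
    return float(np.polyfit(t_centers[ok], mnf_series[ok], 1)[0])


def cci(e_a: np.ndarray, e_b: np.ndarray) -> float:
    """Co-contraction index: sum of min over sum of max of two envelopes.

    Both envelopes must be non-negative and equal length; CCI lies in [0, 1]
    (1 = identical activation, 0 = disjoint). Two all-zero envelopes give a
    masked NaN.
    """
    a = np.asarray(e_a, dtype=float)
    b = np.asarray(e_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("envelopes must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("envelopes must be non-negative")
    denom = np.sum(np.maximum(a, b))
    if denom == 0:
        return float("nan")
    return float(np.sum(np.minimum(a, b)) / denom)


def emd_delay(emg_onset: float | None, motion_onset: float | None) -> float:
    """Electromechanical delay: motion onset minus EMG onset, seconds.

    Negative values (motion before EMG) are flagged with a warning; a missing
    onset yields a masked NaN.
    """
    if emg_onset is None or motion_onset is None:
        return float("nan")
    delay = motion_onset - emg_onset
    if delay < 0:
        warnings.warn(f"negative electromechanical delay ({delay:.3f} s)",
                      stacklevel=2)
    return float(delay)


def xcorr_peak_lag(e: np.ndarray, speed: np.ndarray, fs: float,
                   max_lag: float = 0.5) -> tuple[float, float]:
    """Peak normalized cross-correlation and its lag (s) between two signals."""
    a = np.asarray(e, dtype=float)
    b = np.asarray(speed, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    a = (a - a.mean()) / (a.std() * np.sqrt(a.size))
    b = (b - b.mean()) / (b.std() * np.sqrt(b.size))
    full = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags) <= int(round(max_lag * fs))
    full, lags = full[keep], lags[keep]
    i = int(np.argmax(full))
    return float(full[i]), float(lags[i] / fs)


def mutual_info(e: np.ndarray, speed: np.ndarray, n_bins: int = 16) -> float:
    """Plug-in histogram mutual information I(e; speed) in bits.

    Non-negative by construction. A degenerate (constant) input yields 0 with
    a warning.
    """
    a = np.asarray(e, dtype=float)
    b = np.asarray(speed, dtype=float)
    if a.shape != b.shape or a.size < 100:
        raise ValueError("inputs must be equal-length with at least 100 samples")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant input: mutual information set to 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# Task-level features
# ---------------------------------------------------------------------------


def fitts_id(distance: float, width: float) -> float:
    """Fitts index of difficulty, ID = log2(D / W + 1), in bits."""
    if width <= 0:
        raise ValueError("target width must be positive")
    if distance <= 0:
        raise ValueError("target distance must be positive")
    return float(np.log2(distance / width + 1.0))


def task_features(trials: list[TrialSpec]) -> dict[str, float]:
    """Fitts-law and outcome aggregates over a list of trials.

    Per-trial index of difficulty ID = log2(D/W + 1) and throughput TP = ID/T
    are averaged; success rate, mean completion time and the inter-trial
    coefficient of variation of completion time summarize task outcomes.
    """
    if not trials:
        raise ValueError("empty trial list")
    ids = np.array([fitts_id(tr.distance_D, tr.width_W) for tr in trials])
    times = np.array([tr.duration_T for tr in trials])
    return {
        "fitts_id": float(ids.mean()),
        "fitts_tp": float(np.mean(ids / times)),
        "success_rate": float(np.mean([tr.success for tr in trials])),
        "completion_time": float(times.mean()),
        "inter_trial_cv": float(times.std() / times.mean()),
    }


# ---------------------------------------------------------------------------
# Baseline normalization
# ---------------------------------------------------------------------------


def ema_update(mu: np.ndarray, x: np.ndarray, alpha: float) -> np.ndarray:
    """One exponential-moving-average baseline step, mu <- alpha x + (1-alpha) mu."""
    return alpha * np.asarray(x, dtype=float) + (1.0 - alpha) * np.asarray(mu, dtype=float)


class BaselineNormalizer(BaseEstimator, TransformerMixin):
    """Normalize features against an individualized calibration baseline.

    Fit on the calibration period (e.g. the first three sessions); transform
    then applies one of three modes:

    - ``zscore``:  (x - mu) / sigma
    - ``robust``:  (x - median) / IQR
    - ``ratio``:   x / baseline-mean

    Features whose spread (sigma or IQR) or baseline mean is zero are masked:
    their transformed values are NaN. The fitted baseline mean can be updated
    online with :meth:`partial_update`, an exponential moving average with
    rate ``ema_alpha`` (default 0.03, within the 0.01-0.05 band used for slow
    drift suppression).
    """

    def __init__(self, mode: str = "zscore", ema_alpha: float = 0.03):
        self.mode = mode
        self.ema_alpha = ema_alpha

    def fit(self, X, y=None):
        if self.mode not in ("zscore", "robust", "ratio"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        self.mu_ = np.nanmean(X, axis=0)
        self.sigma_ = np.nanstd(X, axis=0, ddof=0)
        self.median_ = np.nanmedian(X, axis=0)
        q75, q25 = np.nanpercentile(X, [75, 25], axis=0)
        self.iqr_ = q75 - q25
        self.baseline_ = self.mu_.copy()  # EMA state mu_t
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mu_")
        X = np.asarray(X, dtype=float)
        if self.mode == "zscore":
            denom = np.where(self.sigma_ > 0, self.sigma_, np.nan)
            return (X - self.mu_) / denom
        if self.mode == "robust":
            denom = np.where(self.iqr_ > 0, self.iqr_, np.nan)
            return (X - self.median_) / denom
        denom = np.where(self.baseline_ != 0, self.baseline_, np.nan)
        return X / denom

    def inverse_transform(self, Z):
        check_is_fitted(self, "mu_")
        Z = np.asarray(Z, dtype=float)
        if self.mode == "zscore":
            return Z * self.sigma_ + self.mu_
        if self.mode == "ratio":
            return Z * self.baseline_
        return Z * self.iqr_ + self.median_

    def partial_update(self, x):
        """EMA baseline update with one new observation (ratio-mode reference)."""
        check_is_fitted(self, "baseline_")
        self.baseline_ = ema_update(self.baseline_, x, self.ema_alpha)
        return self


# ---------------------------------------------------------------------------
# Feature selection / reduction
# ---------------------------------------------------------------------------


class OnlineFeatureSelector(BaseEstimator, TransformerMixin):
    """Lightweight online feature selection within a fixed budget.

    Drops near-zero-variance columns, ranks the remainder by mutual
    information with the target, and keeps at most ``budget`` features while
    pruning redundant ones (absolute pairwise correlation above
    ``corr_threshold`` with an already-kept feature). Ties in the MI ranking
    are broken by column index, which makes the selection deterministic.
    """

    def __init__(self, budget: int = 30, var_threshold: float = 1e-12,
                 corr_threshold: float = 0.95, random_state: int = 0):
        self.budget = budget
        self.var_threshold = var_threshold
        self.corr_threshold = corr_threshold
        self.random_state = random_state

    def fit(self, X, y):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).all(axis=0).any():
            raise ValueError("feature matrix contains all-NaN columns")
        variances = np.nanvar(X, axis=0)
        candidates = np.flatnonzero(variances > self.var_threshold)
        Xc = np.nan_to_num(X[:, candidates])
        mi = mutual_info_regression(Xc, y, random_state=self.random_state)
        order = np.argsort(-mi, kind="stable")  # index order breaks ties
        corr = np.corrcoef(Xc, rowvar=False)
        corr = np.atleast_2d(corr)
        kept: list[int] = []
        for j in order:
            if len(kept) >= self.budget:
                break
            if any(abs(corr[j, k]) > self.corr_threshold for k in kept):
                continue
            kept.append(int(j))
        self.support_ = np.sort(candidates[kept])
        self.mi_ = mi
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_features(X, y=None, budget: int = 30, mode: str = "online",
                    variance_retained: float = 0.95, random_state: int = 0):
    """Select (online) or reduce (offline) a feature matrix.

    ``mode="online"`` returns the selected column indices (variance filter +
    MI ranking + correlation pruning, at most ``budget`` columns).
    ``mode="offline"`` returns a fitted PCA retaining at least
    ``variance_retained`` cumulative variance.
    """
    if mode == "online":
        if y is None:
            raise ValueError("online selection requires a target y")
        sel = OnlineFeatureSelector(budget=budget, random_state=random_state)
        return sel.fit(X, y).support_
    if mode == "offline":
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("offline PCA requires a complete matrix")
        pca = PCA(n_components=variance_retained, svd_solver="full",
                  random_state=random_state)
        return pca.fit(X)
    raise ValueError(f"unknown mode {mode!r}")
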