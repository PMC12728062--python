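"""Calibration, filtering, sensor fusion, alignment, cleaning and segmentation.

The streaming front end of the pipeline: Butterworth filtering (zero-phase
offline, causal online), sEMG conditioning (20-450 Hz bandpass + mains notch,
rectification, low-pass envelope), gyro integration and EKF quaternion
attitude fusion, cross-correlation lag estimation, resampling onto a common
100 Hz timeline, Hampel/MAD artifact removal, Teager-Kaiser onset detection,
and trial segmentation with 200 ms sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

from aanrehab.streams import SignalStream
from aanrehab.synth import TrialSpec

#: Data-quality threshold below which a segment is downweighted in scoring.
QUALITY_TAU = 0.9


@dataclass
class FilterSpec:
    """Butterworth / notch filter specification.

    kind is one of ``lowpass, bandpass, notch``; ``cutoff_hz`` is a scalar for
    lowpass/notch and a (low, high) pair for bandpass. Notch filters are
    2nd-order IIR with quality factor ``notch_q`` (default 30).
    """

    kind: str
    cutoff_hz: float | tuple[float, float]
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        edges = np.atleast_1d(self.cutoff_hz)
        if np.any(edges <= 0):
            raise ValueError("cutoff frequencies must be positive")

    def validate_against(self, fs: float) -> None:
        edges = np.atleast_1d(self.cutoff_hz)
        if np.any(edges >= fs / 2):
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz at or above Nyquist ({fs / 2} Hz)"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate_against(fs)
        if self.kind == "notch":
            b, a = signal.iirnotch(self.cutoff_hz, self.notch_q, fs=fs)
            return signal.tf2sos(b, a)
        return signal.butter(
            self.order, self.cutoff_hz, btype=self.kind, fs=fs, output="sos"
        )


def butterworth_filter(
    x: SignalStream, spec: FilterSpec, mode: str = "offline"
) -> SignalStream:
    """Apply a Butterworth (or notch) filter to every channel.

    ``mode="offline"`` uses forward-backward (zero-phase) filtering;
    ``mode="online"`` uses a single causal pass. Lowpass filters have unit DC
    gain by construction.
    """
    if mode not in ("offline", "online"):
        raise ValueError("mode must be 'offline' or 'online'")
    sos = spec.sos(x.fs)
    filt = signal.sosfiltfilt if mode == "offline" else signal.sosfilt
    return x.copy(data=filt(sos, x.data, axis=-1))


def emg_condition(
    x: SignalStream,
    notch_hz: float = 50.0,
    envelope_hz: float = 5.0,
    mode: str = "offline",
) -> tuple[SignalStream, SignalStream]:
    """Condition raw sEMG: bandpass + notch, then rectified low-pass envelope.

    4th-order 20-450 Hz bandpass and a mains notch (default 50 Hz, Q=30),
    followed by full-wave rectification and a 2nd-order low-pass (default
    5 Hz) to obtain the activation envelope e(t), clipped to be non-negative.

    Returns
    -------
    (filtered, envelope) : pair of SignalStream
    """
    if x.modality != "emg":
        raise ValueError(f"expected emg stream, got {x.modality!r}")
    if x.fs < 900:
        raise ValueError(
            f"fs={x.fs} Hz too low for the 20-450 Hz sEMG band (need >= 900 Hz)"
        )
    band = FilterSpec("bandpass", (20.0, min(450.0, 0.49 * x.fs)), order=4)
    filtered = butterworth_filter(x, band, mode=mode)
    filtered = butterworth_filter(filtered, FilterSpec("notch", notch_hz), mode=mode)
    rect = filtered.copy(data=np.abs(filtered.data))
    env = butterworth_filter(rect, FilterSpec("lowpass", envelope_hz, order=2),
                             mode=mode)
    env = env.copy(data=np.clip(env.data, 0.0, None), modality="envelope")
    return filtered, env


def integrate_gyro(omega: SignalStream) -> SignalStream:
    """Cumulative trapezoidal integration of angular rate to angle (degrees).

    theta(t0) = 0 for every channel.
    """
    if omega.modality != "imu_gyro":
        raise ValueError(f"expected imu_gyro stream, got {omega.modality!r}")
    theta = integrate.cumulative_trapezoid(
        omega.data, dx=1.0 / omega.fs, axis=-1, initial=0.0
    )
    names = [n.replace("gyro", "angle") for n in omega.channel_names]
    return omega.copy(data=theta, modality="angle", channel_names=names)


def integrate_accel_position(
    accel: SignalStream, highpass_hz: float = 0.5
) -> SignalStream:
    """Double-integrate acceleration to position with drift removal.

    Each integration stage is followed by a 2nd-order high-pass (default
    0.5 Hz) to suppress the unbounded drift of naive double integration.
    """
    if accel.modality != "imu_accel":
        raise ValueError(f"expected imu_accel stream, got {accel.modality!r}")
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=accel.fs, output="sos")
    vel = integrate.cumulative_trapezoid(
        accel.data, dx=1.0 / accel.fs, axis=-1, initial=0.0
    )
    vel = signal.sosfiltfilt(sos, vel, axis=-1)
    pos = integrate.cumulative_trapezoid(vel, dx=1.0 / accel.fs, axis=-1, initial=0.0)
    pos = signal.sosfiltfilt(sos, pos, axis=-1)
    return accel.copy(data=pos, modality="angle",
                      channel_names=[f"pos_{c[-1]}" for c in accel.channel_names])


# ---------------------------------------------------------------------------
# Extended Kalman filter attitude fusion
# ---------------------------------------------------------------------------


@dataclass
class KalmanState:
    """State of the quaternion + gyro-bias attitude EKF.

    x = [q_w, q_x, q_y, q_z, b_x, b_y, b_z]; P is the 7x7 error covariance.
    """

    x: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0, 0, 0, 0, 0, 0])
    )
    P: np.ndarray = field(default_factory=lambda: np.eye(7) * 1e-2)
    q_proc: float = 1e-5
    r_meas: float = 1e-2

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (7, 7):
            raise ValueError("P must be 7x7")
        if not np.allclose(self.P, self.P.T, atol=1e-9):
            raise ValueError("P must be symmetric")
        if np.linalg.eigvalsh(self.P).min() < -1e-9:
            raise ValueError("P must be positive semidefinite")

    @property
    def quaternion(self) -> np.ndarray:
        return self.x[:4]

    @property
    def gyro_bias(self) -> np.ndarray:
        return self.x[4:]


def kalman_update(x, P, z, H, R):
    """One linear Kalman measurement update (gain, posterior state/covariance).

    x_post = x + K (z - H x),  K = P H' (H P H' + R)^-1, Joseph-form covariance.
    """
    x, P, z, H, R = (np.asarray(a, dtype=float) for a in (x, P, z, H, R))
    S = H @ P @ H.T + R
    K = P @ H.T @ np.linalg.inv(S)
    x_post = x + K @ (z - H @ x)
    IKH = np.eye(P.shape[0]) - K @ H
    P_post = IKH @ P @ IKH.T + K @ R @ K.T
    return x_post, P_post, K


def _quat_xi(q: np.ndarray) -> np.ndarray:
    """4x3 matrix with dq/dt = 0.5 * Xi(q) @ omega."""
    w, x, y, z = q
    return np.array([[-x, -y, -z], [w, -z, y], [z, w, -x], [-y, x, w]])


def _gravity_in_sensor(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([2 * (x * z - w * y), 2 * (y * z + w * x),
                     w * w - x * x - y * y + z * z])


def _gravity_jacobian(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [-2 * y, 2 * z, -2 * w, 2 * x],
            [2 * x, 2 * w, 2 * z, 2 * y],
            [2 * w, -2 * x, -2 * y, 2 * z],
        ]
    )


def quat_to_euler_deg(q: np.ndarray) -> tuple[float, float]:
    """Roll and pitch (degrees) of a unit quaternion (aerospace convention)."""
    w, x, y, z = q
    roll = np.arctan2(2 * (w * x + y * z), 1 - 2 * (x * x + y * y))
    pitch = np.arcsin(np.clip(2 * (w * y - x * z), -1.0, 1.0))
    return float(np.rad2deg(roll)), float(np.rad2deg(pitch))


def ekf_attitude(
    gyro: SignalStream,
    accel: SignalStream,
    state0: KalmanState | None = None,
) -> tuple[SignalStream, KalmanState]:
    """Fuse gyroscope and accelerometer into drift-corrected attitude angles.

    Predict: quaternion propagation of the bias-corrected gyro rates (deg/s).
    Update: normalized accelerometer as a gravity-direction measurement.
    The quaternion is renormalized after every step. Returns a two-channel
    ``angle`` stream (roll, pitch in degrees) and the final filter state.
    """
    if gyro.modality != "imu_gyro" or accel.modality != "imu_accel":
        raise ValueError("expected (imu_gyro, imu_accel) streams")
    if gyro.fs != accel.fs or gyro.n_samples != accel.n_samples:
        raise ValueError("gyro and accel streams must be time-aligned (same fs/length)")
    st = state0 or KalmanState()
    x, P = st.x.copy(), st.P.copy()
    dt = 1.0 / gyro.fs
    Q = np.eye(7) * st.q_proc
    R = np.eye(3) * st.r_meas

    n = gyro.n_samples
    angles = np.empty((2, n))
    omega_rad = np.deg2rad(gyro.data[:3].T)  # (n, 3)
    for k in range(n):
        q, b = x[:4], x[4:]
        w_corr = omega_rad[k] - b
        xi = _quat_xi(q)
        q_pred = q + 0.5 * dt * xi @ w_corr
        q_pred /= np.linalg.norm(q_pred)
        F = np.eye(7)
        wx, wy, wz = w_corr
        F[:4, :4] += 0.5 * dt * np.array(
            [[0, -wx, -wy, -wz], [wx, 0, wz, -wy], [wy, -wz, 0, wx],
             [wz, wy, -wx, 0]]
        )
        F[:4, 4:] = -0.5 * dt * xi
        x = np.concatenate([q_pred, b])
        P = F @ P @ F.T + Q * dt

        a = accel.data[:3, k]
        norm = np.linalg.norm(a)
        if norm > 1e-9:
            z = a / norm
            H = np.zeros((3, 7))
            H[:, :4] = _gravity_jacobian(x[:4])
            innov = z - _gravity_in_sensor(x[:4])
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ innov
            IKH = np.eye(7) - K @ H
            P = IKH @ P @ IKH.T + K @ R @ K.T
        x[:4] /= np.linalg.norm(x[:4])
        P = 0.5 * (P + P.T)
        angles[:, k] = quat_to_euler_deg(x[:4])

    out = SignalStream(angles, fs=gyro.fs, modality="angle", t0=gyro.t0,
                       channel_names=["roll", "pitch"])
    return out, KalmanState(x=x, P=P, q_proc=st.q_proc, r_meas=st.r_meas)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def estimate_lag(e: SignalStream, speed: SignalStream, max_lag: float) -> float:
    """Propagation lag between two streams by normalized cross-correlation.

    Returns the delay Delta-t* (seconds) that maximizes the normalized
    cross-correlation of the first channels over lags in [-max_lag, max_lag];
    positive when ``speed`` lags ``e``. Ties are broken toward the smallest
    absolute lag.
    """
    if e.fs != speed.fs:
        raise ValueError("streams must share a sampling rate (resample first)")
    a, b = e.data[0], speed.data[0]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant signal: cross-correlation undefined")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    max_shift = int(round(max_lag * e.fs))
    full = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags) <= max_shift
    full, lags = full[keep], lags[keep]
    best = full.max()
    candidates = lags[np.isclose(full, best, rtol=0, atol=1e-9 * abs(best) + 1e-12)]
    lag = candidates[np.argmin(np.abs(candidates))]
    return float(lag) / e.fs


def resample_align(
    streams: list[SignalStream],
    target_fs: float = 100.0,
    hold: list[bool] | None = None,
    lags: list[float] | None = None,
) -> list[SignalStream]:
    """Resample streams onto a shared uniform timeline.

    Continuous channels are linearly interpolated; streams flagged in ``hold``
    use zero-order hold (for event/logical channels). ``lags`` (seconds per
    stream, e.g. from :func:`estimate_lag`) are subtracted from each stream's
    timestamps before interpolation to phase-align fast channels.
    """
    if not streams:
        raise ValueError("no streams to align")
    hold = hold or [False] * len(streams)
    lags = lags or [0.0] * len(streams)
    t_starts, t_ends = [], []
    for s, lag in zip(streams, lags):
        t_starts.append(s.t0 - lag)
        t_ends.append(s.t0 - lag + (s.n_samples - 1) / s.fs)
    t0, t1 = max(t_starts), min(t_ends)
    if t1 <= t0:
        raise ValueError("streams have no overlapping time range")
    t_new = t0 + np.arange(int(np.floor((t1 - t0) * target_fs)) + 1) / target_fs

    out = []
    for s, zoh, lag in zip(streams, hold, lags):
        t_old = s.times - lag
        if zoh:
            idx = np.searchsorted(t_old, t_new + 1e-12, side="right") - 1
            data = s.data[:, np.clip(idx, 0, s.n_samples - 1)]
        else:
            data = np.vstack([np.interp(t_new, t_old, ch) for ch in s.data])
        out.append(s.copy(data=data, fs=target_fs, t0=float(t_new[0])))
    return out


# ---------------------------------------------------------------------------
# Artifact cleaning
# ---------------------------------------------------------------------------

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


def hampel_clean(
    x: SignalStream,
    half_window: int = 5,
    n_mad: float = 4.0,
    max_gap_frac: float = 0.10,
) -> tuple[SignalStream, np.ndarray]:
    """Windowed Hampel/MAD outlier replacement with short-gap interpolation.

    Samples deviating from the rolling window median by more than ``n_mad``
    robust standard deviations (MAD * 1.4826) are replaced by that median;
    replacement is iterated to a fixed point (a few passes at most), which
    makes the cleaner idempotent. NaN gaps no longer than ``max_gap_frac`` of
    the signal are linearly interpolated; longer gaps are interpolated too
    but the stream is flagged low quality (warning). Returns the cleaned
    stream and a boolean mask of touched samples; quality
    Q = 1 - mask.mean() per stream.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    data = x.data.copy()
    mask = np.zeros_like(data, dtype=bool)
    win = 2 * half_window + 1
    for ci, ch in enumerate(data):
        nan = ~np.isfinite(ch)
        if nan.any():
            runs = _runs(nan)
            if max(e - s for s, e in runs) > max_gap_frac * ch.size:
                warnings.warn(
                    "gap exceeds 10% of segment; flagged low-quality", stacklevel=2
                )
            good = ~nan
            ch[nan] = np.interp(np.flatnonzero(nan), np.flatnonzero(good), ch[good])
            mask[ci, nan] = True
        for _ in range(5):
            padded = np.pad(ch, half_window, mode="edge")
            windows = np.lib.stride_tricks.sliding_window_view(padded, win)
            med = np.median(windows, axis=-1)
            mad = np.median(np.abs(windows - med[:, None]), axis=-1)
            thresh = n_mad * _MAD_TO_SD * mad
            out = np.abs(ch - med) > np.maximum(thresh, 1e-12)
            if not out.any():
                break
            ch[out] = med[out]
            mask[ci, out] |= True
        data[ci] = ch
    return x.copy(data=data), mask


def quality_score(mask: np.ndarray) -> float:
    """Fraction of valid (untouched) samples, Q in [0, 1]."""
    return float(1.0 - np.mean(mask))


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where ``flags`` is True."""
    if not flags.any():
        return [(0, 0)]
    edges = np.diff(flags.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(flags.size)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# Onset detection and windowing
# ---------------------------------------------------------------------------


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator Psi[x](n) = x(n)^2 - x(n-1) x(n+1).

    Output has the same length as the input; the two edge samples replicate
    their neighbors.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("signal shorter than 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0], psi[-1] = psi[1], psi[-2]
    return psi


def tkeo_onset(
    x: SignalStream,
    threshold_k: float = 8.0,
    min_consecutive: int = 10,
    baseline_s: float = 0.5,
    smooth_ms: float = 10.0,
) -> list[float]:
    """Energy-burst onsets via TKEO with adaptive baseline thresholding.

    The TKEO trace is lightly smoothed (moving average over ``smooth_ms``) and
    compared against baseline_mean + k * baseline_sd, where the baseline is
    the first ``baseline_s`` seconds. An onset is declared at the start of
    every maximal run of at least ``min_consecutive`` supra-threshold
    samples. Returns onset times in seconds.
    """
    if x.n_channels != 1:
        raise ValueError("tkeo_onset expects a single-channel stream")
    psi = tkeo(x.data[0])
    win = max(1, int(round(smooth_ms / 1000.0 * x.fs)))
    if win > 1:
        psi = np.convolve(psi, np.ones(win) / win, mode="same")
    n_base = max(int(round(baseline_s * x.fs)), 2)
    base = psi[:n_base]
    thresh = base.mean() + threshold_k * base.std()
    above = psi > thresh
    onsets = []
    for start, end in _runs(above):
        if end - start >= min_consecutive:
            onsets.append(x.t0 + start / x.fs)
    return onsets


@dataclass
class Window:
    """Half-open sample-index window [start, end) inside a segment."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TaskSegment:
    """One functional trial (reach-grasp-release), delimited by the VR log."""

    trial_id: int
    start: int
    end: int
    windows: list[Window] = field(default_factory=list)
    quality: float = 1.0

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def segment_and_window(
    x: SignalStream,
    trial_log: list[TrialSpec],
    window_ms: float = 200.0,
    overlap: float = 0.5,
) -> list[TaskSegment]:
    """Cut a stream into per-trial segments tiled with sliding windows.

    One :class:`TaskSegment` per trial (half-open [t_start, t_end)); windows of
    ``window_ms`` with the given fractional overlap tile each segment and
    never cross its boundaries. A segment shorter than one window yields zero
    windows with a warning.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    t_end_stream = x.t0 + x.n_samples / x.fs
    segments = []
    for tr in trial_log:
        if tr.t_start < x.t0 - 1e-9 or tr.t_end > t_end_stream + 1e-9:
            raise ValueError(
                f"trial {tr.trial_id} [{tr.t_start}, {tr.t_end}) outside stream range"
            )
        i0 = int(round((tr.t_start - x.t0) * x.fs))
        i1 = int(round((tr.t_end - x.t0) * x.fs))
        length = int(round(window_ms / 1000.0 * x.fs))
        step = max(int(round(length * (1.0 - overlap))), 1)
        seg = TaskSegment(trial_id=tr.trial_id, start=i0, end=i1)
        n = i1 - i0
        if length > n:
            warnings.warn(
                f"window ({length} samples) longer than segment ({n}); "
                "segment yields zero windows",
                stacklevel=2,
            )
        else:
            for k in range((n - length) // step + 1):
                seg.windows.append(
                    Window(start=i0 + k * step, end=i0 + k * step + length)
                )
        segments.append(seg)
    return segments
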