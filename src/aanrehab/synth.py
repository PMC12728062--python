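"""Virtual patients and synthetic multimodal recordings.

Generates the raw material every downstream stage consumes: reach-grasp-release
joint-angle trajectories (minimum-jerk point-to-point profiles with
impairment-dependent range and 4-12 Hz tremor), band-limited
activation-modulated sEMG with antagonist co-contraction and optional mains
interference, Fitts-style trial logs, and longitudinal 20-session courses with
clinical anchor scores.

A :class:`VirtualPatient` holds latent parameters (motor capability, calibrated
range of motion, tremor amplitude, antagonist coupling, performance noise,
per-session learning rate). Movement quality on a trial follows a logistic
response in capability, assistance and task difficulty,

    q = clip(sigma(b0 + b1*c + b2*u - b3*d) + eps, 0, 1),

which scales movement amplitude and muscle activation; trial success follows a
separate logistic with a smaller assistance coefficient, reflecting that
external torque support improves movement quality more than it improves
autonomous task completion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from aanrehab.streams import SignalStream

GRAVITY = 9.81  # m/s^2

#: Movement-quality response coefficients (intercept, capability, assist, difficulty).
DEFAULT_QUALITY_BETA = (-1.5, 2.0, 1.0, 1.2)
#: Trial-success response coefficients. Task completion improves steeply with
#: training progress (motor relearning plus task familiarity), is helped only
#: marginally by external torque, and is penalized moderately by difficulty;
#: the steep capability slope is what lets success climb ~20 pp over a course
#: whose clinical score gains ~15 % of scale.
DEFAULT_SUCCESS_GAMMA = (-4.0, 7.0, 0.3, 0.5)

FMA_MAX = 66.0  # Fugl-Meyer Assessment, upper extremity
ARAT_MAX = 57.0  # Action Research Arm Test


@dataclass
class ClinicalAnchors:
    """Baseline and end-of-course clinical scale scores."""

    fma_0: float
    fma_t: float
    arat_0: float
    arat_t: float

    def __post_init__(self) -> None:
        for name, value, top in (
            ("fma_0", self.fma_0, FMA_MAX),
            ("fma_t", self.fma_t, FMA_MAX),
            ("arat_0", self.arat_0, ARAT_MAX),
            ("arat_t", self.arat_t, ARAT_MAX),
        ):
            if not 0.0 <= value <= top:
                raise ValueError(f"{name}={value} outside [0, {top}]")


@dataclass
class VirtualPatient:
    """Latent capability and response parameters of one simulated patient.

    Parameters
    ----------
    capability : float in [0, 1]
        Latent motor capability for the current session.
    rom_base : float, degrees
        Individually calibrated baseline range of motion; must be positive.
    tremor_amp : float, degrees
        Amplitude of the 4-12 Hz tremor component added to joint angle.
    cocontraction : float in [0, 1]
        Fraction of the agonist activation envelope mirrored by the antagonist.
    noise_sd : float
        Trial-to-trial performance noise (sd of the additive term on quality);
        also scales sensor noise in the generated streams.
    learn_rate : float
        Per-session capability gain of the linear improvement rule.
    anchors : ClinicalAnchors
        Baseline / week-4 FMA-UE and ARAT scores.
    subject_id : str
    """

    capability: float = 0.45
    rom_base: float = 60.0
    tremor_amp: float = 1.0
    cocontraction: float = 0.3
    noise_sd: float = 0.04
    learn_rate: float = 0.015
    anchors: ClinicalAnchors = field(
        default_factory=lambda: ClinicalAnchors(30.0, 40.0, 20.0, 28.0)
    )
    subject_id: str = "S00"
    quality_beta: tuple[float, float, float, float] = DEFAULT_QUALITY_BETA
    success_gamma: tuple[float, float, float, float] = DEFAULT_SUCCESS_GAMMA

    def __post_init__(self) -> None:
        if not 0.0 <= self.capability <= 1.0:
            raise ValueError(f"capability={self.capability} outside [0, 1]")
        if not 0.0 <= self.cocontraction <= 1.0:
            raise ValueError(f"cocontraction={self.cocontraction} outside [0, 1]")
        if self.rom_base <= 0:
            raise ValueError("rom_base must be positive")
        if self.tremor_amp < 0 or self.noise_sd < 0:
            raise ValueError("tremor_amp and noise_sd must be non-negative")

    def quality(self, u: float, d: float) -> float:
        """Noise-free movement quality under assistance ``u``, difficulty ``d``."""
        b0, b1, b2, b3 = self.quality_beta
        return _sigmoid(b0 + b1 * self.capability + b2 * u - b3 * d)

    def success_probability(self, u: float, d: float) -> float:
        """Probability of completing a trial under assistance ``u``, difficulty ``d``."""
        g0, g1, g2, g3 = self.success_gamma
        return _sigmoid(g0 + g1 * self.capability + g2 * u - g3 * d)

    def evolved(self, n_sessions: int = 1) -> "VirtualPatient":
        """Patient after ``n_sessions`` applications of the linear learning rule."""
        c = float(np.clip(self.capability + self.learn_rate * n_sessions, 0.0, 1.0))
        return with_capability(self, c)


def with_capability(patient: VirtualPatient, capability: float) -> VirtualPatient:
    """Patient at a new capability, with impairment features co-evolved.

    Tremor amplitude and antagonist co-contraction are signs of impairment
    that recede as motor capability recovers; they scale with the residual
    impairment (1 - c), so a patient reaching c = 1 is tremor-free with no
    pathological co-contraction. This longitudinal coupling is what makes
    recovery observable in the signal features independently of assistance.
    """
    c_new = float(np.clip(capability, 0.0, 1.0))
    if patient.capability >= 1.0:
        scale = 1.0
    else:
        scale = (1.0 - c_new) / (1.0 - patient.capability)
    return replace(
        patient,
        capability=c_new,
        tremor_amp=patient.tremor_amp * scale,
        cocontraction=float(min(1.0, patient.cocontraction * scale)),
    )


@dataclass
class TrialSpec:
    """One Fitts-style reach-grasp-release trial.

    distance_D and width_W are the target distance and width in cm; duration_T
    is the movement time in seconds.
    """

    trial_id: int
    distance_D: float
    width_W: float
    duration_T: float
    t_start: float
    t_end: float
    success: bool = False

    def __post_init__(self) -> None:
        if self.distance_D <= 0 or self.width_W <= 0 or self.duration_T <= 0:
            raise ValueError("D, W and T must all be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass
class CourseConfig:
    """Layout of a longitudinal training course (default: 20 sessions)."""

    n_sessions: int = 20
    trials_per_session: int = 16
    window_ms: int = 200
    seed: int = 0
    emg_fs: float = 1000.0
    imu_fs: float = 100.0
    n_emg_channels: int = 2
    rest_s: float = 0.5  # inter-trial gap

    def __post_init__(self) -> None:
        if min(self.n_sessions, self.trials_per_session, self.window_ms) <= 0:
            raise ValueError("all counts must be positive")


def _sigmoid(x) -> float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def minimum_jerk_position(t: np.ndarray, duration: float) -> np.ndarray:
    """Normalized minimum-jerk position profile, 0 -> 1 over ``duration``."""
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_velocity(t: np.ndarray, duration: float) -> np.ndarray:
    """Time derivative of :func:`minimum_jerk_position` (peak 1.875/duration)."""
    tau = np.asarray(t, dtype=float) / duration
    v = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    return np.where((tau < 0) | (tau > 1), 0.0, v)


def reach_angle_profile(t: np.ndarray, t_start: float, t_end: float,
                        amplitude: float) -> np.ndarray:
    """Joint angle of one reach-grasp-release cycle in degrees.

    Minimum-jerk rise over the first 40 % of the trial, hold for 20 %, and
    minimum-jerk return over the final 40 %; peak-to-peak excursion equals
    ``amplitude`` exactly.
    """
    t = np.asarray(t, dtype=float)
    total = t_end - t_start
    rise, hold = 0.4 * total, 0.2 * total
    rel = t - t_start
    out = amplitude * minimum_jerk_position(rel, rise)
    back = amplitude * (1.0 - minimum_jerk_position(rel - rise - hold, rise))
    return np.where(rel < rise + hold, out, back) * ((rel >= 0) & (rel <= total))


def _trapezoid_consistent_rate(theta: np.ndarray, fs: float,
                               v0: float = 0.0) -> np.ndarray:
    """Rate signal whose trapezoidal integral reproduces ``theta`` exactly.

    Solves (g[n] + g[n+1]) / 2 * dt = theta[n+1] - theta[n] for g, so that
    cumulative trapezoidal integration of the returned gyro signal recovers
    the angle trajectory to machine precision.
    """
    d = 2.0 * np.diff(theta) * fs
    signs = (-1.0) ** np.arange(1, theta.size)
    h = v0 + np.concatenate([[0.0], np.cumsum(signs * d)])
    return h * (-1.0) ** np.arange(theta.size)


def _band_limited_noise(n: int, fs: float, low: float, high: float,
                        rng: np.random.Generator, order: int = 4) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def _timeline(trials: list[TrialSpec], fs: float, rest_s: float) -> np.ndarray:
    t_max = max(tr.t_end for tr in trials) + rest_s
    return np.arange(int(round(t_max * fs))) / fs


def _per_trial_quality(patient: VirtualPatient, trials: list[TrialSpec],
                       performance) -> np.ndarray:
    if performance is None:
        return np.full(len(trials), patient.capability, dtype=float)
    performance = np.asarray(performance, dtype=float)
    if performance.shape != (len(trials),):
        raise ValueError("performance must give one value per trial")
    return performance


def gen_imu_stream(
    patient: VirtualPatient,
    trials: list[TrialSpec],
    fs: float = 100.0,
    rng: np.random.Generator | int | None = None,
    performance=None,
) -> tuple[SignalStream, SignalStream]:
    """Synthesize gyroscope and accelerometer streams for a list of trials.

    The underlying joint angle is a minimum-jerk reach-hold-return profile per
    trial whose amplitude is ``performance * rom_base`` (``performance``
    defaults to the patient's capability), plus band-limited 4-12 Hz tremor of
    amplitude ``tremor_amp`` and additive sensor noise scaled by ``noise_sd``.
    The motion is a rotation about the sensor x axis, so ``gyro_x`` carries the
    joint angular velocity (deg/s) and the accelerometer reads the rotated
    gravity vector (m/s^2).

    Returns
    -------
    (gyro, accel) : pair of SignalStream
    """
    if not trials:
        raise ValueError("trial list is empty")
    if fs < 50:
        raise ValueError(f"fs={fs} Hz below the 50 Hz minimum for IMU synthesis")
    rng = np.random.default_rng(rng)
    quality = _per_trial_quality(patient, trials, performance)

    t = _timeline(trials, fs, rest_s=0.5)
    theta = np.zeros_like(t)
    for tr, q in zip(trials, quality):
        theta += reach_angle_profile(t, tr.t_start, tr.t_end, q * patient.rom_base)

    tremor = np.zeros_like(t)
    if patient.tremor_amp > 0:
        if fs / 2 <= 12:
            warnings.warn(
                f"fs={fs} Hz below tremor Nyquist; tremor omitted", stacklevel=2
            )
        else:
            tremor = _band_limited_noise(t.size, fs, 4.0, min(12.0, 0.45 * fs), rng)
            tremor *= patient.tremor_amp / (np.sqrt(2.0) * max(tremor.std(), 1e-12))

    theta_total = theta + tremor
    gyro_signal = _trapezoid_consistent_rate(theta_total, fs)

    gyro_noise_sd = 2.0 * patient.noise_sd  # deg/s
    gyro = np.vstack(
        [
            gyro_signal + gyro_noise_sd * rng.standard_normal(t.size),
            gyro_noise_sd * rng.standard_normal(t.size),
            gyro_noise_sd * rng.standard_normal(t.size),
        ]
    )

    theta_rad = np.deg2rad(theta_total)
    accel_noise_sd = 0.05 * GRAVITY * patient.noise_sd
    accel = np.vstack(
        [
            np.zeros_like(t),
            GRAVITY * np.sin(theta_rad),
            GRAVITY * np.cos(theta_rad),
        ]
    ) + accel_noise_sd * rng.standard_normal((3, t.size))

    names_g = ["gyro_x", "gyro_y", "gyro_z"]
    names_a = ["accel_x", "accel_y", "accel_z"]
    return (
        SignalStream(gyro, fs=fs, modality="imu_gyro", channel_names=names_g),
        SignalStream(accel, fs=fs, modality="imu_accel", channel_names=names_a),
    )


def activation_envelope(t: np.ndarray, trials: list[TrialSpec],
                        levels: np.ndarray) -> np.ndarray:
    """Agonist activation envelope: a smooth bump per trial, peak = level."""
    env = np.zeros_like(t)
    for tr, level in zip(trials, levels):
        total = tr.t_end - tr.t_start
        rel = (t - tr.t_start) / total
        bump = np.sin(np.pi * np.clip(rel, 0.0, 1.0)) ** 2
        env = np.maximum(env, level * bump)
    return env


def gen_emg_stream(
    patient: VirtualPatient,
    trials: list[TrialSpec],
    fs: float = 1000.0,
    n_channels: int = 2,
    rng: np.random.Generator | int | None = None,
    performance=None,
    assist: float = 0.0,
    line_amp: float = 0.0,
    line_hz: float = 50.0,
    noise_floor: float = 0.02,
) -> SignalStream:
    """Synthesize a multichannel sEMG stream.

    Each channel is Gaussian noise band-limited to 20-450 Hz, amplitude
    modulated by an activation envelope synchronized to trial phases. Even
    channels are agonists; odd channels are antagonists receiving the agonist
    envelope scaled by the patient's co-contraction ratio. External assistance
    reduces the voluntary drive needed for the same movement, so activation
    shrinks by the relief factor (1 - 0.4 ``assist``). An optional mains
    component (default 50 Hz) is added at amplitude ``line_amp``.
    """
    if not trials:
        raise ValueError("trial list is empty")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if n_channels < 2 and patient.cocontraction > 0:
        raise ValueError(
            "co-contraction requires an antagonist channel (n_channels >= 2)"
        )
    if fs < 1000:
        warnings.warn(
            f"fs={fs} Hz is below the recommended 1000 Hz for sEMG", stacklevel=2
        )
    rng = np.random.default_rng(rng)
    quality = _per_trial_quality(patient, trials, performance)

    t = _timeline(trials, fs, rest_s=0.5)
    # activation scales with movement quality, relieved by assistance
    levels = (0.2 + 0.8 * quality) * (1.0 - 0.4 * float(np.clip(assist, 0, 1)))
    env_ag = activation_envelope(t, trials, levels)
    env_ant = patient.cocontraction * env_ag

    high = min(450.0, 0.49 * fs)
    data = np.empty((n_channels, t.size))
    for ch in range(n_channels):
        carrier = _band_limited_noise(t.size, fs, 20.0, high, rng)
        carrier /= max(carrier.std(), 1e-12)
        env = env_ag if ch % 2 == 0 else env_ant
        gain = 1.0 if ch < 2 else float(rng.uniform(0.7, 1.0))
        data[ch] = carrier * (noise_floor + gain * env)
    if line_amp > 0:
        data += line_amp * np.sin(2 * np.pi * line_hz * t)

    names = [f"ch_{i:02d}" for i in range(n_channels)]
    return SignalStream(data, fs=fs, modality="emg", channel_names=names)


def make_trials(
    rng: np.random.Generator,
    n_trials: int,
    difficulty: float = 0.4,
    t0: float = 0.0,
    rest_s: float = 0.5,
) -> list[TrialSpec]:
    """Draw Fitts-style trial parameters for one session at VR difficulty ``d``.

    The scalar difficulty d in [0, 1] maps linearly onto the task attribute
    ranges: target diameter 15 -> 5 cm, reach distance 20 -> 50 cm; movement
    time grows with the resulting Fitts index of difficulty.
    """
    d = float(np.clip(difficulty, 0.0, 1.0))
    trials = []
    t = t0
    for k in range(n_trials):
        width = 15.0 - 10.0 * d + rng.uniform(-1.0, 1.0)
        dist = 20.0 + 30.0 * d + rng.uniform(-3.0, 3.0)
        width = max(width, 2.0)
        fitts_id = np.log2(dist / width + 1.0)
        duration = float(np.clip(1.5 + 0.8 * fitts_id + rng.uniform(-0.3, 0.3),
                                 1.5, 6.0))
        trials.append(
            TrialSpec(
                trial_id=k,
                distance_D=float(dist),
                width_W=float(width),
                duration_T=duration,
                t_start=t,
                t_end=t + duration,
            )
        )
        t += duration + rest_s
    return trials


@dataclass
class SessionBundle:
    """Signals, trial log and latent state of one synthetic session."""

    session: int
    capability: float
    assist: float
    difficulty: float
    trials: list[TrialSpec]
    quality: np.ndarray  # per-trial realized movement quality
    emg: SignalStream
    gyro: SignalStream
    accel: SignalStream


@dataclass
class SyntheticCourse:
    """A full longitudinal course of synthetic sessions plus clinical anchors."""

    patient: VirtualPatient
    config: CourseConfig
    sessions: list[SessionBundle]

    @property
    def anchors(self) -> ClinicalAnchors:
        return self.patient.anchors

    @property
    def capabilities(self) -> np.ndarray:
        return np.array([s.capability for s in self.sessions])


def gen_course(
    patient: VirtualPatient,
    config: CourseConfig | None = None,
    assist_schedule=None,
    difficulty_schedule=None,
) -> SyntheticCourse:
    """Generate a longitudinal course of synthetic sessions.

    Capability improves linearly between sessions, c_{s+1} = c_s + learn_rate,
    clipped to [0, 1], with tremor and co-contraction receding in proportion
    to the residual impairment. Assistance and difficulty follow session
    schedules emulating a typical 4-week progression (assistance tapered
    0.7 -> 0.4, difficulty raised 0.3 -> 0.6, with small per-session jitter)
    unless explicit schedules are supplied. Clinical anchors are attached at
    sessions 1 and n_sessions via the patient's ``anchors``.
    """
    config = config or CourseConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_sessions
    frac = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    if assist_schedule is None:
        assist_schedule = np.clip(
            0.7 - 0.3 * frac + rng.uniform(-0.08, 0.08, n), 0.0, 1.0
        )
    if difficulty_schedule is None:
        difficulty_schedule = np.clip(
            0.3 + 0.3 * frac + rng.uniform(-0.05, 0.05, n), 0.0, 1.0
        )

    sessions = []
    for s in range(n):
        cap = float(np.clip(patient.capability + patient.learn_rate * s, 0.0, 1.0))
        p_s = with_capability(patient, cap)
        u, d = float(assist_schedule[s]), float(difficulty_schedule[s])
        trials = make_trials(rng, config.trials_per_session, difficulty=d,
                             rest_s=config.rest_s)
        base_q = p_s.quality(u, d)
        quality = np.clip(
            base_q + patient.noise_sd * rng.standard_normal(len(trials)), 0.0, 1.0
        )
        for tr in trials:
            tr.success = trial_success(p_s, u, d, rng)
        emg = gen_emg_stream(p_s, trials, fs=config.emg_fs,
                             n_channels=config.n_emg_channels, rng=rng,
                             performance=quality, assist=u)
        gyro, accel = gen_imu_stream(p_s, trials, fs=config.imu_fs, rng=rng,
                                     performance=quality)
        sessions.append(
            SessionBundle(
                session=s + 1, capability=cap, assist=u, difficulty=d,
                trials=trials, quality=quality, emg=emg, gyro=gyro, accel=accel,
            )
        )
    return SyntheticCourse(patient=patient, config=config, sessions=sessions)


def trial_success(patient: VirtualPatient, u: float, d: float,
                  rng: np.random.Generator, rule: str = "logistic") -> bool:
    """Draw one trial's success outcome.

    ``rule="logistic"`` (default) draws from the dedicated success model;
    ``rule="threshold"`` declares success when noisy movement quality reaches
    0.5, tying success deterministically to the quality response.
    """
    if rule == "threshold":
        q = patient.quality(u, d) + patient.noise_sd * rng.standard_normal()
        return bool(np.clip(q, 0.0, 1.0) >= 0.5)
    if rule != "logistic":
        raise ValueError(f"unknown success rule {rule!r}")
    return bool(rng.random() < patient.success_probability(u, d))


def reference_improving_patient() -> VirtualPatient:
    """Mild-to-moderate improving patient used in closed-loop course studies.

    Capability 0.62 (FMA-UE ~ 41), learning ~0.1-0.15 capability over a
    20-session course once attenuated by the proximal-development kernel —
    matching the clinically reported gain band.
    """
    return VirtualPatient(capability=0.62, rom_base=60.0, tremor_amp=1.22,
                          cocontraction=0.34, noise_sd=0.04, learn_rate=0.03,
                          subject_id="demo")


def reference_steady_patient() -> VirtualPatient:
    """Static patient (no learning) at the capability where the score target
    band is reachable at interior assistance; used for settling studies."""
    return VirtualPatient(capability=0.70, rom_base=60.0, tremor_amp=0.96,
                          cocontraction=0.27, noise_sd=0.04, learn_rate=0.0,
                          subject_id="steady")


def make_cohort(
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
    n_sessions: int = 20,
    learn_rate: tuple[float, float] = (0.01, 0.02),
) -> list[VirtualPatient]:
    """Draw a cohort of virtual patients with realistic parameter spreads.

    Baseline capability is uniform on [0.25, 0.75], spanning the mild-to-
    severe impairment band admitted to robot-assisted training (FMA-UE
    roughly 15-50 of 66). Learning rates are uniform on ``learn_rate``, and
    clinical anchors are noisy linear mappings of the capability trajectory
    onto the FMA-UE (0-66) and ARAT (0-57) scales. Tremor amplitude and
    co-contraction scale with the residual impairment (1 - c0): more impaired
    patients present stronger tremor and antagonist coupling, as in clinical
    populations.
    """
    rng = np.random.default_rng(rng)
    cohort = []
    for i in range(n_subjects):
        c0 = rng.uniform(0.25, 0.75)
        lr = rng.uniform(*learn_rate)
        c_t = float(np.clip(c0 + lr * (n_sessions - 1), 0.0, 1.0))
        fma_0 = float(np.clip(FMA_MAX * c0 + rng.normal(0, 1.5), 5, FMA_MAX))
        fma_t = float(np.clip(FMA_MAX * c_t + rng.normal(0, 1.5), fma_0, FMA_MAX))
        arat_0 = float(np.clip(ARAT_MAX * c0 + rng.normal(0, 1.5), 2, ARAT_MAX))
        arat_t = float(np.clip(ARAT_MAX * c_t + rng.normal(0, 1.5), arat_0, ARAT_MAX))
        cohort.append(
            VirtualPatient(
                capability=float(c0),
                rom_base=float(rng.uniform(50, 80)),
                tremor_amp=float(rng.uniform(1.5, 3.5) * (1.0 - c0)),
                cocontraction=float(rng.uniform(0.4, 0.9) * (1.0 - c0)),
                noise_sd=float(rng.uniform(0.02, 0.06)),
                learn_rate=float(lr),
                anchors=ClinicalAnchors(fma_0, fma_t, arat_0, arat_t),
                subject_id=f"S{i:02d}",
            )
        )
    return cohort
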