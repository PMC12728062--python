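"""Closed-loop virtual-patient simulation: perception -> score -> action.

Couples the synthetic patient, preprocessing, feature extraction, the scoring
bundle and the AAN controller into session and course simulations. Each trial
the patient executes a reach under the current assistance u and difficulty d;
the generated sEMG/IMU streams are preprocessed and featurized, scored, and
the smoothed score drives one controller update per 200 ms cycle. The patient
responds to the updated (u, d) at the next trial; between sessions capability
evolves through a zone-of-proximal-development learning rule and the session
score bias is gently recalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aanrehab.control import AANController, ControlConfig
from aanrehab.pipeline import FEATURE_NAMES, trial_feature_row
from aanrehab.scoring import ModelBundle, ScoreSmoother, bias_correct
from aanrehab.synth import (
    VirtualPatient,
    gen_emg_stream,
    gen_imu_stream,
    make_trials,
    trial_success,
    with_capability,
)

TRACE_COLUMNS = ["cycle", "t_s", "trial_id", "S_t", "S_smooth", "sigma_t",
                 "u_t", "d_t", "mode"]


@dataclass
class SessionRecord:
    """Per-cycle trace, per-trial outcomes and summaries of one session."""

    session: int
    trace: pd.DataFrame
    trials: pd.DataFrame
    target: float

    def summary(self) -> dict[str, float]:
        """Session summaries, recomputable from the traces (self-consistent)."""
        return {
            "session": self.session,
            "mean_u": float(self.trace["u_t"].mean()),
            "mean_d": float(self.trace["d_t"].mean()),
            "mean_s_smooth": float(self.trace["S_smooth"].mean()),
            "tracking_error": float(
                (self.trace["S_smooth"] - self.target).abs().mean()
            ),
            "success_rate": float(self.trials["success"].mean()),
            "n_cycles": int(len(self.trace)),
        }


@dataclass
class CourseRecord:
    """Ordered session records plus the latent capability trajectory."""

    sessions: list[SessionRecord] = field(default_factory=list)
    capabilities: list[float] = field(default_factory=list)

    def summaries(self) -> pd.DataFrame:
        return pd.DataFrame([s.summary() for s in self.sessions])


def run_session(
    patient: VirtualPatient,
    bundle: ModelBundle,
    controller: AANController,
    rng: np.random.Generator | int | None = None,
    n_trials: int = 12,
    session_index: int = 1,
    smoother: ScoreSmoother | None = None,
    emg_baseline: float | None = None,
    session_target: float | None = None,
    bias_eta: float = 0.1,
) -> SessionRecord:
    """Simulate one training session in closed loop.

    Per trial: the patient moves under the controller's current (u, d) with
    logistic movement quality plus performance noise; sEMG and IMU streams
    are generated, preprocessed and featurized; the bundle scores the trial
    and estimates uncertainty; then one control cycle runs per 200 ms of
    trial time on the exponentially smoothed score (the score holds between
    feature updates). The updated (u, d) take effect at the next trial.
    """
    bundle.check_features(FEATURE_NAMES)
    rng = np.random.default_rng(rng)
    smoother = smoother or ScoreSmoother()
    cfg = controller.config

    trace_rows, trial_rows, feature_rows = [], [], []
    cycle = 0
    t_global = 0.0
    for k in range(n_trials):
        u, d = controller.u, controller.d
        trial = make_trials(rng, 1, difficulty=d)[0]
        quality = float(np.clip(
            patient.quality(u, d) + patient.noise_sd * rng.standard_normal(),
            0.0, 1.0,
        ))
        success = trial_success(patient, u, d, rng)

        emg = gen_emg_stream(patient, [trial], rng=rng, performance=[quality],
                             assist=u)
        gyro, _ = gen_imu_stream(patient, [trial], rng=rng,
                                 performance=[quality])
        row = trial_feature_row(emg, gyro, trial, patient.rom_base)
        x = np.array([[row[name] for name in FEATURE_NAMES]])
        feature_rows.append(x[0])
        s_t = float(bundle.predict_score(x))
        sigma_t = float(np.atleast_1d(bundle.uncertainty(x))[0])

        n_cycles = max(1, int(round(trial.duration_T / cfg.cycle_s)))
        for _ in range(n_cycles):
            s_smooth = smoother.update(s_t)
            state = controller.step(
                s_smooth, sigma_t,
                emg_level=row["rms"], emg_baseline=emg_baseline,
                speed=row["v_mean_n"] * patient.rom_base,
            )
            trace_rows.append(
                (cycle, t_global, k, s_t, s_smooth,
                 sigma_t, state.u, state.d, state.mode)
            )
            cycle += 1
            t_global += cfg.cycle_s

        trial_rows.append(
            {
                "trial": k,
                "u": u,
                "d": d,
                "quality": quality,
                "success": success,
                "S_t": s_t,
                "sigma_t": sigma_t,
            }
        )

    if session_target is not None and feature_rows:
        # lightweight session-level domain adaptation: only the fusion-layer
        # bias moves, nudging the session mean score toward the target mean
        s_pred = np.atleast_1d(bundle.predict_score(np.vstack(feature_rows)))
        bundle.bias = bias_correct(bundle.bias, float(session_target),
                                   float(s_pred.mean()), eta=bias_eta)

    trace = pd.DataFrame(trace_rows, columns=TRACE_COLUMNS)
    return SessionRecord(session=session_index, trace=trace,
                         trials=pd.DataFrame(trial_rows), target=cfg.target)


def zpd_capability_update(
    capability: float,
    learn_rate: float,
    mean_difficulty: float,
    mean_assist: float,
    width: float = 0.3,
    floor: float = 0.25,
) -> float:
    """Zone-of-proximal-development learning rule between sessions.

    c_{s+1} = clip(c_s + learn_rate * (floor + (1 - floor) * K)
                         * (1 - 0.5 u_bar), 0, 1),
    K = exp(-(d_bar - c_s)^2 / (2 width^2)).

    Learning is fastest when session difficulty matches current capability
    (the proximal-development kernel K) and is attenuated by passive reliance
    on assistance. The kernel floor reflects that repetitive practice in the
    subacute recovery window produces gains even when the task is far from
    the optimal challenge point; without it, an under-challenged session
    would contribute nothing at all.
    """
    kernel = np.exp(-((mean_difficulty - capability) ** 2) / (2.0 * width**2))
    gain = learn_rate * (floor + (1.0 - floor) * kernel) * (1.0 - 0.5 * mean_assist)
    return float(np.clip(capability + gain, 0.0, 1.0))


def run_course(
    patient: VirtualPatient,
    bundle: ModelBundle,
    control_config: ControlConfig | None = None,
    n_sessions: int = 20,
    trials_per_session: int = 12,
    rng: np.random.Generator | int | None = None,
    u0: float = 0.62,
    d0: float = 0.42,
    smoothing_lam: float = 0.3,
    zpd_width: float = 0.3,
) -> CourseRecord:
    """Simulate a longitudinal course in closed loop.

    The controller state (final u, d of a session) seeds the next session's
    initial assistance and difficulty; capability evolves between sessions by
    :func:`zpd_capability_update`; the score smoother resets each session.
    """
    rng = np.random.default_rng(rng)
    controller = AANController(control_config or ControlConfig(), u0=u0, d0=d0)
    record = CourseRecord()
    current = patient
    for s in range(1, n_sessions + 1):
        record.capabilities.append(current.capability)
        session = run_session(
            current, bundle, controller, rng=rng,
            n_trials=trials_per_session, session_index=s,
            smoother=ScoreSmoother(smoothing_lam),
        )
        record.sessions.append(session)
        summary = session.summary()
        new_cap = zpd_capability_update(
            current.capability, current.learn_rate,
            summary["mean_d"], summary["mean_u"], width=zpd_width,
        )
        current = with_capability(current, new_cap)
    return record
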