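"""Assistance-as-needed dual-channel controller.

Every 200 ms control cycle the smoothed composite score drives two coupled
channels: exoskeleton assistance u_t moves opposite to performance
(u_t = clip(u_{t-1} + k_u (S* - S~_t))) and VR difficulty d_t moves with it,
so an improving patient sees assistance withdrawn and challenge raised.
Three anti-chattering constraints shape every step — a dead zone around the
target score, a per-cycle rate limit, and a hysteresis band that gates
direction reversals — plus three safety overrides: score lower-bound
protection (ramp to maximum assistance), uncertainty-triggered gain
reduction, and a physiological disengagement monitor that pauses the task.

Constraint order per step: dead zone -> gain scaling -> rate limit -> bounds
-> hysteresis gate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class ControlConfig:
    """Controller gains, thresholds and bounds.

    k_u and k_d are the assist/difficulty gains (k_d stored as a magnitude;
    set ``literal_difficulty_sign=True`` to reproduce the raw signed update
    d += k_d (S~ - S*) with k_d = -0.08, which lowers difficulty for good
    performance). ``target`` is the setpoint S* in the recommended 0.7-0.8
    challenge band.
    """

    k_u: float = 0.05
    k_d: float = 0.08
    target: float = 0.75
    r_max: float = 0.02  # max |step| per cycle
    dead_zone: float = 0.05
    theta_low: float = 0.65
    theta_high: float = 0.85
    u_min: float = 0.0
    u_max: float = 1.0
    d_min: float = 0.0
    d_max: float = 1.0
    theta_safe: float = 0.4
    sigma_thresh: float = 0.15
    cycle_s: float = 0.2
    emg_floor_frac: float = 0.10  # disengagement: sEMG below 10 % of baseline
    speed_floor: float = 2.0  # deg/s
    disengage_s: float = 5.0
    literal_difficulty_sign: bool = False

    def __post_init__(self) -> None:
        if not self.u_min < self.u_max or not self.d_min < self.d_max:
            raise ValueError("channel bounds must satisfy min < max")
        if self.r_max <= 0:
            raise ValueError("rate limit r_max must be positive")
        if not 0.0 < self.dead_zone < self.theta_high - self.theta_low:
            raise ValueError("dead zone must lie in (0, theta_high - theta_low)")
        if not 0.0 <= self.theta_low < self.theta_high <= 1.0:
            raise ValueError("hysteresis band must satisfy 0 <= low < high <= 1")


@dataclass
class ControlState:
    """Snapshot of the controller after one cycle."""

    u: float
    d: float
    mode: str = "normal"  # normal | protect | degraded_gain | paused
    assist_dir: int = 0  # last committed step direction of u (+1 / -1 / 0)
    diff_dir: int = 0
    k_u_eff: float = 0.05
    recalibrate: bool = False
    low_signal_s: float = 0.0


class AANController:
    """Stateful dual-channel assistance-as-needed controller.

    Call :meth:`step` once per control cycle with the smoothed score and
    (optionally) the score uncertainty and physiological monitors; it returns
    the committed :class:`ControlState`. Every reachable transition obeys the
    per-cycle rate limit, including safety-mode ramps.
    """

    def __init__(self, config: ControlConfig | None = None,
                 u0: float = 0.5, d0: float = 0.3):
        self.config = config or ControlConfig()
        c = self.config
        self.state = ControlState(
            u=float(min(max(u0, c.u_min), c.u_max)),
            d=float(min(max(d0, c.d_min), c.d_max)),
            k_u_eff=c.k_u,
        )
        self.events: list[dict] = []

    # -- channel updates -----------------------------------------------------

    def _channel_step(self, value, raw_step, lo, hi, last_dir, s_smooth,
                      reversal_band):
        """Apply rate limit, bounds and the hysteresis reversal gate."""
        c = self.config
        step = float(min(max(raw_step, -c.r_max), c.r_max))
        new_dir = 0 if step == 0 else (1 if step > 0 else -1)
        if new_dir != 0 and last_dir != 0 and new_dir != last_dir:
            low_ok, high_ok = reversal_band
            # A reversal commits only once the score has crossed the band.
            if new_dir > 0 and not (s_smooth < low_ok):
                return value, last_dir
            if new_dir < 0 and not (s_smooth > high_ok):
                return value, last_dir
        new_value = float(min(max(value + step, lo), hi))
        if new_value != value:
            last_dir = 1 if new_value > value else -1
        return new_value, last_dir

    def update_assist(self, s_smooth: float, sigma: float = 0.0) -> ControlState:
        """One assistance-channel update u_t = clip(u + k_u (S* - S~), bounds).

        Dead zone freezes the channel within +-dead_zone of the target; high
        uncertainty (sigma > sigma_thresh) halves the effective gain; raw
        steps are clipped to the rate limit and the bounds; direction
        reversals are gated by the hysteresis band (increasing assistance
        again requires S~ < theta_low, decreasing again requires
        S~ > theta_high).
        """
        c, st = self.config, self.state
        s = float(min(max(s_smooth, 0.0), 1.0))
        k_eff = c.k_u * (0.5 if sigma > c.sigma_thresh else 1.0)
        st.k_u_eff = k_eff
        if abs(c.target - s) < c.dead_zone:
            return replace(st)
        st.u, st.assist_dir = self._channel_step(
            st.u, k_eff * (c.target - s), c.u_min, c.u_max, st.assist_dir, s,
            reversal_band=(c.theta_low, c.theta_high),
        )
        return replace(st)

    def update_difficulty(self, s_smooth: float) -> ControlState:
        """One difficulty-channel update: d rises when the score exceeds S*.

        Uses step |k_d| (S~ - S*) with the same dead zone, rate limit, bounds
        and a mirrored hysteresis gate (raising difficulty again requires
        S~ > theta_high, lowering again requires S~ < theta_low).
        ``literal_difficulty_sign`` flips the step to the raw signed form.
        """
        c, st = self.config, self.state
        s = float(min(max(s_smooth, 0.0), 1.0))
        if abs(c.target - s) < c.dead_zone:
            return replace(st)
        gain = -abs(c.k_d) if c.literal_difficulty_sign else abs(c.k_d)
        raw = gain * (s - c.target)
        # Mirrored gate: +d needs high score, -d needs low score.
        st.d, st.diff_dir = self._mirrored_step(st.d, raw, s)
        return replace(st)

    def _mirrored_step(self, value, raw_step, s_smooth):
        c, st = self.config, self.state
        step = float(min(max(raw_step, -c.r_max), c.r_max))
        new_dir = 0 if step == 0 else (1 if step > 0 else -1)
        last_dir = st.diff_dir
        if new_dir != 0 and last_dir != 0 and new_dir != last_dir:
            if new_dir > 0 and not (s_smooth > c.theta_high):
                return value, last_dir
            if new_dir < 0 and not (s_smooth < c.theta_low):
                return value, last_dir
        new_value = float(min(max(value + step, c.d_min), c.d_max))
        if new_value != value:
            last_dir = 1 if new_value > value else -1
        return new_value, last_dir

    # -- safety --------------------------------------------------------------

    def apply_safety(self, s_smooth: float, sigma: float = 0.0,
                     emg_level: float | None = None,
                     emg_baseline: float | None = None,
                     speed: float | None = None) -> str:
        """Evaluate the safety monitors and set the controller mode.

        Precedence: protect (score below theta_safe) dominates paused
        (physiological disengagement) dominates degraded_gain (high
        uncertainty). Returns the committed mode.
        """
        c, st = self.config, self.state
        low_signal = (
            emg_level is not None and emg_baseline is not None
            and speed is not None
            and emg_level < c.emg_floor_frac * emg_baseline
            and abs(speed) < c.speed_floor
        )
        st.low_signal_s = st.low_signal_s + c.cycle_s if low_signal else 0.0

        if s_smooth < c.theta_safe:
            if st.mode != "protect":
                self.events.append({"event": "protect_engaged", "s": s_smooth})
            st.mode = "protect"
        elif st.low_signal_s > c.disengage_s:
            if st.mode != "paused":
                self.events.append({"event": "paused_disengagement",
                                    "low_signal_s": st.low_signal_s})
            st.mode = "paused"
        elif sigma > c.sigma_thresh:
            st.mode = "degraded_gain"
            st.recalibrate = True
        else:
            st.mode = "normal"
        return st.mode

    # -- full cycle ----------------------------------------------------------

    def step(self, s_smooth: float, sigma: float = 0.0,
             emg_level: float | None = None,
             emg_baseline: float | None = None,
             speed: float | None = None) -> ControlState:
        """One complete control cycle: safety, then both channel updates."""
        c, st = self.config, self.state
        mode = self.apply_safety(s_smooth, sigma, emg_level, emg_baseline, speed)
        if mode == "paused":
            return replace(st)
        if mode == "protect":
            prev = st.u
            st.u = float(min(st.u + c.r_max, c.u_max))
            if st.u != prev:
                st.assist_dir = 1
            d_before = st.d
            self.update_difficulty(s_smooth)
            if st.d > d_before:  # difficulty frozen against increase
                st.d, st.diff_dir = d_before, st.diff_dir
            return replace(st)
        self.update_assist(s_smooth, sigma)
        self.update_difficulty(s_smooth)
        return replace(st)

    @property
    def u(self) -> float:
        return self.state.u

    @property
    def d(self) -> float:
        return self.state.d
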