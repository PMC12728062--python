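# Methods

This note documents the models, parameter choices and limitations behind
`aanrehab`: what the virtual-patient simulator assumes, how the scoring and
control pipeline is calibrated, and what the passing tests do and do not
establish about real data.

## 1. The virtual patient

No clinical recordings ship with the package; every evaluation runs on
synthetic patients. A `VirtualPatient` carries latent parameters:

| parameter | unit | default | meaning |
|---|---|---|---|
| `capability` c | — (0–1) | 0.45 | latent motor capability per session |
| `rom_base` | deg | 60 | individually calibrated range of motion |
| `tremor_amp` | deg | 1.0 | 4–12 Hz tremor amplitude |
| `cocontraction` | — (0–1) | 0.3 | antagonist coupling ratio |
| `noise_sd` | — | 0.04 | trial-to-trial performance noise |
| `learn_rate` | /session | 0.015 | capability gain per session |

**Movement quality.** On a trial executed under assistance u and difficulty
d, movement quality is

    q = clip( σ(β₀ + β₁ c + β₂ u − β₃ d) + ε, 0, 1 ),
    β = (−1.5, 2.0, 1.0, 1.2),  ε ~ N(0, noise_sd²).

q scales the reach amplitude (minimum-jerk rise–hold–return profile,
amplitude q·ROM_base) and the sEMG activation envelope. The β defaults give
a patient whose quality responds to capability about twice as strongly as
to assistance, with difficulty as a moderate antagonist; all four are
configurable.

**Trial success.** Success follows its own logistic model,

    P(success) = σ(γ₀ + γ₁ c + γ₂ u − γ₃ d),  γ = (−4.0, 7.0, 0.3, 0.5).

Success is deliberately *not* a function of movement quality alone: a
controller that regulates the quality-based score to a constant target
would otherwise pin the success rate at a constant too, which contradicts
how these systems behave — reported courses show success rising ~20
percentage points while the score is held at its target and difficulty
rises ~64 %. Back-solving that arithmetic (Δlogit ≈ +1.07 for Δc ≈ 0.14,
Δd ≈ +0.27, Δu ≈ −0.17) requires a steep success-versus-progress slope,
which is why γ₁ is large: task success in VR reaching reflects motor
relearning *and* task familiarity, both of which track training progress.
A threshold rule (success ⇔ q ≥ 0.5) remains available via
`trial_success(..., rule="threshold")`.

**Impairment co-evolution.** Tremor amplitude and antagonist co-contraction
are signs of impairment and recede proportionally to the residual deficit:
moving a patient to capability c′ rescales both by (1−c′)/(1−c)
(`with_capability`). Without this coupling, recovery would be nearly
invisible in the signal features whenever assistance is tapered in step
with capability gains, which is neither realistic nor learnable.

**Assistance relief.** External torque reduces the voluntary drive required
for the same movement; the sEMG activation envelope shrinks by
(1 − 0.4 u). This makes the assistance level indirectly observable from the
EMG-to-kinematics ratio, as in real recordings.

**Cohorts.** `make_cohort` draws baseline capability uniformly on
[0.25, 0.75] — the mild-to-severe band admitted to robot-assisted training
(FMA-UE roughly 15–50 of 66) — with tremor/co-contraction coefficients
scaled by the residual impairment (impairment severities correlate across
domains in clinical populations), per-session learning rates of 0.01–0.02,
and clinical anchors that are noisy linear maps of the capability
trajectory onto the FMA-UE and ARAT scales (sd 1.5 points).

**What the generator does not emulate:** volume conduction and electrode
placement variability, motor-unit physiology, spasticity and synergy
patterns, fatigue within sessions, multi-joint kinematics (one rotational
DoF drives the IMU), and non-stationary sensor artifacts beyond additive
noise and mains interference. Passing tests therefore demonstrate the
*pipeline's* correctness and closed-loop behavior under a plausible
generative model, not clinical validity.

## 2. Preprocessing

- sEMG: 4th-order 20–450 Hz Butterworth bandpass, 2nd-order notch at 50 Hz
  (Q = 30, 60 Hz selectable), full-wave rectification, 2nd-order 5 Hz
  low-pass envelope (3–10 Hz sensible range). Offline filtering is
  zero-phase (forward–backward); an online causal mode exists.
- IMU: trapezoidal gyro integration; optional quaternion + gyro-bias EKF
  (7-state, process noise 1e-5, gravity-direction measurement noise 1e-2
  per axis) that bounds drift under gyro bias. The closed-loop simulator
  integrates directly because its synthetic gyro is bias-free; the EKF is
  exercised by its own drift tests.
- Double integration of acceleration to position applies a 0.5 Hz
  high-pass after each integration stage to suppress drift.
- Artifact removal: rolling Hampel filter (half-window 5, 4 robust SDs),
  iterated to a fixed point so cleaning is idempotent; NaN gaps ≤ 10 % are
  linearly interpolated, longer gaps flag the stream low-quality
  (Q < τ = 0.9, downweighted as weight Q/τ in model fitting).
- TKEO onsets: Ψ[x](n) = x(n)² − x(n−1)x(n+1), 10 ms moving-average
  smoothing, threshold = baseline mean + 8 sd over the first 0.5 s,
  ≥ 10 consecutive supra-threshold samples.
- Windows are half-open [start, end) sample intervals; 200 ms length, 50 %
  overlap, never crossing trial-segment boundaries.

## 3. Features and normalization

The online feature vector (24 features, within the 20–40 online budget)
spans kinematics (ROMn, ROM-normalized velocity statistics, time-to-peak
velocity, LDLJ, SPARC, path efficiency, tremor ratios on angle and
velocity, dwell ratio), agonist EMG time/frequency features, the
co-contraction index, antagonist RMS, and Fitts task metrics. Two details
matter:

- **Individualized scaling.** Amplitude-dependent kinematics enter
  normalized by the calibrated ROM_base; without this, between-subject
  anatomical variation (reach amplitude) swamps the capability signal for
  held-out subjects.
- **Velocity-domain tremor ratio.** Differentiation amplifies the 4–12 Hz
  band relative to the slow voluntary movement, giving a far more
  sensitive tremor measurement than the angle-domain ratio (both are
  computed).

SPARC uses the standard definition (spectrum normalized by its peak,
adaptive cutoff at amplitude 0.05 within 0–20 Hz, 4-level zero padding);
LDLJ is −ln(T⁵/A² ∫‖jerk‖² dt) with A the peak speed, so that smoother
movements score *higher* on both metrics and both degrade monotonically
under added jitter. Welch spectra use 128-sample segments at 50 % overlap.
Mutual information uses a 16-bin plug-in histogram estimator (bits).
ZC/SSC apply a configurable noise deadband. Feature selection is
mutual-information ranking with variance filtering and |r| > 0.95
redundancy pruning online (index-order tie-break for determinism), PCA at
≥ 95 % cumulative variance offline.

## 4. Scoring and calibration

Per task, RF (200 trees, depth 8, min leaf 5) and RBF SVR (γ = 0.01,
C = 10, ε = 0.1) base learners feed a ridge meta-learner (λ = 0.5) trained
on out-of-fold predictions (GroupKFold by subject; an explicit split in
which any subject appears on both sides raises). The meta-learner is fitted
by three rounds of iteratively reweighted least squares against the Huber
objective (δ = 1 on standardized residuals) times quality weights. Task set
{FMA-UE proxy, ARAT proxy, ROMn, SPARC}; Huber task weights 0.4/0.3/0.2/0.1
by clinical relevance; composite coefficients α equal.

**Composite calibration.** The composite S = σ(a Σ α_m z_m + b) is
calibrated so that S equals the *standing of the current performance within
the reference training distribution*: (a, b) are least-squares fitted to
the empirical CDF of the weighted z-sum over the training courses. This
makes the 0.7–0.8 target band attainable mid-course at interior assistance
— the operating regime the controller needs. Calibrating (a, b) directly
against the baseline-to-healthy reference was rejected: a forest cannot
extrapolate to healthy-range features, which collapses the fit. The
interpretive reference S_ref = clip((ŷ_FMA − μ₀)/(μ_ref − μ₀), 0, 1) — μ₀
the subject's calibration-period (first three sessions) expectation,
μ_ref = 62 FMA points as the healthy-control expectation — is retained and
aligned with S by an isotonic (or Platt) calibrator for reporting.

Online, scores are exponentially smoothed (λ = 0.3, initialized at the
first observation); a session-level bias step b ← b + η(S̄ − Ŝ̄) with
η = 0.1 implements gentle domain adaptation of the fusion layer only, and
is exposed (but off by default in the simulator, which has no external
session-target series). Uncertainty is σ_t = sqrt(½ Var_trees + ½
EMA(residual²)) computed on the score scale by propagating per-tree
predictions through the composite map (a 50-tree subsample keeps the
online path cheap); with no residual history the ensemble term stands
alone. Single-row forest predictions use a direct per-tree fast path that
is numerically identical to the standard prediction.

## 5. The AAN controller

Constants (all configurable): k_u = 0.05, |k_d| = 0.08, target S* = 0.75
(recommended band 0.7–0.8), rate limit 0.02/cycle, dead zone ±0.05,
hysteresis band [0.65, 0.85], bounds [0, 1] on both channels, θ_safe = 0.4,
σ_thresh = 0.15, 200 ms cycle. Constraint order per step: dead zone → gain
scaling (uncertainty halves k_u) → rate limit → bounds → hysteresis gate.
Hysteresis is a per-channel direction latch: resuming an *increase* of
assistance after a decrease requires S̃ < 0.65, the reverse requires
S̃ > 0.85 (mirrored for difficulty). The difficulty step is
+|k_d|(S̃ − S*), i.e. difficulty rises with good performance; the literal
signed form (k_d < 0, which lowers difficulty for good scores) is available
via `literal_difficulty_sign` for comparison. Safety precedence: protect
(S̃ < 0.4; assistance ramps to maximum at the rate limit, difficulty frozen
against increase) dominates pause (sEMG < 10 % of baseline and speed
< 2°/s sustained > 5 s) dominates gain degradation (σ_t > σ_thresh, which
also flags recalibration). The scalar difficulty d maps linearly onto the
VR task attributes: target diameter 15 → 5 cm, reach distance 20 → 50 cm,
with movement time growing with the resulting Fitts index.

## 6. Closed loop and learning across sessions

Each trial the patient moves under the current (u, d); the generated
streams are preprocessed and featurized; the bundle scores the trial; one
control cycle runs per 200 ms of trial time on the smoothed score (the
score holds between feature updates, and the patient responds to the new
(u, d) at the next trial). Controller state carries across sessions;
capability evolves between sessions by a zone-of-proximal-development rule

    c ← clip(c + learn_rate · (0.25 + 0.75·K) · (1 − 0.5 ū), 0, 1),
    K = exp(−(d̄ − c)² / (2 · 0.3²)).

Learning is fastest when session difficulty matches capability and is
attenuated by passive reliance on assistance. The kernel keeps a 0.25
floor: repetitive assisted practice in the subacute window yields gains
even far from the optimal challenge point — without the floor, any session
the controller parks at low difficulty would contribute nothing and every
simulated course stalls at maximum assistance.

Standard study conditions (used by the tests and the acceptance script):
training cohort of 20 subjects × 10 sessions × 6 trials; closed-loop
courses of 20 sessions × 10 trials starting from the reported week-1
operating point (u₀ = 0.62, d₀ = 0.42) with a mild-to-moderate improving
patient (c₀ = 0.62, learn_rate 0.03 before kernel attenuation, net
capability gain ≈ 0.1–0.15 per course, matching the clinically reported
band); settling studies use a static patient at c = 0.70, for whom the
target band is reachable at interior assistance. These sizes keep the full
evaluation within minutes on one CPU while leaving every claimed effect
detectable; they are direction-level claims — magnitudes of the simulated
trends are patient-model-dependent and are not claimed to reproduce any
reported effect size.

## 7. Proxy labels and statistics

Window/trial labels interpolate the clinical anchors linearly across
sessions (FMA_s = FMA₀ + (t_s/T)(FMA_T − FMA₀)); a biomechanical
refinement scales the session value by (1 + 0.05·z̄) with z̄ the mean
within-session z-score of ROMn, SPARC and RMS (session means, and hence
inter-session monotonicity, are preserved because within-session z-scores
average to zero); a simulated expert source discretizes the truth onto a
0–10 analog scale with rater noise (synthetic stand-in; no clinician data
exists here). Sources blend by *data fraction* 80/15/5 via stratified
assignment with largest-remainder apportionment. ICC(2,1) is computed from
the two-way ANOVA mean squares (cross-checked against pingouin);
weighted kappa wraps the standard quadratic-weight computation; the paired
effect size uses Hedges' small-sample correction 1 − 3/(4(n−1)−1) with the
pooled pre/post SD; confidence intervals for mean changes use the t
distribution on paired differences; Bonferroni is the only multiplicity
correction provided (m = 5 secondary outcomes by default).

## 8. Numerical details and edge cases

- Fixed seeds make every generator, fit and simulation bit-reproducible;
  all randomness flows through `numpy.random.Generator`.
- The synthetic gyro channel is constructed to be *trapezoid-consistent*:
  cumulative trapezoidal integration recovers the ground-truth angle to
  machine precision in the noise-free case.
- Masked features are NaN; degenerate statistics (zero spread, all-zero
  windows, 0/0 co-contraction) mask rather than raise, while contract
  violations (negative envelopes, cutoff ≥ Nyquist, subject leakage,
  feature-hash mismatch between training and serving) raise.
- Scores are clipped to [0, 1] at every stage; the controller state
  respects its rate limit across every reachable transition including
  safety-mode ramps.

## 9. Known limitations

- The capability→signal link is low-dimensional; real sEMG/IMU data are
  far richer and noisier, so the reported cross-validated R² (~0.78 at
  simulation scale) should be read as "the pipeline recovers the latent
  trajectory under its own generative model", not as an expected clinical
  accuracy.
- The closed-loop score tracking error (~0.05–0.08) and trend magnitudes
  depend on the patient model's response coefficients.
- One rotational degree of freedom drives the kinematics; spatial target
  error features (target RMSE, endpoint error) are masked placeholders
  until a spatial task model exists.
- The session-level bias adaptation is implemented and tested as a
  primitive but not exercised by the course simulator, which lacks an
  external target series.
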