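# Methods

This note documents the models implemented in `ecgsim`, the numerical
choices behind the integrator and renderer, the semantics of the preset
parameters, and what the shipped configurations do and do not demonstrate.

## Models

### Heterogeneous oscillator network (`heterogeneous`, 14 states)

Three modified Van der Pol oscillators represent the natural pacemakers
(SA node, AV node, His–Purkinje system):

    dx_i/dt = y_i
    dy_i/dt = -a_i (x_i^2 - u) y_i - f_i x_i (x_i + d)(x_i + e_i)
              + K_i (y_upstream(t - tau_i) - y_i)

The damping term switches sign at |x| = sqrt(u), giving a relaxation limit
cycle; the cubic term sets the restoring force. Coupling is a one-way
delayed cascade: the SA node is autonomous (K_SA = 0), the AV node reads
the SA velocity delayed by tau_AV, and the HP system reads the AV velocity
delayed by tau_HP. Setting K_AV = 0 severs SA→AV conduction (complete
SA–AV block); K_HP = 0 severs AV→HP conduction (AV–HP block). Because the
pacemakers have different intrinsic frequencies (the AV and HP parameters
make them slower), a severed downstream node reverts to its own escape
rhythm — the mechanism behind the block presets, and the property checked
by the conduction-block test (normal: atrial and ventricular channel rates
agree within 1%; block: they separate by far more than 5%).

Four modified FitzHugh–Nagumo oscillators generate the muscle responses
(P wave, atrial repolarization Ta, QRS complex, T wave):

    dz_j/dt = k_j (-c_j z_j (z_j - w_j1)(z_j - w_j2) - b_j v_j
                   - g_j v_j z_j + I_j)
    dv_j/dt = k_j h_j (z_j - v_j)

with stimulation currents I_j = C_j Y_j H(Y_j) driven by the rectified
pacemaker velocities Y = (y_SA, -y_SA, y_HP, -y_HP). H is the unit step
with H(0) = 0: currents switch on only for strictly positive drive; the
trajectory spends measure-zero time at zero so the choice is dynamically
immaterial, but it must be fixed for bit-for-bit determinism.

The ECG of one lead is `z0 + a1 z1 - a2 z2 + a3 z3 + a4 z4`. The lead-II
weight row (1, 1, 1, 1) with z0 = 0.2 is the canonical composition; the
shipped weight rows for lead I and the precordials V1–V6 are plausible
approximations chosen to reproduce the textbook precordial QRS
progression (negative in V1, transition around V3–V4, positive in V5–V6),
and are user-overridable per preset — they are presentation coefficients,
not dynamics.

### Discretized reaction–diffusion network (`reaction_diffusion`, 4 states)

The spatial discretization of the BVAM reaction–diffusion system yields
two asymmetrically coupled two-variable oscillators:

    dx1/dt = x1 - x2 - C x1 x2 - x1 x2^2
    dx2/dt = H x1 - 3 x2 + C x1 x2 + x1 x2^2 + beta (x4 - x2)
    dx3/dt = x3 - x4 - C x3 x4 - x3 x4^2
    dx4/dt = H x3 - 3 x4 + C x3 x4 + x3 x4^2 + 2 beta (x2 - x4)

H and C select the dynamical regime, beta the interaction strength; the
ECG is the mixing `K1 x1 + K2 x2 + K3 x3 + K4 x4`. The arrhythmia presets
override only H, the K weights, and the time scale; C and beta are
inherited from the normal row.

A subtlety discovered during implementation: states with x1 = x3 and
x2 = x4 form an invariant synchronization subspace on which both coupling
terms vanish and the reduced two-variable system is only marginally stable,
so a symmetric initial state creeps back to the origin and produces a flat
record. The default initial state is therefore asymmetric,
(0.01, 0, -0.01, 0), which engages the unstable transverse mode and
converges onto the limit cycle.

### Delay-coupled oscillator ring (`ring`, 6 states)

Three modified Van der Pol oscillators (SA, AV, HP) with position/velocity
pairs (x1, x2), (x3, x4), (x5, x6):

    dx2/dt = -a x2 (x1 - w1)(x1 - w2) + rho sin(omega t)
             - x1 (x1 - d)(x1 - e)
             - k_SA-AV (x1 - x3(t - tau)) - k_SA-HP (x1 - x5(t - tau))

(and cyclically for the other nodes). The sinusoidal drive is additive —
at sin(omega t) = 1 it contributes exactly rho to the velocity equation —
and is inactive in the normal preset (all drive frequencies zero); the
ventricular-fibrillation preset switches all three drives on at
omega = 7.33, which desynchronizes the ring and produces the irregular
inter-peak intervals that trip the rate estimator's irregularity flag.
Each directed coupling k_{X-Y} names the edge *into* node X *from* node Y;
the normal cascade runs through k_AV-SA = 5 (with a 0.8 time-unit
transport delay) and k_HP-AV = 20. The HP oscillator's shape parameters
(a = 7, w = (1.65, -2), d = 3, e = 7) follow the published three-oscillator
heart model from which this family derives; the device table does not
repeat them. ECG = (alpha0 + alpha1 x1 + alpha3 x3 + alpha5 x5) * beta_G.

### Quasi-periodic Gaussian-kernel model (`quasi_periodic`, 5 states)

A planar system with an attracting unit limit cycle,

    dx/dt = alpha x - omega y,   dy/dt = alpha y + omega x,
    alpha = 1 - sqrt(x^2 + y^2),

carries the phase angle theta = atan2(y, x) around one revolution per
beat. (The rotation terms are written so that (x, y) actually rotates; a
sign slip in transcription would instead give a saddle flow with no limit
cycle, contradicting the model's defining geometry.) Each of seven events
P-, P+, Q, R, S, T-, T+ is a Gaussian kernel (a_i, b_i, theta_i) that
pushes and pulls one of three waveform channels as the phase passes it:

    dz/dt = -sum_i a_i dtheta_i exp(-dtheta_i^2 / (2 b_i^2)) - (z - z0(t))

with dtheta_i = wrap(theta - theta_i) to [-pi, pi), and the shared
baseline z0(t) = A sin(2 pi f_r t) coupled to respiration. ECG =
P + C + T. The kernel amplitudes are used exactly as tabulated; an
optional transform replaces a_i by a_i b_i^2 for parameter tables quoted
in that convention (`with_width_scaled_amplitudes`, off by default).

The angular frequency is either constant, omega = 2 pi HR / 60, or drawn
beat-by-beat from an RR-interval series with a bimodal power spectrum
(low-frequency lobe at 0.1 Hz, high-frequency/respiratory lobe at
0.25 Hz, LF/HF ratio 0.5), standardized to a requested heart-rate mean and
standard deviation and fully determined by a seed. Within each beat omega
is constant, so every beat completes exactly one revolution.

## Preset parameters

Presets are the software twin of the device's parameter tables: a model, a
rhythm name, the complete parameter set, a time-scale factor, and a target
R-peak gain in [0.5, 4] mV (the output window a bedside electrocardiograph
expects). Arrhythmia presets are stored as sparse overrides of the model's
normal row, which makes "only the listed fields differ" a testable
property. Values not printed in the arrhythmia tables are inherited from
the normal row (e.g. C and beta for the reaction–diffusion arrhythmias,
the drive amplitudes rho for the ring).

Defaults chosen where the tables are silent:

- Quasi-periodic heart rates per rhythm: normal 60, sinus bradycardia 45
  (a slow regular rhythm is one under 60 bpm), sinus tachycardia 130,
  ventricular tachycardia 150 (a ventricular rhythm faster than 120 bpm),
  ventricular flutter 270 (within the 250–300 bpm band), atrial
  fibrillation an irregular tachogram with mean 110 and sd 15 bpm
  (an irregularly irregular rhythm, clinically often 100–160 bpm). All
  overridable.
- Respiratory baseline: A = 0.005 model units, f_r = 0.25 Hz — a small
  wander at a typical resting respiratory rate.
- Output sampling rate 500 Hz (typical clinical ECG acquisition) and gain
  1 mV, both run settings.

Time-scale semantics: Gamma_t (reaction–diffusion) and beta_T (ring) are
time-compression factors — the output time axis is model time divided by
the factor, so a larger value yields a faster rhythm. This is consistent
with the tachycardia row carrying Gamma_t = 21 against the normal row's 7:
rendering the *same* trajectory under both factors changes the beat rate
by exactly 3, which is one of the acceptance checks.

## Numerics

- **Integrator.** Classical fixed-step RK4. Default step 1e-3 model time
  units for all four models. For the models without delays, halving the
  step changes a 30 s trajectory by well under 0.1% RMS (measured ~1e-6
  relative for the reaction–diffusion system, ~1e-9 for the
  quasi-periodic one). The delayed models are dominated by the O(h)
  delayed-lookup error, so halving shifts the trajectory phase by O(h)
  while leaving beat rates and morphology unchanged; the step is small
  enough that the nearest-sample delay offsets (92 samples for
  tau = 0.092, 800 for tau = 0.8) resolve the delays to ≤ 0.06%. The
  stiffest subsystem (the QRS muscle oscillator, rate constant k = 1e4)
  keeps |h·lambda| ≈ 2.4, inside the RK4 real-axis stability interval.
- **Delays.** Past samples are buffered with capacity ceil(tau_max/h);
  a delayed value is the stored sample round(tau/h) steps back, held
  frozen through the four RK4 stages of a step (the natural discipline
  for a real-time fixed-step solver). History before t0 is the constant
  initial state — the standard constant-prehistory convention for delay
  differential equations. A linearly interpolating lookup is available
  (`delay_mode="linear"`) and is used by tests to bound the cost of
  nearest-sample rounding.
- **Initial conditions.** Pacemaker-bearing models start slightly
  off-equilibrium ((0.1, 0) per oscillator pair, muscles at rest); the
  reaction–diffusion network starts at the asymmetric state discussed
  above; the quasi-periodic model starts on the limit cycle at (1, 0).
  The renderer discards a leading transient: 20% of the run, capped at
  5 s of output time, configurable.
- **Divergence.** Any non-finite state aborts integration immediately and
  reports the last finite state and time.
- **Rendering.** Composition to a scalar potential, time-axis division by
  the time-scale factor, linear interpolation onto the uniform output
  grid (the waveforms are smooth at the integration-step scale), and one
  multiplicative calibration so the largest excursion from the median
  baseline — the detected R-peak magnitude — equals the requested gain.
  A flat signal falls back to unit scale with a warning. For 12-lead
  assembly a single common scale (calibrated on lead II) multiplies all
  channels, so the Einthoven and Goldberger identities survive
  calibration exactly; electrode potentials are fixed by the zero-sum
  gauge RA + LA + LL = 0 (Wilson central terminal at zero), the unique
  choice reproducing leads I and II with a zero Wilson terminal.
- **Beat-rate estimation.** Slow baseline wander is removed with a 0.6 s
  rolling median; the dominant deflection is flipped upward; candidate
  peaks are local maxima separated by a 0.2 s refractory window; the
  detection threshold is 0.6 times the 98th percentile of candidate-peak
  amplitudes. Referencing the threshold to *peak* amplitudes rather than
  raw samples matters: a narrow R wave occupies so few samples that a raw
  98th-percentile sits near the T-wave level and double-counts beats.
  The rate is 60 over the median inter-peak interval; a coefficient of
  variation of the intervals above 0.1 marks the rhythm irregular, and
  fewer than two detected peaks marks it undefined — either condition
  raises the flag expected of fibrillation-like rhythms.
- **Serialization.** CSV uses shortest round-trip decimal representation,
  so write→read is value-exact and write→read→write byte-identical. WFDB
  records are the standard text header plus 16-bit little-endian samples;
  the per-channel gain maps the channel's range onto ±32000 counts, so
  read-back error is at most half a quantization step (bounded by one
  step in the tests); amplitudes that would clip raise instead.

## Performance

The integration loops are compiled with numba; the readable NumPy
reference derivatives in `ecgsim.models` define the equations and the two
paths are cross-checked to agree bitwise in the test suite (a pure-Python
engine built from `rk4_step` and `DelayBuffer` can be selected with
`engine="python"`). Test and acceptance runs use 30 s of rendered output
per preset (60 s for the conduction-block comparison, 10 s of model time
for the delayed-lookup oracle), sizes at which every measured property is
stable well beyond its tolerance.

## What the shipped configurations show — and what they do not

All waveforms are synthetic solutions of low-dimensional deterministic
models. They reproduce the morphological grammar of an ECG (P–QRS–T
sequencing, rate ordering across rhythms, irregularity of fibrillation,
lead algebra of a 12-lead acquisition) and are exactly reproducible, which
is what calibration and algorithm-testing workflows need. They do not
contain measurement noise, electrode artifacts, muscle tremor, or the
beat-to-beat morphological variability of real recordings (except for the
explicit respiratory baseline and the stochastic interval series of the
atrial-fibrillation preset), so a detector that performs perfectly here
may still fail on clinical data.

Known limitations:

- The absolute beat rates of the reaction–diffusion and ring families
  under their tabulated time-scale factors (for example ~43 bpm for the
  reaction–diffusion normal rhythm and ~227 bpm for the ring normal
  rhythm at 500 Hz) are set by the models' intrinsic limit-cycle periods
  and the published factors; the families are shipped for their *relative*
  rhythm structure, and the time-scale factor is the natural knob for
  retuning absolute rates.
- The 12-lead weight table beyond lead II is an approximation (see above);
  users with a reference weight set should supply it via the preset
  schema.
- The reaction–diffusion arrhythmia attractors are quasi-periodic, so
  their detected inter-peak intervals carry genuine variability; their
  irregularity flags reflect the dynamics, not detector noise.
- Only the rhythms of the published tables ship as presets; other
  conditions reachable in parameter space are accessed through parameter
  overrides (`--param`), mirroring the device's parameter-settings menu.
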