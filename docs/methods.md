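# Methods

## Model

`spikewave` implements a minimal neural mass model of the thalamocortical
loop that generates spike-wave discharges (SWDs), the EEG signature of
generalized absence seizures. Four population activities evolve as

```
dPY/dt = tau_py (h_py − PY + c1 f(PY) − c3 f(IN) + c9 f(TC))
dIN/dt = tau_in (h_in − IN + c2 f(PY))
dTC/dt = tau_tc (h_tc − TC + c7 f(PY) − c6 s(RE))
dRE/dt = tau_re (h_re − RE + c8 f(PY) + c5 s(TC) − c4 s(RE))
```

with PY cortical pyramidal, IN cortical inhibitory, TC thalamocortical
relay and RE thalamic reticular populations. `f(u) = 1/(1 + ε^{−u})`
(ε = 2.5·10⁵) is a near-step sigmoid used for the cortical compartment;
the thalamic compartment, which operates in the near-linear range of the
sigmoid, uses the affine activation `s(u) = a·u + b` (a = 2.8, b = 0.5).
A `thalamic_activation="sigmoid"` switch restores `f` there; the
qualitative picture (stable background equilibrium, bistable SWD upon
perturbation) is unchanged, which the test suite verifies.

The connectivity signs encode the physiological loop: PY self-excites
and excites IN, TC and RE; TC excites PY and RE; IN inhibits PY; RE
inhibits TC and itself. Time is in seconds; the cortical rates
(tau_py = 26, tau_in = 32.5 s⁻¹) are an order of magnitude faster than
the thalamic ones (2.6 s⁻¹), and it is this fast–slow structure that
produces the spike-then-wave morphology at ~3 Hz. The model EEG is the
mean of the two cortical activities, `(PY + IN)/2`.

Two parameter presets are shipped, differing only in the TC input
offset and the noise amplitude:

| preset | h_tc | alpha | used for |
|---|---|---|---|
| `deterministic` | −2.0 | 0 | basin slices, one-cycle stimulation scans |
| `noise` | −2.05 | 0.022 | spontaneous seizures, probabilistic maps |

All other constants are shared (c1..c9 = 1.8, 4, 1.5, 0.2, 10.5, 0.6,
3, 3, 1; h_py = −0.35, h_in = −3.4, h_re = −5).

## Integration and noise

Deterministic reference trajectories use an adaptive embedded
Runge–Kutta 4(5) pair (`scipy.integrate.solve_ivp`, rtol 1e−8,
atol 1e−10) with dense output sampled onto a uniform grid.

Stochastic runs use fixed-step Euler–Maruyama with an additive Gaussian
increment of standard deviation `alpha·sqrt(dt)` applied to the TC
component only, modelling non-specific ascending brain-stem input. All
increments come from PCG64 generators keyed by
`SeedSequence(entropy=base_seed, spawn_key=(…, trial))`, so per-trial
streams are mutually independent and invariant to evaluation order, and
a `NoisePlan` can splice two streams at a switch time — the mechanism
by which stimulation trials share their pre-stimulus noise and vary
only the post-stimulus noise.

**Step size.** The default is dt = 2·10⁻⁴ s. This value matters more
than usual: at the noise preset the SW limit cycle of the exact flow
has just undergone its fold (the cycle exists for h_tc ≳ −2.047), and
it is the mild numerical bias of the fixed-step scheme that sustains
the cycle at h_tc = −2.05. The noisy regime was therefore calibrated
against the model's target behaviour — spontaneous seizures of about
5–10 s roughly every few minutes at alpha = 0.022: at dt = 2·10⁻⁴ the
median episode duration is ≈ 6 s (IQR 4–10 s, one episode per ~7 min
over an hour of simulation); at 10⁻⁴ only 1-s bursts survive, at 10⁻³
seizures become near-permanent. Consequently every analysis that
touches the SW attractor of the noise preset (attractor landmarks,
basin scans, stimulation trials, regime classification) runs on this
same discretization; the adaptive solver is used where the exact flow
is the object of interest (deterministic preset trajectories, period
measurement, convergence tests). A convergence test verifies the
zero-noise Euler endpoint approaches the adaptive solution as dt halves.

## Background equilibrium and SW attractor

The background fixed point is found by a Powell-hybrid root search with
the analytic Jacobian, seeded at the decoupled equilibrium
(h_py, h_in, h_tc, h_re), with a relaxation-along-the-flow fallback.
A root is accepted only if ‖f‖∞ < 10⁻¹⁰ and all Jacobian eigenvalues
have negative real part; an unstable root raises a distinct error so a
saddle is never silently returned.

On-attractor states are produced by kicking both cortical populations
by −0.6 from the equilibrium (the same direction convention as
stimulation; the magnitude lies well beyond the separatrix) and
discarding a 20-s transient. EEG spike peaks are maxima above the SW
threshold separated by ≥ 0.2 s, so the slow-wave hump of a complex is
never double-counted; cycles are delimited spike peak to spike peak.
The deterministic-column cycle period is 0.337 s (frozen as a
regression value); inside noisy seizures the median spike-to-spike
interval is ≈ 0.33 s, i.e. a 3 Hz rhythm.

## Classification rules

A trajectory is classified background vs seizure over a 3-s horizon by
one of three rules:

* `eeg_threshold` — EEG ≤ θ at every sample of the horizon (strict);
* `fp_vicinity` — the state at exactly horizon's end lies within a
  4-D Euclidean ball (default radius 0.1) around the fixed point;
* `sw_termination` — no super-threshold EEG sample after the horizon
  (checked over a 0.4-s settling margin), i.e. all SW activity ceased
  within the horizon.

θ defaults to the midpoint between the fixed-point EEG and the maximum
EEG of the SW cycle (≈ 0.31 for the shipped presets), computed at run
time rather than hard-coded. The minimum distance from the SW cycle to
the fixed point is ≈ 0.19, so the 0.1 ball is discriminative.

The rules differ on seizures that terminate late in the horizon: the
state needs ~1.5 s to decay into the 0.1 ball (slowest eigenvalue
≈ −1.7 s⁻¹), so `fp_vicinity` effectively shortens the horizon, and
the strict rule rejects any transient exceedance. Success-rate maps
therefore use `sw_termination` — a pulse is successful when the
seizure is over within 3 s — while basin scans default to the strict
threshold rule. All three agree on the unambiguous cases, which is
tested.

## Basin reconstruction and return probabilities

Basin slices fix one or two state variables and classify a grid of
initial conditions over the rest; `slice_along_attractor` pins the
fourth variable to its value on the SW cycle at a sequence of cycle
times, producing the time-varying 3-D view of the 4-D basin. Under
noise each grid point is replaced by a return probability: the success
fraction over 20 independent noise realizations (granularity 1/20).
With alpha = 0 the probabilistic scan reduces exactly to the binary
scan because both run the same zero-noise fixed-step integrator. Grid
points carry seed streams keyed by their linear index, so results are
independent of chunking or evaluation order.

Note one physical subtlety: the return probability at the fixed point
itself is not exactly 1 — a seizure can ignite spontaneously within
the 3-s horizon with probability ~1% per trial. The basin core is
asserted as ≥ 0.95 at the fixed point and ≥ 0.9 averaged over a small
surrounding ball.

## Stimulation experiments

A stimulus is an instantaneous state reset `x → x + A·(1, 1, 0, 0)`
(equal pulse to both cortical populations, emulating an unsteerable
cortical stimulus). Scans cover a timing grid over a seizure segment ×
an amplitude grid × (for noisy maps) 20 post-stimulus noise seeds.

Standard study conditions, frozen in `spikewave.workflows`:

* deterministic one-cycle scan: 200 timings over one SW cycle of the
  deterministic preset × 59 amplitudes in [−0.30, −0.01];
* noisy headline map: a 3-s window of a spontaneous seizure of the
  noise preset starting 0.3 s after detected onset, 60 timings × 15
  amplitudes in [−0.30, −0.01] × 20 post-stimulus seeds.

The amplitude range is shared between the two scans and brackets the
reference pulse of −0.0825; its lower end extends past the amplitudes
where the six-phase success structure appears (≈ −0.22). In the
deterministic scan the minimum effective |amplitude| is ≈ 0.07, success
at the reference amplitude is confined to a single narrow phase on the
descending wave, and stronger pulses reveal up to six phases per cycle
of which exactly one is broad. Deterministic outcomes are provably
equivalent to basin membership of the post-pulse state, which the
acceptance battery verifies cell by cell; prolongation (a failed pulse
that leaves the seizure running longer than the unstimulated course) is
observable through the recorded post-stimulus seizure duration.

Map summaries report the whole-map mean rate, per-amplitude
timing-averaged rates with the best amplitude (the primary "optimised
amplitude" statistic), the best single cell, the minimum effective
amplitude, and per-cycle success-phase counts (cells count as
successful at rate > 0.5).

## Seizure detection, embedding, state-space binning

`detect_seizures` marks samples with |EEG − baseline| above a
threshold, merges super-threshold runs separated by < 0.5 s (the EEG
dips through baseline once per 0.33-s cycle, so within-seizure gaps
must not split an episode), and drops episodes shorter than 1 s. For
model data the baseline is the fixed-point EEG and the threshold the
SW threshold expressed as a deviation from it; for external recordings
the baseline defaults to the series median.

Attractor reconstruction low-pass filters the scalar EEG with a
zero-phase 4th-order Butterworth (6 Hz cutoff; forward–backward so
group delay cannot rotate the embedded geometry) and delay-embeds it
with lag 0.06 s and dimension 3 at a 500 Hz working rate (lag = 30
samples, resolving the ~30 ms spike). The filtered, embedded
deterministic cycle closes on itself to within 1% of the attractor
diameter after one period.

`bin_state_space_success` aggregates stimulation outcomes on a uniform
cubic binning of the embedding space — the learning-phase table of an
adaptive, patient-specific stimulation protocol. Bins with no attempts
are absent from the output, never reported as zero.

## What the synthetic conditions do and do not show

All experiments run on model-generated data; no clinical recordings are
included or required. The noise preset emulates the statistics the
model is calibrated to (3 Hz SWD, episodes of seconds, onsets every few
minutes) but not the nonstationarity, artifacts, multi-channel
structure or patient variability of clinical EEG; passing tests
demonstrate the internal consistency of the dynamical analysis, not
clinical detector performance. External single-channel CSV series are
accepted by the `embed` command for comparison; EDF input is not
implemented.

## Numerical choices and limitations

* Sigmoid evaluated as a logistic in `u·ln ε` (scipy's `expit`), stable
  to |u·ln ε| ≈ 700 and beyond.
* Pulses in deterministic scans hit the interpolated segment state; in
  stochastic scans the step state (reproducibility over
  micro-accuracy).
* Scan trajectories are thinned to 1 kHz for classification.
* Regime classification (`monostable_background` / `bistable` /
  `monostable_swd` / `other`) probes equilibrium persistence over 10 s
  and seizure ignition by a ±0.6 cortical pulse applied after 3 s of
  rest; both pulse signs are probed so the label is sign-convention
  free. Probes run on the fixed-step discretization — deliberately, as
  that is the system the stochastic experiments study; under the exact
  flow the noise preset would classify as monostable because its SW
  fold lies marginally past h_tc = −2.05.
* The headline success-rate levels depend on which spontaneous seizure
  the seed draws and on the scan extents; between-seed spreads of
  ±5–10 percentage points in map means are expected and are genuine
  model behaviour (cycle-to-cycle variability), not estimator noise
  alone.
* No bifurcation continuation, spatial extension, or closed-loop
  controller is implemented; the learning-phase table is the only part
  of the adaptive protocol covered.
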