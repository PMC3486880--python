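# Methods

## Perception models

The package models the continuously reported magnitude of thermal pain,
P(t) on a 0–100 scale, as the output of a deterministic dynamical system
driven by the skin temperature T(t) in °C.

**Second-order model.**

    P̈ = k₁·⌈T − T₀⌉₊ − γ·Ṗ + k₂·(Ṫ − T_c)·P ,  with P ≥ 0 enforced.

Parameters: forcing gain k₁ (rating·s⁻²·°C⁻¹), decay rate γ (s⁻¹),
restoring/driving gain k₂ (°C⁻¹·s⁻¹), pain threshold T₀ (°C, admissible
range 30–55), and rate threshold T_c (°C/s). The forcing is a ramp in
temperature: zero below T₀, linear above. The third term is signed by the
temperature's rate of change: negative (restoring) when Ṫ < T_c — limiting
pain under a sustained stimulus and suppressing sub-threshold fluctuations —
and positive (driving) when the temperature rises quickly. Because the
restoring force scales with both the fall rate and the current pain level,
a rapid temperature drop collapses perception much faster than the rise
built it up; this asymmetry is the model's account of offset analgesia.
All terms are linear in P, so trajectory *timing* is invariant to output
amplitude; only the thresholds and the non-negativity clamp are nonlinear.

**First-order reduction.**  Ṗ = A·⌈T − T₀⌉₊ − P/τ, obtained by dropping P̈
(large γ) and the rate term; A = k₁/γ, 1/τ = k₂·T_c/γ. One time constant
governs both rise and fall — the feature the second-order model exists to
relax.

**Variants.**  A power-law drive ⌈T − T₀⌉₊^δ (δ = 1 reduces exactly to the
first-order model; the drive at exactly T = T₀ is defined as 0 so negative
exponents never produce 0^δ), and a two-time-constant model summing
independent fast and slow leaky processes that share T₀ (tau_fast <
tau_slow strictly; the degenerate case is rejected).

**Null predictors.**  P̂ ∝ T (linear) and P̂ ∝ ⌈T − T₀⌉₊ (threshold-linear,
T₀ estimated). Correlation-based adequacy needs no output scale; for SSE
and AIC a scalar gain is least-squares-fitted (intercept-free), but the
free-parameter counts keep the conventional accounting k = 0 and k = 1.

Assumptions shared by all models: the commanded thermode profile is the
stimulus (no skin-heat-transfer model), ratings are an instantaneous
read-out of perception up to additive noise, and initial state is zero at
run start. Slow processes — habituation, sensitization across minutes —
are outside the models' descriptive scope.

## Integration

The second-order system is integrated with classical fixed-step RK4 on the
stimulus grid, substepped so the effective step never exceeds `dt_sim`
(default 0.05 s; halving the step to 0.0005 s changes the complex-protocol
trajectory by < 1e-4 rating units, measured by the acceptance script).
Temperature is linearly interpolated to substeps; Ṫ is the central-
difference derivative of the supplied trace (one-sided at the ends), so
measured and generated stimuli are treated identically. Non-negativity
uses a reflecting clamp after every substep: if P would go negative, P ← 0
and Ṗ ← max(Ṗ, 0).

The first-order family uses an exact exponential-integrator update per
grid step with the temperature held at the step midpoint, which reproduces
constant-drive segments to machine precision (closed-form step response
error ~1e-14). Kernels are JIT-compiled (numba) and have batch variants
that accumulate the residual sum of squares directly, so a random search
never materializes its candidate trajectories.

## Estimation and model comparison

Least squares via seeded uniform random search over a bounded box
(default 20,000 draws, ties broken by the first-encountered minimum),
followed by Nelder–Mead polish from the best draw with out-of-bounds
points penalized to +∞. Default bounds: T₀ ∈ [40, 50] °C, τ ∈ [0.5, 60] s,
A ∈ [0, 10], k₁ ∈ [0, 5], γ ∈ [0, 5] s⁻¹, k₂ ∈ [0, 1], T_c ∈ [−2, 5] °C/s,
δ ∈ [−0.5, 3] (covering the fitted exponent range reported for this kind
of data). The threshold-linear null searches T₀ only, with the gain
profiled out in closed form. A fit that yields a constant prediction
(e.g. an entirely sub-threshold stimulus) raises an error rather than an
undefined correlation.

Adequacy is the zero-lag Pearson r between model output and rating;
a derivative correlation (Pearson r between the time derivatives) is
available as a stricter, offset-insensitive check. Model comparison uses
AIC = n·ln(SS/n) + 2k with the dataset constant dropped, and the
normalized Akaike gain (AIC_contrast − AIC_model)/n; no small-sample
correction is applied. SS = 0 returns −∞ with a warning.

Identical (seed, config, data) triples give bit-identical fits.
`cross_predict` freezes fitted parameters and evaluates on an independent
run or protocol; `group_average_fit` averages ratings pointwise across
subjects who received the identical protocol before fitting.

## Stimulus protocols

All protocols start and end at the 35 °C baseline, ramp every transition
at the thermode slew rate (8 °C/s), and are sampled at dt = 0.1 s (≥ 10
samples per 8 °C transition). Ramp durations snap *up* to the grid so the
slew rate is never exceeded; holds snap to the nearest grid multiple.

- *Simple*: nine rectangular pulses, peaks 45/47/49 °C balanced three
  each, plateau durations uniform on [10, 40] s. The inter-stimulus
  distribution is not published; uniform [20, 40] s is used, which keeps
  run length comparable to published traces. Order, durations and ISIs
  are drawn from one seed.
- *Complex*: deterministic three-pulse pattern — 30 s baseline; 47 °C 5 s,
  +1 °C 5 s, 47 °C 20 s; 50 s baseline; 47 °C 35 s; 60 s baseline; 47 °C
  5 s + 48 °C 5 s; 30 s tail.
- *Offset-analgesia rate series*: identical rise to a 47 °C/20 s plateau,
  then descent at each requested rate (0.5–5 °C/s).
- *Offset-perturbation triples*: per plateau X — constant X for a 30 s
  window; X with a +1 °C excursion at 15 s for 5 s; X with an early return
  to baseline at 15 s. The window timings are reconstructed defaults (the
  original protocol's exact timings are not reprinted) and are arguments.

The offset-rate experiment measures the 90→10% perception fall duration
per rate. Because the second-order sub-threshold decay rate is
k₂·(T_c − Ṫ)/γ, its fall duration scales with the stimulus fall duration
(the normalized duration — perception fall over stimulus fall — is nearly
constant), whereas the first-order model imposes its fixed τ regardless of
the stimulus; the experiment therefore reports the *spread of normalized
fall durations*, which is several times smaller for the second-order model.

## Synthetic data

**Ratings.** `synth_rating` simulates a model, optionally applies a
first-order motor-lag smoothing (time constant `smooth_tau`), adds i.i.d.
Gaussian noise, and clamps to [0, 100] — emulating a potentiometer-based
continuous rating device with hard range limits. It does not emulate
reaction-time lags that vary within a run, scale-use idiosyncrasies,
or attention lapses. One consequence measured by the acceptance script:
the clamp rectifies the noise floor during sub-threshold baselines
(mean ≈ noise_sd/√(2π)), which biases least-squares threshold estimates
upward by ≈ 1.3 °C at the default demonstration amplitude (rating peak
≈ 17) with noise sd 5 — the estimator itself recovers T₀ to < 0.1 °C when
the same noise is left unclamped, and exactly on noise-free data. Fits to
real ratings, whose amplitudes are several-fold larger relative to the
device floor, are proportionally less affected.

**BOLD.** `synth_bold` resamples temperature and rating to the scanner
repetition time (TR = 2.5 s, half-open convention: a 600 s series gives
240 volumes), convolves each with a canonical double-gamma hemodynamic
response (peak 6 s, undershoot 16 s, ratio 1/6), standardizes, and assigns
log-normal gains with random signs to a seeded random subset of voxels
(defaults: 500 voxels, 5% temperature-coding, 5% pain-coding). Every voxel
receives AR(1) Gaussian noise (ρ = 0.3, acknowledging that TRs are not
truly independent) scaled to snr = 1. Pain-coding voxels encode the
*rating*, not the stimulus, so the fMRI→pain map inherits the perception
model's nonlinearity. There is no spatial structure, motion, or
physiological confound, and only lag-0 encodings of a single convolved
signal per target — a deliberate minimal structure whose consequences for
the Combined decoder are discussed below.

## Decoding

Voxels are predictors, TRs are treated as independent samples, the first
120 TRs train and the remaining TRs test; accuracy is the test-set Pearson
r against the rating.

- *OLS*: minimum-norm least squares (pseudo-inverse when n_voxels exceeds
  TRs); no intercept, as voxel time courses are mean-centered upstream.
- *EN*: Elastic Net, min ‖y − Xβ‖² + λ₂‖β‖² + λ₁‖β‖₁, solved by
  coordinate descent with λ₁ located by bisection so the active set is the
  largest not exceeding the requested predictor count. Predictors are
  standardized internally; coefficients are returned on the original
  scale with an intercept. Defaults λ₂ = 1, n_select = 25: with ~120
  training samples a 100-predictor active set measurably overfits (test r
  drops by ~0.1–0.2 and falls below OLS), while 25 matches the informative-
  voxel count of the default fixture.
- *EN w/lags*: every (voxel, lag 0–7 TR) pair, shifted forward, screened
  by |correlation with the target| > 0.2 computed on training rows only;
  the first 7 rows are dropped.
- *Combined*: EN decodes temperature from fMRI; the analytic model, fitted
  on the actual training (temperature, rating) series upsampled to 0.1 s,
  maps decoded temperature to pain; an intercepted least-squares mix
  combines this with the direct fMRI→pain EN. Because the ODE's output
  hinges on how often the decoded temperature crosses the fitted T₀, the
  analytic pathway can degenerate when the regression estimate is
  attenuated; mixing weights are therefore accepted only if the stack
  beats the pure EN pathway under contiguous-block cross-validation within
  the training rows, with an EN-only fallback.

On the default synthetic fixture the measured ranking is
EN ≈ Combined > EN w/lags > OLS, with the Combined−EN difference
fluctuating within ±0.02 of zero across seed sets. Two structural features
of the fixture explain the absence of a larger Combined advantage: the
direct EN-pain pathway reads voxels that encode the (convolved) rating
itself and already operates near the rating-noise ceiling, and a lag-0
linear readout cannot deconvolve the hemodynamic smearing of temperature,
so the decoded temperature under-occupies the supra-threshold region out
of sample. Passing these desk-scale experiments therefore demonstrates
correctness of the pipeline — split hygiene, no target leakage (shuffle
control), calibrated decoders — not the magnitude of combined-model gains
attainable on real multi-region recordings.

## Problem sizes and determinism

Default experiment sizes: 20 replicates × 20,000 draws for parameter
recovery and model selection on the complex protocol (≈ 2500 samples per
fit at dt 0.1 s); 10 seeded fixtures × 240 TRs × 500 voxels for decoding.
Every random quantity — protocol randomization, rating noise, voxel
assignment and noise, search draws — descends from explicit integer seeds,
and all experiments are bit-reproducible given (seed, config, data).

## Known limitations

- The stimulus is the commanded profile; skin temperature dynamics and
  individual thermal conductance are not modelled.
- The models are deterministic; rating variability enters only as additive
  output noise, not as stochastic dynamics.
- The threshold-estimation bias under clamped low-amplitude ratings
  (above) means absolute T₀ estimates from data hugging the rating floor
  should be interpreted with care.
- The BOLD emulator's minimal encoding structure understates what richer,
  multi-lag neural representations would afford the Combined decoder.
- Habituation/sensitization across stimuli and runs are outside scope.
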