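# Methods

This note records the models implemented in `dragtag`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Drag-dummy physics

Dummies are spheres, so drag is dominated by pressure (shape) drag and
the quadratic law `F_D = ½ ρ V² c_D A` applies, with `A` the
cross-sectional area `π(d/2)²`. Defaults: seawater density
ρ = 1020 kg m⁻³, sphere drag coefficient c_D = 0.45, reference speed
V = 0.65 m s⁻¹ (the optimal swimming speed of untagged silver eels).
Note the published sizing table is only consistent with `A` as the
cross-sectional area, not the diameter; inverting the law with the area
convention reproduces the printed diameters (2.56, 3.62 cm), with the
largest class landing at 5.12 cm — necessarily exactly twice the
0.05 N sphere, since force scales with d².

Calibration curves are fit through the origin (`F = αV² + βV`, no
constant): zero speed must give zero force, and the published curves
carry no constant term. Replicate forces are averaged per speed before
fitting (raw-point fitting is available). The theory-vs-measurement
comparison is made at the reference speed; at the low end of the
0.2–0.9 m s⁻¹ calibration range the fitted polynomial (which has a
negative linear term) necessarily departs from the pure-quadratic
theory, so the 5 % agreement statement is a reference-speed statement.

## Respirometry

MO2 at each speed is the OLS slope of the O2 concentration against
time, scaled by the effective water volume (chamber volume minus fish
mass, taking fish density ≈ 1 kg L⁻¹; configurable) and divided by fish
mass. A sample is accepted only if the slope is negative, significant
at α = 0.05 and the regression r² reaches the floor. The function
default floor is 0.9 (the recommended standard for smaller-volume
systems); the analysis configs in the tests use 0.85, the floor
appropriate for large-volume tunnels whose background noise depresses
trace r².

The metabolic model `MO2 = SMR·e^{cU}` is fit by unweighted nonlinear
least squares with log-linear starting values. SMR is the model's
extrapolation to zero speed — eels do not swim at U = 0 in the tunnel,
so SMR is by construction a model quantity. The derived endpoints
follow from calculus on the model: `COT(U) = SMR·e^{cU}/(3.6U)`
(mgO2 kg⁻¹ km⁻¹; the 3.6 converts m s⁻¹ to km h⁻¹) has its unique
interior minimum at `U_opt = 1/c`, where `COT_min = SMR·c·e/3.6`.
Cohort summaries of COT_min must be computed per individual and then
averaged: because COT_min is a convex function of the individual
parameters, plugging cohort-mean SMR and U_opt into the closed form
underestimates the mean COT_min (Jensen), and the pipeline therefore
never reports the plugged-in value.

The solid-blocking correction uses the conventional fractional error
`ε_S = τ·λ·(A_O/A_T)^{3/2}` with flume shape factor τ = 0.8 and object
shape factor λ = 0.5; the exponent is configurable for sensitivity
analysis. The correction multiplies all tunnel speeds before any
fitting, commutes with the Brett formula, and is toggleable. The
default tunnel cross-section (17 671 mm², a 150 mm circular section)
makes the correction a fraction of a percent for a 150 mm² eel; no
tunnel cross-section is published for the original rig, so the
percent-level correction magnitude reported there cannot be
reconstructed and is not asserted anywhere.

## Critical swimming speed

`U_crit = U_i + ΔU·(T_i/ΔT)` with ΔU = 0.1 m s⁻¹ and ΔT = 20 min by
default. Fatigue itself is an operational judgement by the
experimenter; the module validates protocol consistency (a fatigue
time longer than the interval is an error — the step was completed).
Convention for fatigue during the very first step: the increment for
that animal is the start speed itself (U_i = 0), so
`U_crit = U_start·T_i/ΔT`, which avoids extrapolating below the first
tested speed.

## Kinematics

Analysis windows follow the blocked randomisation of the video
protocol: the recording is cut into equal blocks (default 3 × 400 s of
a 1200 s recording), each divided into 20 s slots, one slot drawn
uniformly per block; windows never overlap and are reproducible under
a seed.

Tail-beat frequency is cycle counting: upward mean-crossings of the
linearly detrended signal, with a hysteresis band of 0.3 signal SDs to
suppress noise-induced double counts, and elapsed cycles divided by
the time between first and last crossing (which removes window-edge
quantisation). An FFT peak is used internally only to find the
dominant period for the wave-speed estimator.

Amplitudes are peak-to-peak (max − min of the lateral excursion),
matching the magnitude convention of the printed tail-tip values
(≈7.6 cm for a ~0.66 m eel); the Strouhal number `St = a·f/U`
accordingly uses the peak-to-peak amplitude in metres, which places
control swimming at St ≈ 0.31 at 0.65 m s⁻¹, inside the reported
0.32 ± 0.12 band. Note that max − min is upward-biased under additive
digitisation noise (by roughly two noise SDs per extreme); with the
generator's default jitter this inflates amplitudes by ~10–20 % and St
with them, still within the reported band.

Body-wave speed divides the arc separation of two landmark sites
(0.125 bl and 0.35 bl; tail tip at 1.0 bl) by the phase lag of their
oscillations. The lag is read from the cross-spectrum phase at the
dominant frequency — the sub-sample-accurate equivalent of locating
the cross-correlation peak — wrapped into one period; a lag
indistinguishable from zero (formally infinite wave speed) raises an
error rather than returning a huge number.

## Impairment model

Per-individual effects are percent changes against the matched
control: `red%U_crit = 100·(U_ctrl − U_trt)/U_ctrl` and
`inc%COT_min = 100·(COT_trt − COT_ctrl)/COT_ctrl`. Both endpoints are
modelled as a through-origin quadratic in added drag,
`E = a·F_D + b·F_D²` — no intercept because zero added drag must
produce zero effect. The fit pools all individual points by default
(8 eels × 3 drag levels = 24 points); per-level means are available.
The linear coefficient is `a` and the quadratic is `b` (for the U_crit
endpoint a = 102.8, b = 527.7; for COT_min a = −8.92, b = 2687): this
assignment — rather than the reverse — is the one that reproduces the
documented field worked example (29.68 % / 66.51 % at 0.159 N), and is
adopted throughout.

Attachment at the centre of mass adds a fixed increment to the drag
effect (+15 percentage points on the U_crit reduction, +63 on the
COT_min increase; configurable). Additivity of drag and site effects
is an explicit assumption — a factorial interaction would give larger
totals. Predictions outside the calibrated 0–0.2 N drag range are
computed but flagged with an extrapolation warning.

The two endpoints agree within a percentage point at 0.05 N and
diverge by > 50 points at 0.2 N; `endpoint_divergence` tabulates this,
because it bounds where a (cheap) fatigue test is a valid proxy for
the (expensive) energetic measurement: only up to roughly 0.1 N.

## Synthetic cohorts

The generator emulates the original study conditions: n = 8 eels,
body mass 0.6494 kg, length 0.657 m, maximum cross-section 150.5 mm²,
SMR 40.58 mgO2 kg⁻¹ h⁻¹, U_opt 0.68 m s⁻¹, control kinematic lines
f = 1.26 + 2.15U and W = 0.23 + 1.05U, per-condition kinematic
parameters for all seven trial conditions, and the impairment
coefficients above. Published dispersions are standard errors at
n = 8; between-individual SDs are taken as SE·√8. Two quantities are
not published and are the package's own choices, stated once here: the
untagged critical swimming speed baseline (0.87 ± 0.11 m s⁻¹, ≈1.3
body lengths s⁻¹, comfortably above the highest MO2 test speed) and
the per-individual drag-response scatter (8.5 percentage points, the
value implied by back-solving the published coefficient standard
errors from a 24-point through-origin fit).

Tag effects enter through the impairment model itself: drag (plus
site-B increments) reduces the true U_crit by E_U % and inflates the
true COT_min by E_C %, the latter by scaling SMR. The exponent c is
changed only at 0.2 N, where U_opt drops (0.68 → 0.47 as observed);
because COT_min ∝ SMR·c, the SMR inflation is compensated by c/c_eff
so the COT_min target is preserved exactly. Below 0.2 N U_opt is
drag-insensitive, matching observation.

O2 traces decline linearly at the slope implied by the effective
metabolic curve, with additive Gaussian noise proportional to the
trace's total concentration drop (fraction 0.118). That choice encodes
the reported fit quality — trace r² of 0.857 ± 2.5 essentially
independent of speed — and implies a per-sample MO2 CV of ≈7 %.
Fatigue logs convert the true treated U_crit into step records with
uniform-step semantics; landmark files carry a travelling wave with
the condition's f(U), W(U) and site amplitudes plus fractional jitter
(default 0.10 of the half-amplitude, a realistic digitisation error).

What the generator does **not** emulate: within-individual
repeatability across conditions (individual parameters are drawn once
and conditions are conditionally independent), behavioural states
(burst-and-coast, irregular swimming), background bacterial
respiration, temperature effects, and any hydrodynamic interaction of
the dummy's wake with the body. Passing end-to-end tests therefore
demonstrate estimator correctness under the stated statistical
structure, not robustness to these real-data features.

## Numerical conventions and problem sizes

- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; every generator function is reproducible under a fixed
  seed, and pipeline reports are byte-identical on re-runs.
- Degenerate inputs fail loudly with typed exceptions (domain,
  insufficient-data, protocol-violation, schema, config); fits on
  degenerate-but-legal data (constant forces) succeed with low r²
  rather than crashing. r² values are clamped to [0, 1].
- Through-origin fits use OLS on the [F, F²] design (uncentred r²);
  coefficient standard errors come from the same fit.
- Recovery tests pool 200 simulated individuals (25 cohorts of 8).
  At the generator's trace noise the per-individual U_opt standard
  error is ≈9 % (the information bound for 7 speed points at ~7 % MO2
  CV), so individual-level estimates scatter accordingly; the
  cohort-pooled estimates recover SMR within 10 % and U_opt within
  5 %, and those are the tolerances asserted.
- Kinematic test signals are 20–60 s at 30 Hz; simulated campaigns in
  tests use shortened recordings (the estimators are
  duration-agnostic).

## Known limitations

- The evaluation tool is calibrated on one species, one size class and
  drags ≤ 0.2 N; predictions beyond that range extrapolate a quadratic
  and are flagged.
- Coefficient uncertainty is reported as standard errors only; no
  bootstrap or prediction intervals in this version.
- The U_crit endpoint mixes aerobic and anaerobic capacity; above
  ~0.1 N it systematically understates the energetic burden (that is
  the point of the divergence table).
- Site increments are constants, not functions of drag; the additive
  model is the documented assumption, not a finding of this package.
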