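# Methods

## Model and assumptions

The spinal needle–manometer assembly is treated as a single first-order
hydraulic system. Laminar, quasi-steady Poiseuille flow through the
needle is driven by the pressure difference between the CSF source and
the fluid column standing in the manometer:

    A dh/dt = (P(t) − ρ h) / R,    h(0) = 0 (dry manometer),

with resistance R (cmH₂O·s/ml), bore area A (cm²) and density ρ (g/ml).
The time constant is τ = R·A/ρ and the constant-head solution is
h(t) = (P/ρ)(1 − e^(−t/τ)). Assumptions: no turbulence or entrance
effects, no capillary (Jurin) correction — at a ~3 mm bore the
capillary rise is millimetres and is neglected — no needle dead volume
or meniscus-formation transient, and a supply reservoir wide enough
(diameter ≥ 10× the manometer bore) that filling the manometer drops
the supply head by < 1%, which `reservoir_pressure_drop_fraction`
checks by volume conservation.

## Units

Canonical system: cm, s, g, ml; pressure in cmH₂O with the convention
that a column of height h and density ρ exerts ρ·h cmH₂O. Viscosity is
carried in cmH₂O·s; `units.viscosity_cmh2o_s` converts data-sheet
mPa·s values (1.002 mPa·s → 1.0218×10⁻⁵ cmH₂O·s via
1 cmH₂O = 98.0665 Pa). Two fluid presets exist: `CSF`
(ρ = 1.0006 g/ml, μ = 1.002 mPa·s) and `CSF_NOMINAL` (ρ = 1,
μ = 1×10⁻⁵ cmH₂O·s), the round-number convention used in desk
calculations and the bundled-table reproduction, whose flow rates are
consistent with ρ ≈ 1. All interface quantities accepted in mm (bore
and needle diameters, lengths in the YAML catalog and CLI) are
converted to cm once, at parse time.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| bore diameter | cm | 0.37 | bench manometer used for the bundled data |
| density ρ | g/ml | 1.0006 (nominal 1.0) | CSF at room temperature |
| viscosity μ | cmH₂O·s | 1.0218e-5 (nominal 1e-5) | 1.002 mPa·s at 20 °C |
| graduation step | cm | 1.0 | reading protocol of the bench experiments |
| driving pressure ΔP | cmH₂O | 13 | stated head of the drop-weight protocol |

The bundled drop-weight rows are internally inconsistent about ΔP: the
reported resistances and flow rates multiply to ~15.0 cmH₂O on every
row although the protocol states 13 cmH₂O. `resistance_from_flow`
therefore takes ΔP explicitly, and the reproduction report prints the
back-calculated per-row ΔP next to resistances recomputed at the
caller's value rather than silently picking a side. Relatedly, one
reported flow rate (Braun Spinocan, third replicate, 0.0107 ml/s) is
not reproducible from its own printed mass and duration, which give
0.0106 ml/s; the report shows both.

## Estimation

`ExponentialRiseEstimator` minimizes squared height residuals of
h(t) = (P∞/ρ)(1 − e^(−t/τ)) with `scipy.optimize.least_squares`
(trust-region reflective, parameters bounded positive). Initialization
is data-driven: P∞₀ = max observed height, τ₀ = the time at which the
observations cross 63% of P∞₀ (linear interpolation), exploiting the
r(τ) = 1 − 1/e anchor of the model. Convergence: relative SSR change
< 1e-10 (plus step/gradient tolerances of 1e-12, needed when residuals
are exactly zero and the SSR criterion cannot fire), budget 500
evaluations; non-convergence raises `EstimationError` carrying the best
iterate instead of returning silently. `fixed_tau` mode is a one-step
linear projection; `fixed_p` optimizes τ alone. R² is the coefficient
of determination 1 − SS_res/SS_tot about the mean observed height;
degenerate (all-equal-height) data are rejected. Duplicated observation
times are rejected at parse time, not averaged.

The τ-vs-R regression is plain OLS (`numpy.linalg.lstsq` on an
intercept design); under τ = R·A/ρ its slope is an estimate of the
manometer area, and `implied_bore_diameter_` inverts A = πD²/4. On the
five bundled published (R, τ) pairs it gives
τ = 0.067·R − 21.01 (implied bore 2.92 mm). Two RMS-validation
protocols are implemented because the choice is genuinely open: the
*theoretical-τ* protocol evaluates h(t) with P = 13 cmH₂O and τ from
the mean measured resistance, the *fitted-τ* protocol uses the pooled
fit's parameters; the report prints both. (For the bundled data the
theoretical protocol reproduces the historically reported RMS for two
of the three needles; the third was not reproducible under either
protocol and is simply reported as computed.)

## Simulator and synthetic data

`simulate_rise` integrates the governing ODE with fixed-step classic
RK4; a guard rejects steps above τ/10. Against the closed form the
error is < 1e-6 cm at dt = τ/1000 and decays at 4th order (tests check
≥ 2nd). Pulsatile forcing is additive sinusoids — one cardiac
(default 1.2 Hz, amplitudes ~1.5 mm) and one respiratory component
(0.3 Hz, ~3.5 mm normal / ~7.5 mm deep breathing) — the minimal
waveform consistent with the amplitude/frequency ranges observed at
lumbar puncture. Steady-state ripple matches the analytic low-pass
gain 1/√(1+(2πfτ)²) within 2% over f·τ ∈ [1, 100].

`crossing_times` emulates the bench reading protocol: first-passage
times through each graduation, linearly interpolated between samples;
graduations never reached are logged and omitted, never fabricated.
`generate_noisy_rise` evaluates the noiseless constant-head solution,
reads it at the graduations, and perturbs the *times* by
ε/h′(t_cross), ε ~ N(0, σ²) with σ = `observation_noise_sd` in cm.
This models what is actually uncertain at the bench — when the meniscus
crosses a line — while graduation heights stay exact; adding height
noise to the trace instead would bias first-passage times early near
the asymptote. All randomness flows from `rng_seed`
(`numpy.random.default_rng`), and generated data are deterministic
given the seed.

What the generator does *not* emulate: needle dead volume and the
meniscus-formation transient (visible in real data as an early-time
offset — regenerated crossing times agree with the bench measurements
only within ~25%), drop-by-drop flow discretization, and non-sinusoidal
pulse shapes. Passing parameter-recovery tests therefore demonstrate
estimator correctness under the model, not robustness to those
unmodelled effects.

## Problem sizes

Default test and acceptance runs use desk-scale inputs: the bundled
tables (9 drop-weight rows, 9 × 13 rise observations, 5 regression
pairs), simulations of ≤ 12 τ at steps down to τ/2000, and a
parameter-recovery study of 200 seeded replicates at σ = 0.1 cm,
τ = 111 s, P = 24 cmH₂O with 1 cm graduations over 5 τ — sizes chosen
to mirror the bench protocol while keeping the whole suite in seconds.

## Known limitations

* Needle inner diameters are rarely published, so the Poiseuille route
  is a forward calculator; measured resistances are preferred whenever
  available (`NeedleSpec.effective_resistance`).
* The model is linear and constant-R; very fast assemblies (large-bore
  needles) may violate the quasi-steady laminar assumption.
* Extrapolation accuracy inherits the uncertainty of τ: it requires
  the needle's R and the manometer bore to be known, which in practice
  means manufacturers declaring them.
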