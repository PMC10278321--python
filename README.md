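# spinaltau

First-order hydraulic modelling of the spinal needle–spinal manometer
assembly used to measure cerebrospinal fluid (CSF) pressure at lumbar
puncture.

## The problem

At a diagnostic lumbar puncture, CSF pressure is read from a graduated
manometer connected to the spinal needle. With fine (≥ 22G) needles the
fluid column can take many minutes to stop rising, so measurements are
often cut short and the equilibrium pressure underestimated. This
package models the needle + manometer as a first-order hydraulic system,
which makes the waiting unnecessary: knowing the assembly's time
constant, an accurate equilibrium pressure can be extrapolated from an
early reading.

## The model

Flow through the needle is driven by the difference between the CSF
pressure and the back-pressure of the column already in the manometer:

    Q(t) = (P_CSF − ρ·h(t)) / R,        A·dh/dt = (P_CSF − ρ·h) / R

with `R` the needle's resistance to flow (cmH₂O·s/ml, Poiseuille:
`R = 128 μ L / (π d⁴)`), `A` the manometer bore area (cm²) and `ρ` the
fluid density (g/ml). The step response is the exponential saturation

    h(t) = (P_CSF/ρ)·(1 − e^(−t/τ)),        τ = R·A/ρ,

so every needle/manometer pairing has one characteristic time constant,
and the time to any *fraction* of equilibrium (50% at 0.693 τ, 63% at τ,
99% at 5 τ) is independent of the pressure itself. Inverting the curve
gives the early-reading extrapolation `P_CSF = ρ·h / (1 − e^(−t/τ))`.
The assembly is also a first-order low-pass filter with cut-off
`f_c = 1/(2π τ)` — a few millihertz, far below respiratory (~0.3 Hz)
and cardiac (> 1 Hz) pulsation, which is why the column looks still.

The package provides:

* `spinaltau.hydraulics` — resistances (Poiseuille and drop-weight),
  time constants, rise curve, extrapolation, frequency response,
  reservoir-adequacy check;
* `spinaltau.estimation` — scikit-learn-style estimators
  (`ExponentialRiseEstimator`, `TauResistanceRegression`) plus
  functional wrappers for fitting rise data, RMS validation,
  equilibration summaries and the τ-vs-R regression;
* `spinaltau.simulator` — fixed-step RK4 integration of the governing
  ODE (optionally with pulsatile forcing), graduation-reading emulation
  and seeded noisy-dataset generation;
* `spinaltau.fixtures` / `spinaltau.report` — bundled bench
  measurements (three 22G needles, 3.7 mm bore manometer) and an
  end-to-end reproduction report;
* a `spinaltau` command-line tool (`resistance`, `tau`, `predict`,
  `extrapolate`, `fit`, `simulate`, `reproduce`).

## Worked example

```pycon
>>> import spinaltau as st
>>> m = st.ManometerSpec(bore_diameter=0.37)          # 3.7 mm bore, cm units
>>> tau = st.time_constant(667.9, m.area, 1.0)        # 22G Pajunk Sprotte
>>> round(tau)
72
>>> st.time_to_fraction(0.5, tau)                     # half-rise time, s
49.77717368395397
>>> st.extrapolate_equilibrium(h=6.5, t=49.9, tau=tau)
12.977822268100226
>>> st.cutoff_frequency(50.0)
0.0031830988618379067
```

A needle with R = 667.9 cmH₂O·s/ml on a 3.7 mm manometer has τ = 72 s:
the column covers half its rise in ~50 s, and a single reading of
6.5 cm taken at 49.9 s extrapolates to the equilibrium pressure of
~13 cmH₂O — no need to wait the ~256 s the column takes to settle.

The same from the shell:

```sh
$ spinaltau tau --resistance 667.9 --bore-mm 3.7
tau = 71.8 s  (nearest second: 72 s)
$ spinaltau extrapolate --height 6.5 --time 49.9 --tau 72
P_CSF = 13.00 cmH2O
$ spinaltau reproduce            # full bench reproduction report
```

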