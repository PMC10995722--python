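# Methods

## The problem

Outpatient parenteral antimicrobial therapy (OPAT) delivers IV antibiotics
through portable elastomeric infusers: a balloon reservoir (nominally 240 mL
here) that empties at a roughly constant flow rate over 24 h. Before use the
filled device may sit refrigerated (2–8 °C) for days; during the infusion it
runs at a body-adjacent temperature (32 °C). A sequential-stability study
asks whether the drug survives this *chained* exposure — fridge storage
followed by the running phase — and how much of the toxic degradation
product pyridine (released hydrolytically from ceftazidime's pyridinium
moiety) the patient would actually receive.

`elastostab` implements the full analysis pipeline for such a study:
design enumeration, forward simulation of measured concentrations, HPLC
calibration statistics, per-phase degradation regression, storage-scenario
prediction, delivered-pyridine integration, and compliance verdicts against
the UK Yellow Cover Document (YCD) band and pharmacopoeial pyridine limits.

## Study design model

A design is the full factorial `devices × dose levels × replicate devices ×
timepoints × duplicate aliquots` over an ordered list of contiguous
temperature phases. The reference configuration is two device types
(Easypump, Dosi-Fuser; 240 mL / 24 h → 10 mL/h), three ceftazidime/avibactam
dose levels (1500/375, 3000/750, 6000/1500 mg in 240 mL; the 0.25 mass
ratio is constant across levels), three replicate devices per cell, and
duplicate sampling at 12 timepoints — 0, 24, 48, 96, 168, 240, 336 h in the
fridge phase and 340, 344, 348, 356, 360 h at 32 °C — for 432 sample slots.

Time lives on a single global clock in hours since filling; phase-local
times are derived views. The boundary sample at 336 h is assigned to the
fridge phase (it is drawn at the end of refrigeration, before equilibration
at 32 °C could have any effect). Temperature is metadata only: rates are
phase-indexed, and no Arrhenius model is fitted — the analysis layer is the
per-phase linear regression used in stability practice, not a mechanistic
temperature model.

## Synthetic data generator

The generator exists so every downstream stage is testable without any
proprietary raw data. It emulates:

* **Degradation.** First-order decay by default (standard β-lactam
  hydrolysis kinetics), with phase-piecewise exponent accumulation
  `C(t) = C₀·exp(−Σ_p k_p t_p)`; an exactly piecewise-linear loss option
  exists because the analysis layer fits straight lines, and linear truth
  makes parameter recovery exact rather than approximate. Default rate
  constants (ceftazidime 3.8×10⁻⁴ /h fridge, 3.5×10⁻³ /h in use;
  avibactam 2.0×10⁻⁴ and 2.0×10⁻³ /h) were chosen once so that noiseless
  endpoints land in realistic windows — ≈75–85 % ceftazidime and ≈83–93 %
  avibactam remaining after 336 h + 24 h — and are config values, not claims
  about any product. Per-dose rate multipliers (1.0/1.1/1.2 for
  low/intermediate/high) reproduce the faster apparent loss observed at
  higher concentration; they are illustrative.
* **Pyridine stoichiometry.** Pyridine concentration is
  `baseline + yield · ΔC_ceftazidime · M_pyr/M_cef` with literature molar
  masses 546.58 and 79.10 g/mol, default yield 1.0 and default baseline 0
  (reconstituted solutions are assumed pyridine-free at t = 0; both are
  config knobs). Mass balance holds to 1e-9 relative at every timepoint.
* **Measurement noise.** Multiplicative log-normal with mean exactly 1,
  composed of a per-replicate-device factor (shared by all samples from that
  device, default CV 1 %) and an i.i.d. per-sample assay factor with the
  validated HPLC precisions (CV 1.9 % for ceftazidime and avibactam, 1.7 %
  for pyridine). Log-normal rather than Gaussian guarantees positivity; at
  these CVs the two are indistinguishable. Everything is driven by one
  `numpy` `default_rng` seed, so outputs are byte-reproducible.

What the generator does **not** emulate: flow-rate variability of real
elastomeric pumps (±10–15 % in practice), chromatographic drift or carryover,
pH- or temperature-dependent mechanism changes, and — importantly —
sub-stoichiometric pyridine release. Real studies measure less pyridine than
1:1 stoichiometry predicts (peak concentrations around 0.5 mg/mL where full
conversion of the degraded ceftazidime would imply ≈0.9 mg/mL), presumably
because degradation proceeds partly through routes that retain or consume the
ring. With the default yield of 1.0 the simulated delivered-pyridine totals
are therefore upper bounds, roughly twice what a comparable bench study
reports; lower the `pyridine_molar_yield` knob to explore that regime.
Passing tests consequently demonstrate the *correctness of the analysis
machinery* under the stated statistical assumptions, not the stability of
any real product.

## Calibration layer

Calibration fits `response = c₂x² + c₁x + c₀` by weighted least squares with
1/x² weights (statsmodels WLS), requiring ≥ 4 distinct positive levels.
r² is computed on weighted residuals — consistent with the estimator — and
the unweighted value is stored alongside. A fitted curve must be strictly
increasing over the calibrated range (the derivative is linear, so endpoint
positivity suffices); otherwise the calibration is rejected rather than
letting back-calculation pick between two roots. Back-calculation returns
the unique root inside the range and raises an out-of-range error otherwise,
mirroring bench practice of diluting (factor 10 or 5) and re-assaying. QC
precision is 100·SD/mean (sample SD) and accuracy the signed
100·(mean − nominal)/nominal; summaries print the absolute bias.

## Degradation kinetics and scenarios

Percent remaining averages duplicate aliquots within each replicate device,
normalises each replicate to its own t₀ mean (so 100 % at baseline holds by
construction; a nominal-concentration baseline rule is available), then
reports mean ± SD across the replicate devices.

Each phase gets an OLS line `C_i = a·t_i + b` on phase-local time, pooled
across the three replicate devices per device-type × dose (per-device-type
regressions keep the two pump designs separate; pooling replicates uses all
15–21 points per fit). Slopes, intercepts, their standard errors and the
residual SD are reported; two-point fits return zero SEs rather than NaNs.

A storage scenario chains the two slopes into a continuous piecewise-linear
trajectory: the storage segment is anchored at 100 % at t = 0 with the
fridge slope, and the running segment continues from the handoff value with
the in-use slope. Both fitted intercepts are discarded — observed
trajectories are continuous, and stitching intercepts would introduce a
spurious jump at the handoff. Threshold crossings (95 %, 90 %, …) are solved
in closed form per segment; a brute-force 0.001 h grid scan is the test
oracle. By default the fridge slope comes from the full 14-day fit; a
`max_storage_fit_h` option refits on a truncated window for users who
prefer a short-storage-only slope.

Note one subtlety: on the global clock, longer storage can *delay* the
crossing of a threshold (the device spends more time degrading slowly), but
the usable running time before the threshold is always non-increasing in
storage duration — that is the monotonicity the package tests and reports.

## Pyridine delivered dose

During the running phase the patient receives, per increment,
`C(t)·f·Δt` mg — concentration (from the in-use pyridine regression on the
concentration scale) times the infused volume. With the default 1-min steps
over 24 h (n = 1440), the reservoir bookkeeping `V_i = V_{i−1} − f·Δt`
reaches exactly zero. Concentration is evaluated at the increment start
(left endpoint); at 1-min resolution the difference from the midpoint rule
is far below the 0.1 % agreement demanded against the closed form
`f·(aT²/2 + bT)` (piecewise where clamping at zero concentration applies).
A "literal" mode that accumulates `C_i·V_i` with the *remaining* reservoir
volume is retained behind a flag for transparency; it is dimensionally a
mass but not a delivered mass (it weights late, concentrated reservoir
contents by a volume the patient never receives in that increment) and is
excluded from compliance evaluation.

## Compliance

Limits are config, not code — the 1.1 mg/mL USP concentration limit is
explicitly *former*, and w/w limits differ by formulation (0.5 % BP/EP,
0.4 % USP sodium-carbonate, 0.3 % USP arginine). The YCD 95–105 % band is
applied to the scenario-end percent, matching the sequential-storage
framing; the 10 % degradation rule is evaluated both at the end of the
configured running time and as a time-to-threshold. Because it is ambiguous
whether % w/w should compare delivered pyridine to the initial dose or to
concurrent remaining ceftazidime, the delivered-over-dose form is the
labelled default row; verdict logic is a pure function of
(observed, limit, direction), property-tested for directionality and
monotonicity. Missing inputs produce `not-evaluable` rows, never silent
drops.

## Problem sizes and numerics

The test suite and the acceptance script run the reference design (432
slots, 1296 measurements), 200-seed regression-recovery repetitions on a
single device × dose cell, 100-model delivery-oracle comparisons and
50-pair crossing grid scans; the whole suite completes in a few seconds on
one core. Numerical tolerances: 1e-6 for noiseless parameter recovery,
1e-8/1e-9 for calibration coefficient recovery and round-trips, 1e-9
relative for mass balance, 0.1 % for the incremental-vs-closed-form
delivery comparison, ±0.001 h for crossing times. Degenerate inputs
(zero-time-variance fits, non-positive baselines, durations beyond the
reservoir emptying time, thresholds outside (0, 100)) raise typed errors
naming the offending quantity.
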