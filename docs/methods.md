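# Methods

This note records the models implemented in drfkit, the defaults and their
rationale, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Sensor-ring statics

The decoupling interface is modelled as a rigid plate on three point
supports at angles {0°, 120°, 240°} on a circle of radius R (default
0.05 m, a plausible ring-fixator scale; every invariant holds for any
R > 0, so R is pure configuration). Sensor 1 sits on the +x axis,
numbering is counter-clockwise, the distraction axis is z and compression
is positive. An axial load F at in-plane eccentricity e is distributed by
solving the 3×3 system {ΣFᵢ = F, ΣFᵢpᵢ = F·e}; for the equidistant layout
this equals the closed form Fᵢ = F(1/3 + 2(e·pᵢ)/(3R²)), which the tests
use as an independent oracle. Loads with |e| ≥ R are rejected (no
guaranteed no-tension solution); mathematically valid negative (tension)
cell forces inside the envelope are returned but flagged with a warning,
because a physical compression-only cell cannot report them. Centroid
recovery divides by the total force and is refused below a 1e-9 N total.

## Calibration metrology

The benchtop campaign is a dead-weight ladder 0 → 200 → 0 N in 20 N steps
with 3 repeats. Metrics:

* **Linearity** — OLS of measured on applied over the pooled loading
  branch; R² = 1 − SS_res/SS_tot. The loading branch alone is used so the
  hysteresis offset does not leak into the linearity statistic.
* **Hysteresis** — max over matched levels of the loading/unloading
  branch-mean gap, as % of full scale (500 N rated capacity).
* **Zero drift** — |mean(last 60 s) − mean(first 60 s)| of a 1 h 100 N
  hold. For a linear ramp of 0.2 N/h this window statistic reads ≈0.197 N.
* **Repeatability** — max over load levels of half the range across
  repeats.
* **Expanded uncertainty** — GUM root-sum-square: U = k√(Σuᵢ²) with
  uᵢ = magnitude/divisor (√3 for rectangular limits, the stated coverage
  factor for normal components). The default budget {noise 0.15 N, drift
  0.2 N, hysteresis 0.2 N (0.1% FS at a 200 N working load), all
  rectangular} gives U(k=2) ≈ 0.37 N. The composition of the budget is an
  interpretation — the individual bounds do not uniquely determine a
  combined figure — and is fully configurable.

**Filtering.** Low-pass Butterworth, order 4, cutoff 5 Hz at 100 Hz
sampling by default, applied forward-backward (zero phase) so distraction
step timing is not delayed; the analysis is offline, so non-causality is
acceptable. DC gain is exactly 1. The "noise floor" statistic is the
post-filter RMS (the bound itself does not pin down peak vs RMS; RMS is
adopted and documented).

**Sensor error model.** reading = truth + white noise (SD, default
0.25 N raw) + linear drift (N/h) + a branch-direction hysteresis offset.
The hysteresis loop is closed: the branch gap is 4·h·FS·f(1−f) with
f = load/FS, zero at the loop endpoints and maximal mid-loop, rather than
a Preisach-type model — sufficient to exercise the metric. With the
default h = 0.1% FS and a 0–200 N ladder on a 500 N cell the measured
metric is ≈0.097% FS. 24-bit ADC quantization is negligible at these
scales and is not modelled.

## Ogden constitutive model

First-order Ogden with Ψ = (μ/α)Σ(λᵢ^α − 1) + (1/D₁)(J−1)² and principal
Cauchy stresses σᵢ = μλᵢ^α − p under exact incompressibility. The μ/α
prefactor is the standard form consistent with that stress expression
(the consistent small-strain shear modulus is G = μα/2, so the defaults
imply G = 7 MPa and a small-strain Young's modulus 3μα/2 = 21 MPa).
Defaults: μ = 700 kPa, α = 20 — strongly strain-stiffening skeletal
muscle in the physiological range.

D₁ deserves a note: a value of 0.049 in Pa⁻¹ would imply a bulk modulus
2/D₁ ≈ 41 Pa, ten orders below water; the package therefore defaults to
interpreting the incompressibility parameter as 0.049 MPa⁻¹
(4.9·10⁻⁸ Pa⁻¹, bulk ≈ 40.8 MPa), i.e. a nearly incompressible material.
Config accepts either unit via an explicit tag. The analytic pipeline
uses exact incompressibility throughout; D₁ only enters the penalty
branch of the bar finite-element solver.

Powers λ^α are evaluated as exp(α·ln λ) with an overflow guard (raised
with guidance to reduce stretch or α) since α = 20 overflows double
precision already at λ ≈ 1e15 — and far earlier in downstream products.

**Parameter identification** fits (ln μ, α) by Levenberg-Marquardt on
uniaxial stress residuals. One term keeps the problem well-posed, but μ
and α remain correlated along a stiffness ridge when the data span only
small stretches; the returned Gauss-Newton covariance proxy makes that
visible. Noiseless self-generated data are recovered to well under 0.1%.

## DRF predictor

The CT-based patient-specific 3-D soft-tissue model is deliberately
replaced by an equivalent incompressible Ogden cylinder: effective gauge
length L₀ and reference area A₀, with A₀ = V/L₀ when a segmented muscle
volume V is supplied. The interface is volume-aware precisely so a 3-D
backend can replace the cylinder later. Prediction:
F(δ) = A₀·P(1 + δ/L₀) with P the engineering stress; force on reference
area is the reporting convention, with true stress exposed via a flag
(the two differ by the factor λ and solver reaction conventions vary).

**Defaults** L₀ = 0.99 m, A₀ = 4.7·10⁻⁴ m² are *effective* values chosen
so the default curve tracks the packaged pilot prediction table; they are
mathematical aggregates of a muscle-fascia-skin composite acting in
parallel over different anatomical lengths, not anatomy. The geometry
calibration (log-parameterized bounded least squares on force residuals,
bounds A₀ ∈ [1e-5, 1e-2] m², L₀ ∈ [0.05, 2] m, deterministic coarse-grid
multi-start fallback) exists exactly because these are fitted, not
measured, quantities. Against the packaged prediction column it converges
to L₀ ≈ 0.85 m, A₀ ≈ 3.8·10⁻⁴ m² with RMSE ≈ 5.3 N, and its relative
error decreases monotonically in force from the 5 mm to the 40 mm step.

**Bar finite-element oracle.** A total-Lagrangian chain of uniaxial Ogden
bar elements under displacement control: Newton-Raphson with the
assembled tridiagonal consistent tangent, residual tolerance 1e-10
(relative to the largest internal force), max 50 iterations, and step
halving on divergence. Elements default to the exactly incompressible
uniaxial response, so a homogeneous chain reproduces the closed form to
machine precision — the oracle equivalence the tests assert. A
``volumetric="penalty"`` variant implements the nearly incompressible
element: the deviatoric energy acts on the isochoric stretches
J^(−1/3)λᵢ (without this split the printed energy form is not stress-free
at the reference state for J ≠ 1) plus the (1/D₁)(J−1)² penalty, with the
transverse stretch solved by bracketed root finding on the analytic
transverse equilibrium. With bulk/shear ≈ 6 at the default D₁ the penalty
element is systematically a few percent softer than the incompressible
closed form; it is a consistency check, not an equal-digits oracle.

## Relaxation

Post-step decay is a normalized Prony series, F(t) = F∞ +
(F_peak−F∞)Σgᵢe^(−t/τᵢ), Σgᵢ = 1; n_terms ∈ {1, 2} with 1 the default —
more exponentials on a 120 s single-subject hold invite non-unique fits.
Fitting is bounded nonlinear least squares multi-started from a
log-spaced τ grid; a fitted τ exceeding the hold duration is flagged (the
equilibrium is then extrapolation, not measurement). Peak = max over a
1 s post-step window; equilibrium = mean of the final 10 s. Both windows
are package conventions and configurable. Each step is fitted
independently; quasi-linear viscoelastic superposition across steps is
out of scope.

## Synthetic data

Generators are pure functions of (spec, seed) via numpy's PCG64.

* **Calibration ladder** — every reading is produced by the full chain:
  a 5 s noisy hold trace at 100 Hz, low-pass filtered, averaged; plus
  campaign-clock drift, the branch hysteresis offset, and a per-repeat
  mounting offset (SD 0.15 N) emulating trial-to-trial variability. Error
  magnitudes default to the benchtop bounds (noise 0.25 N raw / ≤0.15 N
  filtered, drift 0.2 N/h, hysteresis 0.1% FS, repeatability within
  ±0.5 N), so the calibration metrics are reproducible by construction;
  tests of the metrology arithmetic itself use separate, harsher inputs.
* **In vivo trace** — six steps on the {5,10,15,20,30,40} mm grid, 1 s
  actuation ramps (actuation speed is a convention; nothing downstream
  depends on it), 120 s holds decaying with τ = 30 s to an equilibrium
  ratio of 0.824, peaks from the predictor curve, split onto three
  channels through the static distribution law at a configurable (even
  time-varying) eccentricity, default (10, 5) mm, with 0.1 N per-channel
  noise.
* **Uniaxial dataset** — λ ∈ [1, 1.1] (the stretch range a 40 mm
  distraction explores on the effective gauge length), 20 points, 2%
  multiplicative noise.

What these fixtures do **not** emulate: gait and posture artifacts, pin
loosening, callus stiffening over treatment, tissue growth during
gradual lengthening, inter-subject variability. Passing tests demonstrate
the correctness of the decoupling statics, metrology arithmetic,
constitutive closed forms and fitting machinery under the stated noise
models — not clinical accuracy on a new subject.

## Degenerate inputs and tie-breaks

Collinear sensors, out-of-envelope centroids, near-zero total force,
cutoffs at/above Nyquist, single-level ladders, single repeats, holds
shorter than the analysis windows, and single-point calibration targets
all raise typed errors or flagged warnings rather than returning silent
numbers. The single-point geometry calibration pins L₀ to its lower
bound and warns, making the non-identifiability explicit.

## Known limitations

* The equivalent cylinder collapses the 3-D stress field to one scalar
  stretch; its fidelity rests on the calibration target, and the fitted
  (A₀, L₀) pair is itself correlated (stiffness ridge), so individual
  values should not be over-interpreted.
* The recomputed RMSE of the packaged comparison table is 6.28 N over its
  six rows, slightly below the 6.45 N summary figure that table carries;
  the table's per-row errors all reproduce exactly, so the summary figure
  likely reflects unrounded or additional data. The package always
  reports the recomputed value.
* The combined-uncertainty budget reproduces ±0.35 N only approximately
  (≈0.37 N) because the budget composition is an interpretation.
* The relaxation model is a reduced representation fitted per hold; it
  does not superpose history across steps.
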