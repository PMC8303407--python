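# Methods

## Model and assumptions

The package models whole-body urea kinetics during and after a
hemodialysis session as two well-mixed pools: extracellular fluid
(blood plus interstitium; the dialyzer is connected here) and
intracellular fluid, exchanging solute across the cell membranes with a
lumped volumetric mass-transfer coefficient `Ah` (total membrane surface
area × overall transfer coefficient; units of a flow, mL/min). The model
assumes:

- passive, gradient-driven transfer between the pools (no active/ion-channel
  transport);
- urea production at a constant rate `S` (mg/min) into the intracellular
  pool;
- dialyzer removal proportional to the extracellular concentration,
  `−K·Cex`, with `K` the clearance;
- a constant extracellular:intracellular volume ratio `ε = Vex/Vin`
  while both volumes shrink (ultrafiltration `ω_f` minus plasma
  refilling `ω_pl` drains the extracellular pool; refilling drains the
  intracellular one). The constant-ratio assumption fixes
  `ω_pl = [ε·Vin(0) − (Vex(0) − ω_f·t)] / [(1+ε)·t]`, which is exactly
  `ω_f/(1+ε)` — time-independent — when ε is the exact volume ratio.
  `ω_pl` is evaluated once (at `t = T`) and held constant; an explicit
  user override is honoured;
- after the session, `K = ω_f = ω_pl = 0`, volumes frozen at
  `Vex(T), Vin(T)`, no fluid or solute intake.

## Closed forms

The substitution `dt* = dt/Vex(t)` (so
`t* = −ln[1 − (ω_f−ω_pl)t/Vex(0)]/(ω_f−ω_pl)`) converts the
variable-coefficient during-dialysis system into a constant-coefficient
one; eliminating `Cin` yields `α C'' + β C' + γ C = S` with

```
α = 1/[ε(Ah+ω_pl)]
β = [(1+ε)Ah + K − ω_f + ω_pl]/[ε(Ah+ω_pl)]
γ = Ah(K−ω_f)/(Ah+ω_pl)
```

These were re-derived from the first-order system rather than read off
the typeset fractions, and the test suite verifies them two independent
ways: an exact-rational symbolic evaluation of the coefficients and
roots, and a central-difference check that the closed-form `(Cex, Cin)`
satisfies the original mass balances along the trajectory. The
characteristic roots are labelled `λ1 ≥ λ2` — the constants `(C1, C2)`
are symmetric under relabelling (tested), so the ordering is purely for
reproducibility. The post-dialysis constants follow from continuity of
both concentrations at `t = T`; the printed-form ambiguity in where the
`exp(−λ3 T)` factor sits is resolved by requiring that continuity
identity to hold (it is asserted to 1e−9 relative in the tests).

## Units

Volumes mL, flows mL/min, time min, production mg/min. Concentrations
are mg/dL at every public interface and mg/mL internally (÷100), which
makes `S/γ` (mg/min ÷ mL/min = mg/mL) directly commensurable with
concentrations.

## Numerical choices

- The during-phase modes `B^(λ/(ω_f−ω_pl))` are evaluated as
  `exp(−λ t*)` with `t*` computed via `log1p`; this is log-space
  evaluation (silent underflow to zero is acceptable — the fast mode
  decays within minutes) and it covers the `ω_f = ω_pl` limit
  (`t* = t/Vex(0)`) without 0/0 arithmetic.
- The post-phase constant `C3` carries `exp(+λ3 T)`, which overflows for
  very large `Ah`; evaluation therefore uses the shifted form
  `C3·exp(−λ3 T)·exp(−λ3(t−T))`. The absolute-time constant is still
  reported on the `PostConstants` object.
- Degenerate and unsupported regimes raise typed errors: `K = ω_f`
  (forcing coefficient `γ = 0`), a non-positive discriminant (repeated or
  complex root — the closed forms cover the distinct-real-root regime
  only, which holds across clinical parameter ranges), a collapsed
  compartment volume, and a refilling estimate that is negative or not
  below `ω_f`. A refilling estimate within 1e−9 mL/min of zero is
  clamped to zero (float round-off in `ε·Vin(0) − Vex(0)`).
- The finite-difference oracle is deliberately plain explicit Euler on
  the raw mass balances — an independent, auditable check on the closed
  forms, not a production integrator. Default `Δt = 0.005` min keeps the
  discretization error below 0.05 mg/dL for standard conditions
  (verified by Richardson extrapolation; observed agreement is ~7e−4
  mg/dL). The published difference formulas contain two apparent typos
  (a `(ω_f−ω_pl)·t` term where the balance requires `(ω_f−ω_pl)·Cex`,
  and a `Vin(T)` denominator where `Vin(t)` is required); the
  mass-balance-consistent forms are the default and the printed variants
  are available behind `as_printed=True` for comparison.
- Single-pool clearance matching (`match_end_concentration`) uses
  bracketed Brent root finding on the monotone end-concentration
  objective, bracket `[1e−3, 10·Ventire/T]` mL/min expanded
  geometrically; unattainable targets raise `NoSolutionError`.

## Parameter defaults

| symbol | default | units | meaning |
|---|---|---|---|
| K | 200 | mL/min | dialyzer clearance |
| T | 240 | min | session length |
| Vex(0), Vin(0) | 14 400, 21 600 | mL | 60 kg × 60 % fluid × 4:6 split |
| ε | Vex(0)/Vin(0) | – | volume ratio (0.667 when rounded) |
| Cs | 80 | mg/dL | initial concentration, both pools |
| ω_f | 20 | mL/min | ultrafiltration (4 800 mL per session) |
| ω_pl | estimated | mL/min | 12 with the exact ratio; 12.016 with ε = 0.667 |
| Ah | 500 | mL/min | membrane mass-transfer coefficient |
| S | 4.0 | mg/min | urea production |

These are the common Japanese clinical conditions and double as the
shipped example config and the estimator's default fixed values /
initial point.

## Fitting

`TwoCompartmentRegressor` minimizes the unweighted sum of squared
residuals between the model's blood (= extracellular) concentration and
the measurements, jointly over all during- and post-phase points — the
simplest defensible objective given that no weighting scheme is
standard for this design. The optimizer is scipy's bounded
trust-region-reflective least squares from a stated initial point
(deterministic; randomness lives only in the synthetic generator).
Default bounds: `K ∈ (ω_f, 500]`, `Ah ∈ [10, 5000]`, `S ∈ [0, 20]`.
Infeasible trial points (degenerate clearance, collapsed volume) are
rejected through a large residual penalty. A failed optimizer run is
reported via `converged_ = False`, not raised.

Identifiability: the production rate `S` is constrained mainly by the
late post-dialysis drift, so fitting `S` without rebound samples
triggers an `IdentifiabilityWarning`. At realistic noise (2 mg/dL) `S`
is strongly collinear with `K` through the during-phase offset, so the
noise-robustness checks estimate `(K, Ah)` with `S` fixed at its
clinical value — in practice the generation rate is taken from
anthropometrics rather than a single session, and the model itself
envisions the patient's transport parameters being characterized in
advance. All three parameters are recovered to ≤0.5 % from noiseless
samples (8 during + 4 post), which is the identifiability ceiling of the
design, not a statement about noisy clinical data.

## Synthetic measurements

`generate_measurements` evaluates the closed-form blood concentration at
a clinical sampling schedule (default: draws at 0, 30, 60, 90, 120, 180,
240 min during the session and 245, 250, 260, 280, 300 min after — the
cadence of rebound studies) and adds independent zero-mean Gaussian
noise, default sd 2 mg/dL, a typical laboratory repeatability for blood
urea nitrogen. What this emulates — and what it does not: real series
carry correlated errors (access recirculation, cardiopulmonary
recirculation, timing jitter, intradialytic intake) and genuinely
time-varying production; passing recovery tests on this generator shows
the estimation machinery is correct and well-conditioned for the design,
not that clinical fits achieve the same accuracy.

## Problem sizes used in validation

The analytic-vs-finite-difference comparison runs 0–400 min at
`Δt = 0.005` (80 000 Euler steps); convergence studies use
`Δt ∈ {0.1, 0.01, 0.001}` and Richardson halving from 0.08 to 0.01;
noise calibration pools 300 replicate series; clearance-robustness fits
100 replicates. These sizes were chosen to make each check decisive at
interactive runtimes.

## Known limitations

- Single solute, constant `K`, `Ah`, `S`, `ω_pl`; no intake during or
  after the session; no access or cardiopulmonary recirculation.
- The repeated-root (critically damped) branch of the during-phase ODE
  is intentionally unsupported (it does not occur in clinical ranges).
- The Gotch comparator is defined during dialysis only; the Shinzato
  post-phase is a pure linear drift (its single pool cannot rebound).
- Volumes are linear in time; the model breaks down (and raises) if
  ultrafiltration would exhaust a compartment.
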