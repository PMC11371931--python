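# Methods

## The model

`edes` implements a physiology-based compartmental model of
insulin-regulated glucose metabolism in the E-DES family (Eindhoven
Diabetes Education Simulator lineage), extended with an interstitial
glucose compartment so that continuous glucose monitoring (CGM) data can
be simulated and fitted alongside — or instead of — plasma glucose.

Six states are integrated (time in minutes):

| state | meaning | units |
|---|---|---|
| `M_gut` | glucose mass in the gut | mg |
| `G_pl`  | plasma glucose | mmol/L |
| `I_pl`  | plasma insulin | mU/L |
| `I_rem` | remote insulin action above basal | mU/L |
| `D_int` | accumulated glucose elevation (integral secretion term) | mmol·min/L |
| `G_int` | interstitial glucose | mmol/L |

**Gut.** The glucose drink empties into the gut with a Weibull-shaped
rate whose time scale is the per-subject parameter `k1` (1/min) and whose
shape `sigma = 1.34` delays the peak; the rate integrates exactly to the
bioavailable dose (`f_bio = 1` for a pure glucose drink), so glucose mass
is conserved through the gut. The gut empties into plasma at rate `k2`.

**Plasma glucose.** dG_pl/dt balances endogenous (hepatic) production —
a basal flux `egp_basal` suppressed linearly by the glucose elevation
(`k3`) and by remote insulin action (`k4`) — against gut appearance,
insulin-independent Michaelis–Menten uptake (constant `K_M = 13.2`
mmol/L), insulin-dependent uptake `k5·β·I_rem·G_pl/(K_M+G_pl)`, and renal
excretion above a 9 mmol/L threshold. The scale of the
insulin-independent uptake term is not a free constant: it is closed so
that all fluxes balance exactly at the subject's basal state, which makes
the basal state a true equilibrium of the system by construction.

**Insulin.** Pancreatic secretion is a PID-style response to the glucose
elevation above basal: a proportional gain `k6` (the per-subject
"glucose-dependent insulin secretion" parameter), an integral term
`(k7/τ_i)·D_int` and a derivative term `k8·τ_d·dG_pl/dt` computed from
the model's own analytic glucose derivative (keeping the right-hand side
smooth for the optimizer). Plasma insulin is cleared first-order above
basal; basal secretion and clearance are folded together so basal insulin
is a steady state. Remote insulin action `I_rem` is a deviation-from-basal
state (zero at rest, as in minimal-model practice) fed by the plasma
insulin elevation (`k9`) and decaying at `k10`. Because it is a deviation,
the state non-negativity rule applied during calibration (below) covers
masses and concentrations but deliberately not `I_rem`.

**Interstitium.** `dG_int/dt = (G_pl − G_int)/τ_g`, a pure first-order
lag with equilibration time `τ_g` (min). `τ_g = 0` (or `None`) is handled
as the algebraic limit `G_int ≡ G_pl`, never as a division: fitted lags
can be numerically zero.

### Fixed-parameter defaults

The non-estimated constants are population-scale values chosen once to
produce a physiological 75 g OGTT response for an adult with overweight
(glucose 5.4 → ≈9.5 mmol/L peak near 40 min, back near basal by 120 min
with a mild undershoot; insulin 12 → ≈53 mU/L peak near 50 min):
`k2 = 0.28`, `k3 = 0.006`, `k4 = 5·10⁻⁴`, `k7 = 0.02`, `k8 = 1.0`,
`τ_i = 31`, `τ_d = 3`, `k9 = 0.03`, `k10 = 0.06`,
`insulin_clearance = 0.07` (all per min where applicable),
`egp_basal = 0.043` mmol/L/min (≈2 mg/kg/min over a 17 L/70 kg
distribution volume), `V_g = 17/70` L/kg, renal threshold 9 mmol/L with
clearance 0.1 L/min. They are serializable to a commented YAML file and
overridable throughout the API.

## Calibration

Per response, the estimable parameters are `(k1, k5, k6)` in plasma mode
and `(k1, k5, k6, τ_g)` in cgm mode. The objective is the max-normalized
least squares over the two fitted metabolites (the glucose channel of the
chosen mode plus plasma insulin),

L(θ) = Σ_i Σ_j ((y_ij − ŷ_ij(θ)) / max(y_i))²,

which puts mmol/L glucose and mU/L insulin residuals on comparable
scales. The t = 0 samples are model inputs (basal values), never fitted
points; the basal glucose input is mode-matched (plasma t = 0 in plasma
mode, CGM t = 0 in cgm mode) and basal insulin is always the plasma
t = 0 insulin. Glucose and insulin points are deliberately weighted
equally per point despite the 26-vs-6 count imbalance in cgm mode.

Optimization is a TikTak-style multistart: 128 scrambled-Sobol points
over the search box, the best 16 polished sequentially by bounded
Nelder–Mead on the unit cube, each polish started from the convex blend
`(1−w_i)·θ_i + w_i·θ_best` with `w_i = clip((i/16)², 0.1, 0.995)`, plus a
final tight polish of the incumbent. Coordinates converging within a
simplex tolerance of a box face are snapped onto it when that does not
worsen the objective, so bound-constrained optima are reported exactly on
the bound (an estimate within 10⁻⁹ of a bound is flagged `boundary_hit`;
`k6 = 10.0` flags are the signature of a failed fit and are excluded from
the distribution and indicator-correlation analyses downstream). A
parameter set whose trajectory goes negative in any mass or concentration
is rejected with a penalty objective (10⁶) rather than clipped, so
structural misfit stays visible to the optimizer. Integration failures
are likewise converted to the penalty; if every start fails, the result
carries the penalty objective with all bounds flagged instead of raising.

Search ranges (linear scale): `k1 ∈ [10⁻³, 0.1]`, `k5 ∈ [10⁻⁴, 0.5]`,
`k6 ∈ [0.01, 10.0]`, `τ_g ∈ [10⁻⁶, 30]` min. Everything — ranges,
budgets, tolerances, seed, penalty — lives in `CalibrationConfig`.
Runs are bitwise reproducible given the seed.

The ODE is integrated with LSODA (stiff-switching, needed because fitted
lags approach the 10⁻⁶ min lower bound) at rtol 10⁻⁶ / atol 10⁻⁸;
sampled observables move by less than 10⁻⁵ relative when the tolerances
are tightened tenfold.

## Practical identifiability

Profile likelihood per fitted model: each of `k1, k5, k6` is scanned
outward from its estimate (τ_g, when present, is re-optimized as a
nuisance but never profiled — it only encodes the sensor lag), with all
other parameters re-optimized at every scan point (warm-started
Nelder–Mead, restarted from the fitted optimum if a walk strands on the
penalty plateau). The 95% confidence endpoint on each side is located by
bisection (absolute tolerance 10⁻⁴) where the profile crosses
`L* + Δ`; an endpoint is reported unbounded when no crossing occurs
inside the scan range (defaulting to the search box). A model is
practically identifiable when all three intervals are finite *strictly*
inside the scan range — an endpoint exactly on the bound counts as open.

**Threshold convention.** The max-normalized objective is a −2
log-likelihood only up to an unknown noise-variance scale, so a raw
χ²(0.95, 1) = 3.84 increment is not usable as-is: measured over the whole
physiological box, noise-free plasma-mode profiles peak near L ≈ 1.5,
i.e. the raw threshold would declare *every* model unidentifiable. The
default is therefore the exact linear-Gaussian result for profile
confidence regions with estimated variance,

Δ = L\* · F(α; 1, n−p) / (n−p),

with `n` the number of fitted points and `p` the number of fitted
parameters (the residual variance is estimated as `L*/(n−p)`). The
`chi2_scaled` and raw `chi2_fixed` conventions remain selectable for
sensitivity analyses.

**Confidence bands** for glucose or insulin are prediction profiles: at
≈9 anchor times the prediction is maximized/minimized over parameter sets
whose objective stays within Δ of the optimum (COBYLA with the objective
as an inequality constraint), then interpolated and united with the point
prediction, which is therefore always contained in the band.

## Metabolic indicators

Computed from the 7-point plasma response with each formula's unit
convention localized in one module (glucose mg/dL = 18.0156 × mmol/L
where the published formula requires it): HOMA-IR `G0·I0/22.5` and
HOMA-β `20·I0/(G0−3.5)` (mmol/L, mU/L); the Matsuda composite index
`10000/√(G0·I0·Ḡ·Ī)` on mg/dL glucose with the means taken over all
available OGTT points; trapezoidal AUC 0–30 min of glucose and insulin;
the insulinogenic index `(I30−I0)/(G30−G0)`; HIRI as the product of the
0–30 min glucose (mg/dL·min) and insulin AUCs; MISI as the post-peak
glucose decline slope (peak to subsequent nadir, mg/dL/min) divided by
the mean insulin, zero for a flat response; and the oral disposition
index as insulinogenic index × Matsuda. Missing or degenerate inputs
(e.g. G30 = G0) yield NaN with a logged reason, never a silent zero. The
clamp-derived M-value requires clamp time series outside this package's
data model and is not computed; the correlation table simply has no such
row.

## Synthetic cohorts

The generator emulates the study designs: a 75 g OGTT with blood draws at
t = 0, 15, 30, 45, 60, 90, 120 min and a CGM trace on a 5-min grid over
a 130-min window, per subject, with known ground truth. Parameters and
context are log-normal: medians `k1 = 0.015`, `k5 = 0.035`, `k6 = 0.8`,
`τ_g = 2.5` min (log-SD 1.8, so the upper quartile reaches ≈8.5 min;
near-zero lags in field data correspond to boundary fits, which a
log-normal tail cannot represent), body mass 90 kg, basal glucose 5.4
mmol/L, basal insulin 12 mU/L. Basal insulin is coupled to the drawn
`k5` (median × `(k5/median k5)^−0.5`), emulating compensatory fasting
hyperinsulinemia — without this coupling the synthetic cohort would miss
the insulin-resistance/fasting-insulin relation that HOMA-IR and the
Matsuda index are built on.

Measurement noise defaults: 2% CV multiplicative on plasma glucose, 7%
on insulin; CGM readings get 5% proportional error plus one additive
bias per trace drawn from N(+0.3, 0.2²) mmol/L — the positive mean
reproduces the systematic interstitial-above-plasma offset seen in
calibrated sensor data during an OGTT, on top of the diffusion lag.
Noisy values are truncated to stay positive. Optional missingness
removes whole blood draws with a configured probability, can drop the
CGM trace, or deletes one interior sensor reading to emulate an
irregular-frequency file; all of it drives the exclusion rules
(responses with >2 missing draws, a missing baseline or 2-h draw, a
non-uniform CGM grid, or a missing glucose channel are excluded, with
reasons recorded).

What the generator does **not** emulate: level- and
rate-of-change-dependent sensor error, calibration drift over wear time,
multi-day free-living traces, or within-subject visit-to-visit
variability. Passing tests therefore demonstrate correctness of the
machinery and behavior under idealized OGTT conditions, not performance
on real sensor data.

## Problem sizes and test design

Cohort-scale checks run at n = 20 subjects × 2 calibration modes
(≈9 s per calibration on one core), the size at which the package's
recovery and concordance properties are asserted: noise-free recovery of
`k1, k5, k6` to <1% relative; rank correlation ≥0.9 between true and
estimated `k1`/`k5` under default noise; cross-mode (plasma vs CGM)
Spearman ρ ≥ 0.85 for `k1`/`k5`. The acceptance script profiles
identifiability on the first 8 responses per mode and reports all summary
statistics from a single cohort run. Report-level signatures (k5–Matsuda
correlation positive and strong, right-skewed MSE distributions) are
checked on the same cohort.

## Known limitations

* Fixed parameters are package defaults, not population fits to any real
  cohort; absolute parameter values are comparable only within runs that
  share them.
* The identifiability threshold assumes i.i.d. Gaussian residuals after
  max-normalization; heteroscedastic sensor error would call for a
  weighted objective before profiling.
* The secretion PID terms `k7`, `k8` weakly identify `k6` from glucose
  data alone (the k5↔k6 compensation is imperfect); with insulin data
  removed, the k6 profile is typically open on one side rather than flat
  everywhere.
* Single-meal, single-visit scope: no exercise, no multi-meal input, no
  insulin dosing.
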