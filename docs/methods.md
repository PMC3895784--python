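# Methods

## Model

Both cohorts share a baseline annual hazard m = MR/100, assumed constant
over time for a given patient (no age drift; Gompertz acceleration is out of
scope). The wait-list arm dies at rate m throughout. The transplant arm's
hazard is m scaled by a piecewise-constant relative-risk profile
r(t): segments of duration d_k and ratio r_k, the last open-ended. Survival
and restricted AUCs are evaluated by exact segment algebra — the cumulative
hazard is piecewise linear, each segment's area contribution is
S(start_k)·(1 − e^(−r_k·m·Δ))/(r_k·m) — so no quadrature error enters
anywhere in the analytic pipeline. The test suite independently re-derives
AUCs by breakpoint-aligned midpoint Riemann sums (step 1e−4) and requires
agreement to 1e−8.

Two characteristic times:

- **Equal percent survival**: smallest t > 0 with R(t) = t, where
  R(t) = ∫r. Both cumulative hazards are proportional to m, so this time
  depends only on the profile; it is found by exact scan of the piecewise
  linear excess E(t) = R(t) − t. If E never becomes positive the convention
  is 0 (the identity profile, or a transplant arm that is never worse). If a
  positive excess persists while the terminal ratio is ≥ 1, there is no
  crossing and a distinct error is raised rather than a sentinel value. A
  tangency (E touches 0 at a boundary without changing sign) returns the
  touch point.
- **Equal cumulative life years t\***: the root of
  AUC_tx(t) − AUC_wait(t) = 0 beyond the crossing. The bracket starts at
  the crossing time, doubles upward until the sign changes (capped at
  200/m, after which a no-catch-up error is raised), and Brent's method
  drives the AUC difference below 1e−10. A lifetime-area pre-check
  (AUC at t = ∞) distinguishes "no catch-up ever" from a distant root.

The decomposition for a deterministic wait of w years is
P(no benefit) = 1 − e^(−mw), P(harm) = e^(−mw)(1 − S_tx(t*)),
P(benefit) = e^(−mw)·S_tx(t*). The harm:benefit ratio
(1 − S_tx(t*))/S_tx(t*) is provably independent of w, and the equivalence
mortality rate is the m solving S_tx(t*(m); m) = 1/2 (continuous mode) or
the largest integer MR on a grid with benefit ≥ harm (integer-grid mode,
after verifying the benefit share is monotone decreasing over the grid).
The harm/benefit boundary is deliberately the AUC-equality time, not the
survival-curve crossing: at the crossing the transplant arm still trails in
cumulative life years, so classifying by the crossing would overstate
benefit.

## Parameters and presets

| parameter | meaning | default | units |
|---|---|---|---|
| MR | baseline wait-list mortality | 15–35 grid | deaths / 100 patient-years |
| w | deterministic waiting time | 2 | years |
| d1, r1 | increased-risk period | 0.2, 2.26 | years, ratio |
| d2, r2 | equal-risk period | 0.8 or 1.0, 1.0 | years, ratio |
| r3 | long-run reduced risk | 0.44 | ratio |
| p | hold/inactive fraction of the list | 0 (0.1/0.2 in sensitivity) | proportion |
| ρ | hold vs active mortality ratio | 2.2 | ratio |

Two presets differ only in d2. With d2 = 0.8 years (preset `paper`, reduced
risk from the end of year one) the closed-form crossing is
(2.26·0.2 + 0.8 − 0.44)/0.56 = 1.45 years; the source description of this
parameterisation quotes 1.6 years, which the stated parameters cannot
produce — the discrepancy is surfaced, not patched. With d2 = 1.0 years
(preset `table_matching`, reduced risk from 1.2 years) the crossing is
1.65 years, inside the 1.5–2-year window reported for elderly deceased-donor
cohorts, and this preset reproduces the published outcome tables most
closely (every harm/benefit cell within ~2 percentage points); it is the
package default.

The hold adjustment multiplies each segment ratio by the mixture factor
f = (1 − p) + p·ρ, by default skipping segments whose ratio is exactly 1
(the adjustment is conventionally quoted only for the increased- and
reduced-risk periods); `scale_equal_segment=True` scales the equal-risk
period too, for sensitivity analysis. Computation always uses the unrounded
products (2.8024, 0.5456); 2.8 and 0.55 are display roundings.

## Calibration

Given anchors (s_wait, s_tx at a horizon h; crossing time t_eq) and fixed
(d1, d2, r2), the baseline hazard is m = −ln(s_wait)/h and (r1, r3) solve a
2×2 linear system: the crossing condition r1·d1 + r2·d2 + r3·(t_eq−d1−d2) =
t_eq and the horizon condition r1·d1 + r2·d2 + r3·(h−d1−d2) = −ln(s_tx)/m.
The solve is exact (residuals zero by construction); a singular system
(t_eq → h) raises an error, and fits with r1 ≤ 1 or r3 ≥ 1 warn as
physically disordered. The informative diagnostic runs the other way:
`implied_anchors` pushes a given profile through the forward model, showing
e.g. that the quoted triple (2.26, 0.8 y, 0.44) under m = −ln(0.51)/4
implies 4-year transplant survival 64.9% (not 66%) and a crossing at 1.45 y
(not 1.6 y). The quoted anchors refit to r1 ≈ 2.915, r3 ≈ 0.362. A grid
least-squares surface (`grid_misfit`) is provided for over-determined or
inconsistent anchors.

## Microsimulation

The microsimulation is both the package's synthetic-data generator and a
stochastic oracle. Per patient: a list-arm death time ~ Exp(m); death before
w classifies as no benefit, otherwise the patient is transplanted at w and a
post-transplant death time is drawn by exact inversion of the piecewise
linear cumulative hazard (locate the segment where H crosses an Exp(1) draw,
convert the residual hazard at that segment's rate — no rejection sampling
or time discretisation). Transplanted patients also get a counterfactual
list-arm death time drawn from the transplant date (exact by memorylessness),
giving a paired restricted-life-year comparison truncated at t\*: the mean
difference converging to zero is an independent stochastic check of the
AUC-equality root. All draws come from one `numpy.random.default_rng(seed)`
stream in a fixed block order (list deaths, transplant deaths,
counterfactuals), so a given (seed, config) is bit-reproducible.

Cohort sizes: unit tests use 2×10⁵–4×10⁵ patients and the convergence check
uses 10⁶, at which all three empirical probabilities sit within 3 binomial
standard errors of the closed form.

What the generator emulates: exponential/piecewise-exponential event times
under exactly the analytic model's assumptions. What it does not emulate:
stochastic waiting times, removal from the list for reasons other than
death, competing risks, organ-quality strata, covariate heterogeneity, or
time-varying baseline mortality. Agreement between simulation and closed
form therefore demonstrates internal consistency of the implementation, not
external validity of the model for real registries.

## Display conventions and degenerate inputs

Tables round probabilities to whole percent and life expectancies to one
decimal with ties away from zero, and harm:benefit ratios to two significant
figures; rounded rows may sum to 100 ± 1. All user-facing rates are deaths
per 100 patient-years; internally everything is an annual hazard. Degenerate
inputs are errors, not silent defaults: non-positive hazards and rates,
negative times, hold fractions outside [0, 1), profiles with non-positive
ratios or a bounded final segment. "No crossing", "no catch-up" and "no
equivalence in range" are distinct exception types.

## Known limitations

- Baseline mortality is constant per patient; long-horizon projections for
  older cohorts would need age-accelerating hazards.
- The waiting time is deterministic; real waits are themselves random and
  correlated with health status.
- The increased-risk period's duration and magnitude are held fixed across
  mortality strata, although observed early risk appears larger in sicker
  cohorts — the decomposition is conservative in favour of transplantation.
- Net life-years gained, quality-of-life weighting and
  number-needed-to-treat summaries are deliberately out of scope; the output
  is the probability split, not a utility.
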