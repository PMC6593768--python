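# Methods

## The measurement and the model

A low-load compression tester lowers a stainless-steel plunger (diameter
0.25 cm) onto a soft hydrogel cast in an 0.8-mm ring on a glass slide. The
plunger approaches at 5 μm/s until the force reaches the touch load
(10 mg ≙ 9.80665 × 10⁻⁵ N with standard gravity); that position, against a
top-of-slide calibration, gives the gel thickness. The gel is then
compressed by 20% of its thickness and the strain is held for 100 s while
the force relaxes.

Force divided by the plunger cross-section is stress; plunger travel past
contact divided by thickness is engineering compression strain. The OLS
slope of stress vs strain over the ramp is the instantaneous stiffness *E*
(kPa). During the hold, stress divided by the constant strain gives the
relaxing stiffness *E(t)*, which is modelled as a generalized Maxwell
(Prony) series

E(t) = E<sub>∞</sub> + Σᵢ Eᵢ·exp(−t/τᵢ),

a parallel array of spring–dashpot pairs with stiffnesses Eᵢ ≥ 0 and
relaxation time constants τᵢ > 0, plus an optional equilibrium spring
E<sub>∞</sub> ≥ 0. The model assumes the hold is an ideal step strain,
linear viscoelasticity at 20% strain, and no poroelastic or adhesion
contributions — the same idealisations under which the protocol interprets
the data.

## Fitting and model-order selection

`fit_fixed_order` minimises the chi-squared error — the unweighted sum of
squared residuals between the model and *E(t)* (no measurement variances
are available; a weighting hook exists but is off by default) — with
bounded trust-region least squares (`scipy.optimize.least_squares`,
E ≥ 0, τ ∈ [10⁻³, 10⁴] s, E<sub>∞</sub> ≥ 0 free by default). Exponential
sums are notoriously multimodal, so the fit is multi-started: τ initialised
log-spaced over [0.1, 100] s (the decade range these gels occupy), E at
E(0)/n, plus seeded log-normal jittered restarts (8 by default). The best
chi-squared wins; elements are reported sorted by ascending τ so "the first
element" is always the fastest. Everything is deterministic given the seed.

`select_order` starts at one element and adds elements until the relative
chi-squared improvement (χ²ₙ − χ²ₙ₊₁)/χ²ₙ falls below ε = 0.05 (an
extra-sum-of-squares F-test stopping rule is selectable), up to `max_n = 4`
— one spare order beyond the 2–3 elements these gels need, so the stopping
rule is actually exercised. Each order is warm-started from the previous
solution padded with a zero-stiffness element placed in the largest log-gap
of the existing τs; since trust-region steps never increase the cost, the
selection trace is non-increasing by construction. A chi-squared below
10⁻¹² × Σ E(t)² is machine precision on this data scale and counts as a
perfect fit, stopping the search (otherwise a noiseless curve would keep
"improving" in the last bits and overfit spurious orders).

Relative importance RIᵢ = 100·Eᵢ/Σⱼ Eⱼ (equilibrium term excluded)
expresses each element's share of the decaying stiffness. Elements are
binned by τ — (0, 1) s "sub-second fluid" (liquid pressed out of the gel),
[1, 10) s "ECM network", [10, 100] s slow modes, > 100 s out of range.
Bins are left-closed; the source protocol states open ranges ("between 1
and 10 s"), so the closure at the boundaries is this package's convention.

## Collapse QC

Gels that cannot sustain the hold yield no usable relaxation data and must
be excluded from summaries. A measurement is flagged collapsed when any of:

1. *E(t)* sits at or below zero for ≥ 10% of the samples in the first tenth
   of the hold. Healthy gels of this class relax almost fully within tens
   of seconds, so the tail of that window lies only ~2σ above zero and
   single noise dips below zero are expected — a fraction criterion
   separates "signal at baseline" (collapse) from "signal grazing zero"
   (normal relaxation), where a literal any-sample rule false-fires.
2. An adjacent-sample drop exceeding 50% of the local stiffness while the
   signal is still above 10% of *E(0)* — a step-like failure. Note this
   cannot fire on a smooth exponential decay sampled at 10 Hz (a 0.2-s
   decay gives 39% per-sample drops); it exists for abrupt give-way events.
3. The fit failed to converge at every order and restart.

## The synthetic-experiment generator

No raw traces are publicly available for these donor hydrogels, so the
package validates itself by parameter recovery on simulated experiments.
`simulate_trace` emulates the protocol: approach at 5 μm/s from 50 μm
clearance, geometric contact snapped onto the sampling grid, ramp at the
approach speed to 20% of thickness, 100-s hold sampled at 10 Hz (1,001
hold samples). Phase boundaries are constructed by sample index, so a
noiseless simulation pushed through the full pipeline reproduces the
generating Prony curve to machine precision — the conservation property the
tests quantify at 10⁻¹⁰ relative.

Simulator design choices:

- **Contact**: the force channel registers the touch load as a snap-on
  offset at geometric contact, riding on the elastic ramp response
  (touch_load + A·E(0)·strain). For a ~1.8-kPa gel the elastic force alone
  would cross the 10-mg threshold only ~9 μm deep, which would bias every
  detected thickness; the snap-on keeps noiseless detection exact to one
  position step. The offset is confined to the ramp (the hold force is the
  pure material response) and is absorbed by the stiffness regression's
  intercept.
- **Ramp response**: elastic at the instantaneous modulus E(0); the
  relaxation clock starts at hold start. A hereditary-integral ramp
  correction is deliberately out of scope, matching the hold-only analysis.
- **Noise**: additive Gaussian on stress with σ = `noise_sigma` × E(0)
  (default 1%), applied to all phases. At that level the force noise is
  ~17% of the touch-load threshold, so noisy contact detection lands a few
  μm (a few tenths of a percent of thickness) past geometric contact — the
  same bias a real instrument incurs. No noise model for the position
  channel.
- **Collapse**: after `collapse_time_s` the hold force decays exponentially
  to baseline with a 0.2-s time constant. This is a testing device for the
  QC path, not a physical model of gel failure.

`simulate_cohort` reproduces the study layout — donors × 3 pregel
solutions × duplicates, ids like `NAM2B-1` — with hierarchical variation:
donor-level element parameters drawn around the group template (E normal
truncated at zero, CV 25%; τ log-normal, log-SD 0.3), pregel-level
deviations at 0.6× and replicate-level at 0.2× of those scales, emulating
the large intradonor (pregel-to-pregel) spread these gels show. The
NAM-like template is a dominant sub-second element (1.2 kPa, τ 0.4 s) plus
an ECM element (0.5 kPa, τ 4 s), with a 30% chance of a third slow element
(0.25 kPa, τ 30 s); DAM-like cohorts assign every trace a collapse time
drawn uniformly from 1–6 s of the hold, reproducing the universal collapse
of the diabetic-derived gels. The generator covers additive noise and
hierarchical parameter spread; it does not emulate position-channel noise,
adhesion/pull-off, substrate compliance, dehydration drift, or nonlinear
strain-stiffening — recovery results bound what the pipeline can do on
ideal-protocol data, not on every real artefact.

## Statistics

Group summaries report mean, sample SD (n−1) and SEM = SD/√n; single-value
groups keep the mean and flag dispersion undefined. Group comparisons use a
one-tailed two-sample t test, pooled-variance Student's by default (Welch
selectable); the direction of the alternative must be stated by the caller,
and zero variance in both groups with equal means returns p = 0.5 with a
flag. No multiple-testing correction is applied by default (a Holm-style
correction can be layered by the caller); collapse-flagged samples are
excluded from all viscoelastic summaries and book-kept with reasons.

## Problem sizes and tolerances

The validation studies use 100 replicates for two-element recovery
(median parameter errors ≈ 0.3–1.5%, well under the 10% bound; order 2
selected in 100/100), 20 curves against a 400×400 exhaustive log-grid
oracle for single-element fits, 50 curves for chi-squared monotonicity
over orders 1–4, and 18–24-trace cohorts for the end-to-end, dominance and
exclusion properties. These sizes give stable medians and rates while
keeping the full validation run under a few minutes on one CPU.

## Known limitations

- Exponential-sum fitting is ill-conditioned when τs are closer than
  ~half a decade; recovered (Eᵢ, τᵢ) pairs can trade off against each other
  while fitting E(t) equally well. The recovery guarantees hold for
  decade-separated elements, which is the regime these gels occupy.
- Engineering strain at 20% compression ignores finite-deformation
  corrections; stiffness is an apparent modulus tied to this protocol.
- The hold-only analysis discards ramp-phase viscoelastic information; a
  gel with τ comparable to the ramp duration partially relaxes during
  loading, and its fitted E(0) underestimates the true instantaneous
  modulus. The simulator's elastic-ramp idealisation hides this effect by
  construction.
- Total relaxation can marginally exceed 100% on noisy, fully relaxed
  curves (the final sample fluctuates below zero); it is reported as
  computed, not clipped.
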