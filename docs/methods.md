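# Methods

`lungpet` quantifies reversible radiotracer binding in lung tissue from a
dynamic thoracic PET acquisition, an image-derived whole-blood input
function (IDIF), and venous blood sampling.  This note records the models,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Data model

An acquisition is a contiguous **frame schedule** starting at t = 0; the
default is the 50-frame, 60-min schedule 24 × 5 s, 6 × 10 s, 3 × 20 s,
2 × 30 s, 5 × 60 s, 10 × 5 min.  A **time–activity curve (TAC)** stores the
frame-averaged activity concentration (kBq/mL) of a region — whole lung or
the pulmonary-artery blood pool.  Venous **blood samples** (nominally 2, 5,
10, 15, 30, 45, 60 min) provide whole-blood and plasma activity and the
parent (unmetabolised) fraction.  Times are seconds internally; rate
constants are per minute, converted at a single boundary when the
convolution grid is built.  TAC values are assumed decay-corrected to
injection time; this is an input contract, not enforced.

## Input function

Kinetic fitting requires the concentration of parent tracer in plasma.  Two
multiplicative corrections are applied to the IDIF: the plasma-to-whole-blood
activity ratio, and the parent fraction, both interpolated
piecewise-linearly from the blood samples to the TAC frame midpoints with
flat extension outside the sampled range (splines overshoot with ~7
samples).

A framed TAC stores frame *averages*.  Reading those as instantaneous
midpoint samples flattens the bolus peak, and on noiseless simulations that
single approximation biased recovered micro-parameters by 10–20 %.
`prepare_input` therefore performs an *average-consistent reconstruction*:
the midpoint knot values are adjusted by a damped fixed-point iteration
(10 iterations, clipped non-negative) until the piecewise-linear curve
through them reproduces the measured frame averages.  The iteration
converges everywhere except the bolus-onset frame, where a midpoint-knot
interpolant cannot represent the sub-frame arrival time; the residual there
is accepted and is the dominant remaining source of input error (it mostly
affects K1; BP_ND bias on noiseless simulations drops below 1 %).  The
plain midpoint convention remains available (`average_consistent=False`).

No dispersion or delay correction between the blood pool and tissue is
applied, and no arterial–venous conversion is modelled.

## Compartment models

The measured region concentration is modelled as

    C_model(t) = (1 − vB) · (h ⊛ Cp)(t) + vB · C_wb(t)

with Cp the parent-plasma input, C_wb the whole-blood curve, vB the
fractional blood volume, and h the reversible two-tissue-compartment (2TC)
impulse response

    h(t) = K1/(α₂−α₁) · [(k₃+k₄−α₁) e^{−α₁t} + (α₂−k₃−k₄) e^{−α₂t}],
    α₁,₂ = ((k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)) / 2.

The one-tissue (1TC) model is the k₃ = k₄ = 0 special case, h = K1 e^{−k₂t}.
Macro-parameters: BP_ND = k₃/k₄, K1/k₂, and V_T = (K1/k₂)(1 + BP_ND); the
identity V_T = (K1/k₂)(1 + BP_ND) holds exactly for every fit by
construction.

Numerics:

* The tissue convolution is evaluated on a uniform 0.5-s grid using an
  exact piecewise-linear exponential update, computed as a first-order
  linear recurrence (`scipy.signal.lfilter`); this is stable for stiff
  exponentials where naive quadrature degrades.  Halving the grid changes
  the fitted V_T by well under 0.1 % (tested).
* Frame averages of the modelled tissue curve come from a cumulative
  trapezoid on the grid.  The blood term needs no grid at all: the frame
  average of vB·C_wb(t) is exactly vB times the measured whole-blood frame
  value, so the measured values are used directly.  This makes the
  noiseless simulate→fit round trip exact to machine precision when the
  true input is supplied.
* Near-degenerate eigenvalues (α₂ − α₁ < 1e-9) are separated by a 1e-9
  nudge; the induced error is O(1e-9·t) and the configuration is only
  reachable at the k₃ → 0, k₂ ≈ k₄ boundary.

## Fitting

Weighted least squares (uniform weights by default; optional
frame-duration weights with variance ∝ value/duration) minimised by a
bounded trust-region solver (`scipy.optimize.least_squares`, tight
tolerances) from 10 deterministic Latin-hypercube starts — log-uniform over
[0.01, 10] /min per rate, uniform over the vB box — because the 2TC
objective is multi-modal.  Bounds: rates in (0, 10] /min; vB either fixed
(e.g. 0.15) or floating in [0.05, 0.3], the physiologic lung blood-volume
window.  The best of all starts is returned with a convergence flag and
the start count.  The fit window defaults to the first 40 min of the
acquisition (46 frames); the full 60 min is available by argument.
Reported parameters are canonical: α₁ < α₂ and non-negative rates, which
resolves the classic 2TC micro-parameter exchange ambiguity.

Model comparison uses the least-squares Akaike information criterion
AIC = n ln(RSS/n) + 2k (no small-sample correction; an AICc variant is
provided).  `select_model` returns the minimum-AIC fit, ties going to the
fewer-parameter model.  Absolute AIC values depend on data scale and frame
count and are not comparable across datasets.

## Logan graphical analysis

For reversible tracers, y(T) = ∫₀ᵀC_lung/C_lung(T) against
x(T) = ∫₀ᵀC_p/C_lung(T) becomes linear after an equilibration time t*
(default 10 min), with slope estimating V_T.  Integrals are trapezoidal on
the frame-midpoint grid anchored at the origin; frames with midpoint after
t* enter an ordinary least-squares line (at least 3 required).  The
analysis is applied to the measured lung TAC including the blood signal
(vB is not removed), which leaves a small documented bias; on noiseless
simulations the slope sits within ~1 % of the true V_T at 60 min, and the
bias shrinks monotonically as the analysis window grows from 20 to 40 to
60 min (tested).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Plasma input**: Feng-style tri-exponential bolus
  Cp(u) = (A1·u − A2 − A3)e^{−λ₁u} + A2e^{−λ₂u} + A3e^{−λ₃u}, u = t − delay,
  zero before onset and continuous at it.  Defaults (A1 = 600 kBq/mL/min,
  A2 = 6, A3 = 2.5 kBq/mL, λ = 4, 0.5, 0.008 /min, delay 0.3 min) give a
  sharp sub-minute peak near 55 kBq/mL and a ~1.5 kBq/mL tail at 60 min —
  a realistic venous-bolus shape chosen once as a convention, since no
  numeric input-function values are published for this tracer cohort.
* **Parent fraction**: single exponential to a floor,
  pf(t) = floor + (1 − floor)e^{−t/τ}, defaults floor 0.15, τ 20 min —
  monotone by construction, matching a rapidly metabolised tracer.
* **Plasma-to-whole-blood ratio**: linear, default constant 1.26.
* **Lung kinetics**: the reversible 2TC model with vB in [0.05, 0.3].
  Cohort draws are mean-parameterised log-normals (default CV 0.2) centred
  per group on the study cohort's means (K1, K1/k₂, BP_ND, vB); k₄ is not
  separately published for lung and is set to 1.0 /min, so k₃ = BP_ND·k₄.
* **Noise**: Gaussian per frame with variance ∝ value/duration scaled by
  α (default 0.1, ≈5 % of the peak on 5-s frames), applied to the lung TAC
  only; α = 0 or mode "none" makes the whole pipeline deterministic.  All
  randomness is owned by explicit seeds.

The generator does not simulate images, scanner resolution, motion,
scatter, or correlated frame noise, and the blood data are noise-free.
Passing simulation tests therefore demonstrate correctness of the
estimators and their implementation — not robustness to the full error
structure of measured PET data.

## Embedded study table

The 15-subject kinetic-results table (three groups of five) is embedded
verbatim and checksummed.  Reproduced group/pooled means ± SD match the
printed block at 2-decimal display precision (round-half-away-from-zero)
for every cell except three means (EC V_T 0.96 vs 0.97, CIG K1/k₂ 1.14 vs
1.13, CON K1 2.00 vs 1.99), each off by exactly 0.01 — the signature of a
summary computed from unrounded source data.  Tie-corrected Kruskal–Wallis
with the chi-square approximation reproduces the printed omnibus P values
for V_T (0.36), K1 (0.09), BP_ND (0.02) and vB (0.31); the K1/k₂ cell
computes to 0.02 vs the printed 0.03 from the rounded inputs.  One printed
row (CIG-22) violates the V_T = (K1/k₂)(1 + BP_ND) identity by ≈0.06;
all others agree within 0.02.

## Statistics

Group summaries are arithmetic mean and sample SD (n − 1).  The
Kruskal–Wallis test uses mid-ranks, the tie-correction factor
1 − Σ(t³−t)/(N³−N), and the chi-square upper tail with g − 1 degrees of
freedom.  The Mann–Whitney test is *exact* for pooled n ≤ 16: U counts
pairs with ½ for ties and the two-sided p is P(|U − μ_U| ≥ |u_obs − μ_U|)
over all C(n_x+n_y, n_x) group assignments; larger samples use the normal
approximation with tie-corrected variance and no continuity correction.
Spearman correlation uses mid-ranks with the two-sided t-approximation.
No multiple-testing adjustment is applied (post hoc p-values are reported
unadjusted).  Sidedness and exactness visibly change small-sample
p-values, hence these conventions are fixed and documented.

## Problem sizes

The test-suite and acceptance computations use the 50-frame schedule with
40-min fit windows, one canonical noiseless subject for recovery checks, a
15-subject noiseless cohort (5 per group) for the Logan–2TC comparison,
and 4 noisy subjects per generating model for AIC selection — sizes chosen
to match the study design while keeping a full run in tens of seconds.

## Known limitations

* Identifiability: at low k₃ or k₂ ≈ k₄ the 2TC micro-parameters are
  weakly identified; V_T remains stable (macro-parameters are the robust
  outputs, as the Logan cross-check shows).
* The input reconstruction cannot represent a sub-frame bolus arrival;
  K1 estimated from framed noiseless data carries a few-percent bias even
  though BP_ND and V_T do not.
* Kruskal–Wallis p uses the chi-square approximation, adequate at n = 5
  per group for the reproduced values but not an exact permutation p.
* No decay-correction handling, no irreversible (Patlak) modelling, no
  voxelwise parametric imaging.
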