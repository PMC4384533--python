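# Methods

This note records the models implemented in `bombpulse`, their assumptions,
the defaults that matter, and the numerical and design choices made where
the underlying methodology left the choice open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Atmospheric record

The calibration reference is a tabulated fraction-modern record
F_atm(t) ± σ_c(t) on decimal calendar years. Both value and uncertainty are
interpolated **piecewise linearly**, exactly at the knots, and never
extrapolated: calibration priors and turnover-model spans must lie inside
the tabulated domain. Users supply their own hemispheric compilation as
delimited text (`year,f14c,sigma`); a pre-bomb tree-ring segment can be
spliced onto a bomb-pulse segment at a boundary year, with each side
filtered to its own side of the boundary.

Dates are decimal years throughout. A documented "year of birth" is known
to ± six months, so the file reader maps whole-number birth years to
mid-year (YYYY.5) by default (`midyear_births="auto"`).

### Synthetic pulse

No third-party compilation is redistributed. Instead a fully synthetic
southern-hemisphere-shaped pulse serves as a self-contained reference on
[1900, 2000]:

| piece | span | form |
|---|---|---|
| Suess decline | 1900 ≤ t < 1955 | 0.980 − 0.0002 (t − 1900) |
| weapons-testing rise | 1955 ≤ t < 1965 | 0.969 + 0.0631 (t − 1955) |
| post-peak decline | 1965 ≤ t ≤ 2000 | 1 + 0.600 e^{−(t−1965)/16} |

with σ_c = 0.005 everywhere. The pieces are continuous at both joins, peak
at 1.600 in 1965, and fall to 1.067 by 2000; the 16-yr e-folding time and
peak height mimic the real southern-hemisphere pulse shape. These are
synthetic parameters for testing, not a published dataset.

## AMS reduction

Reduction to fraction modern uses the internationally standard convention:
the sample ratio is fractionation-normalised to δ¹³C = −25‰ with the
squared factor [0.975/(1 + δ/1000)]², then divided by 0.95× the
(−19‰-normalised) oxalic-acid-I standard ratio. The instrument background
(radiocarbon-free graphite, fraction-modern equivalent) is removed by
linear subtraction — adequate because backgrounds are far below sample
levels — with sigmas combined in quadrature and negative results clipped to
zero and flagged.

Procedural-blank carbon (solvent residue carried through extraction,
realistically 10–20 μg against 70–120 μg targets) is removed by
two-component mass balance with **total-mass semantics**: the combusted
target of mass M contains m_b μg of blank carbon at f_b, so
f_s = (f_m·M − f_b·m_b)/(M − m_b). A blank mass at or above the total is an
error (the blank dominates). Uncertainty propagates first order over
(f_m, f_b, m_b); a seeded Monte-Carlo alternative is available and agrees
with the delta method to within ~10% at realistic inputs.

Where no counting statistics accompany a measurement, a per-batch precision
policy supplies sigma: 0.5% relative for targets ≥ 50 μg carbon, 2% below,
scaled by optional per-batch multipliers (batches prepared on different CO₂
handling lines differ in precision).

F¹⁴C is treated as already decay-standardised; no additional radioactive
decay correction is applied over decadal spans (the calibration record uses
the same convention, and the effect is < 1%).

## Calibration

For a measurement F ± s the likelihood at year t is Gaussian with variance
s² + σ_c(t)² — the curve's uncertainty enters additively, as in standard
calibration software. The posterior is the likelihood times a uniform prior
over a user-set range, normalised on a regular grid (default step 0.05 yr).
Normalisation is done in log space, so very small sigmas do not underflow.

* **Modes** are maximal contiguous grid runs with posterior above
  peak × 10⁻³.
* **HPD intervals** (68.3%, 95.4%) collect cells in descending density.
* **Point estimate**: the posterior mean of the highest-mass mode (ties
  toward the earlier mode). An alternative rule selects the mode nearest a
  documented reference year — appropriate for validation studies where the
  truth is known and the question is measurement fidelity, since the pulse
  makes post-bomb posteriors bimodal. The rule used is recorded per donor.
* The per-donor uncertainty reported by the pipeline is the half-width of
  the 68.3% HPD of the selected mode, floored at half a grid step.

`invert_monotone` provides the deterministic counterpart — bisection of the
interpolated curve on a strictly monotone limb to 10⁻⁶ yr — and is used as
an independent oracle: in the small-measurement-noise limit, with the prior
restricted to one limb, the posterior point estimate agrees with the
bisection root to within two grid steps. Two caveats delimit that
equivalence, both consequences of the posterior-mean rule rather than
defects: (i) near a prior edge the truncated posterior's mean shifts away
from the root, so oracle comparisons sample targets several posterior
widths inside the prior; (ii) on the nearly flat pre-bomb limb
(|dF/dt| = 2×10⁻⁴/yr) the curve uncertainty alone (0.005) spans ~25
calendar years, so a point year there is dominated by the prior — the
package reports the full (wide) posterior, which is the honest answer, and
the oracle equivalence is checked on the two bomb limbs.

A further small-sigma regime is worth naming: when the measurement sigma is
far below the grid's F¹⁴C resolution, each limb's posterior collapses to
its single nearest grid cell and the *relative* mass of the two limbs
degenerates into a rounding lottery. Identity checks therefore use sigmas
at or above the grid resolution (10⁻³ at 0.05-yr steps), or a
limb-restricted prior.

## Turnover model

The minimal formalisation of "does this pool exchange carbon?" is
one-compartment first-order exchange at rate k (per year):

F(T) = e^{−kΔ} F_atm(t₀) + ∫ₜ₀ᵀ k e^{−k(T−u)} F_atm(u) du,  Δ = T − t₀,

with the exact limits F_atm(t₀) at k = 0 and F_atm(T) as k → ∞. For birth
years at the record's start the integral simply starts there; no earlier
exposure history is modelled. The integral is evaluated segment-exactly:
on each sub-interval of a (default 0.1 yr) grid the curve is linear, and
k e^{−k(T−u)}(a + bu) has the closed-form antiderivative
e^{−k(T−u)}(a + bu − b/k), so the quadrature is exact for affine curves at
any step and O(h²) otherwise.

The fit profiles the Gaussian log-likelihood (measurement sigmas taken as
known) over a fixed grid of rates — 0 plus 60 log-spaced points in
[10⁻⁴, 1]/yr — then polishes the maximiser by bounded continuous
optimisation around the grid argmax. Confidence intervals are
likelihood-ratio intervals at deviance 1.00 (68%) and 3.84 (95%) for one
parameter, with the endpoints located by **root-finding the continuous
deviance** between bracketing grid nodes rather than read off the grid:
near informative data the likelihood-ratio interval is several times
narrower than the grid spacing, and grid-resolved endpoints undercover
badly (simulation during development showed ~56% instead of 95% at
k = 0.1/yr with grid-snapped intervals, restored to the nominal range by
continuous endpoints — the coverage test in the suite verifies ≥ 90% over
200 replicates). The likelihood-ratio statistic against k = 0 sits on the
parameter boundary, so its null distribution is the 50:50 mixture of a
point mass at zero and χ²₁; the reported p-value is one-sided and
boundary-corrected.

## Contamination mass balance

δ¹³C mixing is linear in the carbon weight fraction,
δ_mix = (1−f)·δ_base + f·δ_source, rather than exact ratio mixing; at the
enrichments involved (source up to ~+9000‰, shifts of a few ‰) the
approximation error is below 0.1‰. The inverse
f = (δ_obs − δ_base)/(δ_source − δ_base) carries first-order propagated
uncertainty; negative solutions are clipped to zero and flagged, and a
source equal to the base is a degenerate-tracer error. Atom fractions
convert to δ via R_VPDB = 0.0111802. The same two-component mixing applied
to fraction modern quantifies how a given contamination level would bias a
radiocarbon measurement; it is the exact inverse of the blank mass-balance
correction when the fraction is expressed as masses.

The labelled-solvent experiment this supports is deliberately reported as
*f for a user-specified source delta*: the package asserts the mass-balance
algebra (round-trip exact to 10⁻¹²), not any particular published fraction,
because the inferred f depends strongly on whether the stated enrichment
refers to the methanol or to the solvent mixture.

## Cohort pipeline and validation regression

`BirthDateModel.fit()` reduces raw records if present (normalise →
background → blank), calibrates each donor, applies the configured point
rule, and regresses predicted on documented birth year by unweighted OLS
(statsmodels); a 1/σ²-weighted WLS variant is available behind a flag. The
regression direction — predicted (response) on documented (predictor) — is
the natural validation orientation. Stage failures attach to the affected
donor and never alter other donors' results; flagged donors are excluded
from the regression with the reason recorded. Output files round years to
0.01; full precision is kept internally.

## Synthetic cohorts

The default `CohortSpec` encodes the emulated study design: 23 donors with
birth dates evenly spaced mid-1948 to mid-1993 (uniform sampling
optional), collection in 2010, no turnover (k = 0), 1% absolute F¹⁴C noise,
70–120 μg targets, 10–20 μg blanks at f ≈ 0.6, batches of 5–6 with
per-batch precision multipliers. One seeded generator drives all
randomness; the seed and every ground-truth quantity are written to a
sidecar table so blinded testing is possible. The raw-record generator
inverts the reduction chain (mix blank, add background, emit ratios at
δ¹³C ~ N(−22.7, 0.5)) so that reduction recovers the mixed values to
machine precision.

What the generator does **not** emulate: the food-chain lag between
atmospheric fixation and tissue biosynthesis (the tissue is assumed to
reflect the birth-year atmosphere directly), lipid-class-specific turnover,
within-lens spatial structure, and real calibration-curve error
correlation. Passing tests therefore demonstrate the correctness and
calibration of the *inference machinery* under the stated noise model, not
the biology of any particular tissue.

## Problem sizes and scale choices

The validation regression uses 23 donors on the falling limb (births
1966–1993, where the pulse is steep enough that a 1% measurement maps to
~0.5–1.5 yr of calendar uncertainty); donors born before ~1955 sit on the
nearly flat pre-bomb limb where bomb-pulse dating is intrinsically
imprecise, and including them mainly demonstrates that wide posteriors are
reported honestly. Turnover-recovery checks use 200 replicates of 23-donor
cohorts at k ∈ {0, 0.1}/yr with 1% noise. The calibration oracle comparison
uses 50 random on-curve targets split between the rising and falling limbs.
The fixed cohort seed used by the acceptance script (20150311) identifies
one defined validation cohort so its statistics are reproducible
bit-for-bit.

## Known limitations

* Point years on the pre-bomb limb are prior-dominated; report intervals,
  not points, for pre-1955 material.
* The two-limb ambiguity of post-bomb values is resolved by posterior mass
  by default; when an independent documented date exists, the `nearest`
  rule is the right validation tool, and neither rule can help a value
  lying near the 1965 peak where the modes merge.
* The turnover likelihood treats measurement sigmas as exact and donors as
  independent; batch-level error correlation is not modelled in the fit
  (only in the generator's multipliers).
* Linear δ mixing and first-order error propagation are approximations,
  each documented above with its validity range.
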