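# Methods

## Two-box interhemispheric transport

The atmosphere is modelled as Northern and Southern Hemisphere boxes,
each holding half of the global conversion factor κ (Pg C per ppm of
CO₂), exchanging air with an e-folding time τ (years). With annual
fossil emissions E, ocean uptake O and net land uptake B per hemisphere
(all Pg C/yr, uptake positive), the explicit annual step for the north
box is

    κ_h · (C_N(t+1) − C_N(t)) = E_N − O_N − B_N − κ_h · (C_N − C_S) / τ

with the transport sign flipped for the south box (κ_h = κ/2). Growth
is assigned by forward difference of annual means, matching annual
budget bookkeeping, and — the property everything downstream leans on —
making the inversion the exact algebraic inverse of the forward step:
`invert(forward(x)) = x` to round-off, which the test suite asserts at
1e-9 Pg C/yr.

The inversion solves the north-box identity for B_N. The southern sink
either closes a prescribed global land series (constrained mode, the
default, mirroring how a consensus global land sink is used as a
constraint) or comes from the south-box budget (unconstrained mode).
In constrained mode B_N + B_S equals the prescribed global sink exactly
every year.

**Stability.** The gradient recursion has multiplier (1 − 2/τ) per
year, so the explicit annual step is stable only for τ ≥ 1 yr. The
default τ = 1.3 yr sits comfortably inside that regime; sub-annual
exchange times would require a smaller internal time step, which
nothing in scope needs.

**Defaults** (all overridable, all recorded in run metadata):
τ = 1.3 yr; κ = 2.124 Pg C/ppm; fossil NH fraction 0.94 (emissions are
overwhelmingly northern); ocean NH fraction 0.45 (the anthropogenic
ocean sink is somewhat larger in the south). These are declared
community-convention defaults, not fitted values. One station record
proxies each hemispheric mean with zero offset.

**Uncertainty.** Monte-Carlo (default n = 2000) with independent
Gaussian perturbations: observation noise per annual concentration,
per-year flux sigmas, and the sigma of the prescribed global land sink.
Per-year 1σ spreads and the raw draw matrix are returned so users can
aggregate (e.g. decadal means) across draws rather than assuming
independence of per-year errors — adjacent years share concentration
noise with opposite sign, so naive quadrature over years would
overstate the spread of multi-year means.

**Scenario re-inversion** multiplies fossil and ocean terms (and their
sigmas) while holding observations fixed. Because ∂B_N/∂E_N = +1 at
fixed observations, reducing fossil emissions weakens the inferred
northern land sink — the direction the −6% fossil / +8% ocean scenario
exhibits in every year on calibrated synthetic data.

## Stock-change pathway

`ΔC_LAND = S · ΔC_VEG` converts a satellite-derived change in living
vegetation carbon into whole-ecosystem accumulation. The scale factor
is computed per ensemble member as cumulative NBP over the analysis
window divided by the member's vegetation-carbon change over the same
window, then averaged (±1σ, n−1 denominator) across members. The
approach assumes stock changes originate as perturbations to the
vegetation pool with downstream adjustment of litter and soil — an
input-driven sink — and may overestimate detrital accumulation;
forest-inventory syntheses suggest lower values (presets 1.25 tropical
/ 1.45 temperate are shipped as documented constants only).

Numerical choices:

- **Fusion** of two ΔC_VEG products uses inverse-variance weighting —
  optimal for independent Gaussian errors, deterministic and seedless.
  The merge weights of the published product pair are not public, so
  this is a declared choice. Cells missing in one product take the
  other's value.
- **Product variance** is the exact independent-product formula
  including the cross term, `S²σ_V² + V²σ_S² + σ_S²σ_V²`; a 10⁶-draw
  Monte-Carlo product matches it within 3% (asserted). On the printed
  inputs 10.1 ± 7.0 and 1.6 ± 0.6 this gives 16.16 ± 13.41 Pg C where
  the published table shows 16.0 ± 13.1 — the difference is consistent
  with rounding of the printed inputs, and the exact formula is kept.
- **Interval convention** is midpoint-to-midpoint: the midpoint of 2000
  to the midpoint of 2019 is 19.0 yr.
- **Degenerate members** with |ΔC_VEG| < 0.1 Pg C are excluded from S
  with a warning instead of contributing unbounded ratios.
- **Relative stock increases** infer the start-of-period stock by
  subtracting the cumulative accumulation from the end-of-period stock:
  100 · c / (end − c).
- **Maps**: per-cell percent change is masked where the early-epoch
  stock is below 1 Mg C/ha (relative change over a near-bare baseline
  is uninterpretable); cell areas follow the spherical cosine-latitude
  formula on a regular cell-centred grid, and the area-weighted sum of
  the absolute-change map reproduces the scalar ΔC_VEG to 1e-9
  relative. The Northern Hemisphere aggregation boundary is the
  equator.

## Budget ledger

All uncertainties are independent 1σ Gaussians; propagation is in
quadrature, and `mc_propagation_check` verifies the assumption against
10⁵ Monte-Carlo draws (agreement within 5% asserted). Scenario closure
multiplies terms and their sigmas; an adjustment of the atmospheric
growth rate beyond 1% triggers a hard warning because that term is
measured too precisely to be a tuning knob. The residual-term
uncertainty routine runs the classic land-sink-by-difference logic in
reverse: with the land sink measured, the fossil term inherits the
quadrature sum of the other sigmas (0.1, 0.5, 0.7 Pg C/yr against a
mean of 8.1 gives ±10.7%, printing as ±11%). Percent differences are
kept unrounded internally and rounded only at report time (−5.8 prints
as −6). Ocean recalibration scales the whole series so the 1994–2007
mean matches a data-constrained target plus a user-supplied
natural-loss adjustment; the adjustment has no published scalar value
and therefore no default other than zero.

## O₂/CO₂ partitioning

In Pg C-equivalent units, `dO₂ = −α_F·F + α_B·B + Z`: fossil combustion
consumes O₂ at its oxidative ratio α_F, land carbon storage releases it
at α_B, the ocean carbon sink is O₂-neutral, and Z is net ocean O₂
outgassing. With the carbon budget `F = dCO₂ + B + O` this is a linear
2×2 system; the partition routine solves it directly, propagates
uncertainties by Monte-Carlo over F, Z and the two trends, and the
forward/inverse round trip is exact to machine precision. Closed-form
sensitivities ∂B/∂F = α_F/α_B > 1 and ∂O/∂F = 1 − α_F/α_B < 0 are
asserted numerically: a fossil reduction simultaneously weakens the
inferred land sink and strengthens the inferred ocean sink.

Unit bridge: 1 per meg/yr = 10⁻⁶ × X_O₂ × N_air mol O₂/yr with
X_O₂ = 0.20946 and N_air = 1.769 × 10²⁰ mol (≈ 3.706 × 10¹³ mol/yr),
times 12 × 10⁻¹⁵ for Pg C-equivalent. Defaults α_F = 1.38, α_B = 1.10
follow the standard O₂-partitioning convention; the published
analysis's exact α values, Z and station weights live in supplementary
material that is not available, so these are declared, overridable and
logged. Trends from raw records use OLS on annual means by default;
`mean_rate` (endpoint difference over the span) is provided because it
recovers the exact mean tendency of an accumulated record when the
tendency drifts, which OLS does not.

## Ensemble diagnostics

Carbon-use efficiency is NPP/GPP per year. The down-regulated-NPP
scenario damps each year's relative NPP increment to a fraction
(default 0.5) of GPP's concurrent relative increment:
`NPP′(t) = NPP′(t−1)·(1 + d·(GPP(t)/GPP(t−1) − 1))`. Year-over-year
anchoring (rather than increments relative to a fixed baseline) is the
only formulation that makes the trajectory independent of window
splitting, which a property test asserts. Under 1%/yr GPP growth with
d = 0.5, NPP grows by 1.005ᵀ while GPP grows by 1.01ᵀ, so CUE declines
by (1.005/1.01)ᵀ — a factor 0.707 over 70 years, 0.499 over the full
140-year idealised run.

Bias statistics report the multimodel mean ± sd (n−1) and
100·(mean − reference)/reference. Variance explained is the squared
Pearson correlation; the cross-model mode attaches a seeded permutation
p-value (10⁴ permutations, add-one corrected so p is never exactly
zero), and the within-model spatial mode averages per-member R² between
per-cell ΔC_VEG and per-cell cumulative NBP. Spatial cells are
unweighted by default (the published choice is unstated); area
weighting can be applied by the caller through the cell arrays.

## Synthetic data

The generator produces the study conditions, not tuned test cases:
2000–2019; fossil emissions growing 2%/yr from 7 Pg C/yr (period mean
≈ 8.5 Pg C/yr); ocean sink 29% of the fossil trend (≈ 2.5 Pg C/yr);
land-sink truth 1.6 Pg C/yr, 85% northern; per-term sigmas
0.4/0.1/0.4/0.6 Pg C/yr; 17 ensemble members with S drawn from
N(1.6, 0.6) truncated at 1 (detrital pools accumulate) unless
prescribed; carbon-use efficiency 0.5; a 24 × 48 global grid carrying a
true vegetation-carbon gain of 10.1 Pg C confined to a random 10% of
cells. The budget closes exactly by construction: the growth rate is
derived so fossil = growth + ocean + land holds with the land term
equal to the configured truth. Station records come from the forward
two-box model and O₂ records from the forward O₂ budget (levels at
year starts, so N flux years give N+1 points and the endpoint rate is
the exact mean tendency). Noise is independent Gaussian on annual
values. One master seed spawns a deterministic child seed per stream;
identical config and seed reproduce bit-identical outputs.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: seasonal cycles and ENSO-scale
variability, autocorrelated or systematic (non-Gaussian) errors,
realistic spatial covariance of biomass uncertainty, rectifier effects
or any 3-D transport structure, and drift between station proxies and
true hemispheric means. Round-trip exactness demonstrates internal
consistency of the discretisation and algebra, not skill against real
observations; the published headline series (cumulative northern sink,
decadal means, observed O₂ case values, the ensemble-derived
S = 1.6 ± 0.6) require the real station, budget, ocean-model and
ensemble inputs, which the pipeline accepts as external files but does
not bundle.

## Problem sizes

Defaults keep everything fast and deterministic: 20-year series, 2000
Monte-Carlo draws for inversions and partitioning, 10⁵ draws for the
quadrature check, 10⁶ only in the product-variance test, 17-member
ensembles, 24 × 48 grids. The full test suite runs in a few seconds;
the acceptance script in well under a minute.

## Known limitations

- The explicit annual step requires τ ≥ 1 yr (above).
- Constrained-mode inversion inherits any bias in the prescribed global
  land series; unconstrained mode instead inherits south-box flux
  errors.
- The scale factor treats the ensemble spread as the full uncertainty
  of S; structural error shared across members is not represented.
- Quadrature propagation ignores correlations between budget terms by
  design.
- The O₂ pathway assumes constant oxidative ratios and a scalar Z over
  the analysis window.
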