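# Methods

This note records what the model computes, which parameters are
measurements and which are the package's own calibrated choices, the
numerical methods, and the limits of what the simulations show.

## Scope and time convention

The model follows one DJ123 upland-rice plant in a homogeneous, strongly
P-fixing Andosol for 35 simulated days with a maximum time step of
0.2 days. The seed is planted at simulation day 0; shoot emergence
(0 days after emergence, DAE) is day 3, so the standard reporting day 31
corresponds to 28 DAE. Root growth is driven by the observed development
of P-deficient plants, not by a carbon budget: under severe P limitation
the binding resource accounted for is phosphorus itself.

## Root architecture

### Axes and classes

Six root classes are modelled: the primary root; branched, fast and
tiller-node nodal (crown) roots; and L-type and S-type laterals. Main
axes are integrated stepwise as 3D polylines; laterals grow straight
along their emission heading. The straight-lateral simplification is
deliberate: laterals carry no gravitropism, their headings are corrected
to horizontal when pointing upward ("cannot grow up"), and the random
impedance acting on the short, fine laterals has negligible geometric
effect at the 1–15 cm scale — while making systems of ~5,000 S-type axes
cheap enough to evaluate thousands of times in scans.

### Elongation

Each class elongates along rate(a) = peak · rise(a) · fall(a) of axis age
a: a quintic ramp from 0 to the class peak over 2 days (so the maximum is
reached at the early edge of the observed 2–10 d window), a plateau, and
a linear 1-day decline whose onset is solved so the lifetime integral
equals the class maximum length. Table of class constants (measured):

| class          | diameter cm | max length cm | peak cm/d | hair density cm⁻¹ | hair length cm |
|----------------|------------|---------------|-----------|-------------------|----------------|
| primary        | 0.065      | 46            | 2.19      | 1400              | 0.020          |
| nodal branched | 0.050      | 35            | 1.46      | 1400              | 0.015          |
| nodal fast     | 0.065      | 45            | 2.14      | 1400              | 0.015          |
| nodal tiller   | 0.060      | 40*           | 1.80*     | 1400              | 0.015          |
| L-type         | 0.020      | 14.6          | 0.73      | 700               | 0.015          |
| S-type         | 0.0045     | 1.08          | 0.14      | 400               | 0.012          |

(*) the tiller-node class is qualitatively "in between" the branched and
fast classes; its constants are the package's interpolation, not
measurements.

Per-axis variability comes from a truncated lognormal rate multiplier
(median 1, σ = 0.3, bounds [0.25, 2.5]) that scales the rate and hence
final length, chosen to reproduce a realistic spread of lateral lengths
without materially exceeding class maxima.

### Emission

Crown roots emerge from the hypocotyl point at 2.3 roots d⁻¹ from day 4,
slowing to 1.5 d⁻¹ after day 10 (the observed slowdown; the cumulative
count is concave). The first roots are all of the branched class; fast
nodal roots appear only after day 10 and their share of new roots ramps
up (6 %/day, capped at 75%). Once tillers exist (defaults: days 12, 16,
20) a share of new crown roots (15% per tiller, capped at 45%) emerges
from tiller nodes instead. These schedule constants are calibrated to the
observed crown-root counts (~45 at 28 DAE) and nodal length (~11 m), not
measured.

Laterals are emitted where the parent tip's cumulative growth crosses
IBD-sampled distances; the emission heading is perpendicular to the local
parent tangent at a uniform radial angle. Child birth time follows from
inverting the parent's elongation curve, so branch timing is exact within
a step. Fast nodal roots double their IBD during the first 14 days of
system development and increase it in proportion to distance from the
base thereafter (their basal halves are the densest).

IBD distributions are truncated normals. **The IBD values are calibrated,
not measured** (the raw branching data were not published): S-type on
nodal/L-type parents mean 0.6 cm (sd 0.18, bounds 0.28–1.2), L-type on
nodal mean 3.1 cm (sd 1.1, bounds 1.1–6.2), with 0.9× these means on the
primary root (the most densely branched axis). They were fixed in one
calibration pass against the observed day-31 class composition — S-type
≈ half of total root length, L-type ≈ one third, nodal + primary the rest,
total ≈ 60–75 m — and then left alone.

### Tropism and angles

Heading update per step: h ← normalize(h + |g|·Δℓ·ẑ + η), with g the
published per-class gravitropism (primary −0.065 as the midpoint of the
printed −0.115…−0.015 range; crown roots −0.0001; laterals 0) applied per
cm grown, and η an isotropic perturbation of magnitude 0.08·√dt
(impedance; package default). Nodal root growth angles (from the
horizontal surface) are 8° + 82°·Beta(1.4, 2.2): mode 28.5°, support
[8°, 90°], P(≤45°) = 0.620, matching the excavation statistics.

## Root hairs

Hairs are explicit cylinders (diameter 5 µm; class-specific length) in
cohorts attached to every segment: all hairs of a cohort share geometry,
so cohort totals (count × one cylinder) are exact. Density starts at the
class ceiling and declines linearly with segment age — the published
600 → 330 hairs cm⁻¹ decline between ages 3 and 40 d, applied as a
relative decline (−1.216 %/day of the ceiling) to every class because
per-class decline rates were not published. Hair age equals host-segment
age. The hair ledger (length, surface, volume, weight at 0.1 g cm⁻³) and
per-host-class shares feed both uptake and cost accounting.

## Phosphate uptake

### Governing equation

Each root segment and each hair owns a radial domain r₀ ≤ r ≤ r₁ with

    b ∂C/∂t = (1/r) ∂/∂r ( r·De·b·∂C/∂r + r·v(r)·C ),  v(r) = v₀·r₀/r,

Michaelis–Menten influx Imax·(C−Cmin)/(Km+C−Cmin) at r₀ and zero flux at
r₁. C is solution concentration (µmol mL⁻¹). Soil constants (measured):
buffer power b = 6000, De = 9.227·10⁻⁶ cm² d⁻¹; v₀ = 0 (no
transpiration-driven mass flow is modelled). The initial solution
concentration defaults to 540 nM — the published recalibration of the
measured 83 nM that stands in for unmodelled rhizosphere P solubilization;
both values are kept in the parameter set.

### Kinetics constants

The Michaelis–Menten constants were not published. Km = 5.8·10⁻³
µmol mL⁻¹ and Cmin = 10⁻⁵ µmol mL⁻¹ are rice-literature placeholders;
Imax was fixed once by bisection so that the day-31 plant P content of
the default architecture (reference seed 20210312) equals the measured
774.3 µg under the 540 nM soil, giving Imax = 0.759 µmol cm⁻² d⁻¹. At
that operating point uptake is largely diffusion/supply-limited (surface
concentrations are drawn far below bulk), which is also why uptake per
unit root length is nearly uniform across classes and stays ~11 µg m⁻¹
over time, as observed. The calibration routine is exposed
(`oryzaroot.uptake.calibrate_imax`); hairs use the same kinetics per unit
area as roots (whether they differ was not published).

### Outer radii

For root segments r₁ is half the local mean inter-root distance,
1/√(π·RLD) from root-length density on a 1 cm³ voxel grid, clipped to
[0.2, 2] cm and aggregated per class (length-weighted mean). Because the
28-day depletion length √(4·De·t) ≈ 0.03 cm is far below the 0.2 cm
floor, this choice barely affects uptake. For hairs the same rule is
applied at the hair scale: r₁ = ½·√(2π·r_root/density), half the mean
spacing between hairs on the host surface (~0.005–0.01 cm). This matters:
it caps each hair's soil allotment, so raising hair *density* mostly
subdivides the same soil volume (weak uptake response) while raising hair
*length* claims new soil (strong response) — the model's headline
sensitivity ranking emerges from geometry, not tuning.

### Numerics

Conservative finite volumes on a logarithmic grid (40 nodes by default,
first cell ≈ the one-step depletion length), implicit Euler steps with a
Newton linearization of the nonlinear boundary (the flux slope enters the
matrix diagonal, which is stable at large Imax), iterated to 10⁻¹⁰ on the
surface concentration. Because the recorded uptake is exactly the flux the
matrix applied, soil P removed equals plant P gained to linear-solver
precision at every step; the global run residual is ~10⁻¹². Degenerate
inputs: C below Cmin yields zero influx; Imax = 0 leaves the domain
untouched.

### Factorized integration

The soil starts homogeneous and every new segment owns a fresh,
non-interacting domain, so cumulative uptake per cm depends only on
(class radius, outer radius, age). The system integrator therefore solves
one representative domain per class (plus one per host class for hairs)
over the horizon and convolves its per-age uptake with the architecture's
length-birth histogram (0.2-day bins). This is numerically identical to
per-segment domains, at ~20 PDE solves per run instead of ~10⁵. Hair
cohorts thin with age; dying hairs freeze their domains, handled exactly
by summation-by-parts over death times.

### Depletion-zone overlap

The overlap diagnostic computes each segment's depletion radius (where the
draw-down falls to 5% of its surface value) from the representative
profiles, then tests pairwise segment–segment distances (exact
Lumelsky distance on ≤1 cm pieces, spatial hash) against the summed
radii. Pairs on the same axis and parent–child pairs are excluded: a
lateral always touches its parent at the junction, which says nothing
about competition between roots exploring the same soil. Default day-21
systems show <10% of length with overlapping zones — inter-root
competition is genuinely small at these densities, consistent with the
observation that fast-nodal presence hardly changes it.

## Economics

Cost of any structure = tissue weight × 0.8 µg P mg⁻¹ (the measured root
P concentration of DJ123 at 28 DAE). Weights use cylinder volume × tissue
density 0.06 (primary/nodal), 0.07 (L-type), 0.1 g cm⁻³ (S-type and
hairs); the alternative density set printed elsewhere in the source
material (0.08/0.09/0.1) is noted in the config comments but not used.
The ledger folds the primary root into the nodal row (the published class
table has no separate primary row) and reports uptake efficiencies and
benefit:cost as exact quotients of its own rows.

Pay-off (cost-recovery) cases:

1. **Static**: cost / daily uptake, both frozen at the report day.
2. **Growing single-class system**: one axis elongating along its class
   curve at multiplier 1, re-initiating whenever it reaches its maximum
   length, with class-default hairs; break-even is the first day
   cumulative uptake covers cumulative cost (live-hair weight included).
   The construction is the package's own (the source does not specify
   one) and is exposed in the API.
3. As case 2 without hairs.

A known, documented divergence: the published class table's nodal weight
(399.9 mg for 10.8 m, ≈0.37 mg cm⁻¹) cannot be reproduced from any
printed diameter/density combination (the stated formulas give at most
~0.27 mg cm⁻¹, typically ~0.2). This package computes weights from the
stated formulas rather than forcing the table, which halves the nodal
cost relative to the published value. Consequently the *orderings* all
reproduce (hairs > S-type > L-type > nodal in benefit:cost; S < L < nodal
in pay-off time) but the nodal pay-off is shorter here, and a growing
hairless nodal system does break even within a few days rather than
never. The same rounding caveat applies to a few published ratio cells
(e.g. a hairs ratio implying an unprinted unrounded weight); these are
not force-matched either.

## Sensitivity scan

One-at-a-time factors 0.25–4 on eight parameters (soil solution P, buffer
power, L-/S-type length and IBD, hair length and density), five replicate
seeds by default. Couplings: buffer factor co-scales De so De·b is
constant; a "length" factor scales the class peak rate and maximum length
jointly (phase timing unchanged, lifetime integral scales by the factor) —
scaling only the maximum length would leave the mostly time-limited
laterals unchanged over a 31-day run and suppress the strong observed
L-type length response; an IBD factor scales the whole truncated
distribution; hair factors apply to all classes jointly. Soil and hair
parameters do not affect growth, so those runs reuse the replicate's
architecture and re-run only the uptake stage. Scans run at reduced
radial resolution (24 nodes; recorded in the result table); the uptake
differences at stake are far larger than the ~1% discretization effect.

## Synthetic-data role and limits

The parameter set *is* the study's data layer: printed constants are used
verbatim, and the unavailable raw tables (IBDs, growth multipliers,
kinetics) are replaced by calibrated defaults with the statistical
structure the model assumes (truncated-normal IBDs, truncated-lognormal
rate multipliers, Beta growth angles, linear hair-density decline). What
passing tests show is therefore that the *mechanisms* — geometry, the
uptake PDE, the economics — reproduce the study's identities, envelopes
and orderings under those conditions; they cannot certify the
unpublished parameter values themselves, exact per-class uptake splits,
or behaviour of real roots beyond the modelled mechanisms (no
mycorrhiza, no exudate chemistry, no senescence, no carbon budget, no
soil heterogeneity or mechanical impedance, no transpiration flow). The
simulated hair-to-root length ratio (~8.6) sits between the published and
derivable values of that self-inconsistent statistic; the report prints
the computed ratio.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script run the full model at day 31
with 3 seeds and 24 radial nodes, the overlap diagnostic at day 21, and
the sensitivity orderings with 2 replicates on the five parameters the
orderings involve — sizes chosen so a complete from-scratch rerun stays
in the minutes range on one CPU while leaving every stochastic envelope
far wider than the seed-to-seed spread.
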