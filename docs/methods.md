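# Methods

This note documents the models, conventions and numerical choices behind
`riskgrid`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Geometry conventions

All geometry is planar, in one shared equal-area frame in metres. The
package never reprojects; real-data users must pre-project all layers to an
equal-area CRS before loading (a `crs_note` free-text field travels with
the GeoJSON files and is compared across files when `crs_check` is on).
Areas are therefore exact polygon areas, never spherical approximations.

Invalid polygons (bowties, slivers — routine in digitized range maps) are
repaired with `shapely.make_valid`, which splits a self-intersecting ring
into valid parts while preserving every enclosed region. The zero-width
buffer trick was rejected because it silently discards lobes whose winding
is reversed, halving a bowtie's area. Every repair is logged.

Protected-area polygons are clipped to the focal region on load; overlap
statistics are computed against their union, so splitting a protected
footprint into many polygons cannot change any result.

## Grid and presence

The grid is anchored at the minimum corner of the focal region's bounding
box and uses square cells (default 100 km edge — coarse enough not to
overstate the precision of digitized range borders, fine enough to resolve
regional pattern). Cells that do not intersect the region are dropped;
retained cells record `land_area = area(cell ∩ region)`, so all
denominators are land, not full squares. Cell squares are conceptually
half-open (shared edges belong to the lower row/col index); this is
immaterial for area-based quantities but fixes an unambiguous tiling.

Presence requires `area(range ∩ cell ∩ region) > presence_epsilon`
(default 1 m²). The epsilon exists solely to stop boundary-contact slivers
from counting as occupancy; genuine occupancy at the 100-km scale exceeds
it by many orders of magnitude. Presence is monotone under range growth
and invariant to translating all layers together (tested properties).

## Hotspots

For any taxon subset, hotspot cells are the cells with the highest
richness up to a cap of `floor(cap_fraction × n_cells)` (default 5%). Ties
are handled per whole richness class: the threshold R is the smallest
richness for which the number of cells with richness ≥ R fits under the
cap, and *all* such cells are taken. A consequence worth knowing: if the
top class alone overflows the cap, the selection is empty — there is no
random tie-breaking, so reproducibility never depends on cell order.

Overlap between two hotspot sets is the mean of the two reciprocal shared
percentages, `100·(|A∩B|/|A| + |A∩B|/|B|)/2`, which removes the asymmetry
between sets of different sizes. Overlap against an empty set is defined
as 0 with a warning rather than an error so parameter sweeps do not abort.
Displayed percentages are rounded half-to-even to integers; CSV output
keeps full precision.

## Peripherality and protection

A taxon's inverse peripherality is
`area(range ∩ focal ∩ mask) / area(range ∩ mask)`, where the hemisphere
mask is a user-supplied polygon (the synthetic default is the whole
generated world). The numerator is a subset of the denominator by
construction, so the ratio is capped at 1 and endemics are exactly 1.0
after clipping. Taxa without a hemisphere range are reported and excluded
from peripherality (but not from hotspot or protection analyses),
mirroring the attrition real digitization pipelines suffer.

Per-taxon protection is computed on the range clipped to the focal region.
Per-cell protection divides by the cell's land area. Hotspot-level
protection is land-weighted (Σ protected / Σ land over member cells), not
a mean of fractions, so large cells count for what they are.

The per-cell protection-vs-richness trends are deliberately descriptive:
grid-cell observations are strongly spatially autocorrelated, so the
confidence bands implied by the fit's covariance are labelled as likely
too narrow and no p-value is surfaced for them. The
protection-vs-time-since-assessment model, whose unit is the taxon, does
carry an LRT.

## Beta regression

Proportion responses are modelled as `y ~ Beta(μφ, (1−μ)φ)` with
`logit(μ) = Xβ` and a single constant precision φ (no precision
covariates — the simplest structure consistent with the model formulas).
Because endemics (exactly 1) and wholly unprotected taxa (exactly 0)
occur, responses are first mapped into the open interval with the
Smithson–Verkuilen squeeze `(y(n−1)+0.5)/n`, with n the number of rows in
the model at hand.

Estimation is deterministic maximum likelihood: starting values from a
least-squares fit on the logit scale plus a method-of-moments φ, then
L-BFGS with the analytic gradient; the covariance is the inverse observed
information (numerically differentiated analytic gradient), with φ's
standard error delta-method-transformed from the log scale. Fits are
cross-checked in the test suite against an independent implementation
(statsmodels' `BetaModel`) and, for the intercept-only case, against a
2-D grid-search maximizer.

### Random intercept

Status models in which a taxon can appear once per listing body share a
Gaussian random intercept `u_g ~ N(0, σ_u²)` per taxon on the logit scale.
The marginal likelihood integrates each group with *adaptive*
Gauss–Hermite quadrature (default 21 nodes): each group's integrand is
located by a coarse grid scan followed by backtracking Newton (the
log-integrand need not be concave for extreme responses), then scaled by
the curvature at the mode. At the fitted parameters the 21-node and
41-node log-likelihoods agree to < 1e-5, and the quadrature matches
brute-force `scipy.integrate.quad` integration to ~1e-7 in tests.

**Identification restriction.** When a group contains *duplicated*
responses — exactly the dual-listing design, where the same proportion
enters once per listing body — the marginal likelihood is unbounded: as
φ → ∞ each duplicated group contributes ~√φ (a density spike squared),
while singleton groups tend to a finite logit-normal limit. The supremum
is therefore not a useful estimator. The fit is anchored at the
fixed-effects solution and constrained to `φ ∈ [φ̂_fixed/50, φ̂_fixed·50]`
and `σ_u ≤ 5` (logit scale), which selects the scientifically meaningful
interior mode. Both members of any likelihood-ratio comparison share the
restriction, so LRTs remain valid comparisons. A fit driven to the
`σ_u = 0` boundary is flagged, not raised; `fix_sigma=0` collapses the
model to the fixed-effects fit exactly (useful because σ_u is weakly
identified when all groups are singletons).

### Tests and contrasts

Fixed effects are tested by likelihood-ratio χ² tests with df equal to the
difference in free-parameter counts. Pairwise factor-level differences use
least-squares means on a balanced reference grid (other factors weighted
equally over their levels, continuous covariates at their observed means),
delta-method standard errors, and Tukey studentized-range adjustment in
its asymptotic (infinite-df) form. The compact letter display assigns one
letter per maximal clique of the non-significance graph at α = 0.05,
ordered by level mean.

### The standard models

- **M1** `prop_in_focal ~ national_status × group` on nationally at-risk
  taxa, vascular plants and mosses merged into `plants` (mosses are too
  few to stand alone); the interaction is dropped when its LRT is
  non-significant, then each main effect is LR-tested.
- **M2** `prop_in_focal ~ status` with six status levels (three national,
  three global), one row per taxon per listing body, random intercept per
  taxon.
- **M3** as M2 with status collapsed to national vs global.
- **M4/M5** `protected_fraction ~ status` for the national / global sets
  (fixed effects).

Status levels absent from the data are dropped from the factor with a
warning; aliased interaction cells (empty group × status combinations) are
dropped from the design with a log message.

## Synthetic data

The generator emulates the structure of a national at-risk-species study
system. Defaults are the study conditions: ~12.5% of focal land protected;
9% of nationally listed taxa also globally listed (plus a small
global-only set); per-taxon target peripherality drawn from the
right-skewed Beta(0.35, 1.6) (analytic median 0.079 — most taxa are thin
range edges, with a small endemic tail); range centroids clustered in one
longitude band (clustered draw with probability c/(1+c), default c = 3)
so richness concentrates there; assessment years uniform over 1980–2020.
Group counts loosely follow a national registry's proportions (plants
dominate; mosses and lichens are small).

Each taxon's rectangular range is placed by 1-D bisection on its
north–south centroid offset until the realized fraction inside the focal
region matches the Beta draw within ±0.01; the range is convex precisely
so this objective is monotone. Ranges too tall to achieve their target
fraction have their height reduced first (area is a nuisance parameter;
the target fraction is not). Protected patches (lognormal sizes) are
rejection-placed — optionally biased toward or away from the richness
cluster — until the union reaches the target coverage, the final patch
being shrunk by bisection to land within ±0.005.

Randomness is split into fixed substreams (taxa vs protection), so adding
taxa does not perturb protected-area placement, and the generator is a
pure function of (scenario, seed): identical inputs give byte-identical
output files.

What passing tests on this generator show — and what they do not: the
pipeline recovers known ground truth (target peripherality within the
placement tolerance, protected coverage within ±0.005, null models
calibrated, injected effects recovered with the right sign). Real range
maps differ in ways the generator deliberately omits: concave and
fragmented ranges, digitization error correlated across taxa, spatial
autocorrelation of occupancy beyond simple clustering, coastline and
freshwater complexity, and protected-area geometry that follows tenure
rather than lognormal patches. Results on real data inherit none of the
generator's guarantees; the geometry operations themselves, however, are
exact for any valid planar input.

## Problem sizes used by the test suite

Unit and acceptance tests run at sizes chosen to make their statistical
assertions sharp: LRT type-I calibration uses 1,000 null replicates at
n = 200; coefficient-recovery bias uses 200 replicates at n = 400;
random-intercept recovery uses 300 groups of two (median error over 25
replicates); generator fidelity uses 500 taxa; oracle-equivalence sweeps
use 1,000 random richness vectors and 10⁵–10⁶ Monte-Carlo points per
geometric check. End-to-end runs use a ~160-taxon scenario on a 480-cell
grid.

## Known limitations

- Shapefile input is not supported; inputs are GeoJSON + CSV in a planar
  frame. No reprojection.
- φ is constant across observations; zero-one-inflated responses are
  handled only via the squeeze, not modelled.
- The mixed model supports a single random intercept (no crossed or
  nested effects), and its precision is restricted as described above.
- Spatial autocorrelation is acknowledged, not modelled: per-cell trends
  are descriptive.
- Hotspot selection is richness-based with a cap; complementarity-based
  prioritization (set cover) is out of scope.
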