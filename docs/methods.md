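# Methods

## Data model and conventions

Rasters are square-celled grids in one projected CRS (meters), 0-based and
row-major with row 0 at the top; the georeferenced origin is the lower-left
corner (ESRI ASCII convention), and point locations snap to the nearest
cell center. Nodata cells are impassable: they are removed from both the
cost graph and the circuit network. Polylines (roads, powerlines,
railroads) are rasterized by supercover tracing — every cell whose square
the line touches is marked, including both cells at an exact corner
crossing — so one-cell-wide linear barriers admit no diagonal leaks.
Class-1 highways are two cells wide (the trace dilated one cell
perpendicular to each segment's dominant orientation).

## Genetic distances

*Dps* between individuals i and j is 1 − S/(2L<sub>ij</sub>), where S
counts shared alleles across loci with multiplicity (0–2 per locus) and
L<sub>ij</sub> is the number of loci typed in both individuals; loci
missing in either member of a pair are excluded pairwise.

Rousset's *â* is the between-individual analogue of F/(1−F). Per locus,
Q̂<sub>w</sub> is the dataset-wide average probability that the two gene
copies within an individual are identical (the homozygosity rate among
individuals typed at that locus), and Q̂<sub>b</sub>(i,j) averages identity
over the four inter-individual gene comparisons. The multilocus estimate is
the ratio of sums â = Σ<sub>l</sub>(Q̂<sub>w,l</sub> − Q̂<sub>b,l</sub>) /
Σ<sub>l</sub>(1 − Q̂<sub>w,l</sub>) over co-typed loci. Negative values are
legitimate (pairs more similar than the within-individual baseline). The
dataset-wide Q̂<sub>w</sub> and ratio-of-sums combination follow the common
population-genetics convention for F-statistic-style estimators; both
metrics are invariant to bijective allele recoding, which the tests fuzz.

Monomorphic datasets (denominator 0) and pairs with no co-typed locus are
errors, not NaNs.

## Cost distances and least-cost paths

Movement is modeled on the 8-connected cell graph with edge weight
(r<sub>a</sub>+r<sub>b</sub>)/2, ×√2 for diagonal moves. Distances come
from exact Dijkstra (scipy's sparse implementation); costs are in
resistance × cell-lengths — cell size is deliberately not multiplied in,
since every downstream statistic (Mantel correlation, MLPE fit) is
invariant to that global scale, and geographic distance is carried
separately in meters. Path extraction walks back from the target along
cells satisfying d(a,u) + w(u,v) = d(a,v), breaking ties by the smallest
flat cell index, so corridors are reproducible across runs and platforms.

## Circuit-theory connectivity

The same grid becomes a resistor network: edge conductance =
(1/r<sub>a</sub> + 1/r<sub>b</sub>)/2, divided by √2 on diagonals. Linear
systems are solved on the grounded Laplacian by direct sparse LU
factorization — exact to machine precision and deterministic, which at
desk scale (≤ a few 10⁵ nodes) is both faster and simpler than an
iterative solver with tolerance bookkeeping. Effective resistance between
two nodes is v<sub>a</sub>−v<sub>b</sub> under a unit current dipole.
All-to-one mode grounds each focal element in turn, injects unit current at
every other focal element, and accumulates per-cell current magnitude,
defined as half the sum of absolute incident branch currents (the half-sum
is the package's stated contract for node-level current accounting). Focal
patches are contracted to super-nodes by merging their cells (infinite
internal conductance) before solving. Focal elements in separate components
are skipped per solve and reported, not fatal.

## Mantel machinery

Mantel r is the Pearson correlation of lower-triangle vectors; significance
comes from joint row/column permutation of the predictor matrix, p =
(1 + hits)/(1 + n_perm), two-sided by default (one-sided available — the
choice is configurable because either convention is defensible). The
partial test regresses both matrices' triangles on the control triangle and
correlates the residuals, permuting the predictor's residual matrix
(residual-permutation method). A control perfectly collinear with the
predictor is rejected as confounded. Default n_perm is 9999 in pipeline
runs; calibration simulations use 99 (the rejection-rate check depends on
replicate count, not permutation depth, and p-granularity 1/100 keeps
α = 0.05 exact).

## Univariate optimization and the plateau rule

Candidates leaving any sampling pair disconnected are skipped with a
warning. Selection: if the global maximum of the partial-r profile is a
strict interior peak, it wins; otherwise the smallest value within
rel_tol = 1% of the maximum is taken as the plateau onset. The 1% tolerance
operationalizes "began to plateau" — a deliberately conservative explicit
criterion, since reproducibility demands one. Profiles with no positive
support return the smallest value with a warning.

## MLPE mixed model and AICc

For pairwise observations y<sub>ij</sub> = μ + βz<sub>ij</sub> + ε, the
covariance is σ²[(1−2ρ)I + ρAAᵀ], where A is the N×n pair–individual
incidence matrix — equivalently, correlation ρ between observations
sharing exactly one individual. The predictor is standardized per model so
AICc comparisons are invariant to cost-unit conventions. Fitting is full
maximum likelihood (not REML, so fixed-effect structures are comparable):
for fixed ρ, the GLS coefficients and σ² are closed-form via the Woodbury
identity (every solve reduces to the n×n individual block, so 137
individuals ≈ 9,300 pairs is still cheap); ρ is then profiled over
[0, 0.499] by bounded scalar minimization with a coarse-grid guard against
local dips. k = 4 (intercept, slope, ρ, σ²). The slope's standard error
comes from the GLS covariance at the optimum; simulation puts 95% CI
coverage at 0.95–0.965 for n = 40 individuals.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n = the number of pairwise
observations. This is knowingly anti-conservative (pairs are not
independent — that is the very point of MLPE), but it is the ranking
convention this workflow reproduces, and ranking is invariant to it when
competitors share k and n, as they do here. The IBD null (geographic
distance as predictor) is always in the candidate set.

## Multivariate surface composition

Overlap precedence is deterministic: start from background 1; barrier
features combine cellwise by maximum; facilitator features then set their
cells to 1 *except* on road carriageway cells; road buffers (one-cell
strips 8-adjacent to a buffered class's carriageway, excluding road cells
of any class) are applied last. This ordering makes "roads as simultaneous
barriers and facilitators" representable in a single surface and reduces to
the buffered-road construction when only roads are present. Where road
classes overlap, the largest resistance wins. Model presets (all-barriers,
natural barriers/facilitators, all facilitators, linear facilitators,
landcover, development+roads, global) enumerate the a-priori hypothesis
set; buffered-class variants (major roads {1,2,3} only vs all classes) run
as alternative models and are ranked like any other.

Features that can plausibly act in either direction (fields, the wetland
types) are tested in both modes univariately; when they enter a
multivariate surface the pipeline resolves them to the direction found for
them empirically (scrub-shrub and palustrine emergent wetlands facilitate;
fields, forested and estuarine wetlands impede), overridable in config.

## Synthetic data: what it emulates, and what it does not

`generate_landscape` grows blob-shaped landcover patches (seeded random
region growth, ~60-cell mean patches) to target proportions on a 30 m
grid; two presets emulate contrasting real compositions — a rural profile
(forest 58.8%, development 11.2%, fields 11.1%, scrub-shrub 4.6%, four
wetland types, water) and a suburban profile (development 28.6%, forest
33.9%, estuarine wetland 9.2%) — with roads of up to six classes,
powerline and railroad polylines overlaid, and an optional ~1%-cover
short-vegetation speckle standing in for a LiDAR-derived 1–3 m vegetation
mask. Realized class proportions land within ±2 percentage points on
200×200 grids.

Two genotype generators serve different purposes. The *pairwise* generator
writes genetic distance directly as μ + β·z(cost) + u<sub>i</sub> +
u<sub>j</sub> + e<sub>ij</sub>, with var(u) = ρ·σ² and var(e) = (1−2ρ)σ²,
so noise has exactly the MLPE correlation structure — exact statistical
control for calibration and recovery experiments. The *forward* generator
runs a finite-island simulation (migration ∝ exp(−λ·cost), row emigration
capped at 0.2, stepwise ±1 mutation on repeat-count alleles, 11 loci) and
samples georeferenced diploids — biological plausibility for end-to-end
checks.

**Calibration landscape.** Recovery of a generating resistance value is
only a well-posed question when the cost-distance pattern actually varies
with the tested value. On blob landcover it barely does: paths either
always cross a patch or always skirt it, so partial-r profiles are flat
and the plateau rule degenerates to the smallest candidate (noiseless
pilots confirmed this; it is a property of such landscapes, not of the
optimizer). The recovery experiments therefore run on a designed
calibration layer (`gapped_barrier_feature`): eight evenly spaced one-cell
walls, half pierced by a single random gap (cross-vs-detour switches at
low/mid resistance values), half complete (mandatory crossings keep pair
costs linear in the value, no high-end saturation). Conditions, frozen at
design time: 100×100 cells, 40 individuals, β = 0.7, noise σ = 0.35
(signal R² ≈ 0.8, "moderate noise"), ρ = 0.25. Under these, the selected
value is the generating value or a grid neighbor in ≥ 95% of replicates
for true values 10, 100, and 500. Model-selection recovery uses a strong
effect (β = 1.0, σ = 0.15) on a 40×40 two-area landscape; the generating
"global" surface takes > 0.9 Akaike weight against all preset competitors
(whose cost distances correlate > 0.9 with the truth, so this genuinely
tests discrimination), and the buffered-road model beats the barrier-only
road model on dual-effect data in essentially every replicate.

What passing these tests does **not** show: that real landscapes carry the
assumed log-linear cost→genetic-distance relationship, that real noise is
MLPE-Gaussian, or that the plateau tolerance matches any particular
analyst's judgment on messy empirical profiles. The synthetic studies
validate the machinery — estimators, solvers, selection rules — under the
model's own assumptions, no more.

## Pipeline, reconciliation, determinism

The config-driven pipeline runs per area: distances → univariate
optimization → univariate MLPE table → multivariate surfaces (presets +
buffered-road variants) → multivariate MLPE table; then across areas it
builds full-extent surfaces from per-area, averaged, and maximum feature
values, scores each by partial Mantel r over the full extent, and feeds
the winner to corridor mapping (LCP path-count raster + GeoJSON, all-to-one
current maps over individual nodes and focal patches, and a divergence
layer marking top-decile-current cells carrying no LCP). Every stage is
seeded from the config seed by fixed offsets; a manifest records seeds,
selected values and files, and reruns are byte-identical. The shipped
example config uses 48×48 cells and 18 individuals per area so the whole
run completes in seconds; the analysis itself has no such limits.

## Known limitations

- No map reprojection; all inputs must share one projected CRS in meters.
- Cost units omit the cell-size factor by design (a global scale).
- AICc's n = pairs caveat above.
- The SPAGeDi-style reference weighting for Rousset's â (reference allele
  frequencies over subsets of individuals) is simplified to dataset-wide
  Q̂<sub>w</sub>; the enumeration oracle in the tests defines the contract.
- Circuit current accounting is node-level half-sum; branch-level exports
  are not provided.
- Pairwise circuit mode over all individual pairs is available through the
  API but not run by default (all-to-one covers the corridor use case at a
  fraction of the cost).
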