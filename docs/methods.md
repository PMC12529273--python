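# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Grid and coordinate conventions

All computation is planar-metric; CRS metadata is an opaque string. Rasters
are row-major with row 0 at maximum y; the center of cell (i, j) is
`(x_min + (j+0.5)·c, y_max − (i+0.5)·c)` for cell size `c` (default 10 m,
with a 50 m profile used throughout the tests). Cell membership is
half-open with ties to the right/below, so sampling at any cell center
returns that cell's own value. Grids cover requested bounds by ceiling the
row/column counts. Nodata sentinels: −9999 for continuous rasters, 0 for
class rasters (classes are 1–3).

Raster I/O uses Esri ASCII grid (text, with a JSON sidecar carrying
kind/nodata/CRS) and single-band GeoTIFF written through tifffile with
ModelPixelScale/ModelTiepoint tags; vectors are GeoJSON; residences are a
CSV with columns `id,x,y,group,birth_day,postal_centroid_id`.

## AHP weights

Default extraction is Saaty's approximate eigenvector: normalize each
column to sum 1, average across columns within each row. Power iteration to
the principal eigenvector is available as an alternative. For either
method, `λmax = (1/n) Σᵢ (A w)ᵢ / wᵢ`, `CI = (λmax − n)/(n − 1)`,
`CR = CI / RI(n)` with the tabulated Saaty random indices (`CR = 0` for
n ≤ 2).

The bundled five-factor judgment matrix is not exactly reciprocal in its
land-use/roads pair (`a = 3` one way but `1/5` the other). Validation
warns on reciprocity violations but does not block: the matrix is processed
exactly as given, which is also what makes its derived weights reproduce
the published multiset {0.37, 0.37, 0.13, 0.09, 0.04} with CR 0.09.
A genuine ambiguity follows from it: recomputation assigns 0.13 to land
use and 0.09 to roads, whereas the canonical published assignment carries
the transposed pair. The pipeline's `default_weights()` keeps the canonical
assignment (land use 0.09, roads 0.13); passing
`ahp_weights(...).weight_map()` to the overlay uses the recomputed one.
Both sum to 1 and share one multiset, so the choice never affects index
bounds, only which of two minor factors gets 0.04 more weight.

## Factor engineering

- **Distances** are exact Euclidean distances from cell centers to the
  nearest feature (KD-tree for points; point-to-segment minimization over
  all polyline segments, chunked over cells). Classification uses the
  literature breakpoints (2000/4000 m for polluting activities, 100/300 m
  for roads) with the *moderate class owning both endpoints*, because
  "high" is defined by the strict inequality below the first break.
- **Density** uses a quartic kernel,
  `f(x) = Σₚ 3/(πh²)·(1 − (d/h)²)²` for `d < h`, reported per km². The
  bandwidth defaults to 2000 m — the same radius used as the emission
  impact range of a polluting activity — and the kernel/bandwidth are
  configurable because no standard density thresholds exist; for the same
  reason the density factor enters the index through a min–max linear
  rescale onto [1, 3] rather than fixed class breaks. A constant density
  surface rescales to all-1 (lowest susceptibility).
- **Land use** maps categories directly to scores (industrial 3,
  residential 2, natural 1); unmapped categories are an error, never
  silently scored.
- **Fog** is binary {1, 3} (not {1, 2}): "high" means 3 across every
  factor, so a binary factor uses the extreme scores.
- Degenerate inputs take the all-low path: with no facilities the distance
  and density factors are uniformly 1.

## Index and classification

`S = Σ wᵢxᵢ` is a convex combination, hence bounded cell-wise by the factor
scores; nodata in any factor propagates. Continuous S is cut into three
classes by equal intervals on the theoretical range [1, 3]
(breaks 5/3 and 7/3, upper class closed at 3) — a deterministic,
data-independent rule; tertile (quantile) classing is available as an
option and the choice is recorded in run metadata.

## Cluster scan

The analysed variable is the binary case indicator over all residence
points, so High–High means "local excess of cases". Neighborhoods are a
fixed 4 km distance band — the maximum plausible reach of an industrial
emission source — row-standardized; records sharing a postal centroid are
mutual neighbors at distance 0 (coarse postal geocoding makes coincident
records the norm, not an edge case). Isolated points are flagged, not
fatal.

With mean deviations `zᵢ` and `m₂ = Σz²/n`,
`Iᵢ = (zᵢ/m₂)·Σⱼ wᵢⱼ zⱼ`. Inference is by conditional permutation: point i
is held fixed and the remaining n−1 values are permuted into its neighbor
slots. The reported p is the folded observed-tail pseudo p,
`(1 + #{permuted I at least as extreme, observed tail})/(1 + n_perm)`, and
the z-score uses the permutation mean/sd. Because the folded p reaches
quantile t with probability ≈ 2t under the null, the *two-sided* labeling
rule at level α thresholds the folded p at α/2; labels are assigned by
quadrant (value above/below mean × spatial lag above/below mean). Tail
selection and tie counting use a 1e-9 relative tolerance so exact ties
(e.g. a point whose neighbors are all other points, where the observed I
equals the permutation mean identically) resolve the same way for any
input ordering. Defaults: n_perm = 999, α = 0.05. An exhaustive mode
enumerates every ordered assignment of held-out values to neighbor slots
for small n, making p exact; the test suite checks it against independent
full enumeration.

## Exposure tables

Contingency tables count case/control residences by sampled exposure
class; classes with zero totals still appear, and residences on nodata
cells go to an explicit exclusions list. Pearson chi-square applies the
Yates continuity correction exactly when the informative table is 2×2
(the convention of the common statistical packages, and the one that
reproduces the published 2×2 fog p-value of .922 — uncorrected it would be
.770). Frequency reports give counts and percentages of the group column
total to 1 decimal; cells with absolute frequency strictly below 3 are
suppressed (count and percentage) for statistical secrecy, leaving group
totals intact.

## Kriged odds-ratio surface

The case indicator is interpolated by ordinary kriging: empirical
semivariogram `γ(h) = (1/2N(h)) Σ (vᵢ−vⱼ)²` in distance bins (default 15
bins to half the maximum pairwise distance), fitted by weighted least
squares (weights = pair counts) from a fixed multi-start grid, so the fit
is deterministic. Exponential (default) and spherical models use the
effective-range parameterisation. Prediction solves the semivariance
system with a Lagrange multiplier (Σλ = 1) over the 16 nearest points;
cells sharing a neighbor set share one factorized solve. Two distinct
records at the same coordinates get off-diagonal semivariance equal to the
nugget, which regularizes the system; with a zero nugget duplicates are
jittered by 0.1 m (or the call fails, per configuration).

The probability surface is clipped to [1e-6, 1−1e-6] and transformed to
`OR = (p̂/(1−p̂)) / (n_cases/n_controls)`, so OR = 1 means no local case
excess relative to the study-wide odds. The indicator-kriging construction
of the odds ratio is a declared design choice; other constructions (e.g.
kriging areal odds ratios) would be equally defensible.

## Synthetic region and cohort

The generator emulates a riverside industrial study area on a
20 km × 15 km local Cartesian frame:

- **Land use** (industrial 8%, residential 32%, natural 60%): a Gaussian
  white-noise field smoothed to an 800 m correlation length is ranked and
  cells are allocated to categories by largest-remainder rounding along the
  ranking (natural on the low tail, industrial on the high tail). Fractions
  are therefore realized exactly (to one cell) while patches stay
  contiguous.
- **Facilities** (default 25): 85% placed uniformly inside industrial
  cells, the rest anywhere — industry clusters but is not confined.
- **Roads** (default 8): polylines spanning the region with jittered
  intermediate vertices.
- **Fog zone**: the southern 20% of the region, a proxy for the low-lying
  riverside band where radiation fog concentrates.
- **Postal centroids** (default 120): sampled with land-use weights
  10 (residential) : 2 (industrial) : 1 (natural) — postal-code centroids
  follow settlement.
- **Cohort** (default 164 cases / 209 controls, the study-area sample
  scale): every residence snaps to a postal centroid; assignment favours
  residential-land centroids 3:1. Cases optionally have their intensity
  multiplied by `cluster_excess` inside a disk (`cluster_center`,
  `cluster_radius`); with excess 1 the two groups draw from the identical
  distribution and are exchangeable — the planted-null property the
  calibration tests rely on. Controls inherit birth days from the case
  multiset, emulating systematic same-day control sampling; the matched
  structure is stored but, as in the downstream analyses here, the tests
  are unmatched. `densest_centroid()` gives the canonical anchor for a
  planted cluster: the centroid with the most other centroids within the
  disk radius, because a cluster planted where population concentrates is
  the detectable (and realistic) configuration.

One root seed derives independent per-layer RNG streams (PCG64), so
changing one layer's count does not perturb the others, and identical
seeds give identical outputs.

What the generator does **not** emulate: real road-network topology,
demographic structure, pregnancy-trimester exposure windows, wind-driven
pollutant dispersion, or the irregular shapes of real postal-code areas.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under controlled spatial structure, not the epidemiological
conclusions one would draw from real geography.

## Problem sizes and numerical tolerances

The test profile uses 50 m cells (400 × 300 grid), n_perm = 199 for the
100-seed calibration simulations (999 for the planted-cluster runs and as
the analysis default), and a 250 m prediction grid for the kriging checks.
Oracle agreement tolerances: 1e-12 for the WLC dot product, 1e-6 m for
distance rasters, 1e-9 for KDE versus the double loop, exact-enumeration
equality for small-n Local Moran, 1e-8 for kriging exactness at data
points.

## Known limitations

- The approximate (column-normalization) and eigenvector AHP weights agree
  closely only for acceptably consistent matrices; for wildly inconsistent
  judgments they genuinely diverge, and no attempt is made to reconcile
  them.
- Local Moran's folded pseudo p-values are granular (1/(n_perm+1)) and the
  permutation bank is shared across points, the standard computational
  practice.
- Kriging weights may be negative (no positivity constraint); predictions
  can then leave the data range, which the OR clipping bounds but does not
  remove.
- The equal-interval classing of S on [1, 3] is one of several defensible
  conventions; observed class shares shift under quantile classing.
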