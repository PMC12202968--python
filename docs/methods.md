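# Methods

This note documents the models, conventions and numerical choices behind
`isomove`, and what the synthetic data do and do not establish.

## Origin assignment

**Error model.**  The fur value of an animal that grew its fur in cell *c*
is modeled as N(μ_c, σ²) with μ_c = β₀ + β₁·δ²H_precip_c.  σ combines the
calibration residual SD and the analytical precision in quadrature,
σ = √(σ_res² + σ_a²); each term can be zeroed in the config, and an
optional per-cell isoscape prediction SE can be added (off by default), in
which case σ_c = √(σ_res² + σ_a² + se_c²).  Quadrature is the standard
composition for independent error sources in isotope assignment; nothing in
the workflow depends on the split between the two terms, only on their sum.

**Equal-area contract.**  Cell probabilities are normalized masses, so the
assignment grid must be equal-area.  The package uses an Albers equal-area
conic on WGS84 (defaults 29.5°/45.5° standard parallels, origin 23°N 96°W —
the common conterminous-US parameterization; all four parameters are
config).  Geographic rasters are resampled to this frame by
nearest-neighbour lookup at cell centers; nearest-cell membership ties
(points exactly on a cell edge) break to the smaller row-major index.

**Assignment domain.**  Probabilities are normalized *after* restricting to
the range mask (a 100-km alpha hull of occurrence-county centroids buffered
by 250 km).  The alternative order — normalize first, clip after — rescales
every in-mask cell by the same constant, so quantile surfaces, likely
regions, bootstrap draws and all downstream statistics are identical; the
config switch for it exists for interface compatibility and shares the same
code path.

**Quantile transform and threshold.**  Each surface is mapped to its
within-surface empirical CDF, q_c = #(p ≤ p_c)/#cells, with ties sharing
the maximal rank (a uniform surface is all-ones; the argmax cell is always
1).  The likely-region threshold is the largest observed true-origin
quantile θ with mean(q_i ≥ θ) ≥ target accuracy (default 0.75).  Taking θ
from the observed set makes calibration exact, seed-free and reproducible:
coverage on the calibrating set is ≥ the target by construction, and the
next candidate up would drop below it.  θ = min(q_i) is always admissible,
so calibration cannot fail.

## Direction and distance

**Bearing convention.**  A replication indicates a southerly origin when
the *travel* azimuth — the initial bearing of the shortest ellipsoid path
from the drawn origin toward the carcass site — is within 90° of due north
(|azimuth| < 90°: the animal flew northward, so it came from the south).
This is the reading consistent with both the north/south pairing of the
classification rule and the direction the field results report; the
opposite convention (azimuth from site to origin, southerly ⇔ |azimuth| >
90°) is available as `bearing_convention: origin` for sensitivity analysis
and yields identical calls away from the east–west boundary.  Draws exactly
at the cutoff count to neither side; draws coincident with the site are
excluded and counted.

**Bootstrap.**  Default 10,000 weighted draws per sample.  Bearings are
computed once per distinct drawn cell and weighted by draw counts, so the
bootstrap converges to the exact mass-weighted fraction (verified at
n = 10⁵ against direct summation, tolerance 0.01).  Per-sample RNG streams
are derived from (run seed, CRC32 of sample id), so sample order cannot
change any sample's draws.

**Distance.**  Minimum travel is measured to likely-cell *centers*; with
the true origin inside the likely region this is a lower bound on the true
displacement, and for a site inside its own likely region it is at most the
map resolution.  Distance ties break to the first cell in row-major order.

## Geodesy and geometry

Distances, bearings and destinations use Vincenty's inverse/direct formulae
on WGS84 (vectorized; sub-mm convergence in the continental domain; a
spherical fallback guards the near-antipodal regime, which never occurs
here).  The test suite checks 1,000 random pairs against an independent
Karney-algorithm solver (< 0.1%) plus frozen oracle values.  The Albers
projection uses the standard ellipsoidal (authalic-latitude) development;
projected planar areas agree with independent ellipsoid areas to < 0.01% on
densified test polygons (tolerance asserted: 0.5%).

Alpha shapes keep Delaunay triangles with circumradius ≤ alpha and union
them.  The dynamic hull searches the ladder alpha = hull-diameter ×
{1, 1/2, …, 1/256} and returns the smallest alpha whose shape is a single
connected polygon covering ≥ 95% of the points, buffered by 50 km and
clipped to the land polygon; if no rung qualifies, it falls back to the
convex hull with a warning.  The achieved inclusion is recorded on every
result and asserted in tests.  The ladder schedule is a package choice (the
approach's name fixes the search, not the schedule).

## Seasons and range algebra

Season windows (both endpoints inclusive, winter wrapping the new year)
tile the calendar exactly; this is asserted for leap and non-leap years.
Year-round range = summer ∩ winter.  Season-only range = that season's hull
minus the union of the other two (so autumn-only excludes both summer and
winter overlap).  The winter-only remainder is computed like the others but
flagged and excluded from downstream use — for this species it is
effectively empty.  Records carrying only a season label (legacy
compilations) bypass date binning.

## Synthetic data: what it emulates and what it does not

The generator's defaults define the test conditions: isoscape
δ²H = −10 − 1.5·latitude + N(0, 3²) ‰ over (100–70°W, 24–48°N) — a gradient
of the order of the real continental δ²H gradient; rescaling truth
(β₀, β₁, σ_res) = (−40, 0.6, 10‰) with the 2.3‰ analytical term added in
quadrature when sampling fur values; 200 known-origin samples dated inside
the molt window (Jun 14–Aug 7); 17 migrant carcasses whose sites are
displaced 500 km due north of their origins; 200 occurrence records per
season drawn uniformly from nested truth polygons (winter ⊂ summer ⊂
autumn); and the deterministic 49-record fatality fixture whose state ×
year and by-month margins equal the published monitoring table.

The synthetic world is deliberately simple: the gradient is purely
latitudinal (real isoscapes have longitudinal and orographic structure),
origins are uniform rather than abundance-weighted, displacement is a fixed
vector rather than a behavioural distribution, and occurrence effort is
spatially unbiased.  Passing tests therefore establish that the estimators
are correct and calibrated *under their own assumptions* — parameter
recovery, coverage within ±10 points of the 75% target, direction power
rising with displacement — not that real fur samples would achieve the same
accuracy.  Synthetic range areas are properties of the truth polygons, not
estimates of any real range.

Grids in the tests and drivers are coarse (0.5° source, 50-km equal-area
cells) — a scale chosen so the statistical properties of interest are
resolved while the full suite runs in well under a minute per module; the
resolution of a real isoscape is a property of its source, not of the
method.

## Degenerate inputs and tie-breaks (summary)

- Coincident points: distance 0; bearing undefined (error).
- Constant precipitation across calibration origins: degenerate-fit error;
  constant fur values: slope 0, flat expected surface.
- Off-grid true origins: listed-and-rejected error naming the samples.
- Surfaces far from all cells are computed in log space (no underflow).
- Empty mask ∩ grid: no-domain error; empty likely region: error.
- Seasons with < 3 records: reported empty with a warning.
- Halfway cell-membership ties: smaller row-major index; distance ties:
  first likely cell in row-major order; threshold ties: largest admissible
  observed quantile.

## Known limitations

- The rescaling fit is ordinary least squares; errors-in-variables
  attenuation from isoscape uncertainty is not corrected (matching standard
  practice), so a fitted slope on resampled grids is mildly attenuated.
- The quantile threshold is calibrated on the empirical test set only; no
  smoothing or interpolation between observed quantiles is attempted.
- Vincenty (not Karney) geodesics: adequate to < 0.1% everywhere tested,
  with a spherical fallback only in the near-antipodal regime.
- Raster I/O is single-band ESRI ASCII grid with a JSON crs sidecar; no
  GeoTIFF/compressed formats.
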