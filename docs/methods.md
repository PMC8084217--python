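# Methods

## Sampling model

The package encodes a paired-site monitoring design from the Beni
savanna gallery forests: one long-grazed site and one site restored by
cattle exclusion, four plots per site. Each plot is a 100 m transect
(shrub-layer line intercepts to 2 m height) with a 20 × 20 m (400 m²)
subplot for adult trees (dbh ≥ 10 cm at 1.3 m), the western 200 m² half
for saplings (height > 0.3 m, dbh < 10 cm) and five regularly spaced
4 m² quadrats for ground cover and seedling counts (height < 0.3 m).
Wildlife is surveyed on two line transects per site, each walked once at
dusk (~1 h, mammals) and once at night (~2 h, mammals and nocturnal
birds).

Units are fixed throughout: dbh in cm, heights in m, areas in m²,
per-hectare rates for densities and basal areas, km for transect
distances. A stem of exactly 10 cm dbh is an adult; every binning in the
package is left-closed/right-open.

Seedlings are never individual records: they exist only as per-quadrat
counts. Snags (standing dead stems) are live=False stems of an ordinary
group, and summaries derive `<group>_snag` reporting classes from that
flag; this keeps one taxonomy and makes every "exclude dead" filter
explicit. "Woody" seedlings are reported under the broadleaf group.

## Stand summaries

Per plot, counts and summed stem basal areas are scaled by the stage's
sampling frame (adults 400 m², saplings 200 m², seedlings 20 m²) and
averaged across the site's plots; SD is the sample standard deviation
(n−1), with SD = 0 for a single plot. Composition percentages are shares
of the stage total including snag classes. Motacú saplings are
acaulescent (no stem, hence no dbh): they contribute no basal area, and
any stage whose basal area is partly unmeasurable reports no basal-area
composition rather than a misleading one. Seedling densities are pooled
per plot (count over the plot's 20 m² of quadrats); for equal quadrat
counts this is identical to scaling per-quadrat means.

Class distributions never drop a stem silently: anything missing its
binning measurement lands in an explicit `unmeasured` bucket, and the
acaulescent motacú saplings form a flagged first band of the dbh scheme.

## Natural Regeneration index

For species *i* and height class *j* over {1–2 m, 2–3 m, > 3 m}:
RD_ij = 100 × (mean per-ha density of *i* in *j*) / Σ over species;
RF_ij = 100 × (plots where *i* occurs in *j*) / Σ over species;
NR_ij = (RD_ij + RF_ij)/2; TNR_i = Σ_j NR_ij / 3. Both RD and RF are
normalised **within class**, and reported per-class values already carry
the 1/3 class weight — the only convention under which class columns sum
to 100/3 and TNR values to 100, which is the structure the published
table exhibits (the raw (RD+RF)/2 intermediates are exposed alongside).
Frequency is presence/absence per plot, the sampling unit for saplings.

Eligibility: live saplings taller than 1 m (advanced regeneration,
past early-mortality filters); broadleaf saplings with dbh ≥ 5 cm are
excluded, motacú saplings always included. A class empty across all
species contributes zero with a warning; a site with no eligible sapling
anywhere is an error. Published row sums of 38.40 and 47.61 against
printed TNRs of 38.41/47.62 are rounding artifacts of the 2-decimal
table; checks use ±0.02.

## Understory ordination

Shrub cover per plot and functional group is the union length of that
group's intercept intervals divided by transect length (overlaps merged,
so cover never exceeds 100%). Ground cover is the mean of the five
quadrat percentages; the default variable set is the 8 recorded
categories plus a derived total-plant-cover column (forbs + ferns +
graminoids), and the column set is configurable because the original
analysis does not enumerate its exact variable list — no claim is made
of matching the published loadings table variable-for-variable.

The PCA z-scores columns (n−1 SD) and eigendecomposes the correlation
matrix. Zero-variance columns are dropped with a warning (their z-score
is undefined). Loadings are eigenvector × √eigenvalue, i.e.
variable–axis correlations, because the |0.5| salience threshold is
conventional on that scaling; retention uses the latent-root criterion
(eigenvalue > 1). Each axis is sign-flipped so its largest-magnitude
loading is positive, making results deterministic and row-order
invariant. Site ellipses are parameterised as axis-aligned centroid ± SD
on PC1/PC2 (no covariance rotation) — the simplest reading of an SD
ellipse. Identities that hold by construction and are enforced in tests:
eigenvalues sum to the number of variables, communalities equal 1,
scores × eigenvectorsᵀ reproduces the z-matrix to 1e-8.

## Wildlife

Encounter rates are per linear km walked (the published table's
arithmetic, e.g. 17/4.25 = 4.00, confirms the "per km²" phrasing in the
source text is a slip). Mammal effort pools dusk + night distances;
nocturnal birds are surveyed only at night, so their effort is
night-only. The rate numerator defaults to individuals (the published
counts) with an events basis available; rates and differences are
computed at full precision and rounded to 2 decimals for reporting.
Night-only per-site distances are not published; the generator's default
effort split uses 2.10 km (grazed) and 2.20 km (restored), back-implied
from the bird rates, and bird-rate reproduction is deliberately not
asserted anywhere.

Segmentation slices each walk into 15-minute bins (final partial bin
kept), concatenated dusk-before-night then by transect id, truncated at
24 segments; the exact method is order-free, so ordering only affects
segment metadata. The accumulation curve is the analytic sample-based
expectation over all C(T, k) segment subsets, with variance from
pairwise joint-absence counts, computed with exact integer binomials
(fractions) — it matches complete enumeration to numerical precision
rather than approximately.

## Synthetic generator

The generator is calibrated so its defaults *are* the study conditions:
adult/sapling/seedling densities and wildlife rates equal the published
site means (e.g. motacú saplings 1300 vs 3200 ha⁻¹), snag and damage
rates match the published snag rows and the 5% grazed damage share, and
effort equals the published 4.25/3.86 km over 351/362 min (yielding
exactly 24 segments per site). Distribution choices are the simplest
standard forms reproducing the reported means and dispersions: Poisson
stem counts, truncated-normal dbh (adults above 10 cm; published motacú
means/SDs, broadleaf means back-solved from basal area ÷ density),
exponential sapling heights above 0.3 m, negative-binomial seedlings
(the published plot SDs exceed their means, strongly so on the restored
site, hence per-site dispersion 3.0 grazed / 0.15 restored), Dirichlet
ground cover and Poisson-per-km encounters with unit group size by
default (published counts are individuals and rates are counts ÷ km, so
unit groups make both rate bases coincide).

Sapling height-decay means (grazed 1.3/2.5 m, restored 1.2/1.7 m for
motacú/broadleaf) and broadleaf sapling dbh (3.2 ± 1.3 cm grazed,
1.6 ± 0.8 cm restored) are this package's own calibration, solved
analytically so the expected TNR split lands near the published ≈38
(grazed) vs ≈48 (restored) and sapling basal areas near the published
means; basal-area targets are emergent from density × dbh distribution,
not enforced, and are tested with a wide ±25% band. Shrub-cover targets
and Dirichlet concentrations reproduce only the qualitative contrast the
study reports (denser, palm-rich restored shrub layer; dung and bare
ground on grazed floors) — no quantitative cover table exists to
calibrate against.

What the generator does **not** emulate: spatial point patterns within
plots, seasonal/flooding dynamics, detection distance effects, and any
within-plot covariance of cover beyond the Dirichlet draw (ground
categories therefore sum to exactly 100% per quadrat, which real data
need not). Passing tests on synthetic data demonstrate the estimators
and index conventions, not field realism.

One master seed drives everything; per-site substreams derive
deterministically from (seed, CRC32(site_id)), so identical seeds give
identical datasets even when sites are generated independently.

## Determinism and outputs

All result tables are UTF-8 CSV with stable column order; the run
metadata JSON records config, seed and library versions but no
timestamps, so identical config + seed yield byte-identical bundles.
Logging (including ISO-timestamped progress) goes to stderr only,
keeping the bundle free of nondeterminism.

## Problem sizes

Tests and the acceptance script use the field design (4 plots, 2
transects per site) for structural and directional checks, 400-plot
simulations for parameter recovery (3-SE criterion on Poisson plot
counts), 100 seeded replicates for the directional TNR contrast, and
T ≤ 10 incidence matrices for enumeration-vs-analytic equivalence —
sizes at which the enumeration oracle is exhaustive and the whole suite
runs in about a minute.

## Known limitations

No distance-sampling or occupancy modelling (raw rates only), no
significance testing of site contrasts (the motivating analysis performs
none), no spatial or temporal dynamics, and the published three-axis
variance figures of the original ordinations (83%/91%) are reproducible
only from the original raw dataset, which this package does not ship;
its own ordination is validated through the algebraic identities and an
independent eigendecomposition cross-check instead.
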