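# beniforest

Quantitative analysis for paired grazed-vs-restored forest monitoring
surveys, built around the gallery forests of the Bolivian Beni savanna,
where long-term cattle grazing suppresses recruitment of the dominant
motacú palm (*Attalea princeps*). The package is aimed at restoration
ecologists and field teams who run nested plot/transect campaigns and
want the full analysis — stand structure, regeneration indices,
understory ordination and wildlife encounter metrics — as a tested,
reproducible pipeline rather than a pile of spreadsheets.

## What it computes

**Stand structure.** Per-plot densities (individuals ha⁻¹) and basal
areas (m² ha⁻¹, from *A* = π(dbh/200)² per stem) by life stage
(seedling / sapling / adult) and functional group (broadleaf, motacú,
other palm, with snags as their own reporting classes), averaged across
plots with sample SD; plus 1 m sapling-height, 10 cm dbh and 3 m
adult-height class distributions (acaulescent motacú saplings form the
smallest "dbh" band).

**Natural Regeneration index.** For species *i* in sapling height class
*j* ∈ {1–2 m, 2–3 m, > 3 m}:

    NR_ij  = (RD_ij + RF_ij) / 2
    TNR_i  = Σ_j NR_ij / 3

with RD the relative density and RF the relative frequency (plot
occurrence share), both normalised across species within a class.
Reported values carry the 1/3 class weight, so class columns sum to
100/3 and TNR to 100 per site.

**Understory ordination.** Plot × variable percent-cover matrices from
shrub-layer line intercepts (union of overlapping intervals / transect
length) and ground quadrats (mean of five 4 m² quadrats), then a
standardized correlation-matrix PCA: latent-root retention (eigenvalue
> 1), loadings as eigenvector × √eigenvalue, |loading| > 0.5 salience,
and per-site centroid ± SD on the first two axes.

**Wildlife.** Encounter rates per km walked (mammal effort = dusk +
night distance, nocturnal-bird effort = night only), per-site richness
and unique/shared species, and exact (analytic) species-accumulation
curves over 15-minute survey segments:
E[S(k)] = Σᵢ [1 − C(T−tᵢ, k)/C(T, k)], with the matching combinatorial
variance — no resampling.

**Synthetic generator.** A seeded simulator of the whole survey design
(Poisson stem counts, truncated-normal dbh, exponential sapling heights,
negative-binomial seedling counts, Dirichlet ground cover, Poisson
encounters) whose default profiles reproduce the published site means of
the motivating study, for calibration, property tests and power
exploration.

## Worked example

```python
from beniforest import simulate_survey, nr_table

ds = simulate_survey(seed=1)        # grazed + restored, 4 plots each
print(nr_table(ds).table.round(2))
```

prints

```
 site_id     group  nr_1-2m  nr_2-3m  nr_>3m  tnr_pct
  grazed broadleaf    18.77    18.33   23.78    60.88
  grazed    motacu    14.56    15.00    9.56    39.12
restored broadleaf    15.44    17.00   18.90    51.33
restored    motacu    17.90    16.33   14.44    48.67
```

Each class column sums to 33.33 and each site's TNR to 100; motacú TNR
is ~10 points higher on the restored site — the regeneration signal the
index is designed to expose. More narrative walk-throughs live in
`examples/` (one script per capability), and a thin CLI
(`beniforest simulate|regen|understory|wildlife|run`) wraps the same
functions for shell use.

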