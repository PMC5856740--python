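# anthonet

Analysis of how flower-visiting insect communities partition an
elevational gradient — by **altitude** (which taxa dominate at which
elevation), by **phenology** (when each taxon's activity peaks, and how
much later that peak falls per metre of altitude), and by **trophic
resource** (whether different taxa visit different sets of plant
species). It is aimed at pollination and community ecologists working
with long-format visitation records (one row = one observed flower
visit) from transect surveys along mountain gradients.

## What it computes

**Visitation networks.** Records aggregate into per-site bipartite
count matrices (insect species × plant species), from which the package
derives community composition by order, plants visited exclusively by a
single focal taxon, and sampling-adequacy checks.

**Phenology GLMs.** Counts per site × day × group follow a log-link
Poisson GLM (quasi-Poisson when the Pearson dispersion χ²/df > 1.5)

  log E[y] = β₀ + f(JD, JD², elev, elev², group) + interactions up to
  group:JD:elev, group:JD²:elev, group:JD:elev²

simplified by backward elimination with chi-square tests on deviance
differences under a marginality constraint. From the final fit the
package extracts, per group and elevation, the Julian day of peak
abundance/richness, and regresses peak day on elevation to report the
phenological delay in days per +300 m with a parametric-bootstrap CI.

**Trophic-overlap randomization test.** Per site and taxon pair, the
statistic is the mean Bray–Curtis dissimilarity over all between-taxa
species pairs, D_obs = mean BC(s₁, s₂) with
BC(x, y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on visit-count profiles. A null
distribution D₀ comes from shuffling taxon labels over the pooled
species (profiles and group sizes fixed, B = 1000); partitioning is
significant when D_obs exceeds the empirical 97.5th percentile of D₀.
Sites qualify only with ≥50 visits and ≥10 species per taxon (order
level; 20/5 at family level). Site p-values combine across the gradient
by the Jost generalization of Fisher's product test,
P = K·Σ_{i<N}(−ln K)ⁱ/i! with K = Πpᵢ, equal to the χ²(2N) upper tail
at −2 ln K.

**Synthetic campaigns.** A seeded generator emulates the sampling
design (13 meadow sites over 972–2659 m, weekly transects, Gaussian
elevation/phenology profiles per taxon, Dirichlet plant preferences,
altitude-delayed bloom windows), with a null mode (shared preferences,
exchangeable taxon labels) used to calibrate the overlap test. Ground
truth is emitted alongside every dataset for parameter-recovery tests.

## Worked example

Run the full pipeline on a simulated campaign and print the report:

```
$ anthonet run --out demo --seed 1
$ anthonet report demo
anthonet run summary
====================
seed: 1
records: 5106 (5418 visits, 13 sites)

Community composition (visits by order)
  Diptera          2745 visits (50.7%), 63 species
  Hymenoptera      1444 visits (26.7%), 37 species
  Coleoptera        934 visits (17.2%), 25 species
  Lepidoptera       295 visits (5.4%), 6 species

Phenology peaks (order level, poisson GLM)
  Coleoptera     delay +5.8 d per +300 m (95% CI 5.1 to 6.5, 12 elevations)
  Diptera        delay +8.4 d per +300 m (95% CI 7.9 to 9.1, 11 elevations)
  Hymenoptera    delay +6.8 d per +300 m (95% CI 6.2 to 7.5, 12 elevations)
  Lepidoptera    delay +8.1 d per +300 m (95% CI 6.3 to 10.7, 6 elevations)

Trophic overlap (order level)
  Coleoptera-Diptera: combined P = 2.01e-14 (N = 7, 7/7 sites significant)
  Coleoptera-Hymenoptera: combined P = 2.01e-14 (N = 7, 7/7 sites significant)
  Diptera-Hymenoptera: combined P = 6.29e-18 (N = 9, 9/9 sites significant)
```

Reading it: flies dominate the simulated community (50.7% of 5,418
visits), every order's activity peak falls roughly a week later per
+300 m of altitude (the generator's true delay is 7 d/300 m for most
groups), and at every qualifying site each pair of orders visits
significantly more dissimilar plant assemblages than label-shuffling
predicts — combined across sites the evidence for trophic partitioning
is overwhelming (P ≪ 0.0001; values at these magnitudes sit at the
permutation resolution limit and mean "as small as B = 1000 can
resolve").

Other subcommands: `anthonet simulate` (write a dataset + ground
truth), `anthonet fit-phenology`, `anthonet overlap`, each reading the
canonical CSV (`site_id, elevation, julian_day, order, family, species,
plant_species, count`). The same functionality is importable
(`anthonet.run_pipeline`, `anthonet.overlap_test`, ...).

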