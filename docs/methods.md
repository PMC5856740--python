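# Methods

`anthonet` analyses flower-visitation records collected along an
elevational gradient and asks three questions about the insect
community: how abundance and species richness vary with altitude and
season (and whether that varies by taxonomic group), whether the
seasonal activity peak shifts later at higher elevation, and whether
two insect taxa exploit different sets of plant species (trophic
partitioning). This note describes each model, its assumptions, the
numerical choices, and what the synthetic data generator does and does
not emulate.

## Data model

The atomic observation is one flower visit: site, elevation (m),
Julian day (1-based day of year), insect order/family/species (or
morphospecies), the plant species visited, and a count (aggregated
identical visits). Specimens not resolved to species carry the
sentinel name `UNIDENTIFIED`; they contribute to abundance totals but
never to species richness or to the overlap test, because both of
those are defined over species identities.

Per site, records aggregate into a bipartite count matrix (insect
species × plant species). All downstream statistics are computed from
this matrix plus the order/family labels of its rows.

## Phenology GLMs

Counts per site × sampling day (× taxonomic group for insect models)
are modelled with a log-link Poisson GLM. The full insect model is

    log E[y] = β₀ + f(JD, JD², elev, elev², group)

with all two-way interactions among {elev, elev², JD, JD², group} that
involve elevation or group, and the three-way interactions
group:JD:elev, group:JD²:elev, group:JD:elev². The quadratic JD terms
give each group's seasonal curve an interior maximum; the JD×elevation
interactions let that maximum shift with altitude; the group
interactions let every group differ in both respects. The plant
(bloom-survey) model is the same surface without the group factor.

Model rows are site-day(-group) aggregates; four transects pooled per
sampling day are treated as one observation unit, and days on which a
site was sampled but a group was absent enter as genuine zeros. Sites
are treated as independent; there is no random site effect (a plain
GLM, not a GLMM).

Numerical choices:

- JD and elevation are centred and scaled to unit variance before
  quadratics and interactions are formed; all reported quantities are
  back-transformed. Fitted values are invariant to this coding (tested
  to 1e-8).
- IRLS runs to a deviance-change tolerance of 1e-8, at most 100
  iterations; non-convergence is an error, never a silent result.
- Rank-deficient designs raise an error naming the aliased columns.
  The pipeline additionally pre-prunes terms that a degenerate design
  (single day, single site, single group level) makes inestimable,
  dropping marginality-droppable terms whose columns contribute no
  rank.
- Overdispersion: when the Pearson χ²/df of the full Poisson fit
  strictly exceeds 1.5 (configurable), the quasi-Poisson family is
  used — identical point estimates, standard errors inflated by √φ.

### Stepwise simplification

Backward elimination: at each step, every *droppable* term is tested
by refitting the model without it and comparing deviances with a
chi-square test (df = parameters removed; deviance difference scaled
by φ under quasi-Poisson). The term with the largest p-value is
removed while that p-value exceeds α = 0.05; ties go to the
highest-order interaction. A term is droppable only if no remaining
term contains it; containment includes the polynomial hierarchy, so
JD stays while JD² or any interaction involving JD or JD² remains.
This is stricter than interaction-only marginality; it prevents
uninterpretable models such as a retained group:JD²:elev without its
lower-order relatives.

### Peaks and the altitudinal delay

For each group and elevation the fitted curve is evaluated on a
0.1-day grid over the observed JD range; the argmax is the peak day.
A maximum at either end of the range means the curve has no interior
peak there ("boundary"); such elevations are excluded. The delay is
the least-squares slope of peak day on elevation, reported in days per
+300 m.

The slope's 95% CI is a parametric bootstrap: 200 coefficient vectors
are drawn from the fitted model's asymptotic sampling distribution
(covariance scaled by φ under quasi-Poisson), and the peak-extraction
and regression are repeated per draw. A naive regression CI on the
point peaks is useless here — the fitted peaks are a smooth function
of elevation, so their scatter around the regression line is nearly
zero and carries no information about estimation uncertainty.

## Trophic-overlap randomization test

Per site and taxon pair (T1, T2), the statistic is

    D_obs = mean over all cross pairs (s₁ ∈ T1, s₂ ∈ T2) of
            BC(s₁, s₂),   BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)

on raw visit counts. BC is a semimetric (symmetric, in [0, 1], the
triangle inequality may fail); 0 means identical visit profiles, 1
disjoint plant sets. Only between-taxa pairs enter the mean;
within-taxon pairs carry no information about the *between*-taxa
contrast being tested.

The null shuffles taxon labels uniformly over the species of T1 ∪ T2,
holding every species' visit profile and both group sizes fixed (an
alternative universe shuffling over all species at the site is
available behind a flag). B = 1000 replicates by default. Because the
statistic depends on species only through their pairwise
dissimilarities, the implementation computes the full pairwise matrix
once and averages a relabelled cross block per replicate —
mathematically identical to recomputing BC each time, and validated
against a brute-force oracle and exhaustive enumeration in the tests.

Significance: partitioning is declared when D_obs strictly exceeds the
empirical 97.5th percentile of the null sample (a one-sided test at
α = 0.025). The p-value uses the add-one estimator
(1 + #{D₀ ≥ D_obs}) / (B + 1), which is never zero. Type-I error of
the whole construction is verified by simulation against the
generator's null mode.

Sites qualify for a pair only when both taxa reach 50 visits and 10
species (order level) or 20 visits and 5 species (family level) in
that site's network; order-level pairs default to
{Diptera, Hymenoptera, Coleoptera} (butterflies are too scarce per
site), family-level pairs to the focal Diptera families.

### Combining sites

Qualifying sites are kilometres apart and treated as independent.
Their p-values combine through the generalization of Fisher's product
test:

    K = Π pᵢ,   P = K · Σ_{i=0}^{N−1} (−ln K)ⁱ / i!

evaluated in log space (logsumexp over i·ln(−ln K) − ln i!) so that
very small K remains accurate. The series is mathematically the
upper-tail probability of a χ²(2N) at −2 ln K, which serves as an
independent oracle in the tests (agreement ≤ 1e-10 over
N ∈ 1..10 × K ∈ [1e-12, 1]). With all qualifying sites at the add-one
floor p = 1/(B+1), the combined P reaches its own floor (B+1)^(−N)
adjusted by the series — combined values below ~1e-17 should be read
as "at the resolution limit", not as literal probabilities.

## Synthetic data generator

The generator emulates the sampling design the analyses assume:
meadow sites spanning a mountain gradient, each walked on a fixed set
of days, every flower visit recorded. Counts per (site, day, insect
species, plant) are Poisson with intensity

    λ = (V_peak / n_species)
        · exp(−(elev − opt)² / 2w_e²)        taxon elevation profile
        · exp(−(JD − μ(elev))² / 2w_p²)      taxon phenology
        · pref[species, plant]               plant preference
        · bloom(plant, JD, elev)             bloom window

with μ(elev) = base_peak + delay·(elev − ref)/300 and ref the lowest
site elevation (so delays are relative, matching how they are
reported). The bloom factor is a Gaussian truncated to exactly zero
beyond ±3 bloom widths, keeping networks sparse. The spread of a
taxon's flight period (`phenology_width`, default 18 d) is a required
shape parameter of the phenology factor.

Preferences: each taxon draws a mean preference vector from a
symmetric Dirichlet whose concentration controls diet breadth (small =
a few favoured plants = strong partitioning); its species then draw
individual vectors from a Dirichlet centred on that mean
(concentration 60, so congeners forage similarly). In **null mode**
all species of all taxa draw from one shared mean — taxon labels are
exchangeable, which is exactly the null hypothesis of the overlap
test; this mode calibrates its type-I error.

The default default Alpine scenario has 13 sites interpolated over
972–2659 m, weekly sampling JD 140–208, 120 plant species with
staggered bloom windows, and 12 focal-family profiles across four
orders (syrphids peaking ~1500 m, empidids ~1800 m,
muscids/anthomyiids ~2300 m; bees fading above ~1400 m; sawflies flat;
leaf beetles with a 10 d/300 m delay against ~1 d for long-horned
beetles). Visit scales are set so a campaign yields ≈5,500 visits
split ≈49/28/18/5% among Diptera/Hymenoptera/Coleoptera/Lepidoptera,
and the preference concentration (0.08) reproduces a realistic
visits-per-plant density and order-exclusive plant fractions of a few
to ~20%. These optima and scales are scenario parameters chosen to
mimic the study system qualitatively, not estimates of it.

What the generator does **not** emulate: weather and observer effects,
detection bias, within-site spatial structure, taxonomically
unresolved specimens, multi-year turnover, and any correlation between
a plant's bloom phenology and which taxa prefer it beyond what the
independent factors induce. Tests passing on this generator therefore
show that the estimators recover the generator's structure — elevation
optima, phenological delays, preference partitioning — at realistic
sample sizes, not that field data meet these assumptions.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to make their Monte-Carlo
error small relative to the tolerance being asserted: type-I
calibration uses 400 null replicates at B = 199 (99% binomial CI
±0.020 around 0.025); power uses 100 strongly partitioned replicates;
the exhaustive-null comparison uses a 7-species network (35 label
assignments) at B = 10,000; delay recovery uses ≥2,000 visits over 9
elevations. The full pipeline on the default Alpine scenario (≈5,500
visits) runs in seconds.

## Known limitations

- The stepwise procedure inherits the usual caveats of sequential
  testing; it is implemented because it is the analysis being
  reproduced, not as a model-selection recommendation.
- Quasi-Poisson scales the chi-square comparison by the Pearson
  dispersion of the larger model; an F-test would be the other
  defensible convention.
- The overlap test conditions on the observed profiles; it does not
  model sampling noise in the profiles themselves.
- Exclusivity fractions are descriptive and depend strongly on
  sampling depth per plant; they are not accompanied by a test.
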