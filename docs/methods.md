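# Methods

## The study system and what the package computes

A solitary koinobiont ichneumonid wasp parasitizes larvae of nettle-feeding
*Aglais* butterflies. Field data consist of butterfly nests (gregarious
larval batches) collected at 9 fortnightly sampling occasions per season
across 19 sites in two regions over two years; each nest contributes the
number of larvae collected, the number that yielded the focal parasitoid,
and the number of parasitoid adults that later emerged from their cocoons.
The package implements the full analysis chain around these counts:

1. **Phenological overlap (`phenology`).** For a site *j* and year *i*, the
   overlap between parasitoid and host is

   OPH<sub>ij</sub> = Σ<sub>k=1..9</sub> min(P<sub>ijk</sub>, H<sub>ijk</sub>),

   where P<sub>ijk</sub> is the proportion of all parasitoid individuals
   reared at that site-year that came from occasion *k* and H<sub>ijk</sub>
   the proportion of the host's nests collected at occasion *k*. Parasitoid
   abundance counts *individuals* and host abundance counts *nests*; the
   mixed units follow the index's definition. OPH ∈ [0, 1]; it is computed
   only for site-years where both species were actually sampled, and
   zero-total distributions are flagged undefined (NaN) rather than imputed.

2. **Parasitism models (`glm`).** The probability that a nest is parasitized
   (Bernoulli per nest) and the proportion of larvae parasitized within
   parasitized nests (binomial per nest) are modelled with a logit link.
   The full model contains host, region, year, pooled instar class
   (1–2, 3, 4, 5), centered sampling week and overlap with their squares,
   the density of native-host nests in the sampling week, and the two-way
   interactions host×{region, year, instar, density} and region×year.
   Terms are tested by Type-II likelihood-ratio tests (a term is compared
   between models that both exclude any higher-order term containing it)
   and selected by backward elimination at α = 0.05, never removing a main
   effect while an interaction containing it is retained, nor a linear term
   while its square is. Land-cover covariates can be merged per nest and
   their contribution summarized as the gain in deviance-based pseudo-R²
   (1 − D<sub>model</sub>/D<sub>null</sub>).

3. **Landscape metrics (`landscape`).** On a categorical 10 m raster,
   buffers of radius 10–500 m around each nest yield per-class percentages
   (a cell belongs to a buffer iff its center is within the radius) and an
   edge length (10 m per 4-adjacent pair of differing classes with both
   centers inside the buffer), a fragmentation proxy.

4. **Molecular summaries (`popgen`).** From pre-aligned barcode fragments:
   haplotype collapse after complete deletion of gap/N-containing sites,
   Nei's unbiased haplotype diversity Hd = n(1 − Σp<sub>i</sub>²)/(n − 1),
   nucleotide diversity π as mean pairwise differences per analyzed site,
   segregating and parsimony-informative site counts, and a median-joining
   haplotype network. From dominant (band presence/absence) marker
   matrices: the percentage of variable markers and a band-state gene
   diversity, mean over loci of 1 − f₁² − f₀².

## Modelling choices that were genuinely open

- **Occurrence windows.** The parasitoid's activity window (first to last
  occasion with a rearing) can be scoped per region-year or per site-year;
  region-year is the default and the scope is carried in output metadata,
  because the regional definition is the one the downstream analyses
  discuss. Nests outside the window, and by default nests at site-years
  where the parasitoid was never observed, are excluded from the model
  frames.
- **Absence rows.** When unoccupied site-years are explicitly included
  (the land-cover analysis informs absences this way), their nests carry
  an overlap of 0: the parasitoid did not occur there, so its phenological
  overlap with the host is zero by definition rather than undefined.
- **Centering.** Week and overlap are centered before squaring to reduce
  collinearity; coefficients are reported on the centered scale and the
  frame records the constants. No attempt is made to report quadratic
  coefficients on any other scale, since the scale used in the published
  tables is not recoverable.
- **Zero-information columns.** A covariate column that is identically
  zero is dropped from the design with zero degrees of freedom (its LR is
  exactly 0, p exactly 1), mirroring aliased-NA handling in R; genuine
  collinearity between informative columns raises an error naming the
  aliased columns. Ties in elimination p-values are broken by dropping the
  higher-order term first, then lexicographically, for determinism.
- **Raster rules.** Cell-center-in-circle membership and 4-neighborhood
  adjacency are the documented contract; area-weighted clipping is not
  attempted. Buffers that extend past the raster report their covered
  fraction and percentages over covered cells.
- **Gene diversity for dominant markers.** The band-state estimator is the
  default; a Hardy-Weinberg variant that reconstructs the null-allele
  frequency as √f₀ is exposed behind `estimator="hw"`, because dominant-
  marker tools disagree on this point and the study's marker matrix is not
  available to adjudicate.
- **Median-joining network.** The construction is minimum spanning network
  (all tied minimum links kept) plus iterative addition of site-wise
  majority-consensus vectors of connected triplets whenever the addition
  strictly reduces the minimum spanning cost of the node set, followed by
  pruning of low-degree medians that no longer reduce that cost. This is a
  deliberate simplification of the reduced-median/maximum-parsimony
  machinery of the classic desktop tool, adequate here because the studied
  haplotypes are few and within three mutational steps of one another. The
  network's `total_cost` is the minimum spanning cost over observed plus
  median nodes, which is the quantity the median vectors minimize.
- **GDD13.** Growing degree-days accumulate max(0, t̄ − 13 °C) over daily
  means from January 1 to August 31, with simple truncation and a hard
  error listing any missing days; no sine-wave interpolation, since only
  the threshold and interval are specified by the design.

## The synthetic-data generator

`synthetic` generates the study conditions so that every pipeline stage is
testable without field or sequence data:

- 19 sites (10 south, 9 north) × 2 years × 9 occasions. Host nest counts
  per site-occasion are Poisson around Gaussian phenology curves (peak,
  spread, and peak intensity per species/region/year); the default
  scenario advances the northern host curves by 1.5 occasions in the
  second year, mimicking a warm spring, so the qualitative pattern of a
  northern overlap drop emerges. These defaults are illustrative, not
  fitted.
- The parasitoid attack window is a continuous Gaussian activity curve
  with sd 0.5 occasions (≈ one week on a fortnightly grid), integrated
  over each occasion and normalized to 1 at its peak. Per-larva parasitism
  probability is activity × expit(η), with η summing a baseline with host
  (+0.41 for *A. urticae*), instar (peaking at instars 3–4), year, and
  south×second-year (+1.04) effects. An attack season disjoint from the
  sampled occasions therefore yields exactly zero parasitism.
- Nest sizes are 1 + negative-binomial with mean ≈ 10 larvae — a
  placeholder stated here because per-nest larvae distributions are not
  published; it is recorded in each dataset's ground-truth metadata.
- Land cover is a Gaussian-smoothed noise field thresholded at the
  quantiles of the requested class proportions, giving spatially coherent
  blobs whose realized proportions match the request to within one cell.
- Sequences are multinomial draws from constructed haplotypes a stated
  number of mutational steps from a reference; dominant markers are
  Bernoulli draws per locus (82 loci, 15 polymorphic by default).
- `simulate_glm_dataset` draws nest- or larva-level binomial responses
  from an explicit linear-logit design; because the generating model is
  exactly the fitted model, refits are unbiased and it is the workhorse of
  the parameter-recovery tests. At larva level, nests with zero
  parasitized larvae are dropped, as the study models larvae only within
  parasitized nests; with study-like nest sizes this zero-truncation is
  negligible for the slope coefficients but leaves the plain binomial
  likelihood mildly misspecified, which is why the null-calibration check
  (uniform Type-II p-values for a pure-noise covariate) is run at nest
  level, and why a dispersion statistic (residual deviance / residual df)
  is reported for larva-level fits.

What passing tests on these data do **not** show: real nests are spatially
and temporally autocorrelated within sites, real phenology curves are
skewed and multi-brooded, detection depends on instar in ways the
stratified design only partly controls, and over-dispersion from shared
nest environments is not generated. Recovery of an effect from the
generator demonstrates the estimator is correct, not that the field
estimate is.

## Problem sizes

Simulation-based tests use study-like sizes: 145 nests for larva-level
recovery (200 replicates), ~390 nests for nest-level recovery, 200–300
replicates for elimination-rate and calibration checks, brute-force
oracles on alignments up to 6 × 40 sites, and random network instances up
to 8 haplotypes. These sizes make every Monte-Carlo tolerance (±2 MC SE,
3-sigma binomial bands) explicit in the tests themselves.

## Known limitations

- The published model-selection tables (coefficients and Type-II ANOVA of
  the field analysis) **cannot be reproduced** here: they require the raw
  field data, which is not released. Those published estimates (+0.41 host
  contrast, +1.04 region×year, −0.0467/+0.026/+0.018 land-cover effects
  per percentage point at 100 m) serve only as simulation ground truths
  that the recovery tests must re-estimate correctly.
- Global diversity of the deposited barcode accessions is checked only
  when a user places the aligned FASTA files under `data/` (they are not
  shipped); the shipped checks cover the analytically forced table cells.
- No mixed-effects structure (site random intercepts), no residual
  simulation diagnostics, no spatial Bayesian clustering, and no
  correction for overlapping 500 m buffers — all outside the package's
  scope.
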