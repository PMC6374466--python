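# Methods

This note documents the models implemented in `coralconnect`, the
conventions chosen where several exist, the defaults and why, and what the
synthetic data do and do not establish.

## Genotype model and filters

Genotypes are unphased diploid microsatellite calls: each call is stored as
a sorted pair of positive integer fragment sizes, `(0, 0)` for missing, and
a call with one unreadable allele is treated as wholly missing.  GenePop
files in both 2- and 3-digit encodings are read and written; population
codes are taken from the leading token of individual identifiers
(`SITE_007`), which round-trips the writer's own output exactly.

Three filters precede all statistics, mirroring the usual workflow for a
clonal broadcast spawner sampled across a cryptic species complex:

1. **Lineage filter.** Individuals are retained when their membership in a
   designated cluster of an externally produced Q-matrix is ≥ 0.70 in
   *every* supplied K block (boundary inclusive).  The clustering itself
   (STRUCTURE-style MCMC) is out of scope; only the membership filter is
   implemented.  Partially missing genotypes do not interact with this
   rule: the filter reads Q values only.
2. **Clone filter.** Individuals matching at every locus scored in both are
   joined into genets (union-find, so matching is transitively closed).
   A duplicated genet counts as a confident clone only when its MLG
   probability of identity — the product over its scored loci of the
   population-level `PI = Σp_i⁴ + Σ_{i<j}(2p_ip_j)²` — is below 0.001.
   One ramet per genet (the first sampled) is kept downstream.  Clonal
   fraction is `1 − MLG/N` regardless of the PI flag, matching how clonal
   richness is normally tabulated.
3. **Population filter.** Populations with fewer than 9 distinct MLGs are
   dropped whole; 9 is kept as the default minimum for meaningful
   frequency estimates and is the default rarefaction depth g.

## Estimator conventions

- **θ (F_ST).** Weir–Cockerham variance components `a, b, c` per allele and
  locus, multilocus estimate `Σa / Σ(a+b+c)`.  Populations untyped at a
  locus drop out of that locus only (pairwise deletion throughout).
  Permutation p-values reallocate individuals among populations;
  p = (1 + #{θ* ≥ θ}) / (B + 1).
- **Jost's D.** Per locus
  `D = (k/(k−1)) (H̃_T − H̃_S)/(1 − H̃_S)` with Nei–Chesser small-sample
  estimators of H_S and H_T.  The multilocus value is the arithmetic mean
  of per-locus D: a harmonic mean is undefined whenever a locus gives
  D ≤ 0, which happens routinely near the null, and the arithmetic mean is
  what GenAlEx (the de-facto reference for this quantity) reports.
- **AMOVA.** Decomposition at the gene-copy level: per locus each genotyped
  individual contributes two allelic units, the inter-unit distance is 0/1
  allele identity, sums of squares follow `SS = Σ_{i<j} d_ij / m`, variance
  components use the standard unequal-size coefficients, and components are
  summed over loci before forming F_CT, F_SC, F_ST.  An inter-individual
  genotype distance (non-shared alleles, 0/1/2) was evaluated as an
  alternative metric and rejected: its fixation index has expectation
  ≈ 1.5 × F under an island model with planted F (the multiset distance is
  a nonlinear function of allele mismatches), whereas the gene-copy
  decomposition has expectation exactly F under a Balding–Nichols model and
  agrees with the convention in which the AMOVA among-population percentage
  equals 100 × F_ST.  The genotype-level distance matrix remains available
  (`allele_distance_matrix`) for individual-level ordination.  Permutation
  schemes: individuals among populations (F_ST), individuals among
  populations within groups (F_SC), whole populations among groups (F_CT).
- **Exact tests.** Genic differentiation per locus on the alleles × 2
  contingency table; the statistic is the multivariate hypergeometric
  probability of the table and the null is sampled by permuting pooled
  allele labels (fixed margins).  This replaces a Markov-chain exact test
  with a plain Monte-Carlo estimate of the same estimand; the default
  resample count (10 000) is the accuracy knob.  Loci are combined by
  Fisher's method (χ², 2L df); monomorphic loci are skipped and reported.
- **Holm (sequential Bonferroni).** Step-down, strict inequality against
  `α/(m − i + 1)`, stopping at the first failure.
- **Assignment.** Rannala–Mountain: posterior predictive genotype
  likelihoods under a Dirichlet prior adding `1/k` per allele (k = alleles
  observed at the locus dataset-wide), two gene copies drawn sequentially,
  leave-one-out for the home population.  Assignment requires top
  probability > 0.70; an assignment into a different region class flags a
  putative immigrant.  The prior guarantees non-zero likelihoods for
  alleles unseen in a reference population.
- **Trees and ordination.** Nei (1972) standard distance `D = −ln I` with
  arithmetic means of homozygosity/identity terms over loci;
  neighbour-joining and PCoA are delegated to scikit-bio; bootstrap support
  resamples loci with replacement and counts internal-edge bipartitions.

## Synthetic genotypes

The island layout draws per-locus ancestral frequencies uniformly on the
simplex and subpopulation frequencies from a Dirichlet with concentration
`(1 − F)/F` (Balding–Nichols), making the planted `fst_target` an analytic
truth: mean multilocus θ over replicates recovers it within Monte-Carlo
error (tested at F ∈ {0.02, 0.05, 0.10, 0.15} with 13 populations × 20
diploids × 8 loci, the study-scale configuration).  The linear
stepping-stone layout starts from the ancestral vector and applies one
binomial resampling of `2Ne` gene copies per link with
`1/(2Ne) = fst_target/(n_pops − 1)`, so the divergence accumulated across
the whole chain is of order `fst_target`; drift along the chain produces
the expected edge-ward decline in diversity and a strong isolation-by-
distance signal.  Clones are exact duplicates made after missingness is
applied; cryptic-lineage admixture draws each gene copy from a second,
diverged frequency pool with a per-individual probability, and the true
admixture proportions are exported as the Q-matrix.

Default configuration (13 populations × 20 diploids × 8 loci, 8 alleles
per locus, planted divergence 0.108, populations on a south→north line
split 3 subtropical / 6 pre-existing temperate / 4 recently expanded)
matches the scale of the retained field data set this pipeline is shaped
around.

What the generator does **not** emulate: mutation (no stepwise model),
null alleles, genotyping error, overlapping generations, selection, or
spatially realistic coastlines.  Tests passing on these fixtures establish
estimator correctness and pipeline behaviour, not robustness to those
artefacts.

## Ocean, phenology and particle tracking

The synthetic ocean is a divergence-free poleward jet: a Gaussian
cross-section (default width 0.8°, peak 0.4 m/s) around a core path given
as (lat, lon) waypoints, with flow directed along the path tangent,
optional seeded eddy noise (off by default), land cells rasterised from
polygons carrying zero velocity, and SST that is linear in latitude with a
sinusoidal season.  This is deliberately minimal forcing for testing the
tracking and scheduling logic, not mesoscale oceanography.

Spawning: daily increments `max(T − 13 °C, 0)` accumulate from February
1st; the exceedance day is the first whose cumulative sum reaches
1000 °C·day; the spawning full moon is the latest full moon on or before
exceedance (full moons are a fixed 29.530588-day arithmetic progression —
scheduling only needs relative timing, not an ephemeris); the release
window spans 10 days from 3 days before that moon at 50 particles/day.
A site-year that never reaches the threshold is reported as non-spawning,
contributing a zero row that stays in the multi-year average's
denominator.

Tracking: RK4 with a 2-hour default step (standard for ~1/12° surface
fields), bilinear spatial and linear temporal velocity interpolation,
degree↔metre conversion via `111320·cos φ`.  A step that would land on a
land cell is cancelled (no-flux coast; particles never die on land);
leaving the grid records the particle as exited.  A particle settles in
the first habitat cell it occupies at an age ≥ 3 days — its natal cell
included, so self-recruitment is possible — and expires unsettled at 42
days.  Settlement is checked at integration steps, so a cell crossed
entirely within one 2-hour step could in principle be missed; at the
default step and field resolution a particle moving 0.5 m/s advances
~0.3 cells per step, so this is immaterial.  Conservation
(settled + expired + exited = released) is asserted in tests for every
run.

Connectivity: entry (i, j) of a year matrix is settlers(i→j)/released(i);
years are averaged element-wise.  Multi-generation "accumulation of
dispersed larvae" is computed as monotone reachability on the
row-normalised settlement chain: `A₁ = C`,
`A_{g+1} = A_g ⊕ (A_g·Ĉ)` with the element-wise saturating combine
`a ⊕ b = a + b − ab`, iterated to 1000 generations or until the largest
element change falls below tolerance.  Entries are monotone non-decreasing
and capped at 1; the result answers "has a lineage from i reached j within
g generations", which reproduces the intended behaviours — stabilisation,
stepping-stone filling, persistent directional barriers — without
asserting any particular population dynamics.  Region aggregation takes,
for each source region, the mean over member sites of the summed
probability of sinking anywhere in the target region.

## Isolation by distance

Genetic distance is raw pairwise F_ST by default (the `FST/(1−FST)`
linearisation is available but off, matching the common practice of
regressing raw values).  Predictors: haversine great-circle distance
(R = 6371 km); shortest sea path by Dijkstra over the 8-connected sea-cell
lattice with great-circle edge weights (a reproducible replacement for
hand-measured around-land routes; it exceeds the great circle by at most
the lattice detour factor, ≈ 8 %, plus one cell of discretisation);
and `−log((C_ij + C_ji)/2 + ε)` on the iterated connectivity matrix with
ε set to half the smallest positive symmetrised entry, which places
zero-flow pairs strictly beyond every connected pair without infinities.
The Mantel test is one-tailed for positive association (the IBD
convention), permuting row/column order of one matrix jointly,
p = (1 + #{r* ≥ r})/(B + 1), default 10 000 permutations, and requires at
least four populations.

## Numerical and reproducibility choices

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from a single master seed via `SeedSequence` and logs them
in the run manifest together with parameter values and input checksums.
Rarefaction uses log-gamma binomials for stability; PI and likelihood
products are accumulated in log space where overflow is possible; Nei
identities are clipped at 1e-12 before the logarithm; tied permutation
statistics count as extreme (conservative).  Pipeline-scale defaults for
the bundled synthetic run (4 spawning years, 13 sites, ~1/12° grid over
a 10°×15° domain, 500 particles per site-year) were chosen as the smallest
configuration that exercises every stage with clearly interpretable
output; the physical parameters (42-day PLD, 3-day competency, 50
particles/day, 10-day window, 13 °C base, 1000 °C·day threshold) are the
biological defaults and are all overridable in the run configuration.

## Known limitations

- Purely passive 2-D surface transport: no vertical behaviour, mortality,
  or temperature-dependent competency.
- The moon table is an arithmetic progression, not an ephemeris; absolute
  spawning dates are schematic.
- The exact test is plain Monte-Carlo, so very small p-values are bounded
  by 1/(resamples + 1).
- The gene-copy AMOVA treats the two copies of an unphased genotype as
  exchangeable units (no within-individual level); F_IS-level structure is
  reported separately via the diversity summary.
- Clone matching tolerates missing loci; two genets identical at every
  mutually scored locus but differing at an unscored one are merged.
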