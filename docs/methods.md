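# Methods

`island_popgen` analyzes diploid microsatellite (SSR) genotypes from
archipelago populations: descriptive diversity and structure first, then
coalescent-simulation-based demographic inference with approximate
Bayesian computation and random forests (ABC-RF). This note records the
models, estimators, defaults, and design choices, and what the synthetic
data do and do not establish.

## Genotype model and conventions

Genotypes are an `(n, L, 2)` integer array; allele states are repeat
counts or fragment sizes, `0` is the missing code, and half-missing
genotypes are rejected at load. Missing data are handled locus-wise: an
individual missing one locus contributes to all others (the convention
of FSTAT/GenAlEx-style tools). Fragment-size to repeat-count conversion
is an explicit transform requiring per-locus motif lengths — never
implicit, because the stepwise mutation machinery operates on repeat
counts while field data are often exported as fragment sizes.

GenePop files use 2- or 3-digit alleles with `pop` separators. Because
GenePop has no population-name field, this package writes the id column
as `label|individual`, recovers both on read, and falls back to the
common first-id-names-the-block convention for foreign files; `csv_wide`
is fully faithful. Round trips are bit-exact in both dialects.

## Diversity and differentiation estimators

* **Allelic richness** `A_R(g)` — hypergeometric rarefaction to `g` gene
  copies: `A_R = sum_i [1 - C(N - N_i, g) / C(N, g)]`. `auto` uses, per
  locus, the minimum observed copy number across populations (FSTAT's
  rule). Exact binomial arithmetic, no approximation.
* **Gene diversity** — Nei's unbiased estimator
  `H_E = (2n / (2n - 1)) (1 - sum p_i^2)`; `H_O` is the heterozygote
  proportion among typed individuals.
* **F_IS** — Weir & Cockerham's *f* from variance components, summed
  over alleles and loci; the randomization test shuffles gene copies
  among individuals within the population (locus-wise) and reports the
  two-sided `(hits + 1)/(n_perm + 1)` p-value. Default 10,000
  permutations; drivers use fewer where the p-value is not the object
  of interest.
* **F_ST** — multilocus Weir–Cockerham theta, `sum a / sum (a + b + c)`.
  Negative estimates are reported as computed (truncation would bias the
  isolation-by-distance regression).
* **D_A** — Nei et al. (1983),
  `1 - (1/L) sum_loci sum_alleles sqrt(x y)`; loci unscored in either
  population are skipped from the average.

All four estimators are verified against naive-loop reference
implementations to 1e-12, and rarefaction against exhaustive subsample
enumeration.

## Trees and isolation by distance

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q
criterion; ties break deterministically by label order. Negative branch
lengths are truncated to zero with the deficit moved to the sister
branch so the joined pair's distance is preserved. Bootstrap support
resamples **loci** with replacement (the convention of population-level
SSR tree programs) and reports the percentage of replicates containing
each internal bipartition of the full-data tree.

The IBD Mantel test correlates `F_ST / (1 - F_ST)` with
`ln(1 + d_km)`, `d` the great-circle (haversine) distance — no
particular distance model is mandated by the data, so the simplest one
is used. Permutations apply to rows/columns of one matrix; when
`n_perm + 1 >= n!` every permutation is enumerated and the p-value is
exact. A pair filter (`distance > threshold`) supports the far-pair
analysis; its correlation is reported two-sided since the expected sign
is not specified in advance. Defaults: 9,999 permutations; pairs with
`F_ST = 1` are dropped with a warning (linearization undefined).

## Coalescent simulator

Genealogies come from msprime's exact backward-in-time coalescent
(piecewise-constant diploid sizes, splits, migration; waiting times are
exact exponentials per epoch). Budding events ("V splits from B") use a
total mass migration at the divergence time because a population split
into an extant ancestral deme is not expressible as a `population_split`
event; migration involving the derived deme is zeroed at that time.

The mutation overlay is a generalized stepwise model (GSM) written
here: per-branch mutation counts are Poisson(mu x branch length), each
mutation moves the repeat count by `k` steps,
`P(k) = (1 - P_GSM) P_GSM^(k-1)`, sign +/- 1/2, and states reflect at
repeat count 1 (`z -> |z + s|` for `z = state - 1`), keeping states
physical without discarding mutations. `P_GSM = 0` is the strict SMM.
The ancestral state defaults to 20 repeats. The reflected walk is
processed in vectorized stretches between boundary crossings and is
bit-equivalent to the mutation-by-mutation update.

### Demographic catalogue

Single-population size-change models: SNM (constant `N_CUR`), PGM
(growth: ancestral size `RN_ANC x N_CUR` with `RN_ANC < 1` before
`T_CHANGE`), SRM (reduction: `RN_ANC > 1`).

Three-group divergence models over B (Bonin), V (Volcano), YD
(Yaeyama + Daito), with B and YD sharing one current size `N_BYD`,
V having `N_V`, and a root size `N_ANC`. **The five topologies are a
reconstruction** — the source figure is not machine-readable — and ship
as: M1 `(B,(YD,V))` with V budding from YD; M2 `(V,(B,YD))` with YD
budding from B; M3 `(YD,(B,V))` with V budding from B; M4 `(B,(V,YD))`
with YD budding from V; M5 a simultaneous trichotomy with a single
divergence time. Migration patterns (also reconstructions): `M1` B-V
only, `M2` all pairs, `M3` stepping-stone B-V and B-YD, symmetric
per-generation rates, active only while both demes exist. Both
catalogues are configurable; conclusions about the real study system
should not lean on the unverifiable details of M1/M2/M4/M5.

## ABC with random forests

* **Reference tables** draw parameters from uniform or log10-uniform
  priors, simulate a dataset, and record a DIYABC-style summary vector:
  per group — mean allele number, mean unbiased `H_E`, mean allele-size
  variance (divisor N), mean Garza–Williamson M-ratio
  (`alleles / (size range + 1)`); per group pair — multilocus theta and
  mean squared difference of mean allele size. Order-constrained draws
  (`T_1 < T_2`) are enforced by resampling, i.e. the joint prior is the
  order-conditioned product. Degenerate draws (NaN statistics) are
  resampled too.
* **Model choice** trains a 500-tree classification forest on
  (statistics -> model); votes on the observed vector rank models,
  out-of-bag misclassification is the prior error rate, and the
  posterior probability of the winner is a regression forest's
  prediction of the out-of-bag success indicator at the observed point —
  the published ABC-RF recipe. Everything is single-threaded and seeded;
  results are exactly reproducible.
* **Parameter estimation** is rejection plus local-linear adjustment
  (DIYABC-style), chosen because the study-style outputs are posterior
  modes with 95% HPD intervals — the signature of that method. Distances
  are Euclidean on statistics standardized by reference-table median
  absolute deviation (falling back to SD for MAD = 0, dropping constant
  columns). The kept fraction (`tolerance`, default 0.05) is
  Epanechnikov-weighted; parameters are logit-transformed on their prior
  scale (after log10 for log-uniform priors) before the weighted linear
  regression, so adjusted draws cannot leave the prior support. With
  `adjust=False` the accepted sample is unweighted, so `tolerance = 1`
  recovers the prior exactly. Modes come from a weighted Gaussian KDE on
  the prior's scale; the 95% HPD is the shortest interval holding 95% of
  the weighted sample. Posterior-predictive goodness of fit reports
  `p = 2 min(P(sim <= obs), P(sim >= obs))` per statistic with the
  `(count + 1)/(n + 1)` correction.

### Default priors

`N_CUR`, `N_BYD`, `N_V`, `N_ANC`: log10-uniform on (1e2, 1e5) diploids.
`RN_ANC`: log10-uniform (1e-2, 1) for PGM, (1, 1e2) for SRM.
`T_CHANGE`, `T_1`: log10-uniform (10, 1e4) generations; `T_2`:
(1e2, 3e4), conditioned on `T_1 < T_2`; M5's single time spans
(1e2, 3e4). `mu`: log10-uniform (1e-4, 1e-3) per locus per generation;
`P_GSM`: uniform (0, 0.8) — typical microsatellite ranges. Migration
rates: log10-uniform (1e-3, 1e-1) per generation; the floor keeps
`4Nm` of order one or larger over most of the size prior, because lower
rates collapse the migration models onto the no-migration model and the
comparison degenerates into a nested-model coin flip.

## Sequential pipeline

Step 1 fits SNM/PGM/SRM per island group (pooled within group); step 2
compares the five divergence topologies without migration and prunes
iteratively — drop models (never the current best) whose confusion-row
error exceeds 0.6, else those with vote share below 0.15, re-compare,
stop at two models or no drops — a formalization of the narrative
5 -> 4 -> 2 cascade; step 3 compares the winning topology against its
three migration variants. The final posterior pools the winner's rows
from steps 2 and 3 when the no-migration topology wins (same generative
model, same priors). Observed group samples are subsampled to the
simulated sample sizes so summary statistics are compared at matched n.
Every comparison is logged in an append-only ledger sufficient to
replay it; reference tables persist as TSV + JSON sidecar.

## Synthetic data

`make_study_mimic` reproduces the study's sampling design exactly
(28 populations, 14 islands, 4 island groups, per-population n of
10-44 totalling 663, 11 loci) under a Yaeyama-rooted colonization
demography: Bonin splits from the Yaeyama lineage 8,000 generations
ago, Daito buds from Yaeyama (2,000), Volcano buds from Bonin (1,500)
with a founder-limited size, local populations bud from their group
deme 100 generations ago, and the CC4 ecotype pair splits only 20
generations ago. Sizes (400-2,200 diploids at mu = 5e-4, P_GSM = 0.3)
put `theta = 8 N mu` in the range that yields study-like gene
diversities (about 0.5-0.75) and the study's qualitative ordering
(Yaeyama > Bonin > Daito > Volcano) as an emergent property. Island
coordinates are approximate real island positions; per-population
offsets are synthetic.

What the mimic does **not** emulate: null alleles, allelic dropout,
genotyping error, within-island spatial structure, and selection. Tests
passing on the mimic establish that the estimators and the inference
machinery behave correctly on data with the assumed generative
structure — not that the real study's numbers are reproduced, which
would require the deposited genotypes.

## Experiment scales

The power/coverage experiments use one reference table per experiment
(2,000 simulations per model, 35 diploids, 11 loci) evaluated against
20 independent observed replicates; the end-to-end pipeline experiment
shares one table budget (2,000 simulations per model for the
single-population step, 1,000 for the divergence step, 400 for the
migration step; groups of 40/20/30 diploids) across 20 observed
replicates with memoized forests. Reference-table size is the dominant
power lever at this scale: divergence-topology discrimination roughly
stops improving only above 1,000 simulations per model, and
single-population bottleneck detection needs about 2,000. These are the package's desk-scale study conditions;
the replicate-to-replicate variation of the observed dataset, not of
the reference table, is the quantity the success counts measure.

The pipeline-recovery scenario is a strong founder event: topology M3
with `N_BYD = N_ANC = 25,000`, `N_V = 250` (a 100-fold reduction at
the V/B split 150 generations ago), `T_2 = 20,000`, mu = 5e-4,
P_GSM = 0.3. The scenario was chosen for identifiability: bottleneck
detection from single-sample SSR statistics is powered by the
M-ratio/diversity anomaly of *recent, sharp* reductions, while old or
low-diversity bottlenecks are near-indistinguishable from a small
constant population (the design measurements behind this are
summarized above in the estimator sections); reduction ratios of order
tens with `T/2N` around 0.3 give per-replicate detection above 95% at
this budget. The acceptance script runs the full pipeline once at 300
simulations per model on the study mimic; because the mimic's Volcano
bottleneck is mild and old (chosen for diversity realism), its
demography step is reported as computed and can legitimately prefer
the constant-size model at that budget.

## Known limitations

* The divergence/migration catalogue beyond topology M3 is a documented
  reconstruction (above).
* Rarefaction convention differences (GenAlEx vs FSTAT) can shift
  `A_R` by a few hundredths; comparisons to published tables should
  allow about +/-0.05.
* The posterior-probability regression forest inherits the classifier's
  out-of-bag noise at small table sizes; below ~300 simulations per
  model its estimates are coarse.
* The pruning cascade is a threshold formalization of a narrative rule;
  reports label it as such and log every decision.
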