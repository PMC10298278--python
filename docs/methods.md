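# Methods

## Scope and data model

The package analyses nuclear-family HLA genotype data at the five
classical loci, handled internally in the fixed order (A, C, B, DRB1,
DQB1); printed 5-locus haplotypes follow the reporting convention
A~B~C~DRB1~DQB1. Allele names are locus + `*` + colon-separated numeric
fields; one field denotes an allele lineage. Field strings keep leading
zeros and parse/render losslessly. Genotypes are unordered allele pairs
per locus (stored sorted, so equality and homozygosity are
order-independent); GL-string-style ambiguity encodings are out of
scope — one name per chromosome per locus.

## Segregation phasing

`phase_family` enumerates the 2^max(h−1,0) distinct haplotype splits of
each parent (h = heterozygous loci) and tests every joint configuration
against all children: a configuration is admissible when each child's
genotype is exactly one paternal haplotype unioned with one maternal
haplotype at every locus, with no recombination allowed. Status is

* `unique` when all admissible configurations agree on the *founder
  haplotype multiset* (child transmission labels may differ — counting
  depends only on founders);
* `ambiguous` when they disagree;
* `inconsistent` when none exists, including single-locus Mendelian
  errors (reported with the offending locus) and recombinant or mutant
  children. Such families are excluded, not repaired: silently dropping
  the offending child would bias direct counting.

Only `unique` families contribute founders (4 chromosomes each), so the
pooled 2n can fall below 4 × families when some families are ambiguous;
this mirrors a design that retains only families with four haplotypes
well-defined by segregation. Phasing runs at the input resolution;
lineage (one-field) reduction is applied after phasing. Loci with any
missing allele in a family member are dropped from that family's
phasing. Uniqueness is monotone: adding a child never turns a unique
family ambiguous (children only remove admissible configurations).

## Frequencies and their SDs

Frequencies are direct counts over pooled founder chromosomes. The
attached SD is sqrt(p(1−p)/(2n−1)). The small-sample (2n−1) denominator
was chosen because it reproduces every row of the packaged published
tables at the printed 4-decimal precision, whereas the plain binomial
/2n form misses 8 of 77 rows by one unit in the last digit; the two
differ by under 1.3e-4 everywhere at 2n = 400. Display thresholds
(e.g. "frequency ≥ 1%") are presentation filters only and never applied
before statistics.

## Hardy–Weinberg exact test

A Monte Carlo exact test in the Guo–Thompson spirit: the 2n observed
alleles are re-paired into n random genotypes per replicate, the
ordering statistic is the conditional probability of the genotype array
given the allele counts (computed in log space as
h·log 2 − Σ log n_ij!, terms constant under fixed allele counts
dropped), and p = (r + 1)/(R + 1) counting replicates with probability ≤
observed, observed table included. The test is deterministic given a
seed; a monomorphic locus returns p = 1 with a flag. Replicates are
floored at 1000; the default is 10,000.

## Ewens–Watterson neutrality test

The neutral null of homozygosity F = Σp² conditional on (n, k) is
parameter-free: a partition with size-multiplicities a_j has
probability ∝ n!/Π_j (j^a_j · a_j!). Sampling:

* n ≤ 20 — all partitions of n into k parts are enumerated and draws
  are exact categorical samples;
* n > 20 — Chinese-restaurant-process generation with rejection on the
  class count K = k. The CRP concentration θ solves E[K] = k
  (Watterson's moment choice); since the conditional law is θ-free this
  affects only acceptance efficiency (~10% in the regimes used here).
  The class-count indicator is vectorized, so rejected draws are cheap;
  class sizes are resolved only for accepted draws.

F_exp and sd(F) are the null sample's moments, F_nd the normalized
deviate, and the p-value the lower tail P(F_null ≤ F_obs) with the
(r + 1)/(R + 1) tie-inclusive convention — balancing selection pushes
homozygosity *down*, so small p means an allele-frequency profile more
even than neutrality predicts.

## Linkage disequilibrium

Per-haplotype D, D′ and χ² follow the classical normalization (Dmax
depends on the sign of D); D′ keeps its sign internally, and reports of
focal (positive-association) haplotypes print positive values. p-values
use the 1-df chi-square tail without continuity correction. The
locus-pair summary builds the joint table by direct counting, drops
zero-frequency alleles (they contribute nothing but break divisions),
and computes the weighted overall D′, Wn and both ALD directions; the
distinct-haplotype count is the number of nonzero cells. No
multiple-testing correction is applied by default, matching raw-p
reporting practice; a Bonferroni column is available behind a flag.

## Population comparison

Nei standard genetic distance unions allele universes per locus with
absent alleles at frequency zero and averages J-sums over loci. Zero
identity (no shared allele) raises an explicit infinite-distance error
rather than returning a number.

Neighbor joining follows Saitou–Nei with Q(i,j) = (r−2)d(i,j) − Σd(i,·)
− Σd(j,·). Determinism: Q-ties select the lexicographically smallest
cluster-label pair (a cluster is labelled by its smallest leaf).
Negative branch lengths are clamped to zero with the deficit moved to
the sister branch, preserving the joined pair's path length. The output
is unrooted (final trifurcation); Newick serialization stores bootstrap
supports as internal node labels and branch lengths at 6 decimals.

Bootstrap supports resample *chromosomes*: per replicate and population,
allele counts are drawn multinomial(2n, p) per locus, the SGD matrix and
NJ tree recomputed, and each original internal edge scored by the
percentage of replicates containing its bipartition. Each population's
random stream is keyed by its rank in sorted label order, so supports
are invariant to input order. Single-locus analyses cannot bootstrap
over loci, which is why the chromosome is the resampling unit — a
documented choice, not the only defensible one.

Correspondence analysis is the standard SVD of
(P − rcᵀ)/sqrt(rcᵀ) on the population-by-allele count table
(frequencies weighted by sample sizes); principal coordinates are
mass-scaled singular vectors times singular values, and axis inertias
sum to the table's total chi-square inertia. Because CA is defined on
frequency/contingency tables rather than distance matrices, ordination
of an SGD matrix is provided separately and explicitly labelled as
classical metric scaling (`classical_mds`).

## Synthetic cohorts

The generator emulates the family-study design: parents drawn
independently from a 5-locus haplotype pool (random mating, no
inbreeding), children per family uniform on 2–7, each child receiving
one gamete per parent. Gametes undergo independent per-interval
crossover (default rate 0, no interference) in the canonical locus
order; genotypes are then unphased and optionally masked at a missing
rate (default 0). Everything is reproducible from a single seed.

The default pool places the 25 published 5-locus haplotypes at their
printed frequencies (total mass 0.2925) and spreads the remaining
0.7075 over the independent product of the residual lineage marginals,
excluding cells that coincide with explicit haplotypes so their
frequencies stay exact (the filler renormalization perturbs marginals
by < 1e-3). Consequences worth knowing: the simulated cohort
marginalizes to the published lineage frequencies, but its *pairwise LD*
is much weaker than the published surface — only the explicit 29% of
pool mass carries association, the filler being independent by
construction. Passing tests on such cohorts therefore demonstrates
correct phasing, counting and calibration, not that the simulator
reproduces a real population's LD structure. Real-data features not
emulated: genotyping error, allele-call ambiguity, inbreeding and
assortative mating, recombination hot/cold spots, and family
ascertainment effects.

## Problem sizes and numerical choices

Default Monte Carlo sizes are 10,000 replicates for HWE and
Ewens–Watterson and 1000 bootstrap replicates for trees. The test suite
uses scaled-down sizes chosen to keep each property's Monte Carlo error
well inside its asserted band: 1000 random families for the phasing
oracle comparison, 200 random joint tables for LD oracle equivalence
(tolerance 1e-10), 250/200 simulated loci for the HWE/EWH calibration
checks, and additive-matrix NJ recovery up to 8 taxa. Floating-point
tie handling in Monte Carlo p-values uses an absolute 1e-9 (log-scale)
or 1e-12 (F-scale) tolerance when counting ties. Joint frequency tables
must sum to 1 within 1e-9; population frequency files are renormalized
with a warning when a locus group's sum is off by more than 1e-3.

## Known limitations

* Phasing is exhaustive over ≤ 16 × 16 joint configurations — exact and
  fast at 5 loci, but exponential in heterozygous loci if the locus set
  grows.
* The Ewens sampler's rejection rate degrades when k is far outside the
  range a CRP with any θ makes likely for the given n (irrelevant for
  the k ≤ 28, n = 400 regime here).
* Inter-population analyses operate on allele-frequency tables; the
  package ships only a small synthetic toy set, so comparisons against
  real reference populations require user-supplied tables in the long
  CSV format.
* The bootstrap's parametric multinomial resampling understates
  uncertainty if the original frequency estimates are themselves from
  small or related samples.
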