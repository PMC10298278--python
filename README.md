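# hlafam

Family-based HLA population genetics in Python: segregation (pedigree)
phasing of parental haplotypes, direct-count allele and haplotype
frequencies, Hardy–Weinberg and Ewens–Watterson tests, multiallelic and
asymmetric linkage disequilibrium, and inter-population comparison by Nei
distances, neighbor-joining dendrograms and correspondence analysis.

## Who this is for

Immunogenetics and anthropological-genetics groups who type nuclear
families at the classical HLA loci (*A*, *C*, *B*, *DRB1*, *DQB1*) and
want the full family-study analysis chain — from raw unphased genotypes
to phased founder haplotypes, frequency tables, neutrality tests, LD
surfaces and population trees — as one reproducible, seeded pipeline.
The package ships the published allele-lineage and haplotype frequency
tables of a 100-family Emirati cohort (2n = 400 founder chromosomes) as a
reference dataset, and a simulator that generates family cohorts with
known ground truth under the same sampling design.

## The statistics at the core

**Segregation phasing.** For each nuclear family, every joint parental
phase configuration is enumerated; a configuration is admissible when
each child's genotype is the locus-wise union of one paternal and one
maternal haplotype (no recombination). Families whose admissible
configurations all agree on the founder haplotype multiset are `unique`
and contribute four founder chromosomes to direct counting; the rest are
reported `ambiguous` or `inconsistent` and excluded.

**Frequencies.** Direct counts over founder chromosomes: p = count / 2n,
with SD = sqrt(p(1−p)/(2n−1)) — the convention the published tables
follow at the printed precision.

**Linkage disequilibrium.** Per haplotype (allele *i*, allele *j*):
D = h − pq, D′ = D/Dmax with Dmax = min(p(1−q), q(1−p)) for D ≥ 0, and
χ² = 2N·D²/(p(1−p)q(1−q)) with a 1-df tail. Per locus pair: the
frequency-weighted overall D′ = Σ pq·|D′|, the multiallelic
Wn = sqrt(ΣD²/(pq) / (k_min − 1)), and the asymmetric (conditional) LD
W_{A/B} = sqrt((F_{A/B} − F_A)/(1 − F_A)) with F_A = Σp² and
F_{A/B} = Σ h²/q, which detects one locus being determined by another
even when the reverse holds only weakly.

**Neutrality.** The Ewens–Watterson test compares F_obs = Σp² with its
neutral distribution conditional on (n, k) — a θ-free conditional of the
Ewens sampling formula, sampled exactly by partition enumeration for
small n and by a rejection-controlled Chinese-restaurant process
otherwise. F_nd = (F_obs − F_exp)/sd(F); the p-value is the lower tail.

**Population comparison.** Nei standard genetic distance D = −ln I,
I = J_xy / sqrt(J_x·J_y) averaged over loci; Saitou–Nei neighbor joining
with deterministic tie-breaks and multinomial (per-chromosome) bootstrap
supports; correspondence analysis as the SVD of standardized residuals
of the population-by-allele table.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a
simulated study-condition cohort (100 families, 2–7 children each,
parents drawn from a pool seeded with the published 5-locus haplotypes):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_phase_and_count.py
python analysis/03_hwe_and_neutrality.py --seed 1
python analysis/04_linkage_disequilibrium.py
python analysis/05_population_comparison.py --seed 1
```

At seed 1 this prints, among other things:

```
phased 100 families: 99 unique, 1 ambiguous, 0 inconsistent
founder chromosomes pooled: 396 (4 per unique family)
most frequent 5-locus haplotype: A*26~B*08~C*07~DRB1*03~DQB1*02 (0.0379 +/- 0.0096)
```

— the phaser keeps only families whose four founder haplotypes are fully
determined by segregation (99 of 100 here), and direct counting recovers
the pool's top haplotype (true frequency 0.0425) within one sampling SD.
Running the Ewens–Watterson test on the *published* frequency tables
(script 03) gives

```
    A: k=17  F_obs=0.106 F_exp=0.219 F_nd=-1.37 p=0.0056
    C: k=14  F_obs=0.122 F_exp=0.261 F_nd=-1.40 p=0.0048
    B: k=28  F_obs=0.092 F_exp=0.129 F_nd=-0.85 p=0.1520
 DRB1: k=13  F_obs=0.130 F_exp=0.277 F_nd=-1.38 p=0.0046
 DQB1: k= 5  F_obs=0.257 F_exp=0.566 F_nd=-1.65 p=0.0070
```

i.e. homozygosity below the neutral expectation at every locus (negative
F_nd, the balancing-selection signature), significant everywhere except
*HLA-B*. Script 04 re-derives the published two-locus D′/χ² surface from
the printed marginal and haplotype frequencies and reports
`11 published rows reproduced exactly`.

The same stages are available as a CLI (`hlafam simulate|phase|freq|
hwe|ld|ewh|dist|tree|ca|run`) and as library functions
(`hlafam.phase_cohort`, `hlafam.pairwise_ld`, `hlafam.ewh_test`, …).

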