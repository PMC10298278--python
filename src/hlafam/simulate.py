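"""Synthetic family cohorts with known ground truth.

The generator emulates the sampling design of a family-based HLA study:
nuclear families whose two parents are drawn independently from a 5-locus
haplotype pool (random mating), each child receiving one gamete per parent.
A gamete is a parental haplotype optionally subjected to crossover between
adjacent loci (independent per interval, no interference); genotypes are
then unphased and optionally masked.  Defaults mirror the study
conditions: 100 families, 2–7 children each (uniform), no recombination,
no missing data, and a pool seeded with the published 5-locus haplotypes
(0.2925 total mass) plus filler haplotypes spreading the remaining mass
over the independent product of the residual lineage marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import Family, FamilyCohort, Genotype, Individual, Role
from .frequencies import FrequencyTable
from .nomenclature import (
    CANONICAL_LOCUS_ORDER,
    AlleleName,
    Haplotype,
    Locus,
    parse_allele_name,
    parse_haplotype,
    sort_loci,
)


@dataclass
class HaplotypePool:
    """A discrete haplotype distribution over a fixed locus set.

    Stored columnar: ``codes[k, l]`` indexes into ``alleles[loci[l]]``;
    kept this way so pools built as products of marginals (hundreds of
    thousands of haplotypes) stay cheap.
    """

    loci: tuple[Locus, ...]
    alleles: dict[Locus, list[AlleleName]]
    codes: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if len(f) == 0:
            raise ValueError("empty haplotype pool")
        if (f < 0).any():
            raise ValueError("negative pool frequency")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"pool frequencies sum to {f.sum():.12f}, expected 1"
            )
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return len(self.frequencies)

    def haplotype(self, idx: int) -> Haplotype:
        return Haplotype(
            tuple(
                self.alleles[locus][self.codes[idx, l]]
                for l, locus in enumerate(self.loci)
            )
        )

    def marginal(self, locus: Locus) -> dict[str, float]:
        l = self.loci.index(locus)
        sums = np.bincount(
            self.codes[:, l],
            weights=self.frequencies,
            minlength=len(self.alleles[locus]),
        )
        return {
            str(a): float(sums[i])
            for i, a in enumerate(self.alleles[locus])
            if sums[i] > 0
        }

    def pairwise_d(self, locus_a: Locus, locus_b: Locus) -> np.ndarray:
        """Gametic disequilibria D_ij of the pool itself (truth LD)."""
        la, lb = self.loci.index(locus_a), self.loci.index(locus_b)
        ka = len(self.alleles[locus_a])
        kb = len(self.alleles[locus_b])
        joint = np.zeros((ka, kb))
        np.add.at(
            joint, (self.codes[:, la], self.codes[:, lb]), self.frequencies
        )
        p = joint.sum(axis=1)
        q = joint.sum(axis=0)
        return joint - np.outer(p, q)

    @classmethod
    def from_haplotypes(
        cls, haplotypes: Sequence[Haplotype], frequencies: Sequence[float]
    ) -> "HaplotypePool":
        if len(haplotypes) != len(frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        loci = haplotypes[0].loci
        alleles: dict[Locus, list[AlleleName]] = {l: [] for l in loci}
        index: dict[Locus, dict[AlleleName, int]] = {l: {} for l in loci}
        codes = np.zeros((len(haplotypes), len(loci)), dtype=np.int64)
        for i, hap in enumerate(haplotypes):
            if hap.loci != loci:
                raise ValueError("pool haplotypes cover different loci")
            for l, a in enumerate(hap.alleles):
                locus = loci[l]
                if a not in index[locus]:
                    index[locus][a] = len(alleles[locus])
                    alleles[locus].append(a)
                codes[i, l] = index[locus][a]
        return cls(
            loci=loci,
            alleles=alleles,
            codes=codes,
            frequencies=np.asarray(frequencies, dtype=float),
        )


def pool_from_frequency_tables(
    tables: Mapping[Locus, FrequencyTable],
    ld_mode: str = "independent",
    explicit: Optional[Sequence[tuple[Haplotype, float]]] = None,
) -> HaplotypePool:
    """Build a haplotype pool from per-locus marginal tables.

    ``ld_mode="independent"`` takes the product of the marginals (all
    pairwise D = 0).  ``ld_mode="table"`` places the ``explicit``
    haplotype list at its stated frequencies and spreads the remaining
    mass over the product of the residual marginals, so the pool
    marginalizes back to the input tables.
    """
    loci = sort_loci(tables.keys())
    names = {
        l: [parse_allele_name(a) for a in tables[l].table["allele"]]
        for l in loci
    }
    marginals = {
        l: tables[l].table["frequency"].to_numpy(dtype=float) for l in loci
    }
    for l in loci:
        total = marginals[l].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"marginals at {l.value} sum to {total}")

    def product_pool(per_locus: dict[Locus, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        sizes = [len(per_locus[l]) for l in loci]
        grids = np.meshgrid(
            *[np.arange(s) for s in sizes], indexing="ij"
        )
        codes = np.stack([g.reshape(-1) for g in grids], axis=1)
        freqs = np.ones(codes.shape[0])
        for l_idx, l in enumerate(loci):
            freqs *= per_locus[l][codes[:, l_idx]]
        return codes, freqs

    if ld_mode == "independent":
        if explicit is not None:
            raise ValueError("explicit haplotypes need ld_mode='table'")
        codes, freqs = product_pool(marginals)
        keep = freqs > 0
        return HaplotypePool(
            loci=loci,
            alleles=names,
            codes=codes[keep].astype(np.int64),
            frequencies=freqs[keep] / freqs[keep].sum(),
        )

    if ld_mode != "table":
        raise ValueError(f"unknown ld_mode {ld_mode!r}")
    if not explicit:
        raise ValueError("ld_mode='table' needs an explicit haplotype list")

    index = {
        l: {a: i for i, a in enumerate(names[l])} for l in loci
    }
    explicit_mass = sum(f for _, f in explicit)
    residual = {l: marginals[l].copy() for l in loci}
    exp_codes = np.zeros((len(explicit), len(loci)), dtype=np.int64)
    exp_freqs = np.zeros(len(explicit))
    for i, (hap, f) in enumerate(explicit):
        if sort_loci(hap.loci) != loci:
            raise ValueError(f"haplotype {hap} does not cover pool loci")
        for l_idx, l in enumerate(loci):
            a = hap.allele_at(l)
            if a not in index[l]:
                raise ValueError(f"allele {a} absent from marginal table")
            code = index[l][a]
            residual[l][code] -= f
            exp_codes[i, l_idx] = code
        exp_freqs[i] = f
    for l in loci:
        if (residual[l] < -1e-9).any():
            bad = names[l][int(np.argmin(residual[l]))]
            raise ValueError(
                f"explicit haplotype frequencies exceed the marginal of {bad}"
            )
        residual[l] = np.clip(residual[l], 0.0, None)

    filler_mass = 1.0 - explicit_mass
    if filler_mass > 1e-12:
        norm = {
            l: residual[l] / residual[l].sum() for l in loci
        }
        codes_f, freqs_f = product_pool(norm)
        keep = freqs_f > 0
        codes_f, freqs_f = codes_f[keep], freqs_f[keep]
        # drop product cells that coincide with explicit haplotypes so the
        # explicit frequencies stay exact; the filler renormalization
        # perturbs marginals only at the removed-cell scale
        sizes = np.array([len(names[l]) for l in loci])
        keys_f = np.ravel_multi_index(codes_f.T, sizes)
        keys_e = np.ravel_multi_index(exp_codes.T, sizes)
        keep = ~np.isin(keys_f, keys_e)
        codes_f, freqs_f = codes_f[keep], freqs_f[keep]
        codes = np.vstack([exp_codes, codes_f.astype(np.int64)])
        freqs = np.concatenate(
            [exp_freqs, filler_mass * freqs_f / freqs_f.sum()]
        )
    else:
        codes, freqs = exp_codes, exp_freqs
    return HaplotypePool(
        loci=loci,
        alleles=names,
        codes=codes,
        frequencies=freqs / freqs.sum(),
    )


def default_pool() -> HaplotypePool:
    """The study-condition pool: published 5-locus haplotypes at their
    printed frequencies, filler mass over the residual lineage marginals."""
    from .reference import (
        load_emirati_five_locus_haplotypes,
        load_emirati_lineage_frequencies,
    )

    tables = load_emirati_lineage_frequencies()
    hap_df = load_emirati_five_locus_haplotypes()
    explicit = [
        (parse_haplotype(row.haplotype), float(row.frequency))
        for row in hap_df.itertuples()
    ]
    return pool_from_frequency_tables(tables, ld_mode="table", explicit=explicit)


@dataclass
class SimulationSpec:
    """Study conditions for the cohort generator."""

    pool: HaplotypePool
    n_families: int = 100
    children_range: tuple[int, int] = (2, 7)
    recombination_rate: float = 0.0
    missing_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.children_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid children range")
        for rate in (self.recombination_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class FamilyTruth:
    founders: tuple[Haplotype, Haplotype, Haplotype, Haplotype]
    #: per child, the transmitted (possibly recombined) gametes
    child_gametes: tuple[tuple[Haplotype, Haplotype], ...]


@dataclass
class TruthSet:
    families: dict[str, FamilyTruth] = field(default_factory=dict)

    def founder_haplotypes(self) -> list[Haplotype]:
        out = []
        for truth in self.families.values():
            out.extend(truth.founders)
        return out

    def to_json(self, path) -> None:
        payload = {
            fam: {
                "founders": [str(h) for h in truth.founders],
                "children": [
                    [str(g[0]), str(g[1])] for g in truth.child_gametes
                ],
            }
            for fam, truth in self.families.items()
        }
        Path(path).write_text(
            json.dumps(payload, indent=1) + "\n", encoding="utf-8"
        )


def _gamete(
    hap_pair: tuple[Haplotype, Haplotype],
    rate: float,
    n_loci: int,
    rng: np.random.Generator,
) -> Haplotype:
    start = int(rng.integers(2))
    if rate > 0:
        crossovers = rng.random(n_loci - 1) < rate
        source = start ^ np.concatenate(
            [[0], np.cumsum(crossovers) % 2]
        ).astype(int)
    else:
        source = np.full(n_loci, start)
    alleles = tuple(
        hap_pair[source[l]].alleles[l] for l in range(n_loci)
    )
    return Haplotype(alleles)


def simulate_cohort(spec: SimulationSpec) -> tuple[FamilyCohort, TruthSet]:
    """Draw a family cohort from the pool; fully reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    pool = spec.pool
    loci = pool.loci
    n_loci = len(loci)
    lo, hi = spec.children_range
    families = []
    truth = TruthSet()
    for fam_idx in range(spec.n_families):
        fam_id = f"F{fam_idx + 1:04d}"
        draw = rng.choice(len(pool), size=4, p=pool.frequencies)
        f1, f2, m1, m2 = (pool.haplotype(int(i)) for i in draw)
        n_children = int(rng.integers(lo, hi + 1))
        gametes = []
        for _ in range(n_children):
            pat = _gamete((f1, f2), spec.recombination_rate, n_loci, rng)
            mat = _gamete((m1, m2), spec.recombination_rate, n_loci, rng)
            gametes.append((pat, mat))

        def genotype_of(h1: Haplotype, h2: Haplotype) -> Genotype:
            pairs = {}
            for l, locus in enumerate(loci):
                if spec.missing_rate > 0 and (
                    rng.random() < spec.missing_rate
                    or rng.random() < spec.missing_rate
                ):
                    pairs[locus] = None
                else:
                    pairs[locus] = (h1.alleles[l], h2.alleles[l])
            return Genotype(pairs)

        father = Individual(
            family_id=fam_id,
            individual_id="P1",
            father_id=None,
            mother_id=None,
            role=Role.FATHER,
            genotype=genotype_of(f1, f2),
        )
        mother = Individual(
            family_id=fam_id,
            individual_id="P2",
            father_id=None,
            mother_id=None,
            role=Role.MOTHER,
            genotype=genotype_of(m1, m2),
        )
        children = tuple(
            Individual(
                family_id=fam_id,
                individual_id=f"C{c + 1}",
                father_id="P1",
                mother_id="P2",
                role=Role.CHILD,
                genotype=genotype_of(pat, mat),
            )
            for c, (pat, mat) in enumerate(gametes)
        )
        families.append(
            Family(
                family_id=fam_id,
                father=father,
                mother=mother,
                children=children,
            )
        )
        truth.families[fam_id] = FamilyTruth(
            founders=(f1, f2, m1, m2), child_gametes=tuple(gametes)
        )
    return FamilyCohort(families), truth
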