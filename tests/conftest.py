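"""Shared fixtures: small allele universes, toy pools and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from hlafam import (
    CANONICAL_LOCUS_ORDER,
    FamilyCohort,
    Genotype,
    HaplotypePool,
    Haplotype,
    Individual,
    Locus,
    Role,
    parse_allele_name,
    parse_haplotype,
)
from hlafam.cohort import Family


def allele(text: str):
    return parse_allele_name(text)


def hap(text: str) -> Haplotype:
    return parse_haplotype(text)


def make_individual(fam, iid, role, genotype, father=None, mother=None):
    return Individual(
        family_id=fam,
        individual_id=iid,
        father_id=father,
        mother_id=mother,
        role=role,
        genotype=genotype,
    )


def make_family(fam_id, father_geno, mother_geno, child_genos):
    father = make_individual(fam_id, "P1", Role.FATHER, father_geno)
    mother = make_individual(fam_id, "P2", Role.MOTHER, mother_geno)
    children = tuple(
        make_individual(
            fam_id, f"C{i + 1}", Role.CHILD, g, father="P1", mother="P2"
        )
        for i, g in enumerate(child_genos)
    )
    return Family(
        family_id=fam_id, father=father, mother=mother, children=children
    )


def genotype_from_haps(h1: Haplotype, h2: Haplotype) -> Genotype:
    pairs = {}
    for a1, a2 in zip(h1.alleles, h2.alleles):
        pairs[a1.locus] = (a1, a2)
    return Genotype(pairs)


def random_pool(
    rng: np.random.Generator,
    n_haplotypes: int = 12,
    loci=CANONICAL_LOCUS_ORDER,
    alleles_per_locus: int = 4,
) -> HaplotypePool:
    """A small random pool (distinct haplotypes, Dirichlet frequencies)."""
    seen = set()
    haps = []
    while len(haps) < n_haplotypes:
        parts = tuple(
            f"{locus.value}*{rng.integers(1, alleles_per_locus + 1):02d}"
            for locus in loci
        )
        if parts in seen:
            continue
        seen.add(parts)
        haps.append(Haplotype(tuple(parse_allele_name(p) for p in parts)))
    freqs = rng.dirichlet(np.ones(n_haplotypes))
    return HaplotypePool.from_haplotypes(haps, freqs)


def random_family(
    rng: np.random.Generator, pool: HaplotypePool, n_children: int, fam_id
):
    idx = rng.choice(len(pool), size=4, p=pool.frequencies)
    f1, f2, m1, m2 = (pool.haplotype(int(i)) for i in idx)
    child_genos = []
    for _ in range(n_children):
        pat = (f1, f2)[int(rng.integers(2))]
        mat = (m1, m2)[int(rng.integers(2))]
        child_genos.append(genotype_from_haps(pat, mat))
    family = make_family(
        str(fam_id),
        genotype_from_haps(f1, f2),
        genotype_from_haps(m1, m2),
        child_genos,
    )
    return family, (f1, f2, m1, m2)


@pytest.fixture(scope="session")
def lineage_tables():
    from hlafam.reference import load_emirati_lineage_frequencies

    return load_emirati_lineage_frequencies()


@pytest.fixture(scope="session")
def lineage_long_table():
    from hlafam.reference import load_emirati_lineage_table

    return load_emirati_lineage_table()


@pytest.fixture(scope="session")
def two_locus_ld_table():
    from hlafam.reference import load_emirati_two_locus_ld

    return load_emirati_two_locus_ld()


@pytest.fixture(scope="session")
def five_locus_table():
    from hlafam.reference import load_emirati_five_locus_haplotypes

    return load_emirati_five_locus_haplotypes()


@pytest.fixture(scope="session")
def toy_populations():
    from hlafam.reference import load_toy_populations

    return load_toy_populations()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort at the pre-committed seed, phased once."""
    import hlafam as hf

    pool = hf.default_pool()
    cohort, truth = hf.simulate_cohort(
        hf.SimulationSpec(pool=pool, n_families=100, seed=0)
    )
    founders, report, phased = hf.phase_cohort(cohort)
    return {
        "pool": pool,
        "cohort": cohort,
        "truth": truth,
        "founders": founders,
        "report": report,
        "phased": phased,
    }
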