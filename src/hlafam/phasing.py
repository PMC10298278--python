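"""Haplotype assignment by segregation (pedigree) analysis.

For each nuclear family the two paternal and two maternal haplotypes are
deduced from the Mendelian transmission pattern in the children: every
joint parental phase configuration is enumerated, a configuration being
admissible when each child's genotype is exactly the locus-wise union of
one paternal and one maternal haplotype (no recombination).  A family is

* ``unique``       — all admissible configurations yield the same multiset
                     of four founder haplotypes (child transmission labels
                     may differ; frequencies depend only on founders);
* ``ambiguous``    — admissible configurations disagree on the founders;
* ``inconsistent`` — no admissible configuration (a Mendelian error or a
                     recombinant/mutant child).

Only ``unique`` families contribute founder chromosomes to downstream
counting, matching a design in which "only families with four haplotypes
well-defined by segregation" are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Optional, Sequence

from .cohort import Family, FamilyCohort, Genotype
from .nomenclature import AlleleName, Haplotype, Locus


class PhasingStatus(str, Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    INCONSISTENT = "inconsistent"


@dataclass
class PhasedFamily:
    family_id: str
    status: PhasingStatus
    loci: tuple[Locus, ...]
    father_haplotypes: Optional[tuple[Haplotype, Haplotype]] = None
    mother_haplotypes: Optional[tuple[Haplotype, Haplotype]] = None
    #: per child, (paternal haplotype index, maternal haplotype index)
    child_transmissions: Optional[tuple[tuple[int, int], ...]] = None
    #: locus at which a Mendelian error was detected, when inconsistent
    offending_locus: Optional[Locus] = None

    @property
    def founder_haplotypes(self) -> tuple[Haplotype, ...]:
        if self.status is not PhasingStatus.UNIQUE:
            raise ValueError("founders are defined only for unique families")
        assert self.father_haplotypes and self.mother_haplotypes
        return self.father_haplotypes + self.mother_haplotypes


@dataclass
class PhasingReport:
    n_unique: int = 0
    n_ambiguous: int = 0
    n_inconsistent: int = 0
    n_skipped: int = 0
    #: (family_id, reason) for every family not contributing founders
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return (
            self.n_unique
            + self.n_ambiguous
            + self.n_inconsistent
            + self.n_skipped
        )


def enumerate_parent_phases(
    genotype: Genotype, loci: Sequence[Locus]
) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct splits of a genotype into an unordered haplotype pair.

    With h heterozygous loci there are 2**max(h-1, 0) distinct pairs (the
    orientation of the first heterozygous locus is fixed to collapse the
    pair symmetry).
    """
    pairs = []
    for locus in loci:
        pair = genotype.pair_at(locus)
        if pair is None:
            raise ValueError(f"locus {locus} untyped; cannot enumerate phases")
        pairs.append(pair)
    het = [i for i, (a, b) in enumerate(pairs) if a != b]
    choices: list[list[tuple[AlleleName, AlleleName]]] = []
    first_het = het[0] if het else None
    for i, (a, b) in enumerate(pairs):
        if i not in het or i == first_het:
            choices.append([(a, b)])
        else:
            choices.append([(a, b), (b, a)])
    out = []
    for combo in product(*choices):
        hap1 = Haplotype(tuple(c[0] for c in combo))
        hap2 = Haplotype(tuple(c[1] for c in combo))
        out.append((hap1, hap2))
    return out


def _mendelian_check(
    family: Family, loci: Sequence[Locus]
) -> Optional[Locus]:
    """Return the first locus with a child allele absent from both parents'
    corresponding possibility, or None when transmissions are possible."""
    for locus in loci:
        f = set(family.father.genotype.pair_at(locus))
        m = set(family.mother.genotype.pair_at(locus))
        for child in family.children:
            c1, c2 = child.genotype.pair_at(locus)
            ok = (c1 in f and c2 in m) or (c2 in f and c1 in m)
            if not ok:
                return locus
    return None


def _child_keys(
    child_genotype: Genotype, loci: Sequence[Locus]
) -> tuple[tuple[AlleleName, AlleleName], ...]:
    return tuple(child_genotype.pair_at(l) for l in loci)  # already sorted


def _explains(
    fhap: Haplotype, mhap: Haplotype, child_key, loci: Sequence[Locus]
) -> bool:
    for idx, locus in enumerate(loci):
        a = fhap.alleles[idx]
        b = mhap.alleles[idx]
        pair = (a, b) if a.sort_key <= b.sort_key else (b, a)
        if pair != child_key[idx]:
            return False
    return True


def phase_family(
    family: Family, loci: Optional[Sequence[Locus]] = None
) -> PhasedFamily:
    """Phase one family by exhaustive segregation analysis.

    ``loci`` defaults to the loci typed in every family member.  Requires
    at least one child; single-child families are accepted but often come
    out ambiguous.
    """
    if loci is None:
        loci = family.fully_typed_loci()
    loci = tuple(loci)
    if not loci:
        raise ValueError(
            f"family {family.family_id}: no locus typed in all members"
        )
    if not family.children:
        raise ValueError(
            f"family {family.family_id}: segregation needs at least one child"
        )

    bad_locus = _mendelian_check(family, loci)
    if bad_locus is not None:
        return PhasedFamily(
            family_id=family.family_id,
            status=PhasingStatus.INCONSISTENT,
            loci=loci,
            offending_locus=bad_locus,
        )

    father_phases = enumerate_parent_phases(family.father.genotype, loci)
    mother_phases = enumerate_parent_phases(family.mother.genotype, loci)
    child_keys = [_child_keys(c.genotype, loci) for c in family.children]

    admissible: list[tuple[int, int, tuple[tuple[int, int], ...]]] = []
    founder_multisets = set()
    for fi, (f1, f2) in enumerate(father_phases):
        for mi, (m1, m2) in enumerate(mother_phases):
            transmissions: list[tuple[int, int]] = []
            ok = True
            for key in child_keys:
                hit = None
                for pi, fhap in enumerate((f1, f2)):
                    for qi, mhap in enumerate((m1, m2)):
                        if _explains(fhap, mhap, key, loci):
                            hit = (pi, qi)
                            break
                    if hit:
                        break
                if hit is None:
                    ok = False
                    break
                transmissions.append(hit)
            if ok:
                admissible.append((fi, mi, tuple(transmissions)))
                founders = tuple(
                    sorted(
                        (f1.alleles, f2.alleles, m1.alleles, m2.alleles),
                        key=lambda alleles: tuple(
                            a.sort_key for a in alleles
                        ),
                    )
                )
                founder_multisets.add(founders)

    if not admissible:
        # every per-locus transmission was possible in isolation, but no
        # joint phase explains all children: a recombinant or mutant child
        return PhasedFamily(
            family_id=family.family_id,
            status=PhasingStatus.INCONSISTENT,
            loci=loci,
        )
    status = (
        PhasingStatus.UNIQUE
        if len(founder_multisets) == 1
        else PhasingStatus.AMBIGUOUS
    )
    fi, mi, transmissions = admissible[0]
    return PhasedFamily(
        family_id=family.family_id,
        status=status,
        loci=loci,
        father_haplotypes=father_phases[fi],
        mother_haplotypes=mother_phases[mi],
        child_transmissions=transmissions,
    )


@dataclass(frozen=True)
class FounderHaplotype:
    """A founder haplotype with its family provenance."""

    family_id: str
    haplotype: Haplotype


def phase_cohort(
    cohort: FamilyCohort,
    loci: Optional[Sequence[Locus]] = None,
) -> tuple[list[FounderHaplotype], PhasingReport, list[PhasedFamily]]:
    """Phase every family; pool founder haplotypes from unique families.

    Returns the pooled founders (4 per unique family), a report itemizing
    exclusions, and the per-family phasing results.  Problems are reported,
    never raised.
    """
    report = PhasingReport()
    founders: list[FounderHaplotype] = []
    phased: list[PhasedFamily] = []
    for family in cohort:
        use_loci = tuple(loci) if loci else family.fully_typed_loci()
        if not use_loci or not family.children:
            reason = (
                "no children" if not family.children else "no fully typed locus"
            )
            report.n_skipped += 1
            report.excluded.append((family.family_id, reason))
            continue
        if loci:
            typed = set(family.fully_typed_loci())
            if not set(use_loci) <= typed:
                report.n_skipped += 1
                report.excluded.append(
                    (family.family_id, "requested locus untyped in a member")
                )
                continue
        result = phase_family(family, use_loci)
        phased.append(result)
        if result.status is PhasingStatus.UNIQUE:
            report.n_unique += 1
            for hap in result.founder_haplotypes:
                founders.append(
                    FounderHaplotype(
                        family_id=family.family_id, haplotype=hap
                    )
                )
        elif result.status is PhasingStatus.AMBIGUOUS:
            report.n_ambiguous += 1
            report.excluded.append((family.family_id, "ambiguous"))
        else:
            report.n_inconsistent += 1
            where = (
                f" (locus {result.offending_locus.value})"
                if result.offending_locus
                else ""
            )
            report.excluded.append(
                (family.family_id, f"inconsistent{where}")
            )
    return founders, report, phased
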