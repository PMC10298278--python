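"""Family cohort containers: genotypes, individuals, nuclear families."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional

from .nomenclature import (
    CANONICAL_LOCUS_ORDER,
    AlleleName,
    Locus,
    reduce_resolution,
)


class Role(str, Enum):
    FATHER = "father"
    MOTHER = "mother"
    CHILD = "child"


AllelePair = tuple[AlleleName, AlleleName]


@dataclass(frozen=True)
class Genotype:
    """Unphased multi-locus genotype: an unordered allele pair per locus.

    Pairs are stored sorted so equality and homozygosity checks are
    order-independent.  A locus may be missing (untyped), represented by
    ``None``.
    """

    pairs: Mapping[Locus, Optional[AllelePair]]

    def __post_init__(self) -> None:
        norm: dict[Locus, Optional[AllelePair]] = {}
        for locus in CANONICAL_LOCUS_ORDER:
            pair = self.pairs.get(locus)
            if pair is None:
                norm[locus] = None
                continue
            a, b = pair
            if a.locus != locus or b.locus != locus:
                raise ValueError(
                    f"allele pair ({a}, {b}) does not match locus {locus}"
                )
            norm[locus] = (a, b) if a.sort_key <= b.sort_key else (b, a)
        object.__setattr__(self, "pairs", norm)

    def pair_at(self, locus: Locus) -> Optional[AllelePair]:
        return self.pairs.get(locus)

    @property
    def typed_loci(self) -> tuple[Locus, ...]:
        return tuple(
            l for l in CANONICAL_LOCUS_ORDER if self.pairs.get(l) is not None
        )

    def is_homozygous(self, locus: Locus, n_fields: Optional[int] = None) -> bool:
        """Homozygosity at ``locus``, optionally after reduction to
        ``n_fields`` fields (lineage level with ``n_fields=1``)."""
        pair = self.pairs.get(locus)
        if pair is None:
            raise KeyError(f"locus {locus} untyped")
        a, b = pair
        if n_fields is not None:
            a = reduce_resolution(a, n_fields)
            b = reduce_resolution(b, n_fields)
        return a == b


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    role: Role
    genotype: Genotype


@dataclass(frozen=True)
class Family:
    """A nuclear family: two parents and their children."""

    family_id: str
    father: Individual
    mother: Individual
    children: tuple[Individual, ...]

    def __post_init__(self) -> None:
        for child in self.children:
            if child.father_id != self.father.individual_id:
                raise ValueError(
                    f"child {child.individual_id} does not reference father "
                    f"{self.father.individual_id}"
                )
            if child.mother_id != self.mother.individual_id:
                raise ValueError(
                    f"child {child.individual_id} does not reference mother "
                    f"{self.mother.individual_id}"
                )

    @property
    def members(self) -> tuple[Individual, ...]:
        return (self.father, self.mother) + self.children

    def fully_typed_loci(self) -> tuple[Locus, ...]:
        """Loci typed in every family member (the loci usable for phasing)."""
        loci = [
            l
            for l in CANONICAL_LOCUS_ORDER
            if all(m.genotype.pair_at(l) is not None for m in self.members)
        ]
        return tuple(loci)


@dataclass
class FamilyCohort:
    """A collection of nuclear families with unique family ids."""

    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family ids in cohort")
        for fam in self.families:
            mids = [m.individual_id for m in fam.members]
            if len(set(mids)) != len(mids):
                raise ValueError(
                    f"duplicate individual ids within family {fam.family_id}"
                )

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[Family]:
        return iter(self.families)

    @property
    def n_parents(self) -> int:
        return 2 * len(self.families)

    def parents(self) -> Iterator[Individual]:
        for fam in self.families:
            yield fam.father
            yield fam.mother
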