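"""HLA allele nomenclature: loci, allele names and multi-locus haplotypes.

An HLA allele name is a locus symbol, an asterisk, and one to four
colon-separated numeric fields, e.g. ``A*26:01:01``.  The first field alone
denotes an allele *lineage* (``A*26``).  Field strings keep their leading
zeros, so names round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence


class Locus(str, Enum):
    """The five classical HLA loci handled by this package."""

    A = "A"
    C = "C"
    B = "B"
    DRB1 = "DRB1"
    DQB1 = "DQB1"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Locus order used internally everywhere (class I by chromosomal position
#: convention A, C, B, then class II DRB1, DQB1).
CANONICAL_LOCUS_ORDER: tuple[Locus, ...] = (
    Locus.A,
    Locus.C,
    Locus.B,
    Locus.DRB1,
    Locus.DQB1,
)

#: Order conventionally used when *printing* 5-locus haplotypes
#: (A~B~C~DRB1~DQB1).
REPORT_LOCUS_ORDER: tuple[Locus, ...] = (
    Locus.A,
    Locus.B,
    Locus.C,
    Locus.DRB1,
    Locus.DQB1,
)

_LOCUS_INDEX = {locus: i for i, locus in enumerate(CANONICAL_LOCUS_ORDER)}

_NAME_RE = re.compile(r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>.*)$")


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be parsed."""


@dataclass(frozen=True, order=False)
class AlleleName:
    """A parsed HLA allele name.

    Parameters
    ----------
    locus:
        The locus the allele belongs to.
    fields:
        One to four numeric field strings; leading zeros are significant
        and preserved (``("02",)`` renders as ``*02``).
    """

    locus: Locus
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("allele name needs at least one field")
        for f in self.fields:
            if not f or not f.isdigit():
                raise AlleleParseError(f"non-numeric allele field {f!r}")

    def __str__(self) -> str:
        return f"{self.locus.value}*{':'.join(self.fields)}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AlleleName({str(self)!r})"

    @property
    def sort_key(self) -> tuple:
        return (_LOCUS_INDEX[self.locus], tuple(int(f) for f in self.fields))

    def __lt__(self, other: "AlleleName") -> bool:
        return self.sort_key < other.sort_key

    def reduce(self, n_fields: int) -> "AlleleName":
        return reduce_resolution(self, n_fields)


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``"A*26:01:01"`` into an :class:`AlleleName`.

    Raises
    ------
    AlleleParseError
        If the locus token is unknown or any field is empty/non-numeric;
        the message names the offending token.
    """
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele name {text!r}")
    locus_token = m.group("locus")
    try:
        locus = Locus(locus_token)
    except ValueError:
        raise AlleleParseError(
            f"unknown locus token {locus_token!r} in {text!r}"
        ) from None
    raw_fields = m.group("fields")
    if raw_fields == "":
        raise AlleleParseError(f"empty field list in {text!r}")
    fields = raw_fields.split(":")
    for f in fields:
        if not f or not f.isdigit():
            raise AlleleParseError(f"non-numeric field {f!r} in {text!r}")
    return AlleleName(locus=locus, fields=tuple(fields))


def reduce_resolution(allele: AlleleName, n_fields: int) -> AlleleName:
    """Truncate an allele name to its first ``n_fields`` fields.

    ``n_fields=1`` maps an allele to its lineage (``A*26:01:01`` ->
    ``A*26``).  Idempotent; keeps every field when fewer are available.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if len(allele.fields) <= n_fields:
        return allele
    return AlleleName(locus=allele.locus, fields=allele.fields[:n_fields])


def sort_loci(loci: Iterable[Locus]) -> tuple[Locus, ...]:
    """Return loci sorted into the canonical (A, C, B, DRB1, DQB1) order."""
    return tuple(sorted(set(loci), key=_LOCUS_INDEX.__getitem__))


@dataclass(frozen=True)
class Haplotype:
    """An ordered combination of alleles, one per locus, on one chromosome.

    Alleles are stored in canonical locus order over the covered subset;
    the string form joins alleles with ``~``.
    """

    alleles: tuple[AlleleName, ...]

    def __post_init__(self) -> None:
        loci = [a.locus for a in self.alleles]
        if len(set(loci)) != len(loci):
            raise ValueError("haplotype repeats a locus")
        ordered = sorted(self.alleles, key=lambda a: _LOCUS_INDEX[a.locus])
        if tuple(ordered) != self.alleles:
            object.__setattr__(self, "alleles", tuple(ordered))

    @property
    def loci(self) -> tuple[Locus, ...]:
        return tuple(a.locus for a in self.alleles)

    def __str__(self) -> str:
        return "~".join(str(a) for a in self.alleles)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Haplotype({str(self)!r})"

    def allele_at(self, locus: Locus) -> AlleleName:
        for a in self.alleles:
            if a.locus == locus:
                return a
        raise KeyError(f"haplotype does not cover locus {locus}")

    def covers(self, loci: Iterable[Locus]) -> bool:
        own = set(self.loci)
        return all(l in own for l in loci)

    def subset(self, loci: Sequence[Locus]) -> "Haplotype":
        return Haplotype(tuple(self.allele_at(l) for l in sort_loci(loci)))

    def reduce(self, n_fields: int) -> "Haplotype":
        return Haplotype(tuple(a.reduce(n_fields) for a in self.alleles))

    def render(self, order: Sequence[Locus] = REPORT_LOCUS_ORDER) -> str:
        """Render with an explicit locus order (default the A~B~C~DRB1~DQB1
        convention used for printed 5-locus tables)."""
        own = {a.locus: a for a in self.alleles}
        chosen = [own[l] for l in order if l in own]
        if len(chosen) != len(self.alleles):
            missing = [l for l in own if l not in set(order)]
            raise ValueError(f"render order omits loci {missing}")
        return "~".join(str(a) for a in chosen)


def parse_haplotype(text: str) -> Haplotype:
    """Parse a ``~``-joined haplotype string such as ``A*26~B*08``."""
    parts = [p for p in text.strip().split("~") if p]
    if not parts:
        raise AlleleParseError("empty haplotype string")
    return Haplotype(tuple(parse_allele_name(p) for p in parts))
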