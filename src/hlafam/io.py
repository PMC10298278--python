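"""Readers and writers for every file format the pipeline touches.

Formats
-------
* Family genotype TSV (PED-like): header ``family_id individual_id father_id
  mother_id role`` then two columns per locus (``A_1 A_2 C_1 C_2 B_1 B_2
  DRB1_1 DRB1_2 DQB1_1 DQB1_2``); missing alleles are ``"."``.
* Population allele-frequency CSV (long format): columns
  ``population,locus,allele,frequency,two_n`` (extra columns such as ``sd``
  are preserved on read where present but not required).
* Haplotype frequency CSV: columns ``haplotype,count,frequency,sd``.
* PHYLIP square distance matrices.

All writers emit UTF-8 with LF line endings and 4-decimal frequencies.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Family, FamilyCohort, Genotype, Individual, Role
from .nomenclature import (
    CANONICAL_LOCUS_ORDER,
    AlleleParseError,
    Locus,
    parse_allele_name,
)

PathLike = Union[str, Path]

MISSING = "."

_META_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "role"]
_LOCUS_COLUMNS = [
    f"{locus.value}_{i}" for locus in CANONICAL_LOCUS_ORDER for i in (1, 2)
]
FAMILY_FILE_COLUMNS = _META_COLUMNS + _LOCUS_COLUMNS


class FamilyFileError(ValueError):
    """Malformed family genotype file; message carries the line number."""


class FrequencyFileError(ValueError):
    """Malformed population frequency file."""


# ---------------------------------------------------------------------------
# family genotype TSV
# ---------------------------------------------------------------------------


def _parse_cell(cell: str, locus: Locus, lineno: int):
    if cell == MISSING:
        return None
    try:
        allele = parse_allele_name(cell)
    except AlleleParseError as exc:
        raise FamilyFileError(f"line {lineno}: {exc}") from exc
    if allele.locus != locus:
        raise FamilyFileError(
            f"line {lineno}: allele {allele} in a {locus.value} column"
        )
    return allele


def read_family_genotypes(path: PathLike) -> FamilyCohort:
    """Read a PED-like tab-separated family genotype file.

    Validates the header, per-column locus membership, and parentage
    references; errors carry the offending line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FamilyFileError("line 1: empty file (missing header)")
    header = lines[0].split("\t")
    if header != FAMILY_FILE_COLUMNS:
        raise FamilyFileError(
            f"line 1: bad header; expected columns {FAMILY_FILE_COLUMNS}"
        )

    rows: dict[str, dict[str, Individual]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(FAMILY_FILE_COLUMNS):
            raise FamilyFileError(
                f"line {lineno}: expected {len(FAMILY_FILE_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        fam_id, ind_id, father_id, mother_id, role_txt = cells[:5]
        try:
            role = Role(role_txt)
        except ValueError:
            raise FamilyFileError(
                f"line {lineno}: unknown role {role_txt!r}"
            ) from None
        pairs = {}
        for k, locus in enumerate(CANONICAL_LOCUS_ORDER):
            a = _parse_cell(cells[5 + 2 * k], locus, lineno)
            b = _parse_cell(cells[6 + 2 * k], locus, lineno)
            if (a is None) != (b is None):
                raise FamilyFileError(
                    f"line {lineno}: half-missing genotype at locus "
                    f"{locus.value}"
                )
            pairs[locus] = None if a is None else (a, b)
        ind = Individual(
            family_id=fam_id,
            individual_id=ind_id,
            father_id=None if father_id == MISSING else father_id,
            mother_id=None if mother_id == MISSING else mother_id,
            role=role,
            genotype=Genotype(pairs),
        )
        if fam_id not in rows:
            rows[fam_id] = {}
            order.append(fam_id)
        if ind_id in rows[fam_id]:
            raise FamilyFileError(
                f"line {lineno}: duplicate individual {ind_id!r} in family "
                f"{fam_id!r}"
            )
        rows[fam_id][ind_id] = ind

    families = []
    for fam_id in order:
        members = rows[fam_id]
        fathers = [m for m in members.values() if m.role is Role.FATHER]
        mothers = [m for m in members.values() if m.role is Role.MOTHER]
        children = [m for m in members.values() if m.role is Role.CHILD]
        if len(fathers) != 1 or len(mothers) != 1:
            raise FamilyFileError(
                f"family {fam_id!r}: needs exactly one father and one mother"
            )
        for child in children:
            if (
                child.father_id not in members
                or child.mother_id not in members
            ):
                raise FamilyFileError(
                    f"family {fam_id!r}: child {child.individual_id!r} "
                    "references a parent not present in the family"
                )
        families.append(
            Family(
                family_id=fam_id,
                father=fathers[0],
                mother=mothers[0],
                children=tuple(children),
            )
        )
    return FamilyCohort(families)


def write_family_genotypes(cohort: FamilyCohort, path: PathLike) -> None:
    path = Path(path)
    lines = ["\t".join(FAMILY_FILE_COLUMNS)]
    for fam in cohort:
        for ind in fam.members:
            cells = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or MISSING,
                ind.mother_id or MISSING,
                ind.role.value,
            ]
            for locus in CANONICAL_LOCUS_ORDER:
                pair = ind.genotype.pair_at(locus)
                if pair is None:
                    cells += [MISSING, MISSING]
                else:
                    cells += [str(pair[0]), str(pair[1])]
            lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# population allele-frequency CSV (long format)
# ---------------------------------------------------------------------------


def read_population_frequencies(
    path: PathLike,
) -> dict[str, dict[Locus, "FrequencyTable"]]:
    """Read a long-format frequency CSV into per-population tables.

    Each (population, locus) group must sum to 1 within 1e-3; groups
    farther off are renormalized with a warning.  Negative frequencies and
    duplicate (population, locus, allele) keys are errors.
    """
    from .frequencies import FrequencyTable  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, dtype={"allele": str, "population": str})
    if df.empty:
        return {}
    required = {"population", "locus", "allele", "frequency", "two_n"}
    missing = required - set(df.columns)
    if missing:
        raise FrequencyFileError(f"missing columns {sorted(missing)}")
    if (df["frequency"] < 0).any():
        bad = df[df["frequency"] < 0].iloc[0]
        raise FrequencyFileError(
            f"negative frequency for {bad['population']}/{bad['allele']}"
        )
    dup = df.duplicated(subset=["population", "locus", "allele"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise FrequencyFileError(
            "duplicate key "
            f"({bad['population']}, {bad['locus']}, {bad['allele']})"
        )

    out: dict[str, dict[Locus, FrequencyTable]] = {}
    for (pop, locus_txt), grp in df.groupby(
        ["population", "locus"], sort=False
    ):
        locus = Locus(locus_txt)
        freqs = grp["frequency"].to_numpy(dtype=float)
        total = freqs.sum()
        if abs(total - 1.0) > 1e-3:
            warnings.warn(
                f"frequencies for {pop}/{locus.value} sum to {total:.4f}; "
                "renormalizing",
                stacklevel=2,
            )
            freqs = freqs / total
        two_n = int(grp["two_n"].iloc[0])
        alleles = [parse_allele_name(a) for a in grp["allele"]]
        for a in alleles:
            if a.locus != locus:
                raise FrequencyFileError(
                    f"allele {a} listed under locus {locus.value}"
                )
        counts = np.rint(freqs * two_n).astype(int)
        table = FrequencyTable.from_frequencies(
            locus=locus,
            alleles=alleles,
            frequencies=freqs,
            two_n=two_n,
            counts=counts,
        )
        out.setdefault(pop, {})[locus] = table
    return out


def write_population_frequencies(
    populations: Mapping[str, Mapping[Locus, "FrequencyTable"]],
    path: PathLike,
) -> None:
    """Write per-population frequency tables in the canonical long format."""
    path = Path(path)
    lines = ["population,locus,allele,frequency,two_n"]
    for pop in populations:
        tables = populations[pop]
        for locus in CANONICAL_LOCUS_ORDER:
            if locus not in tables:
                continue
            t = tables[locus]
            for row in t.table.itertuples():
                lines.append(
                    f"{pop},{locus.value},{row.allele},"
                    f"{row.frequency:.4f},{t.two_n}"
                )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# haplotype frequency CSV
# ---------------------------------------------------------------------------


def write_haplotype_table(table, path: PathLike) -> None:
    """Write a :class:`~hlafam.frequencies.HaplotypeFrequencyTable` as CSV."""
    path = Path(path)
    lines = ["haplotype,count,frequency,sd"]
    for row in table.table.itertuples():
        lines.append(
            f"{row.haplotype},{row.count},{row.frequency:.4f},{row.sd:.4f}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------


def write_phylip(labels: Sequence[str], matrix: np.ndarray, path: PathLike,
                 precision: int = 6) -> None:
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match label count")
    lines = [str(n)]
    for i, label in enumerate(labels):
        vals = " ".join(f"{matrix[i, j]:.{precision}f}" for j in range(n))
        lines.append(f"{label}  {vals}")
    Path(path).write_text(
        "\n".join(lines) + "\n", encoding="utf-8", newline="\n"
    )


def read_phylip(path: PathLike) -> tuple[list[str], np.ndarray]:
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    n = int(lines[0].strip())
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return labels, np.asarray(rows, dtype=float)
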