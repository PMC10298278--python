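"""Direct-count allele/haplotype frequencies and Hardy–Weinberg testing.

Frequencies are estimated by direct counting over founder (parental)
chromosomes — 2 chromosomes per parent, so a cohort of 100 fully phased
families yields 2n = 400.  The standard deviation attached to every
frequency is the binomial form with the small-sample denominator,
``sqrt(p(1-p)/(2n-1))`` — the convention the published frequency tables
follow (verified at 4 decimals over every printed row).

The Hardy–Weinberg test is a Monte Carlo exact test in the spirit of the
Guo–Thompson permutation approach: the 2n observed alleles are repeatedly
shuffled into n genotype pairs, and the p-value is the proportion of
shuffles whose conditional probability given the allele counts is at most
that of the observed genotype array (the observed table counts in both
numerator and denominator).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import AllelePair, FamilyCohort
from .nomenclature import AlleleName, Haplotype, Locus, sort_loci


def binomial_sd(p: np.ndarray, two_n: int) -> np.ndarray:
    """SD of a direct-count frequency, ``sqrt(p(1-p)/(2n-1))``."""
    denom = max(two_n - 1, 1)
    return np.sqrt(np.asarray(p) * (1.0 - np.asarray(p)) / denom)


@dataclass
class FrequencyTable:
    """Per-locus allele counts, frequencies and binomial SDs.

    ``table`` columns: ``allele`` (string), ``count``, ``frequency``,
    ``sd``; rows sorted by descending frequency then allele name.
    """

    locus: Locus
    two_n: int
    table: pd.DataFrame

    @classmethod
    def from_counts(
        cls, locus: Locus, counts: Counter, two_n: Optional[int] = None
    ) -> "FrequencyTable":
        if not counts:
            raise ValueError(f"no alleles observed at locus {locus}")
        if two_n is None:
            two_n = sum(counts.values())
        alleles = sorted(counts, key=lambda a: a.sort_key)
        n = np.array([counts[a] for a in alleles], dtype=int)
        p = n / two_n
        df = pd.DataFrame(
            {
                "allele": [str(a) for a in alleles],
                "count": n,
                "frequency": p,
                "sd": binomial_sd(p, two_n),
            }
        )
        df = df.sort_values(
            ["frequency", "allele"], ascending=[False, True]
        ).reset_index(drop=True)
        return cls(locus=locus, two_n=two_n, table=df)

    @classmethod
    def from_frequencies(
        cls,
        locus: Locus,
        alleles: Sequence[AlleleName],
        frequencies: np.ndarray,
        two_n: int,
        counts: Optional[np.ndarray] = None,
    ) -> "FrequencyTable":
        p = np.asarray(frequencies, dtype=float)
        if counts is None:
            counts = np.rint(p * two_n).astype(int)
        df = pd.DataFrame(
            {
                "allele": [str(a) for a in alleles],
                "count": counts,
                "frequency": p,
                "sd": binomial_sd(p, two_n),
            }
        )
        df = df.sort_values(
            ["frequency", "allele"], ascending=[False, True]
        ).reset_index(drop=True)
        return cls(locus=locus, two_n=two_n, table=df)

    @property
    def k(self) -> int:
        """Number of distinct alleles."""
        return len(self.table)

    def frequency_of(self, allele: str) -> float:
        hit = self.table[self.table["allele"] == allele]
        if hit.empty:
            raise KeyError(f"allele {allele} not in table")
        return float(hit["frequency"].iloc[0])

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.table["frequency"].to_numpy(),
            index=self.table["allele"].to_numpy(),
            name=self.locus.value,
        )


@dataclass
class HaplotypeFrequencyTable:
    """Direct-count frequencies of multi-locus haplotypes.

    ``table`` columns: ``haplotype``, ``count``, ``frequency``, ``sd``.
    """

    loci: tuple[Locus, ...]
    two_n: int
    table: pd.DataFrame


def count_allele_frequencies(
    haplotypes: Iterable[Haplotype],
    locus: Locus,
    n_fields: Optional[int] = None,
) -> FrequencyTable:
    """Direct-count allele frequencies at one locus over founder chromosomes.

    Haplotypes not covering the locus are ignored; ``n_fields`` optionally
    reduces names (1 = lineage level) before counting.
    """
    counts: Counter = Counter()
    for hap in haplotypes:
        if not hap.covers([locus]):
            continue
        a = hap.allele_at(locus)
        if n_fields is not None:
            a = a.reduce(n_fields)
        counts[a] += 1
    if not counts:
        raise ValueError(f"no haplotypes cover locus {locus}")
    return FrequencyTable.from_counts(locus, counts)


def count_haplotype_frequencies(
    haplotypes: Iterable[Haplotype],
    loci: Sequence[Locus],
    n_fields: Optional[int] = None,
    min_frequency: Optional[float] = None,
    render_order: Optional[Sequence[Locus]] = None,
) -> HaplotypeFrequencyTable:
    """Direct-count frequencies of haplotypes over a locus subset.

    ``min_frequency`` is a display filter only — apply it when printing,
    never before downstream statistics.
    """
    loci = sort_loci(loci)
    counts: Counter = Counter()
    for hap in haplotypes:
        if not hap.covers(loci):
            continue
        sub = hap.subset(loci)
        if n_fields is not None:
            sub = sub.reduce(n_fields)
        counts[sub] += 1
    if not counts:
        raise ValueError(f"no haplotypes cover loci {[str(l) for l in loci]}")
    two_n = sum(counts.values())
    haps = sorted(counts, key=lambda h: tuple(a.sort_key for a in h.alleles))
    n = np.array([counts[h] for h in haps], dtype=int)
    p = n / two_n
    label_order = tuple(render_order) if render_order else None
    df = pd.DataFrame(
        {
            "haplotype": [
                h.render(label_order) if label_order else str(h) for h in haps
            ],
            "count": n,
            "frequency": p,
            "sd": binomial_sd(p, two_n),
        }
    )
    df = df.sort_values(
        ["frequency", "haplotype"], ascending=[False, True]
    ).reset_index(drop=True)
    if min_frequency is not None:
        df = df[df["frequency"] >= min_frequency].reset_index(drop=True)
    return HaplotypeFrequencyTable(loci=loci, two_n=two_n, table=df)


# ---------------------------------------------------------------------------
# Hardy–Weinberg Monte Carlo exact test
# ---------------------------------------------------------------------------


@dataclass
class HWEResult:
    locus: Optional[Locus]
    statistic: str
    p_value: float
    replicates: int
    seed: Optional[int]
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _log_conditional_probability(
    genotype_counts: np.ndarray, n_het: int
) -> float:
    """Log of P(genotype array | allele counts), up to terms constant in
    the genotype configuration: -sum(log n_ij!) + n_het * log 2."""
    return float(n_het * np.log(2.0) - gammaln(genotype_counts + 1.0).sum())


def hwe_exact_test(
    genotypes: Sequence[AllelePair],
    replicates: int = 10_000,
    seed: Optional[int] = None,
    locus: Optional[Locus] = None,
) -> HWEResult:
    """Monte Carlo exact test of Hardy–Weinberg proportions at one locus.

    Parameters
    ----------
    genotypes:
        Unordered allele pairs, one per individual (n >= 2).
    replicates:
        Number of random re-pairings of the 2n alleles (>= 1000).
    seed:
        Seed for the permutation stream; required for reproducibility.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 individuals")
    if replicates < 1000:
        raise ValueError("replicates must be >= 1000")

    labels = sorted({str(a) for pair in genotypes for a in pair})
    k = len(labels)
    if locus is None:
        first = genotypes[0][0]
        locus = first.locus if isinstance(first, AlleleName) else None
    if k == 1:
        return HWEResult(
            locus=locus,
            statistic="conditional probability (monomorphic)",
            p_value=1.0,
            replicates=replicates,
            seed=seed,
            monomorphic=True,
        )
    code = {lab: i for i, lab in enumerate(labels)}
    pairs = np.array(
        [sorted((code[str(a)], code[str(b)])) for a, b in genotypes],
        dtype=np.int64,
    )
    n = len(pairs)
    alleles = pairs.reshape(-1)

    cell = pairs[:, 0] * k + pairs[:, 1]
    obs_counts = np.bincount(cell, minlength=k * k)
    obs_het = int((pairs[:, 0] != pairs[:, 1]).sum())
    obs_logp = _log_conditional_probability(obs_counts, obs_het)

    rng = np.random.default_rng(seed)
    tiled = np.tile(alleles, (replicates, 1))
    perm = rng.permuted(tiled, axis=1)
    a = perm[:, 0::2]
    b = perm[:, 1::2]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    cells = lo * k + hi
    offset = (np.arange(replicates, dtype=np.int64) * (k * k))[:, None]
    flat = (cells + offset).reshape(-1)
    counts = np.bincount(flat, minlength=replicates * k * k).reshape(
        replicates, k * k
    )
    het = (lo != hi).sum(axis=1)
    logp = het * np.log(2.0) - gammaln(counts + 1.0).sum(axis=1)

    r = int((logp <= obs_logp + 1e-9).sum())
    p_value = (r + 1) / (replicates + 1)
    return HWEResult(
        locus=locus,
        statistic=(
            "Monte Carlo exact test; conditional probability of the "
            "genotype array given allele counts"
        ),
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )


def founder_genotypes_at_locus(
    cohort: FamilyCohort,
    locus: Locus,
    n_fields: Optional[int] = None,
) -> list[AllelePair]:
    """Parental genotype pairs at a locus (the HWE sampling unit)."""
    out: list[AllelePair] = []
    for parent in cohort.parents():
        pair = parent.genotype.pair_at(locus)
        if pair is None:
            continue
        a, b = pair
        if n_fields is not None:
            a, b = a.reduce(n_fields), b.reduce(n_fields)
        out.append((a, b))
    return out
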