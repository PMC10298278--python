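"""Two-locus linkage disequilibrium for multiallelic HLA data.

Per haplotype (allele i at locus a, allele j at locus b):

* ``D_ij  = h_ij - p_i q_j``
* ``D'_ij = D_ij / Dmax`` with ``Dmax = min(p(1-q), q(1-p))`` for positive
  D and ``min(pq, (1-p)(1-q))`` for negative D (signed internally).
* ``chi2_ij = 2N * D_ij**2 / (p(1-p) q(1-q))`` with a 1-df chi-square tail
  and no continuity correction.

Across a full joint table:

* overall D' = sum_ij p_i q_j |D'_ij| (frequency-weighted mean absolute
  normalized disequilibrium);
* ``Wn = sqrt( [sum_ij D_ij^2/(p_i q_j)] / (min(ka,kb)-1) )``, the
  multiallelic Cramer's-V analogue;
* asymmetric LD (ALD): ``W_{a/b} = sqrt((F_{a/b} - F_a)/(1 - F_a))`` with
  ``F_a = sum_i p_i^2`` and ``F_{a/b} = sum_ij h_ij^2 / q_j`` — the
  normalized gain in locus-a homozygosity when conditioning on locus-b
  alleles.  ``W_{a/b} = 1`` when locus a is completely determined by
  locus b, even when the reverse direction is weaker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .frequencies import binomial_sd
from .nomenclature import Haplotype, Locus


@dataclass
class HaplotypePairLD:
    allele_a: str
    allele_b: str
    frequency: float
    sd: float
    D: float
    dprime: float
    chi2: float
    p_value: float


@dataclass
class LDSummary:
    locus_a: Locus
    locus_b: Locus
    overall_dprime: float
    wn: float
    w_a_given_b: float
    w_b_given_a: float
    n_distinct_haplotypes: int
    two_n: int


def pairwise_ld(
    h_ij: float,
    p_i: float,
    q_j: float,
    two_n: int,
    allele_a: str = "",
    allele_b: str = "",
) -> HaplotypePairLD:
    """LD statistics for one haplotype from its frequency and marginals."""
    if not (0.0 < p_i < 1.0 and 0.0 < q_j < 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if h_ij < 0 or h_ij > min(p_i, q_j) + 1e-12:
        raise ValueError(
            f"haplotype frequency {h_ij} exceeds min(p, q) = "
            f"{min(p_i, q_j)}"
        )
    D = h_ij - p_i * q_j
    if D >= 0:
        dmax = min(p_i * (1.0 - q_j), q_j * (1.0 - p_i))
    else:
        dmax = min(p_i * q_j, (1.0 - p_i) * (1.0 - q_j))
    dprime = 0.0 if dmax == 0 else D / dmax
    chi2 = two_n * D * D / (p_i * (1 - p_i) * q_j * (1 - q_j))
    p_value = float(chi2_dist.sf(chi2, df=1))
    return HaplotypePairLD(
        allele_a=allele_a,
        allele_b=allele_b,
        frequency=h_ij,
        sd=float(binomial_sd(h_ij, two_n)),
        D=D,
        dprime=dprime,
        chi2=chi2,
        p_value=p_value,
    )


def _validate_joint(joint: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h = joint.to_numpy(dtype=float)
    if (h < -1e-12).any():
        raise ValueError("negative cell in joint table")
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    if abs(h.sum() - 1.0) > 1e-9:
        raise ValueError("joint haplotype frequencies must sum to 1")
    return h, p, q


def _drop_zero_margins(joint: pd.DataFrame) -> pd.DataFrame:
    """Zero-frequency alleles contribute nothing but break divisions."""
    h = joint.to_numpy(dtype=float)
    rows = h.sum(axis=1) > 0
    cols = h.sum(axis=0) > 0
    return joint.loc[joint.index[rows], joint.columns[cols]]


def overall_dprime(joint: pd.DataFrame) -> float:
    """Frequency-weighted mean absolute normalized disequilibrium."""
    joint = _drop_zero_margins(joint)
    h, p, q = _validate_joint(joint)
    total = 0.0
    for i in range(h.shape[0]):
        for j in range(h.shape[1]):
            D = h[i, j] - p[i] * q[j]
            if D >= 0:
                dmax = min(p[i] * (1 - q[j]), q[j] * (1 - p[i]))
            else:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            dprime = 0.0 if dmax == 0 else D / dmax
            total += p[i] * q[j] * abs(dprime)
    return float(total)


def wn(joint: pd.DataFrame) -> float:
    """Multiallelic overall LD (Cramer's-V analogue), in [0, 1]."""
    joint = _drop_zero_margins(joint)
    h, p, q = _validate_joint(joint)
    ka, kb = h.shape
    if ka < 2 or kb < 2:
        raise ValueError("Wn undefined for a monomorphic locus")
    D = h - np.outer(p, q)
    stat = float((D * D / np.outer(p, q)).sum())
    return float(np.sqrt(stat / (min(ka, kb) - 1)))


def ald(joint: pd.DataFrame) -> tuple[float, float]:
    """Asymmetric LD ``(W_a_given_b, W_b_given_a)`` for a joint table with
    locus-a alleles on the rows and locus-b alleles on the columns."""
    joint = _drop_zero_margins(joint)
    h, p, q = _validate_joint(joint)
    F_a = float((p * p).sum())
    F_b = float((q * q).sum())
    if F_a >= 1.0 or F_b >= 1.0:
        raise ValueError("ALD undefined for a monomorphic locus")
    F_a_given_b = float((h * h / q[np.newaxis, :]).sum())
    F_b_given_a = float((h * h / p[:, np.newaxis]).sum())
    w_a_given_b = np.sqrt(max(F_a_given_b - F_a, 0.0) / (1.0 - F_a))
    w_b_given_a = np.sqrt(max(F_b_given_a - F_b, 0.0) / (1.0 - F_b))
    return float(w_a_given_b), float(w_b_given_a)


def joint_haplotype_counts(
    haplotypes: Iterable[Haplotype],
    locus_a: Locus,
    locus_b: Locus,
    n_fields: Optional[int] = None,
) -> pd.DataFrame:
    """Direct-count joint table (rows: locus-a alleles, cols: locus-b)."""
    pairs = []
    for hap in haplotypes:
        if not hap.covers((locus_a, locus_b)):
            continue
        a = hap.allele_at(locus_a)
        b = hap.allele_at(locus_b)
        if n_fields is not None:
            a, b = a.reduce(n_fields), b.reduce(n_fields)
        pairs.append((str(a), str(b)))
    if not pairs:
        raise ValueError(
            f"no haplotypes cover loci {locus_a.value}, {locus_b.value}"
        )
    df = pd.DataFrame(pairs, columns=["a", "b"])
    return pd.crosstab(df["a"], df["b"])


def ld_summary_for_pair(
    haplotypes: Sequence[Haplotype],
    locus_a: Locus,
    locus_b: Locus,
    n_fields: Optional[int] = None,
) -> tuple[LDSummary, list[HaplotypePairLD]]:
    """Full two-locus LD report from phased founder haplotypes.

    Returns the locus-pair summary (overall D', Wn, both ALD directions,
    number of distinct haplotypes) and the per-haplotype statistics for
    every observed haplotype.
    """
    counts = joint_haplotype_counts(haplotypes, locus_a, locus_b, n_fields)
    two_n = int(counts.to_numpy().sum())
    joint = counts / two_n
    w_ab, w_ba = ald(joint)
    summary = LDSummary(
        locus_a=locus_a,
        locus_b=locus_b,
        overall_dprime=overall_dprime(joint),
        wn=wn(joint),
        w_a_given_b=w_ab,
        w_b_given_a=w_ba,
        n_distinct_haplotypes=int((counts.to_numpy() > 0).sum()),
        two_n=two_n,
    )
    h = joint.to_numpy()
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    rows: list[HaplotypePairLD] = []
    for i, a_name in enumerate(joint.index):
        for j, b_name in enumerate(joint.columns):
            if h[i, j] <= 0:
                continue
            rows.append(
                pairwise_ld(
                    h[i, j],
                    float(p[i]),
                    float(q[j]),
                    two_n,
                    allele_a=str(a_name),
                    allele_b=str(b_name),
                )
            )
    rows.sort(key=lambda r: (-r.frequency, r.allele_a, r.allele_b))
    return summary, rows


def ld_table(
    rows: Sequence[HaplotypePairLD], bonferroni: bool = False
) -> pd.DataFrame:
    """Tabulate per-haplotype LD rows; optional Bonferroni column."""
    df = pd.DataFrame(
        {
            "haplotype": [f"{r.allele_a}~{r.allele_b}" for r in rows],
            "frequency": [r.frequency for r in rows],
            "sd": [r.sd for r in rows],
            "dprime": [r.dprime for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    if bonferroni:
        m = len(df)
        df["p_bonferroni"] = np.minimum(df["p_value"] * m, 1.0)
    return df
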