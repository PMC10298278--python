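"""Ewens–Watterson homozygosity test of neutrality.

The observed homozygosity ``F_obs = sum_i p_i**2`` at a locus is compared
with its distribution under the neutral Ewens sampling formula conditioned
on the sample size n (chromosomes) and the observed allele count k.  The
conditional law is parameter-free: a partition of n with size-multiplicities
``a_j`` has probability proportional to ``n! / prod_j (j**a_j * a_j!)``
(theta cancels on conditioning).

Sampling strategy: for n <= 20 every partition of n into k parts is
enumerated and draws are taken from the exact conditional distribution;
for larger n partitions are generated with a Chinese-restaurant process
whose concentration theta solves ``E[K] = k`` (Watterson's moment choice,
efficiency only) and rejected unless exactly k classes appear.

``F_nd = (F_obs - mean F_null) / sd F_null``; the p-value is the lower
tail ``P(F_null <= F_obs)`` with the (r+1)/(R+1) convention — balancing
selection pushes homozygosity below its neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .frequencies import FrequencyTable
from .nomenclature import Locus


@dataclass
class EWHResult:
    locus: Optional[Locus]
    n: int
    k: int
    f_obs: float
    f_exp: float
    sd_f: float
    f_nd: float
    p_value: float
    replicates: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def observed_homozygosity(table: FrequencyTable) -> float:
    """``F_obs = sum_i p_i**2`` over the allele frequencies of a locus."""
    p = table.table["frequency"].to_numpy(dtype=float)
    if len(p) == 0:
        raise ValueError("empty frequency table")
    return float((p * p).sum())


# ---------------------------------------------------------------------------
# exact conditional distribution by partition enumeration (small n)
# ---------------------------------------------------------------------------


def _partitions_into(n: int, k: int, maximum: Optional[int] = None):
    """Yield the partitions of n into exactly k positive parts
    (non-increasing)."""
    if maximum is None:
        maximum = n
    if k == 1:
        if n <= maximum:
            yield (n,)
        return
    first_min = -(-n // k)  # ceil(n/k): largest part at least the mean
    for first in range(min(maximum, n - k + 1), first_min - 1, -1):
        for rest in _partitions_into(n - first, k - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=None)
def conditional_partition_distribution(
    n: int, k: int
) -> tuple[tuple[tuple[int, ...], ...], tuple[float, ...]]:
    """All partitions of n into k parts with their Ewens conditional
    probabilities (weights ``prod_j j**-a_j / a_j!`` normalized)."""
    parts = tuple(_partitions_into(n, k))
    logw = []
    for part in parts:
        sizes, counts = np.unique(part, return_counts=True)
        lw = -(
            counts * np.log(sizes)
        ).sum() - sum(_log_factorial(int(c)) for c in counts)
        logw.append(lw)
    logw_arr = np.array(logw)
    w = np.exp(logw_arr - logw_arr.max())
    w /= w.sum()
    return parts, tuple(float(x) for x in w)


def _log_factorial(m: int) -> float:
    from math import lgamma

    return lgamma(m + 1)


def exact_null_moments(n: int, k: int) -> tuple[float, float]:
    """Exact conditional mean and SD of F under neutrality (n <= ~20)."""
    parts, probs = conditional_partition_distribution(n, k)
    f = np.array([sum((c / n) ** 2 for c in part) for part in parts])
    p = np.array(probs)
    mean = float((f * p).sum())
    var = float(((f - mean) ** 2 * p).sum())
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# CRP sampler with rejection on the class count (large n)
# ---------------------------------------------------------------------------


def watterson_theta(n: int, k: int) -> float:
    """theta solving E[K] = sum_i theta/(theta+i) = k (i = 0..n-1)."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9

    i = np.arange(n, dtype=float)

    def expected_k(theta: float) -> float:
        return float((theta / (theta + i)).sum())

    return brentq(lambda t: expected_k(t) - k, 1e-9, 1e6)


def _crp_partition_sizes(
    n: int, new_table: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Class sizes of one CRP seating given the new-class indicator.

    A non-opening customer joins the class of a uniformly chosen earlier
    customer (size-biased choice).
    """
    table = np.empty(n, dtype=np.int64)
    targets = (rng.random(n) * np.arange(n)).astype(np.int64)  # targets[i] < i
    next_id = 0
    for i in range(n):
        if new_table[i]:
            table[i] = next_id
            next_id += 1
        else:
            table[i] = table[targets[i]]
    return np.bincount(table, minlength=next_id)


def ewens_null_sample(
    n: int,
    k: int,
    replicates: int = 10_000,
    seed: Optional[int] = None,
    enumeration_limit: int = 20,
) -> np.ndarray:
    """Sample homozygosity values F under the neutral conditional null.

    Exact categorical sampling over enumerated partitions for
    ``n <= enumeration_limit``; CRP-with-rejection otherwise.  Fully
    deterministic given ``seed``.
    """
    if k > n:
        raise ValueError("k cannot exceed n")
    if k < 1 or n < 1:
        raise ValueError("need n >= 1 and k >= 1")
    rng = np.random.default_rng(seed)

    if k == n:
        # only the all-singletons partition exists
        return np.full(replicates, 1.0 / n)

    if n <= enumeration_limit:
        parts, probs = conditional_partition_distribution(n, k)
        f = np.array([sum((c / n) ** 2 for c in part) for part in parts])
        idx = rng.choice(len(parts), size=replicates, p=np.array(probs))
        return f[idx]

    theta = watterson_theta(n, k)
    p_new = theta / (theta + np.arange(n, dtype=float))
    out = np.empty(replicates, dtype=float)
    got = 0
    batch = max(replicates, 512)
    while got < replicates:
        u = rng.random((batch, n))
        new = u < p_new[np.newaxis, :]
        ks = new.sum(axis=1)
        hits = np.nonzero(ks == k)[0]
        for row in hits:
            sizes = _crp_partition_sizes(n, new[row], rng)
            out[got] = float(((sizes / n) ** 2).sum())
            got += 1
            if got == replicates:
                break
    return out


def ewh_test(
    table: FrequencyTable,
    n: Optional[int] = None,
    replicates: int = 10_000,
    seed: Optional[int] = None,
) -> EWHResult:
    """Ewens–Watterson homozygosity test for one locus.

    ``n`` defaults to the table's chromosome count (2n of the cohort).
    """
    if n is None:
        n = table.two_n
    k = table.k
    f_obs = observed_homozygosity(table)
    null = ewens_null_sample(n, k, replicates=replicates, seed=seed)
    f_exp = float(null.mean())
    sd_f = float(null.std(ddof=0))
    f_nd = (f_obs - f_exp) / sd_f if sd_f > 0 else 0.0
    r = int((null <= f_obs + 1e-12).sum())
    p_value = (r + 1) / (replicates + 1)
    return EWHResult(
        locus=table.locus,
        n=n,
        k=k,
        f_obs=f_obs,
        f_exp=f_exp,
        sd_f=sd_f,
        f_nd=f_nd,
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )
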