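"""Independent reference implementations used only as test oracles.

Every function here is written as a literal, loop-based transcription of
the defining formula (or an exhaustive enumeration), deliberately sharing
no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# linkage disequilibrium, cell by cell
# ---------------------------------------------------------------------------


def oracle_pairwise(h, p, q, two_n):
    D = h - p * q
    if D >= 0:
        dmax = min(p * (1 - q), q * (1 - p))
    else:
        dmax = min(p * q, (1 - p) * (1 - q))
    dprime = 0.0 if dmax == 0 else D / dmax
    chi2 = two_n * D**2 / (p * (1 - p) * q * (1 - q))
    return D, dprime, chi2


def oracle_overall_dprime(joint: np.ndarray) -> float:
    p = [sum(row) for row in joint]
    q = [sum(col) for col in joint.T]
    total = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            D = joint[i, j] - p[i] * q[j]
            if D >= 0:
                dmax = min(p[i] * (1 - q[j]), q[j] * (1 - p[i]))
            else:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            if dmax > 0:
                total += p[i] * q[j] * abs(D / dmax)
    return total


def oracle_wn(joint: np.ndarray) -> float:
    p = [sum(row) for row in joint]
    q = [sum(col) for col in joint.T]
    s = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            D = joint[i, j] - p[i] * q[j]
            s += D * D / (p[i] * q[j])
    k = min(joint.shape)
    return math.sqrt(s / (k - 1))


def oracle_ald(joint: np.ndarray) -> tuple[float, float]:
    p = [sum(row) for row in joint]
    q = [sum(col) for col in joint.T]
    F_a = sum(x * x for x in p)
    F_b = sum(x * x for x in q)
    F_ab = 0.0
    F_ba = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            F_ab += joint[i, j] ** 2 / q[j]
            F_ba += joint[i, j] ** 2 / p[i]
    w_ab = math.sqrt(max(F_ab - F_a, 0.0) / (1 - F_a))
    w_ba = math.sqrt(max(F_ba - F_b, 0.0) / (1 - F_b))
    return w_ab, w_ba


def random_joint_table(
    rng: np.random.Generator, ka: int, kb: int
) -> np.ndarray:
    """A random joint frequency table with strictly positive marginals."""
    while True:
        t = rng.dirichlet(np.ones(ka * kb)).reshape(ka, kb)
        if (t.sum(axis=1) > 1e-6).all() and (t.sum(axis=0) > 1e-6).all():
            return t


# ---------------------------------------------------------------------------
# Hardy–Weinberg: exact permutation distribution by full enumeration
# ---------------------------------------------------------------------------


def _log_conditional(pairs) -> float:
    counts = Counter(tuple(sorted(p)) for p in pairs)
    het = sum(v for k, v in counts.items() if k[0] != k[1])
    return het * math.log(2.0) - sum(
        math.lgamma(v + 1) for v in counts.values()
    )


def oracle_hwe_exact_p(genotypes) -> float:
    """P(conditional probability <= observed) over all orderings of the
    allele multiset paired consecutively (uniform law, small 2n only)."""
    alleles = [a for pair in genotypes for a in pair]
    obs = _log_conditional(genotypes)
    hits = 0
    total = 0
    for perm in itertools.permutations(alleles):
        pairs = [
            (perm[2 * i], perm[2 * i + 1]) for i in range(len(perm) // 2)
        ]
        if _log_conditional(pairs) <= obs + 1e-9:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# Ewens conditional null: exact moments by partition enumeration
# ---------------------------------------------------------------------------


def _partitions(n, k, maximum=None):
    if maximum is None:
        maximum = n
    if k == 1:
        if n <= maximum:
            yield (n,)
        return
    for first in range(min(maximum, n - k + 1), (n + k - 1) // k - 1, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


def oracle_ewens_moments(n: int, k: int) -> tuple[float, float]:
    weights = []
    fs = []
    for part in _partitions(n, k):
        mult = Counter(part)
        logw = -sum(
            a * math.log(j) + math.lgamma(a + 1) for j, a in mult.items()
        )
        weights.append(math.exp(logw))
        fs.append(sum((c / n) ** 2 for c in part))
    z = sum(weights)
    mean = sum(w * f for w, f in zip(weights, fs)) / z
    var = sum(w * (f - mean) ** 2 for w, f in zip(weights, fs)) / z
    return mean, math.sqrt(var)


# ---------------------------------------------------------------------------
# segregation phasing: independent brute force over ordered splits
# ---------------------------------------------------------------------------


def oracle_phase_family(father_pairs, mother_pairs, child_pairs):
    """Exhaustively classify a family given per-locus genotype pairs.

    ``father_pairs``/``mother_pairs``: list (per locus) of 2-tuples of
    allele tokens; ``child_pairs``: list (per child) of per-locus sorted
    2-tuples.  Returns (status, founder multisets) with status in
    {"unique", "ambiguous", "inconsistent"}.

    Enumerates ALL 2**h ordered splits per parent (no pair collapsing) and
    checks every child against every (paternal haplotype, maternal
    haplotype) choice — an intentionally redundant search.
    """
    n_loci = len(father_pairs)

    def ordered_splits(pairs):
        out = []
        for mask in itertools.product((0, 1), repeat=n_loci):
            h1 = tuple(pairs[l][mask[l]] for l in range(n_loci))
            h2 = tuple(pairs[l][1 - mask[l]] for l in range(n_loci))
            out.append((h1, h2))
        return out

    founder_sets = set()
    admissible = 0
    for fsplit in ordered_splits(father_pairs):
        for msplit in ordered_splits(mother_pairs):
            ok = True
            for child in child_pairs:
                explained = False
                for fh in fsplit:
                    for mh in msplit:
                        if all(
                            tuple(sorted((fh[l], mh[l]))) == child[l]
                            for l in range(n_loci)
                        ):
                            explained = True
                            break
                    if explained:
                        break
                if not explained:
                    ok = False
                    break
            if ok:
                admissible += 1
                founder_sets.add(
                    tuple(sorted(fsplit + msplit))
                )
    if admissible == 0:
        return "inconsistent", founder_sets
    if len(founder_sets) == 1:
        return "unique", founder_sets
    return "ambiguous", founder_sets


# ---------------------------------------------------------------------------
# Nei distance, spelled out
# ---------------------------------------------------------------------------


def oracle_nei_sgd(x_tables: dict, y_tables: dict) -> float:
    """x_tables/y_tables: locus -> {allele: frequency} dictionaries."""
    loci = sorted(set(x_tables) & set(y_tables))
    jx = jy = jxy = 0.0
    for locus in loci:
        alleles = set(x_tables[locus]) | set(y_tables[locus])
        for a in alleles:
            px = x_tables[locus].get(a, 0.0)
            py = y_tables[locus].get(a, 0.0)
            jx += px * px
            jy += py * py
            jxy += px * py
    m = len(loci)
    return -math.log((jxy / m) / math.sqrt((jx / m) * (jy / m)))
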