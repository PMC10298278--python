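"""Inter-population comparison: Nei standard genetic distances,
neighbor-joining dendrograms with bootstrap supports, and correspondence
analysis of population-by-allele frequency tables.

Nei's standard genetic distance between populations x and y over a shared
locus set is ``D = -ln I`` with ``I = J_xy / sqrt(J_x J_y)``, where ``J_x``
is the mean over loci of ``sum_i x_i^2`` and ``J_xy`` the mean of
``sum_i x_i y_i`` (allele universes unioned per locus, absent alleles at
frequency 0).

The neighbor-joining implementation follows the Saitou–Nei agglomeration
with the Q-criterion; ties are broken on the lexicographically smallest
label pair, and negative branch lengths are clamped to zero with the
deficit transferred to the sister branch so tip-to-tip paths through the
join are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .frequencies import FrequencyTable
from .nomenclature import CANONICAL_LOCUS_ORDER, Locus

PopulationTables = Mapping[Locus, FrequencyTable]


class InfiniteDistanceError(ValueError):
    """Genetic identity of 0 between two populations (no shared allele at
    some locus set): the Nei distance is infinite."""


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.labels, columns=self.labels
        )


# ---------------------------------------------------------------------------
# Nei standard genetic distance
# ---------------------------------------------------------------------------


def _shared_loci(
    x: PopulationTables, y: PopulationTables, loci: Optional[Sequence[Locus]]
) -> tuple[Locus, ...]:
    if loci is None:
        loci = [l for l in CANONICAL_LOCUS_ORDER if l in x and l in y]
    else:
        loci = list(loci)
        for l in loci:
            if l not in x or l not in y:
                raise ValueError(f"locus {l} missing from a population")
    if not loci:
        raise ValueError("no shared locus between populations")
    return tuple(loci)


def nei_sgd(
    x: PopulationTables,
    y: PopulationTables,
    loci: Optional[Sequence[Locus]] = None,
) -> float:
    """Nei standard genetic distance ``-ln(J_xy / sqrt(J_x J_y))``."""
    loci = _shared_loci(x, y, loci)
    jx = jy = jxy = 0.0
    for locus in loci:
        sx = x[locus].as_series()
        sy = y[locus].as_series()
        alleles = sx.index.union(sy.index)
        px = sx.reindex(alleles, fill_value=0.0).to_numpy()
        py = sy.reindex(alleles, fill_value=0.0).to_numpy()
        jx += float((px * px).sum())
        jy += float((py * py).sum())
        jxy += float((px * py).sum())
    m = len(loci)
    identity = (jxy / m) / math.sqrt((jx / m) * (jy / m))
    if identity <= 0:
        raise InfiniteDistanceError(
            "genetic identity is 0; distance is infinite"
        )
    return -math.log(identity)


def sgd_matrix(
    populations: Mapping[str, PopulationTables],
    loci: Optional[Sequence[Locus]] = None,
) -> DistanceMatrix:
    labels = tuple(populations)
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_sgd(
                populations[labels[i]], populations[labels[j]], loci
            )
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree (represented rooted at the final join)."""

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())


@dataclass
class Tree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    root: TreeNode
    labels: tuple[str, ...]

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(
                f"{fmt(c)}:{ln:.{precision}f}" for c, ln in node.children
            )
            sup = (
                ""
                if node.support is None
                else f"{node.support:.0f}"
            )
            return f"({inner}){sup}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each encoded as the side not
        containing the alphabetically first label."""
        all_labels = frozenset(self.labels)
        anchor = min(self.labels)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_labels) - 1:
                    out.add(
                        side
                        if anchor not in side
                        else all_labels - side
                    )
                below = below | side
            return below

        walk(self.root)
        return out

    def internal_edges(self) -> list[tuple[TreeNode, frozenset]]:
        """(child node, bipartition) for every internal edge."""
        all_labels = frozenset(self.labels)
        anchor = min(self.labels)
        out = []

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_labels) - 1:
                    key = side if anchor not in side else all_labels - side
                    out.append((child, key))
                below = below | side
            return below

        walk(self.root)
        return out

    def tip_distances(self) -> DistanceMatrix:
        """Path-length distances between every pair of tips."""
        labels = tuple(sorted(self.labels))
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.label]: 0.0}
            groups = []
            for child, ln in node.children:
                below = walk(child)
                groups.append({k: v + ln for k, v in below.items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            d[a, b] = d[b, a] = da + db
            merged: dict[int, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        walk(self.root)
        return DistanceMatrix(labels=labels, values=d)

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick"
        )


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Deterministic: Q-ties resolved on the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest leaf).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)  # tie-break label per cluster
    d = dm.values.copy()
    active = list(range(n))

    def clamp(pair: list[tuple[TreeNode, float]]):
        # negative branch -> 0, deficit moved to the sister branch
        (na, la), (nb, lb) = pair
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return [(na, max(la, 0.0)), (nb, max(lb, 0.0))]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, tuple(sorted((names[i], names[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        new = TreeNode(
            children=clamp([(nodes[i], li), (nodes[j], lj)])
        )
        # distances from the new node to the remaining clusters
        new_idx = len(nodes)
        nodes.append(new)
        names.append(min(names[i], names[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            d[new_idx, m] = d[m, new_idx] = (
                d[i, m] + d[j, m] - d[i, j]
            ) / 2
        active = [m for m in active if m not in (i, j)] + [new_idx]

    # final three clusters joined at one internal (trifurcating) node
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    children = [
        (nodes[i], max(li, 0.0)),
        (nodes[j], max(lj, 0.0)),
        (nodes[k], max(lk, 0.0)),
    ]
    root = TreeNode(children=children)
    return Tree(root=root, labels=dm.labels)


# ---------------------------------------------------------------------------
# parametric bootstrap over chromosomes
# ---------------------------------------------------------------------------


def _resample_population(
    tables: PopulationTables, rng: np.random.Generator
) -> PopulationTables:
    out: dict[Locus, FrequencyTable] = {}
    for locus, t in tables.items():
        p = t.table["frequency"].to_numpy(dtype=float)
        p = p / p.sum()
        counts = rng.multinomial(t.two_n, p)
        freqs = counts / t.two_n
        from .nomenclature import parse_allele_name

        alleles = [parse_allele_name(a) for a in t.table["allele"]]
        out[locus] = FrequencyTable.from_frequencies(
            locus=locus,
            alleles=alleles,
            frequencies=freqs,
            two_n=t.two_n,
            counts=counts,
        )
    return out


def bootstrap_supports(
    populations: Mapping[str, PopulationTables],
    loci: Optional[Sequence[Locus]] = None,
    replicates: int = 1000,
    seed: Optional[int] = None,
) -> Tree:
    """NJ tree with bootstrap supports from a multinomial resample of
    allele counts (the chromosome is the resampling unit).

    Per-population random streams are keyed by the population's rank in
    sorted label order, so supports do not depend on input order.
    """
    base = nj_tree(sgd_matrix(populations, loci))
    sorted_labels = sorted(populations)
    rngs = {
        label: np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rank,))
        )
        for rank, label in enumerate(sorted_labels)
    }
    counts: dict[frozenset, int] = {key: 0 for _, key in base.internal_edges()}
    for _ in range(replicates):
        resampled = {
            label: _resample_population(populations[label], rngs[label])
            for label in sorted_labels
        }
        try:
            tree = nj_tree(sgd_matrix(resampled, loci))
        except (InfiniteDistanceError, ValueError):
            continue
        bips = tree.bipartitions()
        for key in counts:
            if key in bips:
                counts[key] += 1
    for node, key in base.internal_edges():
        node.support = 100.0 * counts[key] / replicates
    return base


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class CAResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    inertia_shares: np.ndarray
    total_inertia: float


def correspondence_analysis(
    matrix: pd.DataFrame, dims: int = 3
) -> CAResult:
    """Standard correspondence analysis of a nonnegative table.

    SVD of the standardized residuals ``(P - r c^T)/sqrt(r c^T)`` of the
    correspondence matrix P; principal coordinates are the mass-scaled
    singular vectors times singular values.  Axis inertias sum to the
    table's total chi-square inertia.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be nonnegative")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column")
    max_dims = min(X.shape) - 1
    if dims > max_dims:
        raise ValueError(f"dims must be <= {max_dims}")
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    sv = sv[:max_dims]
    U = U[:, :max_dims]
    V = Vt.T[:, :max_dims]
    total_inertia = float((sv**2).sum())
    shares = (
        sv**2 / total_inertia if total_inertia > 0 else np.zeros_like(sv)
    )
    row_pc = (U / np.sqrt(r)[:, None]) * sv[None, :]
    col_pc = (V / np.sqrt(c)[:, None]) * sv[None, :]
    axes = [f"axis{i + 1}" for i in range(dims)]
    return CAResult(
        row_coords=pd.DataFrame(
            row_pc[:, :dims], index=matrix.index, columns=axes
        ),
        col_coords=pd.DataFrame(
            col_pc[:, :dims], index=matrix.columns, columns=axes
        ),
        singular_values=sv,
        inertia_shares=shares,
        total_inertia=total_inertia,
    )


def population_allele_matrix(
    populations: Mapping[str, PopulationTables],
    loci: Optional[Sequence[Locus]] = None,
) -> pd.DataFrame:
    """Population-by-allele count matrix (frequency times 2n per locus),
    the input to correspondence analysis."""
    rows = {}
    for label, tables in populations.items():
        use = loci or [l for l in CANONICAL_LOCUS_ORDER if l in tables]
        row = {}
        for locus in use:
            t = tables[locus]
            for rec in t.table.itertuples():
                row[rec.allele] = rec.frequency * t.two_n
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical metric scaling of a distance matrix — an explicitly
    labelled alternative ordination when only distances are available
    (correspondence analysis proper operates on frequency tables)."""
    d2 = dm.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.clip(vals[:dims], 0.0, None)
    coords = vecs[:, :dims] * np.sqrt(keep)[None, :]
    return pd.DataFrame(
        coords,
        index=dm.labels,
        columns=[f"axis{i + 1}" for i in range(dims)],
    )
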