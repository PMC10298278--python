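"""Nei distances, neighbor joining (with additive-matrix recovery and an
external cross-check), parametric bootstrap, and correspondence analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hlafam as hf
from hlafam.frequencies import FrequencyTable
from hlafam.popcompare import (
    DistanceMatrix,
    InfiniteDistanceError,
    TreeNode,
    Tree,
    classical_mds,
    population_allele_matrix,
)
from helpers_oracles import oracle_nei_sgd


def _pop(freqs_by_locus: dict[str, dict[str, float]], two_n: int = 400):
    out = {}
    for locus_txt, freqs in freqs_by_locus.items():
        alleles = [hf.parse_allele_name(a) for a in freqs]
        locus = hf.Locus(locus_txt)
        out[locus] = FrequencyTable.from_frequencies(
            locus=locus,
            alleles=alleles,
            frequencies=np.array(list(freqs.values())),
            two_n=two_n,
        )
    return out


class TestNeiSGD:
    def test_identical_populations_zero(self):
        x = _pop({"A": {"A*01": 0.6, "A*02": 0.4}})
        assert hf.nei_sgd(x, x) == pytest.approx(0.0)

    def test_disjoint_fixed_alleles_infinite(self):
        x = _pop({"A": {"A*01": 1.0}})
        y = _pop({"A": {"A*02": 1.0}})
        with pytest.raises(InfiniteDistanceError):
            hf.nei_sgd(x, y)

    def test_matches_hand_computed_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            fx = rng.dirichlet(np.ones(3))
            fy = rng.dirichlet(np.ones(3))
            gx = rng.dirichlet(np.ones(4))
            gy = rng.dirichlet(np.ones(4))
            x = _pop(
                {
                    "A": dict(zip(["A*01", "A*02", "A*03"], fx)),
                    "B": dict(
                        zip(["B*07", "B*08", "B*35", "B*51"], gx)
                    ),
                }
            )
            y = _pop(
                {
                    "A": dict(zip(["A*01", "A*02", "A*03"], fy)),
                    "B": dict(
                        zip(["B*07", "B*08", "B*35", "B*51"], gy)
                    ),
                }
            )
            oracle = oracle_nei_sgd(
                {"A": dict(zip(["A*01", "A*02", "A*03"], fx)),
                 "B": dict(zip(["B*07", "B*08", "B*35", "B*51"], gx))},
                {"A": dict(zip(["A*01", "A*02", "A*03"], fy)),
                 "B": dict(zip(["B*07", "B*08", "B*35", "B*51"], gy))},
            )
            assert hf.nei_sgd(x, y) == pytest.approx(oracle, abs=1e-12)
            assert hf.nei_sgd(y, x) == pytest.approx(oracle, abs=1e-12)

    def test_mixture_population_is_closer(self):
        a = {"A*01": 0.8, "A*02": 0.1, "A*03": 0.1}
        c = {"A*01": 0.1, "A*02": 0.1, "A*03": 0.8}
        b = {k: (a[k] + c[k]) / 2 for k in a}
        pa, pb, pc = (_pop({"A": f}) for f in (a, b, c))
        assert hf.nei_sgd(pa, pb) < hf.nei_sgd(pa, pc)

    def test_matrix_consistent_with_pairwise(self, toy_populations):
        dm = hf.sgd_matrix(toy_populations)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        a, b = dm.labels[0], dm.labels[3]
        assert dm.get(a, b) == pytest.approx(
            hf.nei_sgd(toy_populations[a], toy_populations[b])
        )


class TestNeighborJoining:
    def test_four_taxon_additive_tree_recovered_exactly(self):
        # ((A,B),(C,D)) with every branch length 1
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            dtype=float,
        )
        tree = hf.nj_tree(
            DistanceMatrix(labels=("A", "B", "C", "D"), values=d)
        )
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert np.allclose(tree.tip_distances().values, d)

    def test_three_taxa_closed_form(self):
        d = np.array(
            [[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float
        )
        tree = hf.nj_tree(DistanceMatrix(labels=("A", "B", "C"), values=d))
        lengths = {
            child.label: ln for child, ln in tree.root.children
        }
        assert lengths["A"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["B"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 8 - 5) / 2)

    def test_q_tie_breaks_lexicographically(self):
        # four equidistant taxa: every pair ties on Q
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = hf.nj_tree(
            DistanceMatrix(labels=("d", "c", "b", "a"), values=d)
        )
        assert tree.bipartitions() == {frozenset({"c", "d"})}

    @staticmethod
    def _random_additive_tree(rng, labels):
        nodes = [TreeNode(label=l) for l in labels]
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]
            joined = TreeNode(
                children=[
                    (a, float(rng.uniform(0.5, 2.0))),
                    (b, float(rng.uniform(0.5, 2.0))),
                ]
            )
            nodes = [
                n for idx, n in enumerate(nodes) if idx not in (i, j)
            ] + [joined]
        root = TreeNode(
            children=[(n, float(rng.uniform(0.5, 2.0))) for n in nodes]
        )
        return Tree(root=root, labels=tuple(labels))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered(self, n_taxa):
        """NJ is consistent on additive inputs: the recovered tree must
        reproduce the generating tree's topology and path lengths."""
        rng = np.random.default_rng(30 + n_taxa)
        labels = [f"T{i}" for i in range(n_taxa)]
        for _ in range(10):
            truth = self._random_additive_tree(rng, labels)
            dm = truth.tip_distances()
            rec = hf.nj_tree(dm)
            assert rec.bipartitions() == truth.bipartitions()
            assert np.allclose(
                rec.tip_distances().values, dm.values, atol=1e-9
            )

    def test_topology_agrees_with_skbio(self, toy_populations):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        dm = hf.sgd_matrix(toy_populations)
        ours = hf.nj_tree(dm).bipartitions()
        sk = skbio_tree.nj(SkbioDM(dm.values, ids=list(dm.labels)))
        anchor = min(dm.labels)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(dm.labels) - 1:
                if anchor in side:
                    side = frozenset(dm.labels) - side
                theirs.add(side)
        assert ours == theirs

    def test_newick_parses_with_dendropy(self, toy_populations):
        import dendropy

        tree = hf.nj_tree(hf.sgd_matrix(toy_populations))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(
            tree.labels
        )


class TestBootstrap:
    def test_separating_edge_gets_full_support(self, toy_populations):
        tree = hf.bootstrap_supports(
            toy_populations, replicates=200, seed=0
        )
        north = frozenset({"NorthA", "NorthB", "NorthC"})
        south = frozenset({"SouthA", "SouthB", "SouthC"})
        supports = {
            key: node.support for node, key in tree.internal_edges()
        }
        split = supports.get(north, supports.get(south))
        assert split is not None and split >= 99.0

    def test_single_replicate_supports_binary(self, toy_populations):
        tree = hf.bootstrap_supports(toy_populations, replicates=1, seed=1)
        for node, _ in tree.internal_edges():
            assert node.support in (0.0, 100.0)

    def test_deterministic_and_order_invariant(self, toy_populations):
        t1 = hf.bootstrap_supports(toy_populations, replicates=50, seed=2)
        reordered = dict(reversed(list(toy_populations.items())))
        t2 = hf.bootstrap_supports(reordered, replicates=50, seed=2)
        s1 = {key: n.support for n, key in t1.internal_edges()}
        s2 = {key: n.support for n, key in t2.internal_edges()}
        assert s1 == s2


class TestCorrespondenceAnalysis:
    def test_rank_one_table_has_zero_inertia(self):
        X = pd.DataFrame(np.outer([1, 2, 3], [4, 5, 6]).astype(float))
        ca = hf.correspondence_analysis(X, dims=2)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ca.row_coords.to_numpy(), 0.0, atol=1e-7)

    def test_inertia_sums_to_total_chi_square(self):
        rng = np.random.default_rng(40)
        X = pd.DataFrame(
            rng.integers(1, 40, size=(6, 9)).astype(float)
        )
        ca = hf.correspondence_analysis(X, dims=5)
        P = X.to_numpy() / X.to_numpy().sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        total = (((P - np.outer(r, c)) ** 2) / np.outer(r, c)).sum()
        assert ca.total_inertia == pytest.approx(total, abs=1e-10)

    def test_row_distances_are_chi_square_profile_distances(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.integers(1, 25, size=(3, 5)).astype(float))
        dims = 2  # full rank for a 3-row table
        ca = hf.correspondence_analysis(X, dims=dims)
        P = X.to_numpy() / X.to_numpy().sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        profiles = P / r[:, None]
        for i in range(3):
            for j in range(3):
                chi_d2 = (((profiles[i] - profiles[j]) ** 2) / c).sum()
                coord_d2 = (
                    (
                        ca.row_coords.iloc[i] - ca.row_coords.iloc[j]
                    ) ** 2
                ).sum()
                assert coord_d2 == pytest.approx(chi_d2, abs=1e-10)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.integers(1, 30, size=(5, 6)).astype(float))
        ca = hf.correspondence_analysis(X, dims=3)
        perm = [3, 0, 4, 1, 2]
        ca_p = hf.correspondence_analysis(X.iloc[perm], dims=3)
        a = ca.row_coords.to_numpy()[perm]
        b = ca_p.row_coords.to_numpy()
        # axes defined up to sign
        for axis in range(3):
            assert np.allclose(a[:, axis], b[:, axis], atol=1e-9) or (
                np.allclose(a[:, axis], -b[:, axis], atol=1e-9)
            )

    def test_all_zero_row_rejected(self):
        X = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        with pytest.raises(ValueError):
            hf.correspondence_analysis(X, dims=1)

    def test_population_matrix_feeds_ca(self, toy_populations):
        m = population_allele_matrix(toy_populations)
        assert m.shape == (6, 6)
        ca = hf.correspondence_analysis(m, dims=2)
        # the dominant axis separates the two synthetic clusters
        axis1 = ca.row_coords["axis1"]
        north = axis1[[l for l in m.index if l.startswith("North")]]
        south = axis1[[l for l in m.index if l.startswith("South")]]
        assert (north.max() < south.min()) or (south.max() < north.min())


def test_classical_mds_recovers_planar_configuration():
    pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1]], dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dm = DistanceMatrix(labels=("a", "b", "c", "d"), values=d)
    coords = classical_mds(dm, dims=2).to_numpy()
    rec = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    )
    assert np.allclose(rec, d, atol=1e-9)
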