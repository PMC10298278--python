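"""Segregation phasing: enumeration counts, family classification, and
agreement with an independent exhaustive oracle."""

from __future__ import annotations

from collections import Counter
from itertools import product

import numpy as np
import pytest

import hlafam as hf
from conftest import (
    genotype_from_haps,
    hap,
    make_family,
    random_family,
    random_pool,
)
from helpers_oracles import oracle_phase_family


def _geno(pairs_by_locus):
    pairs = {}
    for locus_txt, (a, b) in pairs_by_locus.items():
        locus = hf.Locus(locus_txt)
        pairs[locus] = (
            hf.parse_allele_name(a),
            hf.parse_allele_name(b),
        )
    return hf.Genotype(pairs)


class TestEnumerateParentPhases:
    def test_fully_homozygous_single_pair(self):
        g = _geno({"A": ("A*01", "A*01"), "B": ("B*08", "B*08")})
        phases = hf.enumerate_parent_phases(g, g.typed_loci)
        assert len(phases) == 1
        h1, h2 = phases[0]
        assert str(h1) == str(h2) == "A*01~B*08"

    def test_two_het_loci_two_pairs(self):
        g = _geno({"A": ("A*01", "A*02"), "B": ("B*08", "B*51")})
        phases = hf.enumerate_parent_phases(g, g.typed_loci)
        assert len(phases) == 2

    def test_five_het_loci_match_brute_force(self):
        g = _geno(
            {
                "A": ("A*01", "A*02"),
                "C": ("C*04", "C*07"),
                "B": ("B*08", "B*51"),
                "DRB1": ("DRB1*03", "DRB1*16"),
                "DQB1": ("DQB1*02", "DQB1*05"),
            }
        )
        loci = g.typed_loci
        phases = hf.enumerate_parent_phases(g, loci)
        assert len(phases) == 16
        # brute force: 32 ordered splits collapse to 16 unordered pairs
        pairs = set()
        per_locus = [g.pair_at(l) for l in loci]
        for mask in product((0, 1), repeat=5):
            h1 = tuple(str(per_locus[l][mask[l]]) for l in range(5))
            h2 = tuple(str(per_locus[l][1 - mask[l]]) for l in range(5))
            pairs.add(tuple(sorted((h1, h2))))
        got = {
            tuple(
                sorted(
                    (
                        tuple(str(a) for a in h1.alleles),
                        tuple(str(a) for a in h2.alleles),
                    )
                )
            )
            for h1, h2 in phases
        }
        assert got == pairs

    def test_missing_locus_rejected(self):
        g = _geno({"A": ("A*01", "A*02")})
        with pytest.raises(ValueError):
            hf.enumerate_parent_phases(g, (hf.Locus.A, hf.Locus.B))


class TestPhaseFamily:
    def test_homozygous_parents_unique(self):
        f = _geno({"A": ("A*01", "A*01"), "B": ("B*08", "B*08")})
        m = _geno({"A": ("A*02", "A*02"), "B": ("B*51", "B*51")})
        c = _geno({"A": ("A*01", "A*02"), "B": ("B*08", "B*51")})
        fam = make_family("F1", f, m, [c])
        res = hf.phase_family(fam)
        assert res.status is hf.PhasingStatus.UNIQUE

    def test_children_resolve_father_phase(self):
        # father het at A and B; two children jointly pin A*26 with B*08
        f = _geno({"A": ("A*26", "A*02"), "B": ("B*08", "B*51")})
        m = _geno({"A": ("A*11", "A*11"), "B": ("B*35", "B*35")})
        c1 = _geno({"A": ("A*26", "A*11"), "B": ("B*08", "B*35")})
        c2 = _geno({"A": ("A*02", "A*11"), "B": ("B*51", "B*35")})
        fam = make_family("F1", f, m, [c1, c2])
        res = hf.phase_family(fam)
        assert res.status is hf.PhasingStatus.UNIQUE
        founders = {str(h) for h in res.founder_haplotypes}
        assert "A*26~B*08" in founders and "A*02~B*51" in founders

    def test_identically_het_parents_single_child_ambiguous(self):
        f = _geno({"A": ("A*01", "A*02")})
        m = _geno({"A": ("A*01", "A*02")})
        c = _geno({"A": ("A*01", "A*02")})
        fam = make_family("F1", f, m, [c])
        # single locus: phases are trivially unique (one pair each)
        res = hf.phase_family(fam)
        assert res.status is hf.PhasingStatus.UNIQUE
        # two loci, both parents identically het, child het at both:
        f2 = _geno({"A": ("A*01", "A*02"), "B": ("B*08", "B*51")})
        c2 = _geno({"A": ("A*01", "A*02"), "B": ("B*08", "B*51")})
        fam2 = make_family("F2", f2, f2, [c2])
        res2 = hf.phase_family(fam2)
        assert res2.status is hf.PhasingStatus.AMBIGUOUS

    def test_mendelian_error_reports_locus(self):
        f = _geno({"A": ("A*01", "A*01"), "B": ("B*08", "B*08")})
        m = _geno({"A": ("A*02", "A*02"), "B": ("B*51", "B*51")})
        c = _geno({"A": ("A*01", "A*03"), "B": ("B*08", "B*51")})
        fam = make_family("F1", f, m, [c])
        res = hf.phase_family(fam)
        assert res.status is hf.PhasingStatus.INCONSISTENT
        assert res.offending_locus is hf.Locus.A

    def test_recombinant_child_inconsistent(self):
        # father haplotypes are A*01~B*08 / A*02~B*51 (fixed by child 1 via
        # homozygous mother); child 2 carries the recombinant A*01~B*51
        f = _geno({"A": ("A*01", "A*02"), "B": ("B*08", "B*51")})
        m = _geno({"A": ("A*11", "A*11"), "B": ("B*35", "B*35")})
        c1 = _geno({"A": ("A*01", "A*11"), "B": ("B*08", "B*35")})
        c2 = _geno({"A": ("A*02", "A*11"), "B": ("B*51", "B*35")})
        c3 = _geno({"A": ("A*01", "A*11"), "B": ("B*51", "B*35")})
        fam = make_family("F1", f, m, [c1, c2, c3])
        res = hf.phase_family(fam)
        assert res.status is hf.PhasingStatus.INCONSISTENT


class TestOracleAgreement:
    def test_matches_brute_force_on_random_families(self):
        """1000 random synthetic families, implementation vs an
        independent enumeration over all ordered splits."""
        rng = np.random.default_rng(0)
        pool = random_pool(rng, n_haplotypes=10, alleles_per_locus=3)
        loci = pool.loci
        mismatches = []
        for i in range(1000):
            n_children = int(rng.integers(1, 5))
            fam, _ = random_family(rng, pool, n_children, f"F{i}")
            res = hf.phase_family(fam)
            father_pairs = [
                tuple(str(a) for a in fam.father.genotype.pair_at(l))
                for l in loci
            ]
            mother_pairs = [
                tuple(str(a) for a in fam.mother.genotype.pair_at(l))
                for l in loci
            ]
            child_pairs = [
                [
                    tuple(sorted(str(a) for a in c.genotype.pair_at(l)))
                    for l in loci
                ]
                for c in fam.children
            ]
            status, _ = oracle_phase_family(
                father_pairs, mother_pairs, child_pairs
            )
            if res.status.value != status:
                mismatches.append((i, res.status.value, status))
        assert mismatches == []

    def test_soundness_children_reconstructed(self, default_cohort):
        """For every unique family, the recorded transmissions regenerate
        each child's genotype exactly."""
        cohort = {f.family_id: f for f in default_cohort["cohort"]}
        for res in default_cohort["phased"]:
            if res.status is not hf.PhasingStatus.UNIQUE:
                continue
            fam = cohort[res.family_id]
            for child, (pi, qi) in zip(
                fam.children, res.child_transmissions
            ):
                fhap = res.father_haplotypes[pi]
                mhap = res.mother_haplotypes[qi]
                rebuilt = genotype_from_haps(fhap, mhap)
                assert rebuilt == child.genotype

    def test_monotonicity_unique_never_becomes_ambiguous(self):
        """Adding a (valid) child can only shrink the admissible set."""
        rng = np.random.default_rng(1)
        pool = random_pool(rng, n_haplotypes=8, alleles_per_locus=3)
        for i in range(150):
            fam, (f1, f2, m1, m2) = random_family(rng, pool, 2, f"F{i}")
            before = hf.phase_family(fam).status
            extra_geno = genotype_from_haps(
                (f1, f2)[int(rng.integers(2))],
                (m1, m2)[int(rng.integers(2))],
            )
            bigger = make_family(
                fam.family_id,
                fam.father.genotype,
                fam.mother.genotype,
                [c.genotype for c in fam.children] + [extra_geno],
            )
            after = hf.phase_family(bigger).status
            if before is hf.PhasingStatus.UNIQUE:
                assert after is hf.PhasingStatus.UNIQUE


class TestPhaseCohort:
    def test_recombination_free_cohort_never_inconsistent(
        self, default_cohort
    ):
        report = default_cohort["report"]
        assert report.n_inconsistent == 0
        assert report.n_total == 100
        assert (
            report.n_unique + report.n_ambiguous + report.n_skipped == 100
        )

    def test_unique_families_contribute_four_founders(self, default_cohort):
        founders = default_cohort["founders"]
        report = default_cohort["report"]
        assert len(founders) == 4 * report.n_unique
        per_family = Counter(f.family_id for f in founders)
        assert all(v == 4 for v in per_family.values())

    def test_founders_match_simulated_truth(self, default_cohort):
        truth = default_cohort["truth"]
        for res in default_cohort["phased"]:
            if res.status is not hf.PhasingStatus.UNIQUE:
                continue
            expected = Counter(
                str(h) for h in truth.families[res.family_id].founders
            )
            got = Counter(str(h) for h in res.founder_haplotypes)
            assert got == expected

    def test_inconsistent_family_reported_not_raised(self):
        f = _geno({"A": ("A*01", "A*01")})
        m = _geno({"A": ("A*02", "A*02")})
        c = _geno({"A": ("A*03", "A*03")})
        fam = make_family("F1", f, m, [c])
        founders, report, _ = hf.phase_cohort(hf.FamilyCohort([fam]))
        assert founders == []
        assert report.n_inconsistent == 1
        assert report.excluded[0][0] == "F1"
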