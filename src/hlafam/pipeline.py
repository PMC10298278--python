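"""End-to-end orchestration: cohort in, full report bundle out.

Stages run in a fixed order — phasing report, per-locus frequency tables,
HWE, two-locus LD (summaries plus per-haplotype tables), the 5-locus
haplotype table, the Ewens–Watterson results, and, when reference
populations are supplied, the SGD matrix, NJ tree with bootstraps and CA
coordinates.  A manifest records package/library versions, the seed and a
hash of the configuration.  A stage failure aborts with the stage name;
artifacts already written are retained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .cohort import FamilyCohort
from .frequencies import (
    count_allele_frequencies,
    count_haplotype_frequencies,
    founder_genotypes_at_locus,
    hwe_exact_test,
)
from .io import (
    read_family_genotypes,
    read_population_frequencies,
    write_haplotype_table,
    write_phylip,
    write_population_frequencies,
)
from .ld import ld_summary_for_pair, ld_table
from .neutrality import ewh_test
from .nomenclature import (
    CANONICAL_LOCUS_ORDER,
    REPORT_LOCUS_ORDER,
    Locus,
    sort_loci,
)
from .phasing import phase_cohort
from .popcompare import (
    bootstrap_supports,
    correspondence_analysis,
    population_allele_matrix,
    sgd_matrix,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    genotypes: str
    out_dir: str
    populations: Optional[str] = None
    loci: Sequence[str] = tuple(l.value for l in CANONICAL_LOCUS_ORDER)
    resolution: int = 1
    hwe: bool = True
    ld: bool = True
    ewh: bool = True
    distances: bool = True
    tree: bool = True
    ca: bool = True
    hwe_replicates: int = 10_000
    ewh_replicates: int = 10_000
    bootstrap_replicates: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None and (self.hwe or self.ewh or self.tree):
            raise ValueError(
                "a seed is required when any Monte Carlo stage is enabled"
            )

    @property
    def locus_objects(self) -> tuple[Locus, ...]:
        return sort_loci(Locus(l) for l in self.loci)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "loci" in data and isinstance(data["loci"], str):
            data["loci"] = data["loci"].split(",")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineReport:
    out_dir: Path
    artifacts: list[str] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig, cohort: Optional[FamilyCohort] = None
) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out)
    loci = config.locus_objects
    res = config.resolution

    if cohort is None:
        cohort = _stage("read")(read_family_genotypes)(config.genotypes)

    founders, phasing_report, _ = _stage("phasing")(phase_cohort)(
        cohort, loci
    )
    haplotypes = [f.haplotype for f in founders]
    lines = [
        f"families_total\t{phasing_report.n_total}",
        f"families_unique\t{phasing_report.n_unique}",
        f"families_ambiguous\t{phasing_report.n_ambiguous}",
        f"families_inconsistent\t{phasing_report.n_inconsistent}",
        f"families_skipped\t{phasing_report.n_skipped}",
        f"founder_chromosomes\t{len(haplotypes)}",
    ] + [f"excluded\t{fid}\t{why}" for fid, why in phasing_report.excluded]
    (out / "phasing_report.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )
    report.artifacts.append("phasing_report.tsv")

    tables = {
        locus: _stage("frequencies")(count_allele_frequencies)(
            haplotypes, locus, res
        )
        for locus in loci
    }
    write_population_frequencies(
        {"cohort": tables}, out / "allele_frequencies.csv"
    )
    report.artifacts.append("allele_frequencies.csv")

    if config.hwe:
        rows = ["locus,p_value,replicates,monomorphic"]
        for i, locus in enumerate(loci):
            genos = founder_genotypes_at_locus(cohort, locus, res)
            r = _stage("hwe")(hwe_exact_test)(
                genos,
                replicates=config.hwe_replicates,
                seed=config.seed + i,
                locus=locus,
            )
            rows.append(
                f"{locus.value},{r.p_value:.6f},{r.replicates},"
                f"{int(r.monomorphic)}"
            )
        (out / "hwe.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
        report.artifacts.append("hwe.csv")

    if config.ld:
        summary_rows = [
            "locus_pair,overall_dprime,wn,w_a_given_b,w_b_given_a,"
            "n_haplotypes"
        ]
        for locus_a, locus_b in combinations(loci, 2):
            summary, rows = _stage("ld")(ld_summary_for_pair)(
                haplotypes, locus_a, locus_b, res
            )
            summary_rows.append(
                f"{locus_a.value}~{locus_b.value},"
                f"{summary.overall_dprime:.4f},{summary.wn:.4f},"
                f"{summary.w_a_given_b:.4f},{summary.w_b_given_a:.4f},"
                f"{summary.n_distinct_haplotypes}"
            )
            ld_table(rows).to_csv(
                out / f"ld_{locus_a.value}_{locus_b.value}.csv",
                index=False,
                float_format="%.6g",
            )
            report.artifacts.append(
                f"ld_{locus_a.value}_{locus_b.value}.csv"
            )
        (out / "ld_summary.csv").write_text(
            "\n".join(summary_rows) + "\n", encoding="utf-8"
        )
        report.artifacts.append("ld_summary.csv")

    if len(loci) > 1:
        hap_table = _stage("haplotypes")(count_haplotype_frequencies)(
            haplotypes, loci, res, render_order=REPORT_LOCUS_ORDER
        )
        write_haplotype_table(hap_table, out / "haplotype_frequencies.csv")
        report.artifacts.append("haplotype_frequencies.csv")

    if config.ewh:
        rows = ["locus,n,k,f_obs,f_exp,sd_f,f_nd,p_value,replicates"]
        for i, locus in enumerate(loci):
            r = _stage("ewh")(ewh_test)(
                tables[locus],
                replicates=config.ewh_replicates,
                seed=config.seed + 100 + i,
            )
            rows.append(
                f"{locus.value},{r.n},{r.k},{r.f_obs:.6f},{r.f_exp:.6f},"
                f"{r.sd_f:.6f},{r.f_nd:.4f},{r.p_value:.6f},{r.replicates}"
            )
        (out / "ewh.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
        report.artifacts.append("ewh.csv")

    if config.populations:
        pops = _stage("populations")(read_population_frequencies)(
            config.populations
        )
        pops = {"cohort": tables, **pops}
        shared = [
            l
            for l in loci
            if all(l in t for t in pops.values())
        ]
        if config.distances and len(pops) >= 2:
            dm = _stage("distances")(sgd_matrix)(pops, shared)
            write_phylip(dm.labels, dm.values, out / "sgd_matrix.phy")
            report.artifacts.append("sgd_matrix.phy")
        if config.tree and len(pops) >= 3:
            tree = _stage("tree")(bootstrap_supports)(
                pops,
                shared,
                replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            (out / "nj_tree.nwk").write_text(
                tree.to_newick() + "\n", encoding="utf-8"
            )
            report.artifacts.append("nj_tree.nwk")
        if config.ca and len(pops) >= 3:
            matrix = population_allele_matrix(pops, shared)
            dims = min(3, min(matrix.shape) - 1)
            ca = _stage("ca")(correspondence_analysis)(matrix, dims=dims)
            coords = ca.row_coords.copy()
            coords.index.name = "population"
            header = "# inertia shares: " + ", ".join(
                f"{s:.4f}" for s in ca.inertia_shares[:dims]
            )
            with (out / "ca_coordinates.csv").open(
                "w", encoding="utf-8"
            ) as fh:
                fh.write(header + "\n")
                coords.to_csv(fh, float_format="%.6f")
            report.artifacts.append("ca_coordinates.csv")
    else:
        report.notices.append(
            "no reference populations supplied; comparison stages skipped"
        )

    manifest = {
        "package": {"hlafam": __version__},
        "versions": _library_versions(),
        "seed": config.seed,
        "config_sha256": config.digest(),
        "families": phasing_report.n_total,
        "families_unique": phasing_report.n_unique,
        "two_n": len(haplotypes),
        "artifacts": report.artifacts,
        "notices": report.notices,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    report.artifacts.append("manifest.json")
    return report


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
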