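"""Packaged reference datasets.

* ``load_emirati_lineage_frequencies`` — published allele-lineage
  frequencies of the Emirati family cohort (100 families, 2n = 400 founder
  chromosomes), direct counts at one-field resolution with binomial SDs.
* ``load_emirati_two_locus_ld`` — published two-locus lineage haplotypes
  whose printed frequency, D' and chi-square are internally consistent with
  the lineage frequencies above (used as the LD verification surface).
* ``load_emirati_five_locus_haplotypes`` — the published 5-locus haplotype
  table (frequencies >= 0.75%), printed in A~B~C~DRB1~DQB1 order.
* ``load_toy_populations`` — a small synthetic 6-population fixture (two
  clusters of three) for exercising distance/tree/ordination machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_population_frequencies
from .nomenclature import Locus


def _data_path(name: str):
    return resources.files("hlafam.data").joinpath(name)


def load_emirati_lineage_frequencies() -> dict[Locus, "object"]:
    """Per-locus :class:`~hlafam.frequencies.FrequencyTable` set for the
    Emirati cohort (2n = 400)."""
    with resources.as_file(
        _data_path("emirati_lineage_frequencies.csv")
    ) as path:
        pops = read_population_frequencies(path)
    return pops["Emirati"]


def load_emirati_lineage_table() -> pd.DataFrame:
    """The raw long-format lineage table, including the printed SD column."""
    with resources.as_file(
        _data_path("emirati_lineage_frequencies.csv")
    ) as path:
        return pd.read_csv(path)


def load_emirati_two_locus_ld() -> pd.DataFrame:
    with resources.as_file(_data_path("emirati_two_locus_ld.csv")) as path:
        return pd.read_csv(path)


def load_emirati_five_locus_haplotypes() -> pd.DataFrame:
    with resources.as_file(
        _data_path("emirati_five_locus_haplotypes.csv")
    ) as path:
        return pd.read_csv(path)


def load_toy_populations():
    """Synthetic 6-population frequency tables (two clusters of three)."""
    with resources.as_file(
        _data_path("toy_populations_synthetic.csv")
    ) as path:
        return read_population_frequencies(path)
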