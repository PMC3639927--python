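"""Packaged published-table fixtures and helpers to consume them.

``table1`` carries, for 13 populations: the pooled aCGH log2 intensity
(relative to the reference population), CNV genotype and allele frequency
percentages, and SNP genotype percentages.  ``table2`` carries, for 31
populations: sample size, the published HWE chi-square and p-value, allele
frequencies and the published LD r-squared.  Values are stored verbatim at
printed precision (including the source's typos in rows not used for
calibration); genotype *counts* are reconstructed from the percentages via
:func:`~lce_cnvpop.popgen_stats.counts_from_percentages`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .popgen_stats import GenotypeCounts, counts_from_percentages

#: Populations appearing in both tables (the pooled-aCGH subset).
TABLE1_POPULATIONS = [
    "PYG", "YRI", "BAN", "ALG", "BED", "FRA", "BRA",
    "HAZ", "CHB", "YAK", "OCE", "PIMA", "MAYA",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("lce_cnvpop.data").joinpath(name).open("rt", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    return _load("table1.tsv")


def load_table2() -> pd.DataFrame:
    return _load("table2.tsv")


def table1_with_n() -> pd.DataFrame:
    """Table-1 rows joined with the per-population sample size from table 2."""
    t1 = load_table1()
    t2 = load_table2()[["population", "n", "hwe_chi2", "hwe_p", "ld_r2"]]
    return t1.merge(t2, on="population", validate="one_to_one")


def cnv_counts_for(row) -> GenotypeCounts:
    """Reconstruct CNV genotype counts for one joined table-1 row."""
    return counts_from_percentages(
        (row["cnv_pp_pct"], row["cnv_het_pct"], row["cnv_mm_pct"]), int(row["n"]), locus="cnv"
    )
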