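"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
Probe table
    Tab-delimited with a leading ``#comparison=<id>`` line, then a header
    naming at least ``chrom  start  end  probe_id  log2_direct  log2_swap``.
    Extra columns are preserved as opaque annotations.  Coordinates are
    0-based half-open; rows sorted by (chrom, start).
Genotype table
    Tab-delimited ``sample_id  population  cnv_genotype  snp_genotype`` with
    genotypes drawn from ``{+/+, +/-, -/-}`` and ``{AA, AG, GG}``; missing
    values use the single token ``NA``.
Regions
    BED6 (0-based half-open); the name column packs
    ``comparison|caller|direction|mean_log2``, the score column is the
    supporting probe count.
Feature intervals
    BED4 with standard BED semantics.
Population summary
    TSV mirroring the published table layout (percentages to 2 decimals,
    chi-square to 2 decimals, r-squared to 3 decimals).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CNV_GENOTYPES,
    CNVRegion,
    MISSING,
    ParseError,
    SNP_GENOTYPES,
    ValidationError,
)

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "log2_direct", "log2_swap"]
GENOTYPE_COLUMNS = ["sample_id", "population", "cnv_genotype", "snp_genotype"]
BED_COLUMNS = ["chrom", "start", "end", "name"]

# Tokens accepted on input for the CNV genotype; canonicalised to ASCII.
_CNV_ALIASES = {
    "+/+": "+/+",
    "+/-": "+/-",
    "-/-": "-/-",
    "+/−": "+/-",   # unicode minus as printed in the source tables
    "−/−": "-/-",
}


@dataclass
class ProbeTable:
    """Probe-level log2 ratios for one test-vs-reference pool comparison."""

    probes: pd.DataFrame
    comparison_id: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.probes
        missing_cols = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"probe table missing columns {missing_cols}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(f"probe row {bad}: start >= end")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        for col in ("log2_direct", "log2_swap"):
            vals = df[col].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite value in {col}")
        # strict sort within chromosome, chromosomes contiguous
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            if len(starts) > 1 and not (np.diff(starts) > 0).all():
                raise ValidationError(f"probes not strictly sorted on {chrom}")

    def __len__(self) -> int:
        return len(self.probes)


def read_probe_table(path, on_unsorted: str = "sort") -> ProbeTable:
    """Read a probe table, validating coordinates and ordering.

    Parameters
    ----------
    path
        TSV file with an optional ``#comparison=<id>`` first line.
    on_unsorted
        ``"sort"`` (default) sorts out-of-order input with a warning;
        ``"error"`` raises :class:`ParseError` instead.
    """
    if on_unsorted not in ("sort", "error"):
        raise ValueError("on_unsorted must be 'sort' or 'error'")
    comparison_id = ""
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        offset = 1
        if first.startswith("#comparison="):
            comparison_id = first.strip().split("=", 1)[1]
            header_line = fh.readline()
            offset = 2
        else:
            header_line = first
        if not header_line.strip():
            raise ParseError("missing header row", path)
        body = header_line + fh.read()
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t", dtype={"chrom": str, "probe_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"unreadable probe table: {exc}", path) from exc
    missing_cols = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing columns {missing_cols}", path, line=offset)
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = offset + 1 + i
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ParseError("non-integer coordinates", path, line=line_no)
        if start >= end:
            raise ParseError(f"start >= end ({start} >= {end})", path, line=line_no)
        for col in ("log2_direct", "log2_swap"):
            v = getattr(row, col)
            if v is not None and not pd.isna(v) and math.isinf(float(v)):
                raise ParseError(f"non-finite {col}", path, line=line_no)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    sorted_df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        if on_unsorted == "error":
            raise ParseError("probe table not sorted by (chrom, start)", path)
        import warnings

        warnings.warn(f"probe table {path} was unsorted; sorting", stacklevel=2)
        df = sorted_df
    else:
        df = df.reset_index(drop=True)
    # canonical column order, extras trailing
    extras = [c for c in df.columns if c not in PROBE_COLUMNS]
    df = df[PROBE_COLUMNS + extras]
    return ProbeTable(probes=df, comparison_id=comparison_id)


def write_probe_table(table: ProbeTable, path) -> None:
    """Write a probe table in canonical form (header line + TSV)."""
    table.validate()
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write(f"#comparison={table.comparison_id}\n")
        table.probes.to_csv(fh, sep="\t", index=False)


def _canonical_cnv(token: str, path, line_no: int, sample: str) -> str:
    if token == MISSING:
        return MISSING
    if token in _CNV_ALIASES:
        return _CNV_ALIASES[token]
    raise ParseError(
        f"sample {sample!r}: illegal CNV genotype token {token!r}", path, line=line_no
    )


def _canonical_snp(token: str, path, line_no: int, sample: str) -> str:
    if token == MISSING:
        return MISSING
    if token == "GA":
        return "AG"
    if token in SNP_GENOTYPES:
        return token
    raise ParseError(
        f"sample {sample!r}: illegal SNP genotype token {token!r}", path, line=line_no
    )


def read_genotype_table(path) -> pd.DataFrame:
    """Read and validate a genotype table.

    Returns a DataFrame with columns ``sample_id, population, cnv_genotype,
    snp_genotype``; missing genotypes carry the token ``NA``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    except Exception as exc:
        raise ParseError(f"unreadable genotype table: {exc}", path) from exc
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing columns {missing_cols}", path, line=1)
    cnv, snp = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        if not row.population:
            raise ParseError(f"sample {row.sample_id!r}: empty population", path, line=line_no)
        cnv.append(_canonical_cnv(row.cnv_genotype, path, line_no, row.sample_id))
        snp.append(_canonical_snp(row.snp_genotype, path, line_no, row.sample_id))
    df = df[GENOTYPE_COLUMNS].copy()
    df["cnv_genotype"] = cnv
    df["snp_genotype"] = snp
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}", path)
    return df.reset_index(drop=True)


def write_genotype_table(df: pd.DataFrame, path) -> None:
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"genotype table missing columns {missing_cols}")
    df[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read feature intervals (BED4; extra columns ignored)."""
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line with <3 fields", path, line=line_no)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, line=line_no)
            if start >= end:
                raise ParseError(f"start >= end ({start} >= {end})", path, line=line_no)
            name = parts[3] if len(parts) > 3 else f"feature_{line_no}"
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(features: pd.DataFrame, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for row in features.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.name}\n")


def write_regions_bed(regions: Sequence[CNVRegion], path) -> None:
    """Write called regions as BED6 (name packs provenance, score = n_probes)."""
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in regions:
            name = f"{r.comparison_id}|{r.caller}|{r.direction}|{r.mean_log2:.4f}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.n_probes}\t.\n")


def read_regions_bed(path) -> list[CNVRegion]:
    """Round-trip reader for :func:`write_regions_bed` output."""
    regions = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("regions BED line with <6 fields", path, line=line_no)
            chrom, start, end, name, score, _strand = parts[:6]
            try:
                comparison_id, caller, direction, mean_log2 = name.split("|")
            except ValueError:
                raise ParseError(f"unparseable region name {name!r}", path, line=line_no)
            regions.append(
                CNVRegion(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    direction=direction,
                    n_probes=int(score),
                    mean_log2=float(mean_log2),
                    caller=caller,
                    comparison_id=comparison_id,
                )
            )
    return regions


SUMMARY_COLUMNS = [
    "population",
    "n",
    "cnv_pp_pct",
    "cnv_het_pct",
    "cnv_mm_pct",
    "cnv_plus_pct",
    "cnv_minus_pct",
    "snp_aa_pct",
    "snp_ag_pct",
    "snp_gg_pct",
    "hwe_chi2",
    "hwe_p",
    "ld_r2",
    "pooled_log2",
]


def _fmt(value, ndigits: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    return f"{value:.{ndigits}f}"


def format_r2(value, compact: bool = True) -> str:
    """Three-decimal r-squared; values >= 0.9995 print as ``1`` when compact."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    if compact and value >= 0.9995:
        return "1"
    return f"{value:.3f}"


def write_population_summary(summaries, path, r2_compact: bool = True) -> None:
    """Write per-population summaries as TSV at published printed precision.

    ``summaries`` is an iterable of :class:`~lce_cnvpop.popgen_stats.PopulationSummary`.
    """
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            hwe_chi2 = s.hwe.chi2 if s.hwe is not None else None
            hwe_p = s.hwe.p_value if s.hwe is not None else None
            fields = [
                s.population,
                str(s.n),
                _fmt(s.cnv_genotype_freqs[0], 2) if s.cnv_genotype_freqs else MISSING,
                _fmt(s.cnv_genotype_freqs[1], 2) if s.cnv_genotype_freqs else MISSING,
                _fmt(s.cnv_genotype_freqs[2], 2) if s.cnv_genotype_freqs else MISSING,
                _fmt(s.cnv_allele_freqs[0], 2) if s.cnv_allele_freqs else MISSING,
                _fmt(s.cnv_allele_freqs[1], 2) if s.cnv_allele_freqs else MISSING,
                _fmt(s.snp_genotype_freqs[0], 2) if s.snp_genotype_freqs else MISSING,
                _fmt(s.snp_genotype_freqs[1], 2) if s.snp_genotype_freqs else MISSING,
                _fmt(s.snp_genotype_freqs[2], 2) if s.snp_genotype_freqs else MISSING,
                _fmt(hwe_chi2, 2),
                _fmt(hwe_p, 2),
                format_r2(s.ld_r2, compact=r2_compact),
                _fmt(s.pooled_log2, 4),
            ]
            fh.write("\t".join(fields) + "\n")


def read_population_summary(path) -> pd.DataFrame:
    """Read a population summary TSV back as a DataFrame (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
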