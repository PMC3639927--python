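"""Per-population genotype statistics: frequencies, Hardy-Weinberg tests,
count reconstruction from printed percentages, and rank correlation.

The Hardy-Weinberg test is the plain 1-df chi-square over the three genotype
classes against expectations from the observed allele frequencies, with no
continuity correction — the convention that reproduces the published
statistics.  Spearman's rho uses midranks for ties and the two-sided t
approximation for its p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CNV_GENOTYPES,
    MISSING,
    SNP_GENOTYPES,
    ValidationError,
)

logger = logging.getLogger(__name__)


class ReconstructionError(ValidationError):
    """No (or no unique) integer genotype counts match the printed percentages."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic locus.

    For the CNV locus the classes are (+/+, +/-, -/-); for the SNP
    (AA, AG, GG).
    """

    locus: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p_value: float
    expected_counts: tuple[float, float, float]
    df: int = 1
    monomorphic: bool = False


@dataclass
class PopulationSummary:
    """One published-table row: per-population frequencies, HWE, LD, intensity."""

    population: str
    n: int
    cnv_genotype_freqs: tuple[float, float, float] | None = None
    snp_genotype_freqs: tuple[float, float, float] | None = None
    cnv_allele_freqs: tuple[float, float] | None = None  # (+%, -%)
    hwe: HWEResult | None = None
    ld_r2: float | None = None
    pooled_log2: float | None = None


def counts_from_percentages(pcts, n: int, locus: str = "cnv") -> GenotypeCounts:
    """Reconstruct integer genotype counts from printed percentages.

    Finds the triple (a, b, c) with a+b+c = n minimising the maximum absolute
    deviation from the targets n*pct/100.  The minimiser must be unique and
    deviate by at most 0.75 counts in every class, otherwise the printed
    percentages are inconsistent with n and a :class:`ReconstructionError`
    is raised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pcts = tuple(float(p) for p in pcts)
    if len(pcts) != 3:
        raise ValueError("need exactly 3 percentages")
    if abs(sum(pcts) - 100.0) > 0.5:
        raise ReconstructionError(f"percentages {pcts} do not sum to ~100")
    targets = [n * p / 100.0 for p in pcts]
    best_dev = math.inf
    best = None
    ties = 0
    for a in range(n + 1):
        for b in range(n + 1 - a):
            c = n - a - b
            dev = max(abs(a - targets[0]), abs(b - targets[1]), abs(c - targets[2]))
            if dev < best_dev - 1e-9:
                best_dev, best, ties = dev, (a, b, c), 1
            elif abs(dev - best_dev) <= 1e-9:
                ties += 1
    if best is None or best_dev > 0.75:
        raise ReconstructionError(
            f"no integer counts within 0.75 of targets {targets} (n={n})"
        )
    if ties > 1:
        raise ReconstructionError(
            f"count reconstruction ambiguous for percentages {pcts} at n={n}"
        )
    return GenotypeCounts(locus, *best)


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(p_ref, p_alt) from genotype counts; alt carries the het + 2*hom_alt dose."""
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute allele frequencies with n = 0")
    p_alt = (counts.n_het + 2 * counts.n_hom_alt) / (2 * n)
    return (1.0 - p_alt, p_alt)


def hwe_chi2(counts: GenotypeCounts) -> HWEResult:
    """Uncorrected 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts are (n*p^2, 2npq, n*q^2) from the observed allele
    frequencies.  A monomorphic locus is reported as chi2 = 0, p = 1 and
    flagged rather than raising.
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot test HWE with n = 0")
    p_ref, p_alt = allele_frequencies(counts)
    expected = (n * p_ref**2, 2 * n * p_ref * p_alt, n * p_alt**2)
    if p_ref == 0.0 or p_alt == 0.0:
        return HWEResult(chi2=0.0, p_value=1.0, expected_counts=expected, monomorphic=True)
    observed = counts.as_tuple()
    chi2 = sum(
        (o - e) ** 2 / e if e > 0 else 0.0 for o, e in zip(observed, expected)
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=float(chi2), p_value=p_value, expected_counts=expected)


def spearman_correlation(
    x, y, exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation with midranks and a two-sided t-approximate p.

    rho is the Pearson correlation of the midrank vectors (identical to
    1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties).  The p-value uses
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df; |rho| = 1 reports p = 0.0.
    ``exact=True`` (n <= 10 only) computes the permutation p-value instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) > 1.0 - 1e-12:  # snap float noise on perfectly ranked data
        rho = math.copysign(1.0, rho)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0 - 1e-15:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def _genotype_counts(series: pd.Series, classes, locus: str) -> GenotypeCounts | None:
    observed = series[series != MISSING]
    if len(observed) == 0:
        return None
    vc = observed.value_counts()
    return GenotypeCounts(locus, *(int(vc.get(g, 0)) for g in classes))


def population_summaries(
    genotypes: pd.DataFrame,
    pooled_log2: dict[str, float] | None = None,
) -> list[PopulationSummary]:
    """Assemble one summary row per population (input order preserved).

    Missing genotypes are excluded per locus; HWE is computed on the CNV
    locus; LD r-squared is the EM estimate from the complete-case CNV x SNP
    cross-table (missing when either locus is absent or monomorphic).
    """
    from .ld_analysis import em_haplotypes, ld_from_haplotypes, tabulate_joint

    pooled_log2 = pooled_log2 or {}
    summaries = []
    for population in genotypes["population"].drop_duplicates():
        sub = genotypes[genotypes["population"] == population]
        cnv_counts = _genotype_counts(sub["cnv_genotype"], CNV_GENOTYPES, "cnv")
        snp_counts = _genotype_counts(sub["snp_genotype"], SNP_GENOTYPES, "snp")
        summary = PopulationSummary(
            population=population,
            n=cnv_counts.n if cnv_counts else 0,
            pooled_log2=pooled_log2.get(population),
        )
        if cnv_counts is None:
            logger.warning("population %s has no CNV genotypes; empty summary row", population)
            summaries.append(summary)
            continue
        n = cnv_counts.n
        summary.cnv_genotype_freqs = tuple(100.0 * c / n for c in cnv_counts.as_tuple())
        p_plus, p_minus = allele_frequencies(cnv_counts)
        summary.cnv_allele_freqs = (100.0 * p_plus, 100.0 * p_minus)
        summary.hwe = hwe_chi2(cnv_counts)
        if snp_counts is not None and snp_counts.n > 0:
            m = snp_counts.n
            summary.snp_genotype_freqs = tuple(100.0 * c / m for c in snp_counts.as_tuple())
            try:
                joint = tabulate_joint(genotypes, population)
                ld = ld_from_haplotypes(em_haplotypes(joint))
                summary.ld_r2 = ld.r2
            except (ValueError, ValidationError) as exc:
                logger.warning("population %s: LD unavailable (%s)", population, exc)
        summaries.append(summary)
    return summaries
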