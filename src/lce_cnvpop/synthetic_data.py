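"""Synthetic genotype and pooled-aCGH data with the structure the analysis assumes.

Individuals are formed by random union of gametes: each of the two haplotypes
is drawn i.i.d. from the population's four two-locus haplotype frequencies
over {(+,A), (+,G), (-,A), (-,G)}, so Hardy-Weinberg proportions hold in
expectation at each locus and the CNV x SNP linkage structure is exactly the
configured one.

Pools are exact allele-frequency mixtures of the simulated individuals.  A
probe inside the deletion interval measures, in expectation,

    attenuation * log2(p_nondel_test / p_nondel_ref)

because a pool's mean diploid copy number at a deletion locus is twice its
non-deleted allele frequency.  The attenuation factor is a phenomenological
stand-in for the signal compression observed on pooled two-channel arrays.
Dye swap is modelled as a sign flip plus independent Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CNV_HET,
    CNV_HOM_ALT,
    CNV_HOM_REF,
    CNVRegion,
    ConfigError,
    GAIN,
    LOSS,
    ValidationError,
)
from .io_formats import GENOTYPE_COLUMNS, PROBE_COLUMNS, ProbeTable

#: Haplotype order used everywhere: (CNV allele, SNP allele).
HAPLOTYPES = (("+", "A"), ("+", "G"), ("-", "A"), ("-", "G"))

#: Deletion interval used by the default configuration (0-based half-open,
#: hg18; span 32,199 bp).
DEFAULT_DELETION = ("chr1", 150_822_166, 150_854_365)

_CNV_FROM_DEL_COUNT = {0: CNV_HOM_REF, 1: CNV_HET, 2: CNV_HOM_ALT}
_SNP_FROM_G_COUNT = {0: "AA", 1: "AG", 2: "GG"}


@dataclass(frozen=True)
class PopulationModel:
    """A population: sample size and two-locus haplotype frequencies."""

    name: str
    n_individuals: int
    haplotype_freqs: tuple[float, float, float, float]

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if freqs.shape != (4,):
            raise ValidationError("haplotype_freqs must have 4 entries")
        if (freqs < 0).any():
            raise ValidationError("haplotype frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValidationError("haplotype frequencies must sum to 1 (tol 1e-12)")

    @property
    def p_nondel(self) -> float:
        """Expected frequency of the non-deleted ('+') allele."""
        return self.haplotype_freqs[0] + self.haplotype_freqs[1]


@dataclass(frozen=True)
class ACGHSimParams:
    """Parameters of the pooled array simulation.

    Probes tile an absolute genomic grid at ``probe_spacing`` (probe interval
    ``[k*spacing, k*spacing + probe_length)``); a probe reports the deletion
    signal when its midpoint falls inside ``deletion_interval``.
    """

    seed: int
    probe_spacing: int = 10_000
    noise_sd: float = 0.1
    attenuation: float = 0.5
    deletion_interval: tuple[str, int, int] = DEFAULT_DELETION
    flank_probes: int = 5
    probe_length: int = 0  # 0 -> contiguous tiling (probe_length = spacing)
    min_probes: int = 3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 < self.attenuation <= 1):
            raise ConfigError("attenuation must be in (0, 1]")
        if self.probe_spacing < 1:
            raise ConfigError("probe_spacing must be >= 1")
        chrom, start, end = self.deletion_interval
        if start >= end:
            raise ConfigError("deletion_interval start >= end")

    @property
    def effective_probe_length(self) -> int:
        return self.probe_length if self.probe_length > 0 else self.probe_spacing


def simulate_genotypes(model: PopulationModel, seed) -> pd.DataFrame:
    """Simulate individual genotypes for one population.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Returns rows in
    the genotype-table schema, sample ids ``<name>_0001`` ...
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.asarray(model.haplotype_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    haps = rng.choice(4, size=(model.n_individuals, 2), p=freqs)
    # haplotype index: bit 1 (>=2) -> deleted CNV allele; odd index -> G allele
    del_counts = (haps >= 2).sum(axis=1)
    g_counts = (haps % 2).sum(axis=1)
    width = max(4, len(str(model.n_individuals)))
    rows = {
        "sample_id": [f"{model.name}_{i + 1:0{width}d}" for i in range(model.n_individuals)],
        "population": [model.name] * model.n_individuals,
        "cnv_genotype": [_CNV_FROM_DEL_COUNT[c] for c in del_counts],
        "snp_genotype": [_SNP_FROM_G_COUNT[c] for c in g_counts],
    }
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def expected_pool_log2(p_nondel_test: float, p_nondel_ref: float, attenuation: float) -> float:
    """Expected pooled log2 ratio at a deletion probe.

    The pool's mean diploid copy number is ``2 * p_nondel`` (genotypes
    +/+, +/-, -/- carry 2, 1, 0 copies), so the test/reference copy ratio is
    ``p_nondel_test / p_nondel_ref``; the result is attenuated.
    """
    if not (0 < p_nondel_test <= 1):
        raise ValueError("p_nondel_test must be in (0, 1]")
    if not (0 < p_nondel_ref <= 1):
        raise ValueError("p_nondel_ref must be in (0, 1]")
    if not (0 < attenuation <= 1):
        raise ValueError("attenuation must be in (0, 1]")
    return attenuation * math.log2(p_nondel_test / p_nondel_ref)


def realised_nondel_frequency(genotypes: pd.DataFrame, population: str) -> float:
    """Non-deleted allele frequency realised in a simulated pool."""
    sub = genotypes[genotypes["population"] == population]
    sub = sub[sub["cnv_genotype"] != "NA"]
    n = len(sub)
    if n == 0:
        raise ValueError(f"population {population!r} has no CNV genotypes")
    counts = sub["cnv_genotype"].value_counts()
    plus = 2 * counts.get(CNV_HOM_REF, 0) + counts.get(CNV_HET, 0)
    return plus / (2 * n)


def probe_grid(params: ACGHSimParams) -> pd.DataFrame:
    """Probe intervals tiling the deletion plus flanks; marks inside probes."""
    chrom, del_start, del_end = params.deletion_interval
    s = params.probe_spacing
    plen = params.effective_probe_length
    first_inside = math.ceil(del_start / s)
    last_inside = (del_end - 1) // s
    starts = []
    inside = []
    for k in range(first_inside - params.flank_probes, last_inside + params.flank_probes + 1):
        if k < 0:
            continue
        start = k * s
        mid = start + plen // 2
        starts.append(start)
        inside.append(del_start <= mid < del_end)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(starts, dtype=np.int64) + plen,
            "probe_id": [f"P{int(st):012d}" for st in starts],
            "inside": inside,
        }
    )
    n_inside = int(df["inside"].sum())
    if n_inside < params.min_probes:
        raise ConfigError(
            f"deletion interval covered by only {n_inside} probes at spacing "
            f"{s} (need >= {params.min_probes})"
        )
    return df


@dataclass
class SimulationResult:
    """Bundle returned by :func:`simulate_pool_acgh`."""

    genotypes: pd.DataFrame
    probe_tables: dict[str, ProbeTable]
    truth_regions: list[CNVRegion]
    pool_frequencies: dict[str, float] = field(default_factory=dict)


def simulate_pool_acgh(
    models: list[PopulationModel],
    reference: PopulationModel,
    params: ACGHSimParams,
) -> SimulationResult:
    """Simulate genotypes and one pooled probe table per test-vs-reference pair.

    Deterministic given ``params.seed``: population genotype draws and probe
    noise each consume an independent child stream of the seed.
    """
    names = [m.name for m in models] + [reference.name]
    if len(set(names)) != len(names):
        raise ConfigError("population names must be unique")

    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(models) + 1 + len(models))
    geno_frames = []
    for model, child in zip(models + [reference], children[: len(models) + 1]):
        geno_frames.append(simulate_genotypes(model, np.random.default_rng(child)))
    genotypes = pd.concat(geno_frames, ignore_index=True)

    pool_freqs = {m.name: realised_nondel_frequency(genotypes, m.name) for m in models}
    pool_freqs[reference.name] = realised_nondel_frequency(genotypes, reference.name)
    grid = probe_grid(params)
    chrom, del_start, del_end = params.deletion_interval
    n_inside = int(grid["inside"].sum())

    # A pool that happens to be fixed for the deletion would give log2(0);
    # clamp the realised frequency to half an allele count.
    def _clamped(name: str, n: int) -> float:
        return max(pool_freqs[name], 1.0 / (4 * n))

    p_ref = _clamped(reference.name, reference.n_individuals)

    probe_tables: dict[str, ProbeTable] = {}
    truth: list[CNVRegion] = []
    for model, child in zip(models, children[len(models) + 1 :]):
        rng = np.random.default_rng(child)
        comparison_id = f"{model.name}_vs_{reference.name}"
        mu = expected_pool_log2(_clamped(model.name, model.n_individuals), p_ref, params.attenuation)
        mean = np.where(grid["inside"].to_numpy(), mu, 0.0)
        direct = mean + (
            rng.normal(0.0, params.noise_sd, size=len(grid)) if params.noise_sd > 0 else 0.0
        )
        swap = -mean + (
            rng.normal(0.0, params.noise_sd, size=len(grid)) if params.noise_sd > 0 else 0.0
        )
        df = grid[["chrom", "start", "end", "probe_id"]].copy()
        df["log2_direct"] = direct
        df["log2_swap"] = swap
        probe_tables[comparison_id] = ProbeTable(probes=df[PROBE_COLUMNS], comparison_id=comparison_id)
        if abs(mu) > 1e-12:
            truth.append(
                CNVRegion(
                    chrom=chrom,
                    start=del_start,
                    end=del_end,
                    direction=LOSS if mu < 0 else GAIN,
                    n_probes=n_inside,
                    mean_log2=mu,
                    caller="truth",
                    comparison_id=comparison_id,
                )
            )
    return SimulationResult(
        genotypes=genotypes,
        probe_tables=probe_tables,
        truth_regions=truth,
        pool_frequencies=pool_freqs,
    )
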