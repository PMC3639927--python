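"""Two-locus haplotype frequency estimation by EM and derived LD statistics.

Unphased diploid genotypes at the deletion (+/-) and the tag SNP (A/G) leave
exactly one phase ambiguity: the double heterozygote (+/-, AG), which is
either (+A, -G) or (+G, -A).  The E-step splits that cell in proportion to
the current haplotype-frequency products; every other cell contributes its
two gametes deterministically.  The log-likelihood is the multinomial over
the nine genotype cells with Hardy-Weinberg haplotype pairing and is
non-decreasing across iterations (asserted).

LD statistics follow the deletion/tag-allele orientation: D is the excess of
the (-, G) haplotype over linkage equilibrium.  r-squared is orientation-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CNV_GENOTYPES, MISSING, SNP_GENOTYPES, ValidationError

#: Haplotype order: (+A, +G, -A, -G).
HAP_LABELS = ("+A", "+G", "-A", "-G")

# Gametes contributed by each unambiguous genotype cell (i = count of "-"
# alleles, j = count of G alleles); cell (1,1) is the ambiguous one.
_CELL_GAMETES = {
    (0, 0): (2, 0, 0, 0),
    (0, 1): (1, 1, 0, 0),
    (0, 2): (0, 2, 0, 0),
    (1, 0): (1, 0, 1, 0),
    (1, 2): (0, 1, 0, 1),
    (2, 0): (0, 0, 2, 0),
    (2, 1): (0, 0, 1, 1),
    (2, 2): (0, 0, 0, 2),
}


@dataclass(frozen=True)
class HaplotypeFrequencies:
    freqs: tuple[float, float, float, float]  # (+A, +G, -A, -G)
    log_likelihood: float
    n_iterations: int
    converged: bool

    def __post_init__(self):
        if abs(sum(self.freqs) - 1.0) > 1e-10:
            raise ValidationError("haplotype frequencies must sum to 1 (tol 1e-10)")


@dataclass(frozen=True)
class LDResult:
    D: float | None
    D_prime: float | None
    r2: float | None
    p_plus: float
    p_minus: float
    p_A: float
    p_G: float

    @property
    def defined(self) -> bool:
        return self.r2 is not None


def tabulate_joint(genotypes: pd.DataFrame, population: str) -> np.ndarray:
    """3x3 complete-case cross-table, CNV genotype (rows) x SNP genotype (cols)."""
    sub = genotypes[genotypes["population"] == population]
    if len(sub) == 0:
        raise ValueError(f"population {population!r} not present")
    complete = sub[(sub["cnv_genotype"] != MISSING) & (sub["snp_genotype"] != MISSING)]
    if len(complete) == 0:
        raise ValueError(f"population {population!r} has no complete CNV+SNP genotypes")
    counts = np.zeros((3, 3), dtype=np.int64)
    cnv_index = {g: i for i, g in enumerate(CNV_GENOTYPES)}
    snp_index = {g: j for j, g in enumerate(SNP_GENOTYPES)}
    for row in complete.itertuples(index=False):
        counts[cnv_index[row.cnv_genotype], snp_index[row.snp_genotype]] += 1
    return counts


def genotype_cell_probs(freqs) -> np.ndarray:
    """3x3 genotype-cell probabilities under random haplotype pairing."""
    f_pA, f_pG, f_mA, f_mG = freqs
    return np.array(
        [
            [f_pA**2, 2 * f_pA * f_pG, f_pG**2],
            [2 * f_pA * f_mA, 2 * (f_pA * f_mG + f_pG * f_mA), 2 * f_pG * f_mG],
            [f_mA**2, 2 * f_mA * f_mG, f_mG**2],
        ]
    )


def loglik(counts: np.ndarray, freqs) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given haplotype freqs."""
    probs = genotype_cell_probs(freqs)
    ll = 0.0
    for idx in np.ndindex(3, 3):
        n = counts[idx]
        if n > 0:
            p = probs[idx]
            if p <= 0:
                return -math.inf
            ll += n * math.log(p)
    return ll


def _base_gamete_counts(counts: np.ndarray) -> np.ndarray:
    base = np.zeros(4)
    for cell, gametes in _CELL_GAMETES.items():
        n = counts[cell]
        if n:
            base += n * np.asarray(gametes, dtype=float)
    return base


def em_haplotypes(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> HaplotypeFrequencies:
    """EM estimate of the four haplotype frequencies from a 3x3 genotype table.

    Initialised at linkage equilibrium of the observed allele frequencies;
    iterates until the largest frequency change drops below ``tol`` or
    ``max_iter`` is reached (then flagged unconverged).  When the
    double-heterozygote cell is empty the first M-step equals direct gamete
    counting and the algorithm stops immediately.
    """
    counts = np.asarray(counts)
    if counts.shape != (3, 3) or (counts < 0).any():
        raise ValueError("counts must be a non-negative 3x3 matrix")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty genotype table")
    two_n = 2 * n
    n_dh = int(counts[1, 1])
    base = _base_gamete_counts(counts)

    # linkage-equilibrium start from marginal allele frequencies
    p_minus = (counts[1, :].sum() + 2 * counts[2, :].sum()) / two_n
    p_G = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / two_n
    freqs = np.array(
        [
            (1 - p_minus) * (1 - p_G),
            (1 - p_minus) * p_G,
            p_minus * (1 - p_G),
            p_minus * p_G,
        ]
    )
    if freqs.sum() <= 0:  # degenerate; uniform start
        freqs = np.full(4, 0.25)
    freqs = freqs / freqs.sum()

    prev_ll = loglik(counts, freqs)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step: split the double-het cell between the two phases
        cis = freqs[0] * freqs[3]   # (+A, -G)
        trans = freqs[1] * freqs[2]  # (+G, -A)
        denom = cis + trans
        w_cis = cis / denom if denom > 0 else 0.5
        expected = base + n_dh * np.array([w_cis, 1 - w_cis, 1 - w_cis, w_cis])
        # M-step
        new_freqs = expected / two_n
        delta = float(np.max(np.abs(new_freqs - freqs)))
        freqs = new_freqs
        ll = loglik(counts, freqs)
        if ll < prev_ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll} at iteration {iterations}"
            )
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    return HaplotypeFrequencies(
        freqs=tuple(float(f) for f in freqs),
        log_likelihood=prev_ll,
        n_iterations=iterations,
        converged=converged,
    )


def direct_haplotype_counts(counts: np.ndarray) -> tuple[float, float, float, float]:
    """Gamete-counting estimate, valid only when the double-het cell is empty."""
    counts = np.asarray(counts)
    if counts[1, 1] != 0:
        raise ValueError("direct counting undefined with double heterozygotes present")
    base = _base_gamete_counts(counts)
    return tuple(base / base.sum())


def ld_from_haplotypes(h: HaplotypeFrequencies) -> LDResult:
    """D, D' and r-squared from haplotype frequencies.

    D is oriented on the (deleted, G) haplotype: D = f(-G) - p(-)*p(G).
    A locus monomorphic in the sample leaves D'/r-squared undefined; the
    result then carries ``None`` rather than raising.
    """
    f_pA, f_pG, f_mA, f_mG = h.freqs
    p_plus, p_minus = f_pA + f_pG, f_mA + f_mG
    p_A, p_G = f_pA + f_mA, f_pG + f_mG
    if min(p_plus, p_minus, p_A, p_G) <= 1e-12:
        return LDResult(None, None, None, p_plus, p_minus, p_A, p_G)
    D = f_mG - p_minus * p_G
    if D >= 0:
        d_max = min(p_minus * p_A, p_plus * p_G)
    else:
        d_max = min(p_minus * p_G, p_plus * p_A)
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D**2 / (p_plus * p_minus * p_A * p_G)
    return LDResult(float(D), float(d_prime), float(min(r2, 1.0)), p_plus, p_minus, p_A, p_G)


def grid_max_loglik(counts: np.ndarray, step: float = 0.01) -> float:
    """Brute-force maximum log-likelihood over a simplex grid (test oracle).

    Enumerates every frequency vector (i, j, k, m-i-j-k)/m on the 3-simplex
    and returns the best multinomial log-likelihood.  The likelihood
    decomposes into per-haplotype gamete-count terms plus one term for the
    double-heterozygote cell, so each grid point costs only precomputed-log
    table lookups; a 0.001 step (~1.7e8 points) stays tractable.
    """
    counts = np.asarray(counts, dtype=np.int64)
    m = int(round(1.0 / step))
    base = _base_gamete_counts(counts)  # log-f coefficients, unambiguous cells
    n_dh = int(counts[1, 1])
    # multiplicity-of-2 constant for the four single-het cells + double-het
    n_het_cells = int(counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1] + n_dh)
    const = n_het_cells * math.log(2.0)

    with np.errstate(divide="ignore"):
        log_f = np.log(np.arange(m + 1) / m)  # log_f[0] = -inf
        # cross term f0*f3 + f1*f2 = (i*l + j*k) / m^2
        log_cross = np.log(np.arange((m // 2) ** 2 + m + 1).astype(float)) - 2 * math.log(m)

    best = -math.inf
    for i in range(m + 1):
        reps = np.arange(m + 1 - i, 0, -1)  # k choices for each j
        jj = np.repeat(np.arange(m + 1 - i), reps)
        kk = np.concatenate([np.arange(r) for r in reps])
        ll_idx = m - i - jj - kk
        block = np.zeros(len(jj))
        if base[0] > 0:
            block += base[0] * log_f[i]
        if base[1] > 0:
            block += base[1] * log_f[jj]
        if base[2] > 0:
            block += base[2] * log_f[kk]
        if base[3] > 0:
            block += base[3] * log_f[ll_idx]
        if n_dh > 0:
            block += n_dh * log_cross[i * ll_idx + jj * kk]
        block_best = float(np.max(block))
        if block_best > best:
            best = block_best
    return best + const


def ld_table(genotypes: pd.DataFrame, populations=None) -> pd.DataFrame:
    """Per-population haplotype frequencies and LD statistics as a DataFrame."""
    if populations is None:
        populations = list(genotypes["population"].drop_duplicates())
    rows = []
    for population in populations:
        try:
            joint = tabulate_joint(genotypes, population)
        except ValueError:
            rows.append({"population": population, "n": 0})
            continue
        h = em_haplotypes(joint)
        ld = ld_from_haplotypes(h)
        rows.append(
            {
                "population": population,
                "n": int(joint.sum()),
                "f_plusA": h.freqs[0],
                "f_plusG": h.freqs[1],
                "f_minusA": h.freqs[2],
                "f_minusG": h.freqs[3],
                "D": ld.D,
                "D_prime": ld.D_prime,
                "r2": ld.r2,
                "converged": h.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "n",
            "f_plusA",
            "f_plusG",
            "f_minusA",
            "f_minusG",
            "D",
            "D_prime",
            "r2",
            "converged",
        ],
    )
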