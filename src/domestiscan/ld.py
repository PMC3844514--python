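"""Linkage disequilibrium from unphased genotypes: two-locus EM and r² decay.

Phase is unobserved in a diploid genotype panel, so haplotype frequencies for
a pair of biallelic loci are estimated by EM under random mating: every
genotype combination except the double heterozygote resolves its two
haplotypes unambiguously; the double heterozygote is split between the
coupling (AB/ab) and repulsion (Ab/aB) configurations in proportion to their
current expected frequencies. r² is then D²/(pA(1-pA)pB(1-pB)).

The EM kernel is vectorised over pairs so whole-chromosome decay curves stay
cheap; ``em_haplotype_freqs`` is the single-pair convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import GenotypeMatrix, PopulationMap

EM_TOL = 1e-9
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class LdConfig:
    """LD scan parameters (defaults match a Haploview-style run).

    max_distance: largest pair separation scored, bp (1,000 kb).
    min_maf: within-pool minor allele frequency floor.
    min_geno: within-pool per-site call-rate floor.
    hw_cutoff: Hardy–Weinberg exact-test p floor; 0 disables the filter.
    bin_width: decay-curve distance bin, bp.
    """

    max_distance: int = 1_000_000
    min_maf: float = 0.1
    min_geno: float = 0.6
    hw_cutoff: float = 0.0
    bin_width: int = 5_000

    def __post_init__(self):
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("require 0 <= min_maf < 0.5")
        if not 0 < self.min_geno <= 1:
            raise ValueError("require 0 < min_geno <= 1")


# ---------------------------------------------------------------------------
# EM over genotype-combination count tables
# ---------------------------------------------------------------------------

def _pair_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """9-cell counts n[3*ga+gb] per pair; rows = pairs, samples with a missing
    call at either locus are dropped pairwise."""
    ga = np.atleast_2d(ga)
    gb = np.atleast_2d(gb)
    valid = (ga >= 0) & (gb >= 0)
    code = np.where(valid, 3 * ga.astype(np.int64) + gb.astype(np.int64), 9)
    counts = np.zeros((code.shape[0], 10), dtype=np.int64)
    for c in range(10):
        counts[:, c] = (code == c).sum(axis=1)
    return counts[:, :9]


def em_from_counts(counts: np.ndarray, tol: float = EM_TOL,
                   max_iter: int = EM_MAX_ITER) -> np.ndarray:
    """ML haplotype frequencies (pAB, pAb, paB, pab) from 9-cell count tables.

    ``counts`` is (P, 9) with cell index 3*dosage_A + dosage_B (dosage of the
    "A"/"B" allele, here the alt allele at each locus). Returns (P, 4).
    A = alt at locus 1, B = alt at locus 2.
    """
    counts = np.atleast_2d(counts).astype(float)
    n = counts
    # unambiguous haplotype counts per pair (cell index = 3*dosA + dosB)
    k_AB = 2 * n[:, 8] + n[:, 7] + n[:, 5]          # from (2,2),(2,1),(1,2)
    k_Ab = 2 * n[:, 6] + n[:, 7] + n[:, 3]          # from (2,0),(2,1),(1,0)
    k_aB = 2 * n[:, 2] + n[:, 1] + n[:, 5]          # from (0,2),(0,1),(1,2)
    k_ab = 2 * n[:, 0] + n[:, 1] + n[:, 3]          # from (0,0),(0,1),(1,0)
    dh = n[:, 4]                                    # double heterozygotes
    total = k_AB + k_Ab + k_aB + k_ab + 2 * dh
    if np.any(total == 0):
        raise ValueError("a pair has no double-called individuals")

    f = np.stack([k_AB + 0.5 * dh, k_Ab + 0.5 * dh,
                  k_aB + 0.5 * dh, k_ab + 0.5 * dh], axis=1) / total[:, None]
    for _ in range(max_iter):
        coupling = f[:, 0] * f[:, 3]
        repulsion = f[:, 1] * f[:, 2]
        denom = coupling + repulsion
        w = np.where(denom > 0, coupling / np.where(denom > 0, denom, 1.0), 0.5)
        new = np.stack([
            k_AB + w * dh, k_Ab + (1 - w) * dh,
            k_aB + (1 - w) * dh, k_ab + w * dh,
        ], axis=1) / total[:, None]
        delta = np.abs(new - f).max()
        f = new
        if delta < tol:
            break
    return f


def em_haplotype_freqs(genotypes_a, genotypes_b) -> tuple[float, float, float, float]:
    """ML (pAB, pAb, paB, pab) for one locus pair of unphased dosages.

    Returned order: alt-alt, alt-ref, ref-alt, ref-ref (A = alt at locus a,
    B = alt at locus b). Missing dosages (-1) drop the individual pairwise.
    """
    ga = np.asarray(genotypes_a, dtype=np.int8)
    gb = np.asarray(genotypes_b, dtype=np.int8)
    if ga.shape != gb.shape:
        raise ValueError("locus dosage vectors must align")
    counts = _pair_counts(ga[None, :], gb[None, :])
    if ((ga >= 0) & (gb >= 0)).sum() < 2:
        raise ValueError("need >= 2 double-called individuals")
    f = em_from_counts(counts)[0]
    return float(f[0]), float(f[1]), float(f[2]), float(f[3])


def genotype_loglik(counts: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of 9-cell genotype counts under haplotype freqs.

    Used to compare the EM solution against brute-force search. ``freqs`` is
    (P, 4) as (pAB, pAb, paB, pab).
    """
    counts = np.atleast_2d(counts).astype(float)
    f = np.atleast_2d(freqs)
    pAB, pAb, paB, pab = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    probs = np.stack([
        pab ** 2,                       # (0,0)
        2 * paB * pab,                  # (0,1)
        paB ** 2,                       # (0,2)
        2 * pAb * pab,                  # (1,0)
        2 * (pAB * pab + pAb * paB),    # (1,1)
        2 * pAB * paB,                  # (1,2)
        pAb ** 2,                       # (2,0)
        2 * pAB * pAb,                  # (2,1)
        pAB ** 2,                       # (2,2)
    ], axis=1)
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), -np.inf)
    term = np.where(counts > 0, counts * logp, 0.0)
    return term.sum(axis=1)


def r2_from_freqs(freqs) -> float:
    """r² = D² / (pA(1-pA) pB(1-pB)) from (pAB, pAb, paB, pab).

    NaN if either locus is monomorphic under the fitted frequencies.
    """
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    pA = f[:, 0] + f[:, 1]
    pB = f[:, 0] + f[:, 2]
    d = f[:, 0] - pA * pB
    var = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var > 0, d * d / np.where(var > 0, var, 1.0), np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    return float(r2[0]) if np.isscalar(freqs[0]) or np.ndim(freqs) == 1 else r2


# ---------------------------------------------------------------------------
# Decay curve
# ---------------------------------------------------------------------------

def ld_decay(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pool: str,
    config: LdConfig = LdConfig(),
) -> pd.DataFrame:
    """Binned mean r² against pair distance for one pool.

    Sites must pass ``min_maf`` and ``min_geno`` within the pool (and the HWE
    exact test when ``hw_cutoff`` > 0); all remaining intra-chromosomal pairs
    within ``max_distance`` are scored. Columns: pool, bin_start, bin_end,
    n_pairs, mean_r2. Deterministic given input.
    """
    idx = popmap.indices(matrix, pool)
    if len(idx) < 4:
        raise ValueError("pool needs >= 4 samples for LD")
    calls = matrix.calls[:, idx]
    called = calls >= 0
    n_called = called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, np.where(called, calls, 0).sum(axis=1)
                     / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (maf >= config.min_maf) & (n_called / len(idx) >= config.min_geno)
    if config.hw_cutoff > 0:
        keep &= _hwe_pvalues(calls) >= config.hw_cutoff

    dists, r2s = [], []
    chrom_arr = matrix.chrom.astype(str)
    for chrom in matrix.chromosomes():
        on = (chrom_arr == chrom) & keep
        cpos = matrix.pos[on]
        g = calls[on]
        m = len(cpos)
        if m < 2:
            continue
        hi = np.searchsorted(cpos, cpos + config.max_distance, side="right")
        ii, jj = [], []
        for i in range(m - 1):
            j = np.arange(i + 1, hi[i])
            ii.append(np.full(len(j), i))
            jj.append(j)
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        counts = _pair_counts(g[ii], g[jj])
        ok = counts.sum(axis=1) >= 2
        freqs = em_from_counts(counts[ok])
        r2 = r2_from_freqs(freqs)
        d = (cpos[jj] - cpos[ii])[ok]
        fin = np.isfinite(r2)
        dists.append(d[fin])
        r2s.append(r2[fin])

    if not dists:
        return pd.DataFrame(columns=["pool", "bin_start", "bin_end", "n_pairs", "mean_r2"])
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    nbins = int(np.ceil(config.max_distance / config.bin_width))
    which = np.minimum(d // config.bin_width, nbins - 1).astype(int)
    rows = []
    for b in range(nbins):
        sel = which == b
        if not sel.any():
            continue
        rows.append((pool, b * config.bin_width, (b + 1) * config.bin_width,
                     int(sel.sum()), float(r2[sel].mean())))
    return pd.DataFrame(rows, columns=["pool", "bin_start", "bin_end", "n_pairs", "mean_r2"])


def _hwe_pvalues(calls: np.ndarray) -> np.ndarray:
    """Chi-square HWE p per site from genotype counts (1 df)."""
    from scipy.stats import chi2

    called = calls >= 0
    n = called.sum(axis=1).astype(float)
    n_het = (calls == 1).sum(axis=1)
    n_alt = np.where(called, calls, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = n_alt / (2 * n)
        exp_het = 2 * p * (1 - p) * n
        stat = np.where(exp_het > 0, (n_het - exp_het) ** 2 / np.where(exp_het > 0, exp_het, 1.0), 0.0)
    # crude 1-df statistic on heterozygote deficit/excess
    return 1.0 - chi2.cdf(stat, df=1)
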