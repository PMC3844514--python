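"""Windowed nucleotide-diversity statistics: θπ, Watterson's θw, Tajima's D.

All estimators work on unphased diploid dosages via within-pool allele counts.
Per-site π is the fraction of differing pairs among the ``n`` called alleles at
the site; window-level θπ/θw are per-bp, dividing by the full window length by
default (monomorphic positions count — the panel derives from whole-genome
sequencing, so diversity is comparable across pools and windows).

Missing data: each site uses its own called-allele count ``n``; the single
``n`` that θw and Tajima's D need per window is the median per-site ``n`` of
the in-window usable sites. Windows with median n < 4 or no segregating sites
get an undefined (NaN) D, which downstream scans treat as "not significant".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import GenotypeMatrix, Interval, PopulationMap


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp (default 20 kb windows, 2 kb step)."""

    size: int = 20_000
    step: int = 2_000

    def __post_init__(self):
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")


def site_pi(alt_count: int, called_alleles: int) -> float:
    """Per-site heterozygosity 2j(n-j)/(n(n-1)): mean pairwise difference.

    Equals the fraction of the n(n-1)/2 allele pairs that differ; symmetric in
    j <-> n-j and maximal at intermediate frequency.
    """
    j, n = alt_count, called_alleles
    if n < 2:
        raise ValueError("site_pi needs >= 2 called alleles")
    if not 0 <= j <= n:
        raise ValueError("alt_count out of range")
    return 2.0 * j * (n - j) / (n * (n - 1))


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (0 for k <= 0)."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k > 0 else 0.0


def tajima_constants(n: int) -> dict[str, float]:
    """The a1,a2,b1,b2,c1,c2,e1,e2 constant chain of Tajima's D for n alleles."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_sums(pi_sum: float, s: int, n: int) -> float:
    """D from window totals: (θπ_sum - S/a1) / sqrt(e1 S + e2 S(S-1)).

    Undefined (NaN) when S = 0 or n < 4.
    """
    if s == 0 or n < 4:
        return float("nan")
    c = tajima_constants(n)
    theta_w_sum = s / c["a1"]
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return (pi_sum - theta_w_sum) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Windowed scan
# ---------------------------------------------------------------------------

def _window_median_n(n_site: np.ndarray, lo: int, hi: int) -> float:
    seg = n_site[lo:hi]
    seg = seg[seg >= 2]
    return float(np.median(seg)) if seg.size else 0.0


def diversity_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pool: str | Sequence[str],
    windows: Sequence[Interval],
    *,
    denominator: str = "window",
) -> pd.DataFrame:
    """θπ, θw and Tajima's D for one pool over sliding windows.

    ``denominator`` is "window" (full window length, default) or "sites"
    (number of genotyped SNP sites in the window — only sensible for relative
    comparisons). Returns one row per window:
    chrom, start, end, pool, n_snps, n_alleles, theta_pi, theta_w, tajimas_d.
    """
    if denominator not in ("window", "sites"):
        raise ValueError("denominator must be 'window' or 'sites'")
    idx = popmap.indices(matrix, pool)
    alt, n_called = matrix.allele_counts(idx)

    usable = n_called >= 2
    j, n = alt.astype(float), n_called.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(usable, 2.0 * j * (n - j) / (n * (n - 1)), 0.0)
    seg = usable & (alt > 0) & (alt < n_called)

    pool_label = pool if isinstance(pool, str) else "+".join(pool)
    pos0 = matrix.pos - 1  # half-open internal coordinates
    chrom_arr = matrix.chrom.astype(str)

    rows = []
    for chrom in sorted({w.chrom for w in windows}):
        on = chrom_arr == chrom
        cpos = pos0[on]
        cpi = pi[on]
        cseg = seg[on].astype(np.int64)
        cuse = usable[on].astype(np.int64)
        cn = n_called[on]
        # prefix sums for O(1) window aggregation
        pi_cum = np.concatenate(([0.0], np.cumsum(cpi)))
        seg_cum = np.concatenate(([0], np.cumsum(cseg)))
        use_cum = np.concatenate(([0], np.cumsum(cuse)))
        for w in windows:
            if w.chrom != chrom:
                continue
            lo = int(np.searchsorted(cpos, w.start, side="left"))
            hi = int(np.searchsorted(cpos, w.end, side="left"))
            s = int(seg_cum[hi] - seg_cum[lo])
            n_use = int(use_cum[hi] - use_cum[lo])
            pi_sum = float(pi_cum[hi] - pi_cum[lo])
            med_n = _window_median_n(cn, lo, hi)
            length = w.length if denominator == "window" else max(n_use, 1)
            theta_w_sum = s / harmonic(int(med_n) - 1) if med_n >= 2 and s > 0 else 0.0
            d = tajimas_d_from_sums(pi_sum, s, int(med_n))
            rows.append((w.chrom, w.start, w.end, pool_label, s, med_n,
                         pi_sum / length, theta_w_sum / length, d))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "pool", "n_snps", "n_alleles",
        "theta_pi", "theta_w", "tajimas_d",
    ])
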