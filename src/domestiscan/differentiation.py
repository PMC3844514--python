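"""Pairwise Fst and the population branch statistic (PBS) for three pools.

The default Fst estimator is Hudson's, accumulated over windows as a ratio of
averages (sum of site numerators / sum of site denominators), which is robust
to rare variants; Weir–Cockerham is available via ``estimator=``. PBS converts
pairwise window Fst into branch lengths T = -ln(1 - Fst) on the three-taxon
tree (wild, landrace, elite) and isolates the focal pool's branch:

    PBS_elite = (T_LE + T_EW - T_LW) / 2

Fst is clamped to [0, 1 - eps] before the log so sampling noise can never
produce infinite branch lengths.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import GenotypeMatrix, Interval, PopulationMap

CLAMP_EPS = 1e-6


def hudson_fst_components(alt1, n1, alt2, n2):
    """Hudson estimator per-site (numerator, denominator, usable mask).

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites where either pool has < 2 called alleles are masked out.
    """
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ok, alt1 / n1, 0.0)
        p2 = np.where(ok, alt2 / n2, 0.0)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.where(ok, n1 - 1, 1) \
            - p2 * (1 - p2) / np.where(ok, n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0), ok


def weir_cockerham_components(alt1, n1, alt2, n2):
    """Weir–Cockerham (1984) two-population per-site (a, a+b+c, usable mask).

    Uses allele counts only (no within-individual heterozygosity correction
    term beyond the standard haploid-allele formulation with h = observed
    heterozygote frequency omitted; genotype dosages enter through counts).
    """
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ok, alt1 / n1, 0.0)
        p2 = np.where(ok, alt2 / n2, 0.0)
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        total = a + b
    return np.where(ok, a, 0.0), np.where(ok, total, 0.0), ok


_ESTIMATORS = {"hudson": hudson_fst_components, "weir_cockerham": weir_cockerham_components}


def fst_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pool_pair: tuple[str, str],
    windows: Sequence[Interval],
    *,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Windowed Fst for one pool pair (ratio of averages, clamped to [0, 1]).

    Windows with no usable site (denominator sum 0) get NaN.
    Columns: chrom, start, end, pool_pair, n_sites, numerator_sum,
    denominator_sum, fst.
    """
    comp = _ESTIMATORS[estimator]
    i1 = popmap.indices(matrix, pool_pair[0])
    i2 = popmap.indices(matrix, pool_pair[1])
    a1, n1 = matrix.allele_counts(i1)
    a2, n2 = matrix.allele_counts(i2)
    num, den, ok = comp(a1, n1, a2, n2)

    pos0 = matrix.pos - 1
    chrom_arr = matrix.chrom.astype(str)
    label = f"{pool_pair[0]}-{pool_pair[1]}"
    rows = []
    for chrom in sorted({w.chrom for w in windows}):
        on = chrom_arr == chrom
        cpos = pos0[on]
        num_cum = np.concatenate(([0.0], np.cumsum(num[on])))
        den_cum = np.concatenate(([0.0], np.cumsum(den[on])))
        ok_cum = np.concatenate(([0], np.cumsum(ok[on].astype(np.int64))))
        for w in windows:
            if w.chrom != chrom:
                continue
            lo = int(np.searchsorted(cpos, w.start, side="left"))
            hi = int(np.searchsorted(cpos, w.end, side="left"))
            ns = float(num_cum[hi] - num_cum[lo])
            ds = float(den_cum[hi] - den_cum[lo])
            k = int(ok_cum[hi] - ok_cum[lo])
            fst = float(np.clip(ns / ds, 0.0, 1.0)) if ds > 0 else float("nan")
            rows.append((w.chrom, w.start, w.end, label, k, ns, ds, fst))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "pool_pair", "n_sites",
        "numerator_sum", "denominator_sum", "fst",
    ])


def branch_length(fst, eps: float = CLAMP_EPS):
    """T = -ln(1 - Fst) with Fst clamped into [0, 1-eps]."""
    f = np.clip(np.asarray(fst, dtype=float), 0.0, 1.0 - eps)
    return -np.log(1.0 - f)


def pbs(fst_le, fst_ew, fst_lw, eps: float = CLAMP_EPS):
    """Focal-elite population branch statistic from the three pairwise Fst.

    PBS = (T_LE + T_EW - T_LW)/2 with T = -ln(1-Fst); L = landrace,
    E = elite, W = wild. May be negative. NaN propagates.
    """
    t_le = branch_length(fst_le, eps)
    t_ew = branch_length(fst_ew, eps)
    t_lw = branch_length(fst_lw, eps)
    return (t_le + t_ew - t_lw) / 2.0


def pbs_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: Sequence[Interval],
    *,
    focal: str = "elite",
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Windowed PBS for the focal pool (default elite: the improvement scan).

    Columns: chrom, start, end, fst_le, fst_ew, fst_lw, pbs. The focal pool
    determines which two branch lengths are added; the formula is symmetric
    under relabeling.
    """
    others = [p for p in ("wild", "landrace", "elite") if p != focal]
    # pairwise scans named by the conventional L/E/W triangle
    f_le = fst_scan(matrix, popmap, ("landrace", "elite"), windows, estimator=estimator)
    f_ew = fst_scan(matrix, popmap, ("elite", "wild"), windows, estimator=estimator)
    f_lw = fst_scan(matrix, popmap, ("landrace", "wild"), windows, estimator=estimator)
    out = f_le[["chrom", "start", "end"]].copy()
    out["fst_le"] = f_le["fst"].to_numpy()
    out["fst_ew"] = f_ew["fst"].to_numpy()
    out["fst_lw"] = f_lw["fst"].to_numpy()
    pair_fst = {
        frozenset(("landrace", "elite")): out["fst_le"].to_numpy(),
        frozenset(("elite", "wild")): out["fst_ew"].to_numpy(),
        frozenset(("landrace", "wild")): out["fst_lw"].to_numpy(),
    }
    t_a = branch_length(pair_fst[frozenset((focal, others[0]))])
    t_b = branch_length(pair_fst[frozenset((focal, others[1]))])
    t_c = branch_length(pair_fst[frozenset(others)])
    out["pbs"] = (t_a + t_b - t_c) / 2.0
    out["focal"] = focal
    return out
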