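"""Sweep-region calling: window grids, Z-test and quantile outlier scans,
region merging, gene annotation, QTL intersection.

Two scans mirror the two bottlenecks of a domesticated crop:

* **domestication** — per window, the log2 ratio of cultivated to wild θπ and
  the cultivated pool's Tajima's D are each standardised across the genome
  (Z = (x - mean)/sd); a window is called when BOTH fall in the lower 5% tail
  of the standard normal (Z < -1.6449 at the default one-tailed P < 0.05).
* **improvement** — windows whose focal-pool PBS exceeds the empirical
  (1 - p) quantile (default top 0.1%) are called; a Z-mode alternative uses
  the same normal machinery as the domestication scan.

Significant windows are merged into maximal regions (overlap or bookended),
so an isolated window yields a region of exactly one window length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

from .diversity import WindowSpec
from .io_model import GeneModel, Interval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Outlier-calling parameters.

    p_domestication: one-tailed normal P for BOTH the π-ratio Z and the D Z.
    p_improvement: upper-tail fraction of windows called by the PBS scan.
    pi_ratio_floor: minimum wild per-bp θπ for a defined cultivated/wild ratio
        (windows below it can never be called).
    cultivated_pools: pools forming the "cultivated" side of the
        domestication contrast.
    improvement_mode: "quantile" (empirical) or "z" (normal tail like the
        domestication scan).
    """

    p_domestication: float = 0.05
    p_improvement: float = 0.001
    pi_ratio_floor: float = 1e-5
    cultivated_pools: tuple[str, ...] = ("landrace", "elite")
    improvement_mode: str = "quantile"

    def __post_init__(self):
        for p in (self.p_domestication, self.p_improvement):
            if not 0 < p < 1:
                raise ValueError("p thresholds must lie in (0, 1)")


@dataclass
class SelectionRegion:
    """A merged run of significant windows with its overlapping genes."""

    interval: Interval
    label: str                    # "domestication" or "improvement"
    n_windows: int
    min_stat: float               # most extreme window statistic inside
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------

def make_windows(chrom_lengths: Mapping[str, int],
                 spec: WindowSpec = WindowSpec()) -> list[Interval]:
    """Sliding windows per chromosome: starts 0, step, 2*step, ...

    The last window is the largest start with start + size <= length (no
    truncated tail). A chromosome shorter than one window yields a single
    truncated window covering it entirely.
    """
    out: list[Interval] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < spec.size:
            out.append(Interval(chrom, 0, length))
            continue
        last = (length - spec.size) // spec.step * spec.step
        for start in range(0, last + 1, spec.step):
            out.append(Interval(chrom, start, start + spec.size))
    return out


# ---------------------------------------------------------------------------
# Outlier scans
# ---------------------------------------------------------------------------

def _zscores(x: np.ndarray) -> np.ndarray:
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return np.full_like(x, np.nan, dtype=float)
    mu = x[ok].mean()
    sd = x[ok].std(ddof=0)
    if sd == 0:
        warnings.warn("degenerate scan statistic (sd = 0): no windows callable")
        return np.full_like(x, np.nan, dtype=float)
    z = np.full_like(x, np.nan, dtype=float)
    z[ok] = (x[ok] - mu) / sd
    return z


def domestication_scan(
    diversity_wild: pd.DataFrame,
    diversity_cultivated: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Joint π-ratio + Tajima's D lower-tail Z test per window.

    Both inputs must be :func:`~domestiscan.diversity.diversity_scan` tables on
    identical windows. Adds columns log2_pi_ratio, z_ratio, z_d, significant.
    Windows with wild θπ below ``pi_ratio_floor`` or undefined cultivated D
    are never significant.
    """
    w, c = diversity_wild, diversity_cultivated
    key = ["chrom", "start", "end"]
    if not (w[key].reset_index(drop=True).equals(c[key].reset_index(drop=True))):
        raise ValueError("wild and cultivated tables must share identical windows")
    out = c[key].copy()
    wild_pi = w["theta_pi"].to_numpy(dtype=float)
    cult_pi = c["theta_pi"].to_numpy(dtype=float)
    defined = wild_pi >= config.pi_ratio_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, cult_pi / wild_pi, np.nan)
        log_ratio = np.where(defined & (ratio > 0), np.log2(np.where(ratio > 0, ratio, 1)),
                             np.nan)
        # a cultivated pool with zero diversity in a defined window is the
        # strongest possible signal; map log2(0) to the finite minimum later
    zero_cult = defined & (cult_pi <= 0)
    out["log2_pi_ratio"] = log_ratio
    d = c["tajimas_d"].to_numpy(dtype=float)

    z_ratio = _zscores(out["log2_pi_ratio"].to_numpy())
    if zero_cult.any():
        finite = z_ratio[np.isfinite(z_ratio)]
        z_ratio[zero_cult] = finite.min() if finite.size else np.nan
    z_d = _zscores(d)
    z_crit = norm.ppf(config.p_domestication)
    out["tajimas_d"] = d
    out["z_ratio"] = z_ratio
    out["z_d"] = z_d
    with np.errstate(invalid="ignore"):
        out["significant"] = (z_ratio < z_crit) & (z_d < z_crit)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def improvement_scan(
    pbs_results: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """PBS upper-tail outlier calling.

    Quantile mode calls the ``floor(p * N)`` windows strictly above the k-th
    largest defined PBS value (tie-free rule); Z mode calls
    Z > norm.ppf(1 - p). Adds columns significant and threshold metadata.
    """
    out = pbs_results.copy()
    x = out["pbs"].to_numpy(dtype=float)
    ok = np.isfinite(x)
    n_def = int(ok.sum())
    if config.improvement_mode == "z":
        z = _zscores(x)
        crit = norm.ppf(1 - config.p_improvement)
        sig = np.where(np.isfinite(z), z > crit, False)
        out["z_pbs"] = z
    else:
        k = int(np.floor(config.p_improvement * n_def))
        if n_def < 1.0 / config.p_improvement:
            warnings.warn(
                f"only {n_def} defined windows for p={config.p_improvement}: "
                "empirical quantile unstable")
        if k == 0:
            sig = np.zeros_like(ok)
            thresh = np.inf
        else:
            thresh = float(np.sort(x[ok])[-k])  # k-th largest
            sig = np.where(ok, x >= thresh, False)
            # strict ">" under ties could call fewer than k; use the k-th
            # largest as an inclusive cut, then trim ties beyond k
            if sig.sum() > k:
                sig = np.where(ok, x > thresh, False)
        out.attrs["pbs_threshold"] = thresh
    out["significant"] = sig.astype(bool)
    return out


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def merge_windows(scan: pd.DataFrame, label: str,
                  stat_column: str = "z_ratio") -> list[SelectionRegion]:
    """Merge significant windows into maximal regions.

    Windows that overlap or are exactly bookended (gap 0) coalesce; region
    boundaries are the union span. Idempotent. ``stat_column`` supplies the
    per-region extreme statistic (min for Z columns, max for "pbs").
    """
    sig = scan[scan["significant"].astype(bool)].sort_values(["chrom", "start"])
    regions: list[SelectionRegion] = []
    take_max = stat_column == "pbs"
    for chrom, grp in sig.groupby("chrom", sort=True):
        cur_start = cur_end = None
        stats: list[float] = []
        count = 0

        def flush():
            if cur_start is None:
                return
            vals = [v for v in stats if np.isfinite(v)]
            extreme = (max(vals) if take_max else min(vals)) if vals else float("nan")
            regions.append(SelectionRegion(
                Interval(str(chrom), int(cur_start), int(cur_end)), label,
                count, extreme))

        for _, row in grp.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if cur_start is None:
                cur_start, cur_end, stats, count = s, e, [], 0
            elif s > cur_end:  # gap > 0: new region
                flush()
                cur_start, cur_end, stats, count = s, e, [], 0
            else:
                cur_end = max(cur_end, e)
            stats.append(float(row.get(stat_column, np.nan)))
            count += 1
        flush()
    return regions


def annotate_regions(regions: Sequence[SelectionRegion],
                     genes: Sequence[GeneModel]) -> list[SelectionRegion]:
    """Assign genes to regions by any-overlap of the gene span (>= 1 bp).

    Multi-transcript genes count once per gene_id. Regions on chromosomes
    absent from the annotation get an empty list (warning logged).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        sp = g.span
        trees.setdefault(sp.chrom, IntervalTree()).addi(sp.start, sp.end, g.gene_id)
    unmatched = 0
    for r in regions:
        tree = trees.get(r.interval.chrom)
        if tree is None:
            unmatched += 1
            r.gene_ids = []
            continue
        hits = tree.overlap(r.interval.start, r.interval.end)
        r.gene_ids = sorted({h.data for h in hits})
    if unmatched:
        log.warning("annotate_regions: %d regions on chromosomes absent from "
                    "the annotation", unmatched)
    return list(regions)


def total_genes(regions: Sequence[SelectionRegion]) -> int:
    """Deduplicated gene count across regions."""
    return len({g for r in regions for g in r.gene_ids})


def regions_to_frame(regions: Sequence[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.interval.chrom, "start": r.interval.start,
        "end": r.interval.end, "label": r.label, "n_windows": r.n_windows,
        "min_stat": r.min_stat, "n_genes": len(r.gene_ids),
        "gene_ids": ",".join(r.gene_ids),
    } for r in regions], columns=["chrom", "start", "end", "label", "n_windows",
                                  "min_stat", "n_genes", "gene_ids"])


# ---------------------------------------------------------------------------
# QTL intersection
# ---------------------------------------------------------------------------

def marker_interval(chrom: str, pos_left: int, pos_right: int) -> Interval:
    """Half-open interval between two 1-based flanking marker positions.

    The genomic distance between the markers is ``pos_right - pos_left`` bp,
    matching the convention of quoting QTL spans between marker coordinates.
    """
    if pos_right <= pos_left:
        raise ValueError("markers must satisfy pos_left < pos_right")
    return Interval(chrom, pos_left - 1, pos_right - 1)


def intersect_qtl(regions: Sequence[SelectionRegion], qtl: Interval) -> dict:
    """Clip regions to a QTL interval and report spans.

    Returns {qtl_bp, qtl_mb (1 decimal, half-up), regions (clipped
    SelectionRegions), inside_bp}. An empty intersection returns the span
    only.
    """
    from .annotation_report import round_half_up

    clipped = []
    for r in regions:
        iv = r.interval.intersect(qtl)
        if iv is not None:
            clipped.append(SelectionRegion(iv, r.label, r.n_windows, r.min_stat,
                                           list(r.gene_ids)))
    return {
        "qtl_bp": qtl.length,
        "qtl_mb": round_half_up(qtl.length / 1e6, 1),
        "regions": clipped,
        "inside_bp": sum(r.length for r in clipped),
    }
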