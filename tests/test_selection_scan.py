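"""Window grids, outlier calling, region merging, gene/QTL intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from domestiscan.diversity import WindowSpec
from domestiscan.io_model import GeneModel, Interval
from domestiscan.selection_scan import (ScanConfig, SelectionRegion,
                                        annotate_regions, domestication_scan,
                                        improvement_scan, intersect_qtl,
                                        make_windows, marker_interval,
                                        merge_windows, total_genes)


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------

def test_make_windows_count_and_starts():
    w = make_windows({"chr1": 100_000}, WindowSpec(20_000, 2_000))
    assert len(w) == 41                       # (100000-20000)/2000 + 1
    assert w[0].start == 0 and w[-1].start == 80_000
    assert all(iv.length == 20_000 for iv in w)


def test_make_windows_boundary_rules():
    assert make_windows({"c": 20_000}, WindowSpec(20_000, 2_000)) == \
        [Interval("c", 0, 20_000)]
    # no truncated tail: length 21,000 yields only [0, 20000)
    assert make_windows({"c": 21_000}, WindowSpec(20_000, 2_000)) == \
        [Interval("c", 0, 20_000)]
    # chromosome shorter than one window: single truncated window
    assert make_windows({"c": 9_000}, WindowSpec(20_000, 2_000)) == \
        [Interval("c", 0, 9_000)]
    with pytest.raises(ValueError):
        make_windows({"c": 0}, WindowSpec(20_000, 2_000))


# ---------------------------------------------------------------------------
# Domestication scan
# ---------------------------------------------------------------------------

def _div_table(pi, d=None):
    n = len(pi)
    starts = np.arange(n) * 2_000
    return pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + 20_000,
        "pool": "x", "n_snps": 10, "n_alleles": 16.0,
        "theta_pi": pi, "theta_w": pi,
        "tajimas_d": np.zeros(n) if d is None else d,
    })


def test_domestication_scan_calls_planted_outliers_exactly():
    """990 null windows near 0 plus 10 windows 3 sd low on both statistics:
    exactly the 10 planted windows are called, matching a direct
    normal-quantile computation."""
    rng = np.random.default_rng(17)
    n = 1000
    wild_pi = np.full(n, 1e-3)
    # null windows drawn tightly near 0 so after mixed standardization no
    # null can cross the 5% tail; planted windows sit ~3 mixed-sd below
    log_ratio = rng.uniform(-0.5, 0.5, size=n)
    d = rng.uniform(-0.5, 0.5, size=n)
    planted = rng.choice(n, size=10, replace=False)
    log_ratio[planted] = -3.0
    d[planted] = -3.0
    cult_pi = 1e-3 * 2.0 ** log_ratio
    wild = _div_table(wild_pi)
    cult = _div_table(cult_pi, d)
    out = domestication_scan(wild, cult)
    assert set(np.flatnonzero(out.significant.to_numpy())) == set(planted)
    # cross-check the threshold against the explicit normal quantile
    z = out.z_ratio.to_numpy()
    crit = norm.ppf(0.05)
    assert ((z < crit) & (out.z_d.to_numpy() < crit)).sum() == 10


def test_domestication_scan_degenerate_sd_calls_nothing():
    wild = _div_table(np.full(50, 1e-3))
    cult = _div_table(np.full(50, 5e-4))
    with pytest.warns(UserWarning):
        out = domestication_scan(wild, cult)
    assert not out.significant.any()


def test_domestication_scan_wild_pi_floor_excludes_window():
    pi_w = np.array([1e-3] * 6 + [0.0])
    pi_c = np.array([1e-3] * 6 + [1e-9])
    wild = _div_table(pi_w)
    cult = _div_table(pi_c, d=np.zeros(7))
    out = domestication_scan(wild, cult)
    assert np.isnan(out.log2_pi_ratio.to_numpy()[6])
    assert not out.significant.to_numpy()[6]


def test_domestication_scan_undefined_d_never_significant():
    rng = np.random.default_rng(3)
    pi_w = np.full(100, 1e-3)
    pi_c = 1e-3 * 2.0 ** rng.normal(0, 0.05, 100)
    d = rng.normal(0, 0.3, 100)
    pi_c[7] = 1e-8          # extreme ratio ...
    d[7] = np.nan           # ... but no defined D
    out = domestication_scan(_div_table(pi_w), _div_table(pi_c, d))
    assert not out.significant.to_numpy()[7]


# ---------------------------------------------------------------------------
# Improvement scan
# ---------------------------------------------------------------------------

def _pbs_table(values):
    n = len(values)
    starts = np.arange(n) * 2_000
    return pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + 20_000, "pbs": values})


def test_improvement_scan_tie_free_top_quantile_size():
    rng = np.random.default_rng(1)
    out = improvement_scan(_pbs_table(rng.uniform(size=5000)))
    assert out.significant.sum() == 5     # floor(0.001 * 5000)


def test_improvement_scan_single_extreme_window_called():
    vals = np.concatenate([np.zeros(1999) + 1e-6 * np.arange(1999), [10.0]])
    out = improvement_scan(_pbs_table(vals))
    assert out.significant.to_numpy()[-1]
    assert out.significant.sum() == 2     # floor(0.001 * 2000)


def test_improvement_scan_few_windows_warns():
    with pytest.warns(UserWarning):
        improvement_scan(_pbs_table(np.arange(100, dtype=float)))


def test_improvement_scan_z_mode():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=3000)
    vals[5] = 30.0
    out = improvement_scan(_pbs_table(vals),
                           ScanConfig(improvement_mode="z"))
    assert out.significant.to_numpy()[5]
    assert out.significant.sum() <= 10


# ---------------------------------------------------------------------------
# Merging and annotation
# ---------------------------------------------------------------------------

def _scan_frame(windows, sig, stat=None):
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "significant": sig,
        "z_ratio": stat if stat is not None else np.zeros(len(windows)),
    })


def test_merge_windows_union_arithmetic():
    windows = [Interval("chr1", 20_000, 40_000), Interval("chr1", 22_000, 42_000)]
    regs = merge_windows(_scan_frame(windows, [True, True]), "domestication")
    assert len(regs) == 1
    assert (regs[0].interval.start, regs[0].interval.end) == (20_000, 42_000)
    assert regs[0].length == 22_000 and regs[0].n_windows == 2


def test_merge_windows_isolated_window_is_minimum_region():
    windows = [Interval("chr1", 0, 20_000), Interval("chr1", 60_000, 80_000)]
    regs = merge_windows(_scan_frame(windows, [True, True]), "domestication")
    assert [r.length for r in regs] == [20_000, 20_000]


def test_merge_windows_bookended_join_and_empty():
    windows = [Interval("chr1", 0, 20_000), Interval("chr1", 20_000, 40_000)]
    regs = merge_windows(_scan_frame(windows, [True, True]), "x")
    assert len(regs) == 1 and regs[0].interval.end == 40_000
    assert merge_windows(_scan_frame([], []), "x") == []


def test_merge_is_idempotent():
    windows = [Interval("chr1", s, s + 20_000) for s in range(0, 100_000, 2_000)]
    sig = [s in (0, 2_000, 40_000) for s in range(0, 100_000, 2_000)]
    regs = merge_windows(_scan_frame(windows, sig), "x")
    as_windows = [r.interval for r in regs]
    again = merge_windows(_scan_frame(as_windows, [True] * len(as_windows)), "x")
    assert [r.interval for r in again] == as_windows


def test_merge_invariant_to_window_ordering():
    windows = [Interval("chr1", s, s + 20_000) for s in (40_000, 0, 2_000)]
    regs = merge_windows(_scan_frame(windows, [True] * 3), "x")
    assert [(r.interval.start, r.interval.end) for r in regs] == \
        [(0, 22_000), (40_000, 60_000)]


def _gene(gid, chrom, start1, end1):
    return GeneModel(gid, f"{gid}.t1", chrom, "+", cds=[(start1, end1)])


def test_annotate_regions_any_overlap_rule():
    regions = [SelectionRegion(Interval("chr1", 1000, 2000), "x", 1, 0.0)]
    genes = [
        _gene("inside", "chr1", 1200, 1400),
        _gene("one_bp", "chr1", 2000, 2400),      # span [1999, 2400): 1 bp in
        _gene("outside", "chr1", 2001, 2400),     # span [2000, 2400): 0 bp in
        _gene("other_chrom", "chr2", 1200, 1400),
    ]
    (r,) = annotate_regions(regions, genes)
    assert r.gene_ids == ["inside", "one_bp"]


def test_annotate_regions_matches_quadratic_brute_force():
    rng = np.random.default_rng(23)
    regions = [SelectionRegion(Interval("chr1", int(s), int(s) + 15_000), "x", 1, 0.0)
               for s in rng.choice(200_000, 10, replace=False)]
    genes = [_gene(f"g{i}", "chr1", int(s) + 1, int(s) + 3_000)
             for i, s in enumerate(rng.choice(215_000, 50, replace=False))]
    annotate_regions(regions, genes)
    brute = {
        g.gene_id
        for g in genes for r in regions
        if g.span.start < r.interval.end and r.interval.start < g.span.end
    }
    assert {gid for r in regions for gid in r.gene_ids} == brute
    assert total_genes(regions) == len(brute)


# ---------------------------------------------------------------------------
# QTL intersection
# ---------------------------------------------------------------------------

def test_marker_interval_span_arithmetic():
    """Flanking markers at 22,874,022 and 27,718,828 bp: 4,844,806 bp = 4.8 Mb."""
    qtl = marker_interval("Gm13", 22_874_022, 27_718_828)
    res = intersect_qtl([], qtl)
    assert res["qtl_bp"] == 4_844_806
    assert res["qtl_mb"] == 4.8
    assert res["regions"] == [] and res["inside_bp"] == 0


def test_intersect_qtl_clips_regions():
    qtl = Interval("Gm13", 1_000_000, 3_700_000)   # 2.7 Mb
    regions = [
        SelectionRegion(Interval("Gm13", 900_000, 1_100_000), "dom", 1, 0.0),
        SelectionRegion(Interval("Gm13", 2_000_000, 2_100_000), "dom", 1, 0.0),
        SelectionRegion(Interval("Gm13", 3_680_000, 3_714_000), "dom", 1, 0.0),
        SelectionRegion(Interval("Gm13", 5_000_000, 5_100_000), "dom", 1, 0.0),
    ]
    res = intersect_qtl(regions, qtl)
    assert len(res["regions"]) == 3
    assert res["inside_bp"] == 100_000 + 100_000 + 20_000
    # a region containing the whole QTL clips to the QTL itself
    res2 = intersect_qtl([SelectionRegion(Interval("Gm13", 0, 9_000_000),
                                          "dom", 1, 0.0)], qtl)
    assert res2["regions"][0].interval == qtl
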