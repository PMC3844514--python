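"""Three-pool genotype simulator with bottlenecks and planted sweeps.

The generator emulates the statistical structure a domestication selection
scan assumes, without a forward or coalescent simulation:

* ancestral (wild) allele frequencies are drawn from a neutral-like 1/x
  frequency spectrum truncated at a small bound ``spectrum_lo`` (default
  2×10⁻⁴; keeping the bound small keeps the sampled site-frequency spectrum
  close to neutral, so θπ ≈ θw and Tajima's D ≈ 0 on equilibrium output).
  The default number of sites is derived from ``base_diversity`` so the wild
  pool's expected per-bp θπ matches it;
* landrace frequencies drift around the wild frequency under a
  Balding–Nichols beta distribution, elite frequencies around the landrace.
  ``f_wl`` / ``f_le`` are *pairwise Hudson Fst targets*: because the pairwise
  Fst between an ancestral pool and a daughter drifted with Balding–Nichols
  parameter φ is φ/2 (between-pool heterozygosity stays at the ancestral
  level while only one pool loses diversity), the generator draws with
  φ = 2f so the windowed estimator recovers the stated targets. The
  hierarchy also makes wild ≥ landrace ≥ elite diversity hold in
  expectation;
* inside each planted sweep the targeted pools' frequencies are pushed
  deterministically toward the nearer of 0/1 so that per-site
  heterozygosity p(1-p) is multiplied by the sweep's ``suppression`` factor
  (0 = complete fixation). Truth intervals are therefore exact;
* haplotypes are drawn with a block-mosaic copula: each haplotype carries a
  Poisson process of breakpoints (mean segment length = the pool's
  ``ld_scale``) and one shared uniform per segment, so allele states within
  a segment are comonotonic while the per-site marginal stays exactly
  Bernoulli(p). This creates genuine within-pool linkage disequilibrium
  that decays with distance — longer segments in the bottlenecked pools
  (elite > landrace > wild) emulate the loss of recombinant lineages —
  without disturbing any site-level expectation (allele counts remain
  Binomial(2n, p), so θ and Fst calibrations are unaffected).

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import GenotypeMatrix, Interval, PopulationMap, write_bed

DOMESTICATION_POOLS = ("landrace", "elite")
IMPROVEMENT_POOLS = ("elite",)


@dataclass(frozen=True)
class DemographyConfig:
    """Panel structure and differentiation targets.

    Defaults mirror a resequencing panel of 8 wild, 8 landrace and 9 elite
    diploid accessions on one 5 Mb chromosome with wild per-bp θπ around
    3×10⁻³ (soybean-like order of magnitude) and moderate
    wild→landrace→elite drift.

    ``n_sites`` left at None is derived from ``base_diversity``:
    n_sites = base_diversity / E[2p(1-p)] × chrom_length, where the
    expectation is under the truncated 1/x spectrum — the density at which
    the wild pool's expected per-bp θπ equals ``base_diversity``. An explicit
    ``n_sites`` overrides the density (realized wild θπ then scales
    proportionally).

    ``f_we`` may be left None to take the value implied by the drift chain,
    f_wl + f_le - 2·f_wl·f_le; an explicit value below that bound is
    inconsistent with a hierarchical model and rejected.
    """

    n_wild: int = 8
    n_landrace: int = 8
    n_elite: int = 9
    n_sites: int | None = None
    chrom_length: int = 5_000_000
    chrom: str = "chr1"
    base_diversity: float = 0.003
    f_wl: float = 0.10
    f_le: float = 0.05
    f_we: float | None = None
    spectrum_lo: float = 2e-4
    ld_scale_wild: int = 5_000
    ld_scale_landrace: int = 20_000
    ld_scale_elite: int = 40_000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_wild, self.n_landrace, self.n_elite) < 2:
            raise ValueError("each pool needs >= 2 diploid samples")
        for f in (self.f_wl, self.f_le):
            if not 0 <= f < 0.5:
                raise ValueError("pairwise Fst targets must lie in [0, 0.5)")
        if self.base_diversity <= 0:
            raise ValueError("base_diversity must be positive")
        if not 0 < self.spectrum_lo < 0.05:
            raise ValueError("spectrum_lo must be a small positive frequency")
        if self.resolved_n_sites() > self.chrom_length:
            raise ValueError("more sites than base pairs")
        implied = self.implied_f_we()
        if self.f_we is not None and self.f_we < implied - 1e-9:
            raise ValueError(
                f"f_we={self.f_we} is below the hierarchical bound "
                f"f_wl + f_le - 2 f_wl f_le = {implied:.4f}; the "
                "wild->landrace->elite drift chain cannot produce less "
                "wild-elite differentiation than it accumulates through the "
                "landrace")

    def implied_f_we(self) -> float:
        return self.f_wl + self.f_le - 2.0 * self.f_wl * self.f_le

    def resolved_n_sites(self) -> int:
        if self.n_sites is not None:
            return self.n_sites
        density = self.base_diversity / expected_site_heterozygosity(self.spectrum_lo)
        return int(round(density * self.chrom_length))


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep.

    ``target`` "domestication" suppresses landrace and elite (the sweep
    predates their split); "improvement" suppresses elite only.
    ``suppression`` multiplies per-site heterozygosity inside the interval
    (0 = monomorphic).
    """

    interval: Interval
    target: str = "domestication"
    suppression: float = 0.05

    def __post_init__(self):
        if self.target not in ("domestication", "improvement"):
            raise ValueError("target must be 'domestication' or 'improvement'")
        if not 0 <= self.suppression < 1:
            raise ValueError("suppression must lie in [0, 1)")


def _check_sweeps(sweeps: Sequence[SweepSpec], length: int) -> None:
    ivs = sorted((s.interval.start, s.interval.end) for s in sweeps)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError("sweep intervals must not overlap")
    for s in sweeps:
        if s.interval.end > length:
            raise ValueError("sweep interval outside the chromosome")


# ---------------------------------------------------------------------------
# Frequency machinery
# ---------------------------------------------------------------------------

def neutral_spectrum_frequencies(n_sites: int, rng: np.random.Generator,
                                 lo: float = 0.005) -> np.ndarray:
    """Frequencies from the density ∝ 1/x on [lo, 1-lo] (neutral-like SFS).

    Inverse-CDF sampling: x = lo * ((1-lo)/lo)**u for u ~ U(0,1).
    """
    u = rng.uniform(size=n_sites)
    return lo * ((1 - lo) / lo) ** u


def expected_site_heterozygosity(lo: float = 0.005) -> float:
    """E[2p(1-p)] under the 1/x spectrum on [lo, 1-lo] (closed form)."""
    return (1 - 2 * lo) / np.log((1 - lo) / lo)


def balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Daughter-population frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def sample_haplotypes(p: np.ndarray, pos: np.ndarray, n_haplotypes: int,
                      ld_scale: float, chrom_length: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Haplotypes (n_sites × n_haplotypes) with block-mosaic linkage.

    Each haplotype gets Poisson breakpoints (mean segment ``ld_scale`` bp)
    and one uniform per segment; site allele = [u_segment < p_site]. The
    marginal at every site is exactly Bernoulli(p); sites sharing a segment
    are comonotonic, giving LD that decays like exp(-distance/ld_scale).
    ``ld_scale`` <= 0 means independent sites (no linkage).
    """
    n_sites = len(p)
    out = np.empty((n_sites, n_haplotypes), dtype=np.int8)
    for h in range(n_haplotypes):
        if ld_scale <= 0:
            u = rng.uniform(size=n_sites)
        else:
            n_breaks = rng.poisson(chrom_length / ld_scale)
            breaks = np.sort(rng.uniform(0, chrom_length, size=n_breaks))
            seg = np.searchsorted(breaks, pos)
            seg_u = rng.uniform(size=n_breaks + 1)
            u = seg_u[seg]
        out[:, h] = u < p
    return out


def suppress_frequency(p: np.ndarray, suppression: float,
                       side: np.ndarray | None = None) -> np.ndarray:
    """Push frequencies toward 0 or 1 so that p'(1-p') = s·p(1-p).

    The quadratic has two roots; by default the one on the same side of 1/2
    as ``p`` is taken, so minor alleles get rarer rather than flipping.
    ``side`` overrides the direction (frequencies > 1/2 push toward 1):
    a pool descended from an already-swept parent must fix the parent's
    swept allele, not whichever allele happens to be locally common —
    otherwise rare drift flips create spurious fixed differences between
    the two cultivated pools.
    """
    h = suppression * p * (1 - p)
    root = (1 - np.sqrt(1 - 4 * h)) / 2        # root <= 1/2
    guide = p if side is None else side
    return np.where(guide <= 0.5, root, 1 - root)


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

_BASE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"),
               ("G", "T")]


def simulate_panel(
    demography: DemographyConfig = DemographyConfig(),
    sweeps: Sequence[SweepSpec] = (),
) -> tuple[GenotypeMatrix, PopulationMap, list[SweepSpec]]:
    """Simulate the three-pool panel; returns (matrix, popmap, sweeps).

    The returned sweep list is the truth (identical to the input); write it
    with :func:`write_truth`.
    """
    cfg = demography
    _check_sweeps(sweeps, cfg.chrom_length)
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.resolved_n_sites()

    pos = np.sort(rng.choice(cfg.chrom_length, size=n_sites, replace=False)) + 1
    p_wild = neutral_spectrum_frequencies(n_sites, rng, cfg.spectrum_lo)
    # pairwise Fst target f -> Balding-Nichols drift parameter 2f (see module
    # docstring); f < 0.5 guarantees 2f < 1
    p_land = balding_nichols(p_wild, 2.0 * cfg.f_wl, rng)

    in_sweep = {s: (pos - 1 >= s.interval.start) & (pos - 1 < s.interval.end)
                for s in sweeps}
    for s, mask in in_sweep.items():
        if s.target == "domestication":
            p_land = np.where(mask, suppress_frequency(p_land, s.suppression), p_land)

    p_elite = balding_nichols(p_land, 2.0 * cfg.f_le, rng)
    for s, mask in in_sweep.items():
        # domestication sweeps also constrain elite (it descends from the
        # swept landrace, so it fixes the landrace's swept allele);
        # improvement sweeps hit elite alone, toward its own common allele
        side = p_land if s.target == "domestication" else None
        p_elite = np.where(
            mask, suppress_frequency(p_elite, s.suppression, side), p_elite)

    pools = (["wild"] * cfg.n_wild + ["landrace"] * cfg.n_landrace
             + ["elite"] * cfg.n_elite)
    sample_ids = [f"{p[0].upper()}{i + 1}" for i, p in enumerate(pools)]
    spec = (("wild", p_wild, cfg.n_wild, cfg.ld_scale_wild),
            ("landrace", p_land, cfg.n_landrace, cfg.ld_scale_landrace),
            ("elite", p_elite, cfg.n_elite, cfg.ld_scale_elite))
    blocks = []
    for _, p, n_dip, scale in spec:
        haps = sample_haplotypes(p, pos, 2 * n_dip, scale,
                                 cfg.chrom_length, rng)
        blocks.append(haps[:, 0::2] + haps[:, 1::2])
    calls = np.hstack(blocks).astype(np.int8)
    if cfg.missing_rate > 0:
        drop = rng.uniform(size=calls.shape) < cfg.missing_rate
        calls = np.where(drop, np.int8(-1), calls)

    pair_idx = rng.integers(0, len(_BASE_PAIRS), size=n_sites)
    flip = rng.uniform(size=n_sites) < 0.5
    ref = np.array([_BASE_PAIRS[k][1 if f else 0] for k, f in zip(pair_idx, flip)],
                   dtype=object)
    alt = np.array([_BASE_PAIRS[k][0 if f else 1] for k, f in zip(pair_idx, flip)],
                   dtype=object)

    matrix = GenotypeMatrix(
        np.full(n_sites, cfg.chrom, dtype=object), pos, ref, alt, calls,
        sample_ids)
    matrix.validate()
    popmap = PopulationMap(dict(zip(sample_ids, pools)))
    return matrix, popmap, list(sweeps)


def write_truth(sweeps: Sequence[SweepSpec], path) -> None:
    """BED of sweep intervals, label column = target."""
    write_bed([s.interval for s in sweeps], path,
              labels=[s.target for s in sweeps])


def read_truth(path) -> list[SweepSpec]:
    """Read a truth BED back (labels from column 4, default domestication)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3] if len(f) > 3 else "domestication"
            out.append(SweepSpec(Interval(f[0], int(f[1]), int(f[2])), label))
    return out


# ---------------------------------------------------------------------------
# Synthetic annotation (reference + gene models) for effect-call testing
# ---------------------------------------------------------------------------

def random_reference(chrom_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """Synthetic random reference sequences keyed by chromosome."""
    rng = np.random.default_rng(seed)
    return {c: "".join(rng.choice(list("ACGT"), size=n))
            for c, n in chrom_lengths.items()}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
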