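# Methods

`domestiscan` re-implements, as a tested library, the population-genetic
machinery used to locate artificial-selection footprints in a three-pool
crop resequencing panel — a wild progenitor pool, traditional landraces, and
modern elite cultivars. This note records the statistical models, the
numerical choices, and what the synthetic data can and cannot demonstrate.

## Diversity statistics

For a site with `j` alternate alleles among `n` called alleles, per-site
nucleotide diversity is the mean pairwise difference

    π_site = 2 j (n − j) / (n (n − 1)),

an unbiased estimator of 2p(1−p). Window-level θπ sums π_site over in-window
SNPs and divides by the **full window length in bp** (default 20 kb windows,
2 kb step): monomorphic positions count, because the panel derives from
whole-genome sequencing and per-bp diversity must be comparable across pools
and windows. A `denominator="sites"` option divides by genotyped SNP count
instead, for relative comparisons only.

Watterson's estimator is θw = S / a_{n−1} / L with S the number of sites
segregating *within the pool sample* and a_k the k-th harmonic number.
Tajima's D uses window totals (not per-bp values):

    D = (θπ_sum − S/a₁) / sqrt(e₁ S + e₂ S (S − 1)),

with the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constant chain computed
from n. D is undefined when S = 0 or n < 4; undefined values propagate as
"not significant" in the scans, never as zero.

**Missing data.** Each site uses its own called-allele count; the single `n`
that θw and D need per window is the median per-site `n` over usable
(≥ 2 called alleles) in-window sites. Windows with median n < 4 get an
undefined D. The choice of a per-window median (rather than assuming
2 × accessions alleles uniformly) is exposed in the API and documented here
because real low-pass panels rarely have complete calls.

## Differentiation and PBS

The default Fst estimator is Hudson's, with per-site components

    num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

aggregated per window as a **ratio of averages** (Σnum / Σden, clamped to
[0, 1]), which is robust to rare variants; Weir–Cockerham is available via
`estimator="weir_cockerham"`. Sites where either pool has fewer than two
called alleles are skipped; a window with no usable denominator is undefined.

The population branch statistic converts pairwise window Fst into branch
lengths T = −ln(1 − Fst) on the (wild, landrace, elite) tree and isolates
the focal branch, e.g. PBS_elite = (T_LE + T_EW − T_LW)/2. Fst is clamped
into [0, 1 − 10⁻⁶] before the log so sampling noise cannot produce infinite
branch lengths; natural log is used throughout. The focal pool defaults to
elite (the landrace→elite "improvement" contrast).

## Linkage disequilibrium

Phase is unobserved, so haplotype frequencies for a locus pair are estimated
by EM under random mating: all genotype combinations except the double
heterozygote resolve unambiguously; the double heterozygote splits between
coupling and repulsion in proportion to their current expected frequencies.
Iteration stops at max |Δf| < 10⁻⁹ or 1,000 rounds. r² = D²/(pA(1−pA)pB(1−pB)).
Defaults mirror a Haploview-style run: max pair distance 1,000 kb (the cited
tool's `-maxdistance 1000` flag is interpreted as kb), within-pool minor
allele frequency ≥ 0.1, within-pool call rate ≥ 0.6, HWE filter disabled.
Decay curves bin pairs in 5 kb distance bins (binning is not prescribed by
the source analysis; it is a configurable choice).

## Outlier scans and regions

* **Domestication scan** — per window, log2(θπ_cultivated/θπ_wild) and the
  cultivated pool's Tajima's D are each standardised across all defined
  windows (Z = (x − mean)/sd, empirical null); a window is called when both
  Z < Φ⁻¹(0.05) = −1.6449 (one-tailed P < 0.05 each). The log2 scale
  symmetrises the ratio before standardisation. "Cultivated" defaults to
  landrace + elite combined; a landrace-only option exists because both
  contrasts are meaningful. Windows with wild θπ below `pi_ratio_floor`
  (10⁻⁵/bp) have an undefined ratio and can never be called — near-zero wild
  diversity makes the ratio meaningless, not significant. A cultivated pool
  with exactly zero diversity in a defined window maps to the most extreme
  finite ratio Z rather than −∞.
* **Improvement scan** — windows whose focal-pool PBS reaches the k-th
  largest value, k = floor(p × N) with p = 0.001 (empirical top 0.1%), are
  called; ties beyond k are trimmed by a strict cut. A Z-mode alternative
  (normal upper tail) is provided for comparison since the original
  significance mechanism is not fully specified.
* **Regions** — significant windows that overlap or are exactly bookended
  merge into maximal regions (union span); an isolated window yields a
  region of one window length, so the minimum region length equals the
  window size. Genes attach to regions by any-overlap (≥ 1 bp) of the gene
  span; totals are deduplicated by gene id. QTL intersection converts
  1-based flanking-marker coordinates to a half-open interval whose length
  is the marker distance (right − left), clips regions to it, and reports
  the span in bp and Mb (one decimal, half-up).

Per-window testing is used throughout; converting window calls into
region-level significance is interpretation, not additional testing.

## SNP effect classification and accounting

Feature precedence is CDS > UTR > intron > intergenic; the first transcript
of a gene wins for multi-isoform genes. For a usable CDS (total length
divisible by 3), the reference codon is rebuilt from the FASTA, the
alternate allele substituted respecting strand (complemented for − strand),
and both codons translated with the standard genetic code. Transcripts whose
CDS length is not a multiple of 3 are flagged at parse time and contribute
feature classification only. Sites whose reference base disagrees with the
panel's ref allele are skipped and logged.

A site is "polymorphic within a pool" when both alleles are observed among
≥ 2 non-missing calls of that pool (the threshold is exposed). The directed
"fixed" sets — polymorphic in the ancestral pool, monomorphic in the derived
pool — quantify diversity lost during domestication (wild→landrace) and
improvement (landrace→elite). Category enrichment uses the Pearson χ² test
on a 2×2 table, one degree of freedom, continuity correction off by default.
Report percentages round half-up to the printed precision of each figure
(documented per field); the genome size constant defaults to 950 Mb.

## Synthetic data

The generator produces the statistical structure the scans assume, at desk
scale, with exact truth:

* **Frequency spectrum.** Wild frequencies follow a density ∝ 1/x truncated
  to [lo, 1−lo], lo = 2×10⁻⁴. The truncation slightly under-produces rare
  variants; at this bound the θπ/θw imbalance it induces is ≈ 0.06% at
  n = 16 alleles — far inside sampling noise. The default site count is
  derived from `base_diversity` (0.003/bp, a soybean-like order of
  magnitude): n_sites = base_diversity / E[2p(1−p)] × chromosome length.
* **Drift hierarchy.** Landrace frequencies are Balding–Nichols draws around
  wild, elite around landrace. The config's `f_wl`, `f_le` are **pairwise
  Hudson Fst targets**: ancestral-vs-daughter pairwise Fst under a BN
  parameter φ is φ/2 (the between-pool heterozygosity stays ancestral while
  only one pool loses diversity), so the generator draws with φ = 2f. The
  implied wild–elite target is f_wl + f_le − 2 f_wl f_le. Realized windowed
  Fst lands within ±0.01 of targets at default sizes.
* **Sweeps.** Inside a sweep interval the targeted pools' frequencies are
  moved deterministically toward fixation so per-site heterozygosity is
  multiplied by the `suppression` factor (default 0.05; 0 = monomorphic).
  Domestication sweeps suppress the landrace before the elite is drawn and
  then pin the elite to the **landrace's** swept allele — the sweep fixed
  one allele in the cultivated pools' common ancestor, and letting each pool
  fix its own locally-common allele would create spurious fixed
  landrace–elite differences with saturated PBS. Truth intervals are exact
  by construction.
* **Linkage.** Haplotypes are drawn with a block-mosaic copula: each
  haplotype carries Poisson breakpoints (mean segment length `ld_scale`:
  5/20/40 kb for wild/landrace/elite) and one shared uniform per segment, so
  within-segment alleles are comonotonic while every per-site marginal stays
  exactly Bernoulli(p). This yields genuine within-pool LD decaying roughly
  as exp(−d/ld_scale), ordered elite > landrace > wild (the bottlenecks'
  loss of recombinant lineages), without disturbing any site-level
  expectation. The scales are deliberately kept at or below the 20 kb window
  size so the genome background stays near-equilibrium for the outlier
  scans; real selfing-crop LD extends much further.

**What the simulator does not model:** recombination maps, gene conversion,
mutation-rate heterogeneity, ascertainment of the SNP panel, sequencing
error, genotype-likelihood uncertainty, admixture/introgression between
pools, and background selection. Passing the recovery tests therefore shows
the scan machinery is correct and calibrated under the assumed model, not
that the thresholds transfer unchanged to real panels.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 0.05–5 Mb panels. The acceptance script
simulates three 20 Mb chromosomes (seeded from `--seed`) each carrying
8 domestication sweeps and 1 improvement sweep of 120 kb at suppression
0.05, scans ~10,000 windows per chromosome, and reports pooled
recall/precision; the improvement-sweep count is kept at one per chromosome
because the empirical top-0.1% rule has a call budget of floor(0.001 × N) ≈ 9
windows, and heavily overlapping sweep plateaus make that budget
winner-take-all across multiple simultaneous improvement sweeps. Null
calibration uses a 40 Mb panmictic panel (20,001 windows). The domestication
sweep density (8 per 20 Mb) matches the order of the published genome-wide
region count (394 regions / 950 Mb).

## Known limitations

* The Fst estimator and the log base of the original PBS pipeline are not
  recorded in the source analysis; Hudson + natural log are this package's
  defaults and are stamped into run metadata.
* The heterozygote rank-sum site filter consumes a pre-computed per-site
  p-value; re-deriving it from base qualities requires reads, which are out
  of scope.
* Chromosome ends shorter than one window beyond the last full window are
  uncovered by the scans (no truncated tail windows).
* "Most doubletons" in the site-filter provenance is operationalised as
  minor allele count ≥ 3 by default, with ≥ 2 available — the original rule
  is not exact, so the stricter reading is the default and the choice is
  exposed.
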