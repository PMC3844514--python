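"""SNP functional partitioning, pool-level SNP set accounting, category
enrichment, and the headline summary report.

``classify_snp_effects`` places each SNP into CDS > UTR > intron > intergenic
(precedence resolves overlapping annotations; the first transcript of a gene
wins for multi-isoform genes) and, inside usable CDS, rebuilds the reference
codon, substitutes the alternate allele respecting strand, and translates
both with the standard genetic code.

``pool_snp_sets`` partitions sites by which pools they segregate in — the
Venn classes across wild/landrace/elite plus the two directed "fixed during
domestication / improvement" sets (polymorphic in the ancestral pool,
monomorphic in the derived one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

from .io_model import GeneModel, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)

CATEGORIES = ("CDS", "UTR", "intron", "intergenic")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (matches how printed percentages round)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def open_reference(path):
    """Open an (indexed) FASTA as the chrom -> sequence mapping that
    :func:`classify_snp_effects` consumes."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


# ---------------------------------------------------------------------------
# SNP effect classification
# ---------------------------------------------------------------------------

@dataclass
class SnpEffect:
    site_index: int
    category: str                 # CDS / UTR / intron / intergenic
    coding_effect: str            # synonymous / nonsynonymous / not_applicable
    gene_id: str | None = None


def _first_transcripts(genes: Sequence[GeneModel]) -> list[GeneModel]:
    seen: set[str] = set()
    out = []
    for g in genes:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            out.append(g)
    return out


def classify_snp_effects(matrix: GenotypeMatrix, genes: Sequence[GeneModel],
                         reference) -> list[SnpEffect]:
    """Classify every site in the matrix by feature and coding effect.

    ``reference`` is a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta``).
    Sites whose reference base disagrees with the matrix ref allele are
    skipped with a log entry. Flagged transcripts (CDS % 3 != 0) contribute
    feature classification only.
    """
    models = _first_transcripts(genes)
    cds_tree: dict[str, IntervalTree] = {}
    utr_tree: dict[str, IntervalTree] = {}
    intron_tree: dict[str, IntervalTree] = {}
    for g in models:
        for s, e in g.cds:
            cds_tree.setdefault(g.chrom, IntervalTree()).addi(s - 1, e, g)
        for s, e in g.utr:
            utr_tree.setdefault(g.chrom, IntervalTree()).addi(s - 1, e, g)
        for s, e in g.introns():
            intron_tree.setdefault(g.chrom, IntervalTree()).addi(s - 1, e, g)

    cds_cache: dict[str, str] = {}

    def coding_sequence(g: GeneModel) -> str:
        if g.transcript_id not in cds_cache:
            seq = "".join(str(reference[g.chrom][s - 1:e]) for s, e in g.cds)
            if g.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
            cds_cache[g.transcript_id] = seq.upper()
        return cds_cache[g.transcript_id]

    effects: list[SnpEffect] = []
    mismatches = 0
    for i in range(matrix.n_sites):
        chrom = str(matrix.chrom[i])
        pos0 = int(matrix.pos[i]) - 1
        ref, alt = str(matrix.ref[i]), str(matrix.alt[i])
        ref_base = str(reference[chrom][pos0:pos0 + 1]).upper()
        if ref_base != ref:
            mismatches += 1
            continue

        hit = next(iter(cds_tree.get(chrom, IntervalTree()).at(pos0)), None)
        if hit is not None:
            g: GeneModel = hit.data
            if g.flagged:
                effects.append(SnpEffect(i, "CDS", "not_applicable", g.gene_id))
                continue
            offset = 0
            for s, e in g.cds:  # genomic order
                if s - 1 <= pos0 < e:
                    offset += pos0 - (s - 1)
                    break
                offset += e - (s - 1)
            cds = coding_sequence(g)
            if g.strand == "-":
                idx = len(cds) - 1 - offset
                alt_coding = alt.translate(_COMPLEMENT)
            else:
                idx = offset
                alt_coding = alt
            codon_i = idx // 3
            within = idx % 3
            codon = cds[3 * codon_i: 3 * codon_i + 3]
            mutant = codon[:within] + alt_coding + codon[within + 1:]
            aa0 = str(Seq(codon).translate())
            aa1 = str(Seq(mutant).translate())
            effect = "synonymous" if aa0 == aa1 else "nonsynonymous"
            effects.append(SnpEffect(i, "CDS", effect, g.gene_id))
            continue

        for cat, trees in (("UTR", utr_tree), ("intron", intron_tree)):
            hit = next(iter(trees.get(chrom, IntervalTree()).at(pos0)), None)
            if hit is not None:
                effects.append(SnpEffect(i, cat, "not_applicable", hit.data.gene_id))
                break
        else:
            effects.append(SnpEffect(i, "intergenic", "not_applicable", None))

    if mismatches:
        log.warning("classify_snp_effects: %d sites skipped "
                    "(reference base != ref allele)", mismatches)
    return effects


def effects_to_frame(effects: Sequence[SnpEffect]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_index": e.site_index, "category": e.category,
        "coding_effect": e.coding_effect, "gene_id": e.gene_id,
    } for e in effects], columns=["site_index", "category", "coding_effect", "gene_id"])


# ---------------------------------------------------------------------------
# Pool SNP sets
# ---------------------------------------------------------------------------

@dataclass
class PoolSnpSets:
    """Polymorphism membership per pool plus the derived set algebra.

    ``polymorphic[pool]`` / ``classifiable[pool]`` are boolean arrays over
    sites: a site is classifiable in a pool when it has >= ``min_calls``
    non-missing genotype calls there, and polymorphic when both alleles are
    observed among those calls. Venn classes are computed over sites
    classifiable in all three pools; the directed "fixed" sets require
    classifiability only in their two pools.
    """

    polymorphic: dict[str, np.ndarray]
    classifiable: dict[str, np.ndarray]

    @property
    def all_classifiable(self) -> np.ndarray:
        w, l, e = (self.classifiable[p] for p in ("wild", "landrace", "elite"))
        return w & l & e

    def venn_counts(self) -> dict[str, int]:
        base = self.all_classifiable
        w = self.polymorphic["wild"] & base
        l = self.polymorphic["landrace"] & base
        e = self.polymorphic["elite"] & base
        return {
            "wild_only": int((w & ~l & ~e).sum()),
            "landrace_only": int((~w & l & ~e).sum()),
            "elite_only": int((~w & ~l & e).sum()),
            "wild_landrace": int((w & l & ~e).sum()),
            "wild_elite": int((w & ~l & e).sum()),
            "landrace_elite": int((~w & l & e).sum()),
            "all_three": int((w & l & e).sum()),
        }

    def fixed_sites(self, ancestral: str, derived: str) -> np.ndarray:
        """Sites polymorphic in ``ancestral`` but monomorphic in ``derived``."""
        base = self.classifiable[ancestral] & self.classifiable[derived]
        return base & self.polymorphic[ancestral] & ~self.polymorphic[derived]

    @property
    def lost_domestication(self) -> np.ndarray:
        return self.fixed_sites("wild", "landrace")

    @property
    def lost_improvement(self) -> np.ndarray:
        return self.fixed_sites("landrace", "elite")


def pool_snp_sets(matrix: GenotypeMatrix, popmap: PopulationMap,
                  min_calls: int = 2) -> PoolSnpSets:
    """Within-pool polymorphism membership for wild / landrace / elite."""
    polymorphic, classifiable = {}, {}
    for pool in ("wild", "landrace", "elite"):
        idx = popmap.indices(matrix, pool)
        alt, n = matrix.allele_counts(idx)
        classifiable[pool] = n >= 2 * min_calls
        polymorphic[pool] = classifiable[pool] & (alt > 0) & (alt < n)
    return PoolSnpSets(polymorphic, classifiable)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment_chi2(selected_in: int, selected_out: int,
                    background_in: int, background_out: int,
                    correction: bool = False) -> tuple[float, float]:
    """Pearson χ² (1 df) on a 2×2 category table; continuity correction off
    by default. Returns (chi2, p). Zero margins raise ValueError."""
    table = np.array([[selected_in, selected_out],
                      [background_in, background_out]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("zero margin: category not testable")
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def enrichment_table(categories: dict[str, tuple[int, int, int, int]],
                     correction: bool = False) -> pd.DataFrame:
    """χ² per category; rows with a zero margin are skipped."""
    rows = []
    for cat, (a, b, c, d) in categories.items():
        try:
            chi2, p = enrichment_chi2(a, b, c, d, correction)
        except ValueError:
            continue
        rows.append((cat, a, b, c, d, chi2, p))
    return pd.DataFrame(rows, columns=[
        "category", "selected_in", "selected_out",
        "background_in", "background_out", "chi2", "p"])


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

def summary_report(
    *,
    total_snps: int | None = None,
    novel_snps: int | None = None,
    fixed_domestication: int | None = None,
    fixed_improvement: int | None = None,
    fixed_domestication_cds: int | None = None,
    fixed_domestication_nonsyn: int | None = None,
    domestication_region_bp: int | None = None,
    improvement_region_bp: int | None = None,
    domestication_genes: int | None = None,
    improvement_genes: int | None = None,
    annotated_genes: int | None = None,
    genome_size: float = 950e6,
) -> dict[str, float | str]:
    """Headline ratios as explicit pure formulas of their inputs.

    Every field is numerator/denominator on the scale the figure is usually
    printed at, rounded half-up to the stated precision; fields whose inputs
    are absent come back as "unavailable". ``genome_size`` defaults to the
    950 Mb soybean reference assembly.
    """
    out: dict[str, float | str] = {}

    def ratio(name, num, den, scale=100.0, digits=1):
        if num is None or den in (None, 0):
            out[name] = "unavailable"
        else:
            out[name] = round_half_up(scale * num / den, digits)

    ratio("novel_snp_pct", novel_snps, total_snps, digits=1)
    ratio("fixed_domestication_cds_pct", fixed_domestication_cds,
          fixed_domestication, digits=1)
    ratio("fixed_domestication_nonsyn_pct", fixed_domestication_nonsyn,
          fixed_domestication, digits=1)
    ratio("improvement_vs_domestication_fixed_pct", fixed_improvement,
          fixed_domestication, digits=0)
    ratio("domestication_genome_pct", domestication_region_bp, genome_size, digits=2)
    ratio("improvement_genome_pct", improvement_region_bp, genome_size, digits=2)
    ratio("domestication_gene_pct", domestication_genes, annotated_genes, digits=1)
    if (domestication_genes is not None and improvement_genes is not None
            and annotated_genes):
        ratio("selected_gene_pct", domestication_genes + improvement_genes,
              annotated_genes, digits=2)
    else:
        out["selected_gene_pct"] = "unavailable"
    return out
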