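"""Genotype panel data model, file I/O and site-quality filtering.

The central container is :class:`GenotypeMatrix`: biallelic SNP calls stored as
alt-allele dosages (0/1/2, -1 for missing) in a sites × samples ``int8`` array,
with per-site chromosome, position and allele metadata. Positions follow VCF
(1-based) at the file boundary; all interval arithmetic inside the package is
0-based half-open (:class:`Interval`).

Readers/writers: VCF 4.2 (GT-only, via cyvcf2 on the read path), GFF3 gene
models, 3-column BED, population-map TSV, per-site quality-metric TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1
POOLS = ("wild", "landrace", "elite")
_BASES = frozenset("ACGT")


class DomestiscanError(Exception):
    """Base error for user-facing failures."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open: covers positions start .. end-1."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "Interval") -> "Interval | None":
        if not self.overlaps(other):
            return None
        return Interval(self.chrom, max(self.start, other.start), min(self.end, other.end))


def vcf_pos_to_interval(chrom: str, pos: int) -> Interval:
    """Map a 1-based VCF position to the half-open interval covering that base."""
    return Interval(chrom, pos - 1, pos)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP panel: sites × samples alt-allele dosages.

    Invariants (checked by :meth:`validate`): sites sorted by (chrom, pos) and
    unique; every call in {0, 1, 2, MISSING}; ref != alt, both in {A,C,G,T};
    ``calls.shape == (n_sites, n_samples)``.
    """

    chrom: np.ndarray          # str per site
    pos: np.ndarray            # int64, 1-based (VCF convention)
    ref: np.ndarray            # single base per site
    alt: np.ndarray            # single base per site
    calls: np.ndarray          # int8 (n_sites, n_samples), MISSING = -1
    sample_ids: list[str]

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim == 1:
            self.calls = self.calls.reshape(len(self.pos), -1)
        self.sample_ids = list(self.sample_ids)

    # -- basic properties ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        n = self.n_sites
        if self.calls.shape != (n, self.n_samples):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {self.n_samples})"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing (-1)")
        for r, a in zip(self.ref, self.alt):
            if r not in _BASES or a not in _BASES or r == a:
                raise ValueError(f"bad allele pair {r}/{a}")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        key = list(zip(self.chrom, self.pos))
        if len(set(key)) != n:
            raise ValueError("duplicate (chrom, pos)")

    def sort_sites(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_sites(order)

    def take_sites(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.calls[idx], self.sample_ids,
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in names if s not in self.sample_ids]
        if missing:
            raise DomestiscanError(f"unknown samples: {missing}")
        cols = [self.sample_ids.index(s) for s in names]
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref, self.alt,
            self.calls[:, cols], list(names),
        )

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.sample_ids.index(s) for s in names], dtype=int)

    def allele_counts(self, sample_idx: Sequence[int] | None = None):
        """Per-site (alt allele count, called allele count) over the given samples."""
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        called = calls >= 0
        alt = np.where(called, calls, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Assignment of each sample to one gene pool (wild / landrace / elite)."""

    assignments: dict[str, str]

    def __post_init__(self):
        bad = {p for p in self.assignments.values() if p not in POOLS}
        if bad:
            raise DomestiscanError(f"unknown pool labels: {sorted(bad)} (allowed: {POOLS})")

    def samples(self, pool: str | Iterable[str]) -> list[str]:
        pools = {pool} if isinstance(pool, str) else set(pool)
        return [s for s, p in self.assignments.items() if p in pools]

    def indices(self, matrix: GenotypeMatrix, pool: str | Iterable[str]) -> np.ndarray:
        names = [s for s in self.samples(pool) if s in matrix.sample_ids]
        if not names:
            raise DomestiscanError(f"pool {pool!r} has no samples in the matrix")
        return matrix.sample_indices(names)

    def check_covers(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise DomestiscanError(f"samples without a pool assignment: {missing}")

    @classmethod
    def read(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "pool"],
                         dtype=str, comment="#")
        return cls(dict(zip(df.sample_id, df.pool)))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records, indels and non-ACGT alleles are skipped (count
    logged). Genotypes map to alt dosage; half-calls and ``./.`` become
    missing. Raises if no site is retained.
    """
    vcf = VCF(str(path), gts012=True)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise DomestiscanError(f"sample_subset names unknown samples: {unknown}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    chrom, pos, ref, alt, rows = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        r, a = v.REF.upper(), v.ALT[0].upper()
        if r not in _BASES or a not in _BASES or r == a:
            skipped += 1
            continue
        # gts012: 0=homref 1=het 2=homalt 3=unknown
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(r)
        alt.append(a)
        rows.append(gt)
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise DomestiscanError(f"no biallelic SNP records retained from {path}")
    m = GenotypeMatrix(
        np.array(chrom, dtype=object), np.array(pos), np.array(ref, dtype=object),
        np.array(alt, dtype=object), np.vstack(rows), samples,
    ).sort_sites()
    m.validate()
    return m


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path,
              chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GT-only VCF 4.2 such that ``read_vcf(write_vcf(m)) == m``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan\n")
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(matrix.pos[matrix.chrom == c].max()) if matrix.n_sites else 1
                for c in matrix.chromosomes()
            }
        for c, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT[int(g)] for g in matrix.calls[i])
            fh.write(f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                     f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Site-quality metrics and filtering
# ---------------------------------------------------------------------------

@dataclass
class SiteMetrics:
    """Per-site calling-quality metrics used by :func:`filter_sites`.

    ``het_ranksum_p`` is NaN for homozygous sites (the rank-sum test only
    applies to heterozygote calls).
    """

    depth: np.ndarray
    copy_number: np.ndarray
    quality: np.ndarray
    het_ranksum_p: np.ndarray      # NaN when absent
    minor_allele_count: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.copy_number = np.asarray(self.copy_number, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        self.het_ranksum_p = np.asarray(self.het_ranksum_p, dtype=float)
        self.minor_allele_count = np.asarray(self.minor_allele_count, dtype=np.int64)
        n = len(self.depth)
        for arr in (self.copy_number, self.quality, self.het_ranksum_p,
                    self.minor_allele_count):
            if len(arr) != n:
                raise ValueError("SiteMetrics arrays must share one length")

    def __len__(self) -> int:
        return len(self.depth)

    @classmethod
    def read(cls, path) -> "SiteMetrics":
        df = pd.read_csv(path, sep="\t")
        return cls(df["depth"].to_numpy(), df["copy_number"].to_numpy(),
                   df["quality"].to_numpy(), df["het_ranksum_p"].to_numpy(),
                   df["minor_allele_count"].to_numpy())

    def write(self, path) -> None:
        pd.DataFrame({
            "depth": self.depth, "copy_number": self.copy_number,
            "quality": self.quality, "het_ranksum_p": self.het_ranksum_p,
            "minor_allele_count": self.minor_allele_count,
        }).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterThresholds:
    """Site-acceptance thresholds.

    Defaults follow the resequencing-panel quality rules: summed depth strictly
    between ``min_depth`` and ``max_depth``, copy number at most
    ``max_copy_number``, consensus quality strictly above ``min_quality``,
    heterozygote rank-sum p at least ``min_het_p`` (only where present), and
    minor allele count at least ``min_mac`` (3 = drop singletons and
    doubletons; relax to 2 to keep doubletons).
    """

    min_depth: float = 20.0
    max_depth: float = 160.0
    max_copy_number: float = 1.5
    min_quality: float = 20.0
    min_het_p: float = 0.05
    min_mac: int = 3


def filter_sites(matrix: GenotypeMatrix, metrics: SiteMetrics,
                 thresholds: FilterThresholds = FilterThresholds(),
                 ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep sites passing all quality criteria; report per-criterion rejections.

    A site must satisfy every criterion; rejection counts are tallied per
    criterion independently (one bad site may increment several counters).
    """
    if len(metrics) != matrix.n_sites:
        raise DomestiscanError(
            f"metrics cover {len(metrics)} sites but matrix has {matrix.n_sites}")
    t = thresholds
    pass_depth = (metrics.depth > t.min_depth) & (metrics.depth < t.max_depth)
    pass_copy = metrics.copy_number <= t.max_copy_number
    pass_qual = metrics.quality > t.min_quality
    p = metrics.het_ranksum_p
    pass_het = np.isnan(p) | (p >= t.min_het_p)
    pass_mac = metrics.minor_allele_count >= t.min_mac
    keep = pass_depth & pass_copy & pass_qual & pass_het & pass_mac
    counts = {
        "depth": int((~pass_depth).sum()),
        "copy_number": int((~pass_copy).sum()),
        "quality": int((~pass_qual).sum()),
        "het_ranksum": int((~pass_het).sum()),
        "minor_allele_count": int((~pass_mac).sum()),
        "retained": int(keep.sum()),
    }
    return matrix.take_sites(keep), counts


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript's gene model with 1-based inclusive segments.

    ``cds`` segments are stored in genomic order; ``strand`` determines coding
    orientation. ``flagged`` marks transcripts whose total CDS length is not a
    multiple of 3 — kept for feature classification but unusable for
    codon-level effect calls.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr: list[tuple[int, int]] = field(default_factory=list)
    flagged: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.cds = sorted(self.cds)
        self.utr = sorted(self.utr)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.transcript_id}")
        self.flagged = self.flagged or (self.cds_length % 3 != 0)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> Interval:
        segs = self.cds + self.utr
        if not segs:
            raise ValueError(f"{self.transcript_id}: no segments")
        return Interval(self.chrom, min(s for s, _ in segs) - 1,
                        max(e for _, e in segs))

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exonic (CDS/UTR) segments, 1-based inclusive."""
        segs = sorted(self.cds + self.utr)
        out = []
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1 + 0, s2 - 1))
        return [(s, e) for s, e in out if s <= e]


_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR", "5'UTR", "3'UTR"}


def read_gff(path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS/UTR features from a GFF3 into GeneModels.

    One model per mRNA. A transcript whose CDS length is not divisible by 3 is
    flagged, not dropped. Orphan CDS/UTR lines (bad Parent) raise.
    """
    transcripts: dict[str, GeneModel] = {}
    t_parent: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    utr: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise DomestiscanError(f"malformed GFF line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "mRNA":
                tid = a.get("ID")
                if tid is None:
                    raise DomestiscanError("mRNA without ID")
                t_parent[tid] = a.get("Parent", tid)
                meta[tid] = (chrom, strand)
            elif ftype == "CDS" or ftype in _UTR_TYPES:
                parent = a.get("Parent")
                if parent is None:
                    raise DomestiscanError(f"{ftype} feature without Parent")
                bucket = cds if ftype == "CDS" else utr
                for p in parent.split(","):
                    bucket.setdefault(p, []).append((int(start), int(end)))

    models = []
    for tid, (chrom, strand) in meta.items():
        models.append(GeneModel(
            gene_id=t_parent[tid], transcript_id=tid, chrom=chrom, strand=strand,
            cds=cds.pop(tid, []), utr=utr.pop(tid, []),
        ))
    orphans = set(cds) | set(utr)
    if orphans:
        raise DomestiscanError(f"CDS/UTR features with unknown Parent: {sorted(orphans)}")
    n_flagged = sum(m.flagged for m in models)
    if n_flagged:
        log.warning("read_gff: %d transcripts flagged (CDS length %% 3 != 0)", n_flagged)
    return models


def write_gff(models: Sequence[GeneModel], path) -> None:
    """Write GeneModels back to GFF3 (gene/mRNA/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            sp = m.span
            fh.write(f"{m.chrom}\tdomestiscan\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tdomestiscan\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t"
                     f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\tdomestiscan\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                         f".\tParent={m.transcript_id}\n")
            for s, e in m.utr:
                fh.write(f"{m.chrom}\tdomestiscan\tfive_prime_UTR\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tParent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    """Read a 3+-column BED (0-based half-open) into Intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[Interval], path,
              labels: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            extra = f"\t{labels[i]}" if labels is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")
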