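"""End-to-end run orchestration: simulate/load → filter → diversity →
differentiation → scans → regions → annotation → report.

Each stage is a pure function of its input tables; the orchestrator only
wires stages together, writes every intermediate table into the run
directory, and echoes the configuration (thresholds, seed) into the report
metadata so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diversity import WindowSpec, diversity_scan
from .differentiation import pbs_scan
from .io_model import (DomestiscanError, FilterThresholds, PopulationMap,
                       SiteMetrics, filter_sites, read_gff, read_vcf,
                       write_vcf)
from .ld import LdConfig
from .selection_scan import (ScanConfig, SelectionRegion, annotate_regions,
                             domestication_scan, improvement_scan,
                             make_windows, merge_windows, regions_to_frame,
                             total_genes)
from .synthetic_data import (DemographyConfig, SweepSpec, read_truth,
                             simulate_panel, write_truth)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline invocation.

    Either ``vcf`` + ``popmap`` point at an existing panel, or ``simulate``
    is true and the panel comes from :mod:`domestiscan.synthetic_data` with
    ``demography``/``sweeps``. Optional: ``metrics`` (site-quality TSV,
    enables filtering), ``gff`` (gene annotation), ``truth_bed``
    (recall/precision against planted sweeps).
    """

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    vcf: str | None = None
    popmap: str | None = None
    metrics: str | None = None
    gff: str | None = None
    truth_bed: str | None = None
    genome_size: float | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    scan: ScanConfig = field(default_factory=ScanConfig)
    ld: LdConfig = field(default_factory=LdConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    demography: DemographyConfig = field(default_factory=DemographyConfig)
    sweeps: list[SweepSpec] = field(default_factory=list)
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io_model import Interval

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        for key, typ in (("window", WindowSpec), ("scan", ScanConfig),
                         ("ld", LdConfig), ("thresholds", FilterThresholds)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = typ(**kw[key])
        if isinstance(kw.get("demography"), dict):
            kw["demography"] = DemographyConfig(**kw["demography"])
        if "sweeps" in kw:
            kw["sweeps"] = [
                SweepSpec(Interval(s["chrom"], s["start"], s["end"]),
                          s.get("target", "domestication"),
                          s.get("suppression", 0.05))
                for s in kw["sweeps"]]
        return cls(**kw)


class StageError(DomestiscanError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                res = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return res
        return wrapped
    return deco


def sweep_recall_precision(regions: list[SelectionRegion],
                           truth: list[SweepSpec], label: str) -> dict:
    """Recall = fraction of planted sweeps hit by >= 1 called region;
    precision = fraction of called regions overlapping >= 1 sweep."""
    planted = [s.interval for s in truth if s.target == label]
    called = [r.interval for r in regions]
    hit = sum(any(p.overlaps(c) for c in called) for p in planted)
    good = sum(any(c.overlaps(p) for p in planted) for c in called)
    return {
        "label": label,
        "n_planted": len(planted),
        "n_called": len(called),
        "recall": hit / len(planted) if planted else float("nan"),
        "precision": good / len(called) if called else float("nan"),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the full scan; returns the run directory.

    Deterministic given config + seed. Refuses to overwrite an existing
    report unless ``config.force``.
    """
    out = Path(config.out_dir)
    report_path = out / "report.json"
    if report_path.exists() and not config.force:
        raise DomestiscanError(f"{report_path} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(fh)

    try:
        return _run(config, out, report_path)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path, report_path: Path) -> Path:
    truth: list[SweepSpec] = []

    @_stage("input")
    def load():
        nonlocal truth
        if config.simulate:
            demo = DemographyConfig(**{**asdict_flat(config.demography),
                                       "seed": config.seed})
            matrix, popmap, sweeps = simulate_panel(demo, config.sweeps)
            truth = sweeps
            write_vcf(matrix, out / "panel.vcf",
                      {demo.chrom: demo.chrom_length})
            popmap.write(out / "panel.popmap.tsv")
            write_truth(sweeps, out / "truth.bed")
            lengths = {demo.chrom: demo.chrom_length}
            return matrix, popmap, lengths
        if not config.vcf or not config.popmap:
            raise DomestiscanError("need vcf and popmap when simulate is false")
        matrix = read_vcf(config.vcf)
        popmap = PopulationMap.read(config.popmap)
        popmap.check_covers(matrix)
        if config.truth_bed:
            truth = read_truth(config.truth_bed)
        lengths = {c: int(matrix.pos[matrix.chrom == c].max())
                   for c in matrix.chromosomes()}
        return matrix, popmap, lengths

    matrix, popmap, lengths = load()

    @_stage("filter")
    def filt(m):
        if config.metrics is None:
            return m, None
        metrics = SiteMetrics.read(config.metrics)
        filtered, counts = filter_sites(m, metrics, config.thresholds)
        return filtered, counts

    matrix, filter_counts = filt(matrix)

    windows = make_windows(lengths, config.window)

    @_stage("diversity")
    def diversity():
        tables = {}
        for pool in ("wild", "landrace", "elite"):
            tables[pool] = diversity_scan(matrix, popmap, pool, windows)
        tables["cultivated"] = diversity_scan(
            matrix, popmap, list(config.scan.cultivated_pools), windows)
        for name, t in tables.items():
            t.to_csv(out / f"diversity.{name}.tsv", sep="\t", index=False)
        return tables

    div = diversity()

    @_stage("differentiation")
    def differentiation():
        t = pbs_scan(matrix, popmap, windows, focal="elite")
        t.to_csv(out / "pbs.tsv", sep="\t", index=False)
        return t

    pbs_table = differentiation()

    @_stage("scan")
    def scans():
        dom = domestication_scan(div["wild"], div["cultivated"], config.scan)
        imp = improvement_scan(pbs_table, config.scan)
        dom.to_csv(out / "scan.domestication.tsv", sep="\t", index=False)
        imp.to_csv(out / "scan.improvement.tsv", sep="\t", index=False)
        return dom, imp

    dom_scan, imp_scan = scans()

    @_stage("regions")
    def regions():
        dom = merge_windows(dom_scan, "domestication", "z_ratio")
        imp = merge_windows(imp_scan, "improvement", "pbs")
        if config.gff:
            genes = read_gff(config.gff)
            annotate_regions(dom, genes)
            annotate_regions(imp, genes)
        for label, regs in (("domestication", dom), ("improvement", imp)):
            df = regions_to_frame(regs)
            df.to_csv(out / f"regions.{label}.tsv", sep="\t", index=False)
            with open(out / f"regions.{label}.bed", "w") as fh:
                for r in regs:
                    fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                             f"{r.interval.end}\t{label}\n")
        return dom, imp

    dom_regions, imp_regions = regions()

    @_stage("report")
    def report():
        genome = config.genome_size or sum(lengths.values())
        rep = {
            "domestiscan_version": __version__,
            "seed": config.seed,
            "config": {
                "window": asdict_flat(config.window),
                "scan": asdict_flat(config.scan),
                "thresholds": asdict_flat(config.thresholds),
                "genome_size": genome,
            },
            "n_sites": int(matrix.n_sites),
            "n_samples": int(matrix.n_samples),
            "filter_counts": filter_counts,
            "n_windows": len(windows),
            "domestication": {
                "n_regions": len(dom_regions),
                "total_bp": sum(r.length for r in dom_regions),
                "genome_pct": 100.0 * sum(r.length for r in dom_regions) / genome,
                "n_genes": total_genes(dom_regions),
            },
            "improvement": {
                "n_regions": len(imp_regions),
                "total_bp": sum(r.length for r in imp_regions),
                "genome_pct": 100.0 * sum(r.length for r in imp_regions) / genome,
                "n_genes": total_genes(imp_regions),
            },
        }
        if truth:
            rep["truth"] = {
                "domestication": sweep_recall_precision(
                    dom_regions, truth, "domestication"),
                "improvement": sweep_recall_precision(
                    imp_regions, truth, "improvement"),
            }
        with open(report_path, "w") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
        return rep

    report()
    return out


def asdict_flat(obj) -> dict:
    """dataclass -> plain dict with JSON-safe values."""
    d = asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
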