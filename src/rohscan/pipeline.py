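"""End-to-end orchestration: qc -> detect -> inbreeding -> islands -> report.

``run_pipeline`` composes the module operations with no hidden state: its
outputs equal what the individual functions return when called directly.
Every run writes its resolved configuration next to the outputs, and a
MANIFEST lists the files produced (or notes incompleteness after a failure).

Report tables round percents to 2 dp and inbreeding coefficients to 3 dp;
full-precision companions are written alongside with a ``_full`` suffix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import inbreeding as inb
from . import io as gio
from . import islands as isl
from .scan import ScanParams, classify_segments, per_chromosome_summary, scan_population

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    genotypes: str
    outdir: str
    format: str = "vcf"
    pedigree: str | None = None
    genes_bed: str | None = None
    qtl_bed: str | None = None
    maf_min: float = 0.05
    call_rate_min: float = 0.30
    l_auto: int = gio.DEFAULT_GENOME_BP
    top_fraction: float = 0.01
    n_males: int | None = None
    n_females: int | None = None
    scan: ScanParams = field(default_factory=ScanParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scan"]["length_class_bounds_mb"] = list(self.scan.length_class_bounds_mb)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        scan_d = d.pop("scan", {})
        if "length_class_bounds_mb" in scan_d:
            scan_d["length_class_bounds_mb"] = tuple(scan_d["length_class_bounds_mb"])
        return cls(scan=ScanParams(**scan_d), **d)


def _round_table(df: pd.DataFrame, percent_cols: tuple[str, ...] = (),
                 f_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    out = df.copy()
    for c in percent_cols:
        if c in out.columns:
            out[c] = out[c].round(2)
    for c in f_cols:
        if c in out.columns:
            out[c] = out[c].round(3)
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.to_yaml(outdir / "resolved_config.yaml")
    outputs: dict[str, Path] = {"resolved_config": outdir / "resolved_config.yaml"}
    manifest = outdir / "MANIFEST.txt"
    stage = "read"
    try:
        g = gio.read_genotypes(cfg.genotypes, cfg.format, genome_length_bp=cfg.l_auto)
        log.info("read %d samples x %d SNPs", g.n_samples, g.markers.n_snps)

        stage = "qc"
        g = gio.qc_filter(g, cfg.maf_min, cfg.call_rate_min)

        stage = "detect"
        segments = scan_population(g, cfg.scan)
        gio.write_segments(segments, outdir / "segments.tsv")
        outputs["segments"] = outdir / "segments.tsv"

        stage = "length_classes"
        classes = classify_segments(segments, n_individuals=g.n_samples,
                                    genome_length_bp=cfg.l_auto,
                                    bounds_mb=cfg.scan.length_class_bounds_mb)
        classes.to_csv(outdir / "length_classes_full.tsv", sep="\t", index=False)
        _round_table(classes, percent_cols=("percent", "coverage_percent"),
                     f_cols=()).round(2).to_csv(outdir / "length_classes.tsv",
                                                sep="\t", index=False)
        outputs["length_classes"] = outdir / "length_classes.tsv"

        stage = "per_chromosome"
        per_chrom = per_chromosome_summary(segments, g.markers.chrom_lengths(), g.n_samples)
        _round_table(per_chrom, percent_cols=("coverage_percent",)).to_csv(
            outdir / "per_chromosome.tsv", sep="\t", index=False)
        outputs["per_chromosome"] = outdir / "per_chromosome.tsv"

        stage = "inbreeding"
        ped = gio.read_pedigree(cfg.pedigree) if cfg.pedigree else None
        ftab = inb.inbreeding_table(g, segments, pedigree=ped, l_auto=cfg.l_auto,
                                    bounds_mb=cfg.scan.length_class_bounds_mb)
        gio.write_inbreeding(ftab, outdir / "f_table_full.tsv")
        gio.write_inbreeding(ftab.round(3), outdir / "f_table.tsv")
        outputs["f_table"] = outdir / "f_table.tsv"
        summary = inb.summarize_estimators(ftab)
        summary.round(3).to_csv(outdir / "f_summary.tsv", sep="\t", index_label="estimator")
        outputs["f_summary"] = outdir / "f_summary.tsv"
        inb.correlation_report(ftab).to_csv(outdir / "correlations.tsv", sep="\t",
                                            index_label="estimator")
        outputs["correlations"] = outdir / "correlations.tsv"

        stage = "diversity"
        div = inb.diversity(g, cfg.n_males, cfg.n_females)
        pd.DataFrame([dataclasses.asdict(div)]).round(4).to_csv(
            outdir / "diversity.tsv", sep="\t", index=False)
        outputs["diversity"] = outdir / "diversity.tsv"

        stage = "islands"
        track = isl.incidence(segments, g.markers, g.n_samples)
        track.to_csv(outdir / "incidence.tsv", sep="\t", index=False)
        outputs["incidence"] = outdir / "incidence.tsv"
        regions = isl.call_islands(track, cfg.top_fraction)
        if cfg.genes_bed:
            regions = isl.overlap_annotations(regions, gio.read_intervals(
                cfg.genes_bed, category="gene"))
        if cfg.qtl_bed:
            regions = isl.overlap_annotations(regions, gio.read_intervals(
                cfg.qtl_bed, category="QTL"))
        gio.write_islands(regions, outdir / "islands.tsv")
        outputs["islands"] = outdir / "islands.tsv"
        ann = gio.AnnotationIntervals(pd.DataFrame(
            [(r.chrom, r.start_bp, r.end_bp, f"island_{k + 1}", "ROH_island")
             for k, r in enumerate(regions)],
            columns=["chrom", "start_bp", "end_bp", "name", "category"]))
        gio.write_intervals(ann, outdir / "islands.bed")
        outputs["islands_bed"] = outdir / "islands.bed"
    except Exception as e:
        with open(manifest, "w") as fh:
            fh.write(f"INCOMPLETE: failed at stage '{stage}': {e}\n")
            for name, p in outputs.items():
                fh.write(f"{name}\t{p.name}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e
    with open(manifest, "w") as fh:
        fh.write("COMPLETE\n")
        for name, p in outputs.items():
            fh.write(f"{name}\t{p.name}\n")
    outputs["manifest"] = manifest
    return outputs
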