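"""ROH islands: per-SNP incidence, top-1% calling, annotation overlap.

Builds the incidence track over the QC'd marker map, selects SNPs in the
top 1% of incidence (ties included), merges adjoining selected SNPs into
islands, and annotates islands against the synthetic gene and QTL interval
sets written by 01.
"""

from pathlib import Path

import rohscan.io as gio
from rohscan import call_islands, incidence, overlap_annotations
from rohscan.islands import islands_to_frame

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"

g = gio.qc_filter(gio.read_genotypes(DATA / "cohort.vcf", "vcf"))
segments = gio.read_segments(BASE / "segments.tsv")

track = incidence(segments, g.markers, g.n_samples)
track.to_csv(BASE / "incidence.tsv", sep="\t", index=False)

islands = call_islands(track, top_fraction=0.01)
islands = overlap_annotations(islands, gio.read_intervals(
    DATA / "genes_synthetic.bed", category="gene"))
islands = overlap_annotations(islands, gio.read_intervals(
    DATA / "qtl_synthetic.bed", category="QTL"))
gio.write_islands(islands, BASE / "islands.tsv")

df = islands_to_frame(islands)
print(f"{len(islands)} islands from {len(track)} SNPs "
      f"(max incidence {track.incidence.max():.3f})")
if len(df):
    print(df.assign(length_mb=(df.length_bp / 1e6).round(3))
            [["chrom", "start_bp", "end_bp", "length_mb", "n_snps", "max_incidence"]]
            .to_string(index=False))
    n_genes = sum(1 for i in islands for a in i.annotations if not a.startswith("QTL:"))
    n_qtl = sum(1 for i in islands for a in i.annotations if a.startswith("QTL:"))
    print(f"annotation overlaps: {n_genes} gene hits, {n_qtl} QTL hits")
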