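"""Simulate a study-shaped cohort with known ground truth.

Generates 93 pigs (17 males, 76 females) on 18 autosomes totalling 2.26 Gb
at ~12.4-kb SNP spacing, with per-individual planted autozygosity ranging
from 0.01 to 0.25 (mean 0.13; tract lengths exponential, mean 5 Mb) to
emulate the wide individual variation in genomic inbreeding the study design
expects, a pedigree containing inbred and outbred families, and synthetic
gene/QTL annotation intervals. Everything downstream (02-05) reads the
files written here.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import rohscan.io as gio
from rohscan import SimulationConfig, simulate_cohort, simulate_pedigree

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

f_targets = np.linspace(0.01, 0.25, 93)
cfg = SimulationConfig(seed=SEED, autozygosity=f_targets, generations_to_ancestor=10.0)
g, truth = simulate_cohort(cfg)
gio.write_vcf(g, OUT / "cohort.vcf")

truth_df = pd.DataFrame([(t.sample, t.chrom, t.start_bp, t.end_bp, t.length_bp)
                         for t in truth],
                        columns=["sample", "chrom", "start_bp", "end_bp", "length_bp"])
truth_df.to_csv(OUT / "truth_tracts.tsv", sep="\t", index=False)

# pedigree: a full-sib line grafted onto founders named like the cohort samples
ped = simulate_pedigree(scheme="full_sib_line", n_generations=2)
gio.write_pedigree(ped, OUT / "pedigree.txt")

# synthetic annotation intervals (random placement; names are placeholders)
rng = np.random.default_rng(SEED)
rows = []
for k in range(300):
    chrom = str(rng.integers(1, 19))
    length = int(rng.integers(5_000, 300_000))
    start = int(rng.integers(1, cfg.chrom_lengths_bp[chrom] - length))
    rows.append((chrom, start, start + length, f"SYNGENE{k:03d}", "gene"))
for k in range(50):
    chrom = str(rng.integers(1, 19))
    length = int(rng.integers(200_000, 3_000_000))
    start = int(rng.integers(1, cfg.chrom_lengths_bp[chrom] - length))
    rows.append((chrom, start, start + length, f"SYNQTL{k:02d}", "QTL"))
ann = gio.AnnotationIntervals(pd.DataFrame(
    rows, columns=["chrom", "start_bp", "end_bp", "name", "category"]))
gio.write_intervals(gio.AnnotationIntervals(ann.table[ann.table.category == "gene"]),
                    OUT / "genes_synthetic.bed")
gio.write_intervals(gio.AnnotationIntervals(ann.table[ann.table.category == "QTL"]),
                    OUT / "qtl_synthetic.bed")

per_ind = truth_df.groupby("sample")["length_bp"].sum() / cfg.genome_length_bp
print(f"wrote cohort: {g.n_samples} individuals, {g.markers.n_snps} SNPs, "
      f"{len(truth)} planted tracts")
print(f"planted autozygosity: mean {per_ind.mean():.4f} "
      f"(range {per_ind.min():.4f}-{per_ind.max():.4f})")
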