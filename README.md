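# rohscan

Runs-of-homozygosity (ROH) analysis for diploid SNP data from a single
population: sliding-window ROH detection, genomic and pedigree inbreeding
coefficients, diversity statistics, and ROH-island (selection-signature
hotspot) mapping with annotation overlap. Built for livestock conservation
genetics — the default genome model is the 18 pig autosomes (2.26 Gb) —
but every genome parameter is configurable.

Because real reduced-representation datasets of this kind are rarely
deposited, the package ships a synthetic-data module that generates
genotype cohorts with *planted* autozygous tracts and shared homozygous
regions, so every stage of the pipeline can be validated against known
ground truth without downloading anything.

## The statistics

**ROH detection** follows the PLINK `--homozyg` scheme: windows of 50 SNPs
slide along each chromosome; a window is homozygous if it has ≤ 1
heterozygous and ≤ 5 missing calls; a SNP is eligible when ≥ 5% of the
windows covering it are homozygous. Maximal runs of eligible SNPs are
trimmed to homozygous end-calls, split at inter-SNP gaps > 1 Mb, and kept
if they have ≥ 100 SNPs, span ≥ 1 Mb, and average ≤ 50 kb per SNP.
Segments are classified into 1–5, 5–10, and > 10 Mb length classes.

**Inbreeding coefficients**, per individual:

- `F_PED` — Wright's coefficient, half the additive relationship between
  the parents, computed by the tabular recursion over the pedigree;
- `F_ROH = L_ROH / L_auto` — the fraction of the autosomal genome covered
  by ROH, with per-length-class components that sum exactly to the total;
- `F_SNP1` = (1/n) Σ (Yᵢ − 2pᵢ)²/hᵢ − 1 (variance of additive genotypes),
  `F_SNP2` = 1 − (1/n) Σ Yᵢ(2 − Yᵢ)/hᵢ (homozygosity excess),
  `F_SNP3` = (1/n) Σ [Yᵢ² − Yᵢ(1 + 2pᵢ) + 2pᵢ²]/hᵢ (uniting-gamete
  correlation), with hᵢ = 2pᵢ(1 − pᵢ) and cohort allele frequencies pᵢ.

All estimator pairs are compared by Pearson correlation. Diversity is
summarised as observed/expected heterozygosity and an effective population
size Nₑ = 16·Nm·Nf/(Nm + Nf) for equalised family sizes (the standard
4·Nm·Nf/(Nm + Nf) is available behind a flag).

**ROH islands**: each SNP's incidence is the fraction of individuals with
an ROH covering its position; SNPs in the top 1% of incidence (ties
included) are selected, and maximal runs of adjoining selected SNPs merge
into islands, which are then intersected with user-supplied gene/QTL BED
intervals (any shared bp counts).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort shaped like a 93-animal conservation herd (write their tables under
`results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_detect_roh.py
python analysis/03_inbreeding_estimates.py
python analysis/04_roh_islands.py
python analysis/05_pedigree_comparison.py
```

`02_detect_roh.py` prints, for the seeded example cohort:

```
QC: 178777 SNPs retained (removed 3472)
4501 ROH segments in 93 individuals
     class  count  percent  mean_length_mb  sd_length_mb  coverage_percent
       1-5   2541    56.45            2.85          1.06              3.45
      5-10   1291    28.68            7.12          1.43              4.37
       >10    669    14.86           14.46          4.53              4.60
Total (>1)   4501   100.00            5.80          4.56             12.42
```

i.e. 4,501 runs of homozygosity whose total coverage (12.42% of
93 × 2.26 Gb) matches the planted mean autozygosity of 0.13 up to detection
loss, and `03_inbreeding_estimates.py` confirms the per-individual recovery:

```
F_ROH_all vs planted autozygosity: r = 1.000 (mean F_ROH 0.1242 vs planted 0.1302)
Ho = 0.322, He = 0.368, Ne(16NmNf/(Nm+Nf)) = 222.3
```

The same operations are available as a library (`import rohscan`) and as a
CLI (`rohscan simulate|qc|detect|inbreeding|islands|run`), e.g.

```sh
rohscan detect --vcf cohort.vcf --min-snp 100 --window-snp 50 --min-kb 1000 -o segments.tsv
```

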