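# Methods

## Scope and data model

`rohscan` analyses diploid autosomal SNP genotypes from one population.
Genotypes are held as a samples × SNPs int8 matrix with codes 0 (hom-ref),
1 (het), 2 (hom-alt) and −1 (missing; half-missing calls are demoted to
missing), aligned with an ordered marker map. Coordinates are 1-based
inclusive internally; BED input/output converts to/from 0-based half-open
at the boundary. Chromosomes outside a declared ordered autosome list
(default: pig autosomes 1–18) are dropped at read time — sex chromosomes
and mitochondria are intentionally out of model. Missing genotypes are
never imputed; imputation, variant calling and phasing are upstream of
this package.

QC keeps SNPs with minor allele frequency ≥ 0.05 (computed on non-missing
calls) and call rate ≥ 0.30. Both thresholds are parameters; the defaults
reflect reduced-representation sequencing panels, whose uneven coverage
makes a permissive call-rate filter appropriate.

## ROH detection

The scanner reproduces the PLINK `--homozyg` logic explicitly:

1. all windows of `window_snp` (50) consecutive SNPs on a chromosome are
   classified; a window passes with ≤ `window_het_max` (1) heterozygous and
   ≤ `window_missing_max` (5) missing calls;
2. a SNP is *eligible* if the fraction of windows covering it that pass is
   ≥ `window_hit_fraction` (0.05);
3. maximal runs of eligible SNPs are split at inter-SNP gaps >
   `max_gap_bp` (1 Mb) and each piece is trimmed so it neither starts nor
   ends on a heterozygous or missing call (trimming is applied after the
   gap split so the guarantee holds for every final segment);
4. pieces are kept if they contain ≥ `min_snp` (100) SNPs, span ≥
   `min_length_bp` (1 Mb), and have density ≤ `density_bp_per_snp`
   (50 kb per SNP).

The window-hit threshold and maximum gap are the PLINK defaults; both are
exposed because tools differ here and the choice matters near segment
boundaries. Windows never span chromosomes. Segment length is defined as
`end_bp − start_bp` (simple difference), matching the island-length
convention, with an `inclusive_length` flag for the `+1` alternative.
Length classes are left-closed right-open: [1, 5), [5, 10), [10, ∞) Mb —
the published class labels are ambiguous exactly at 5 and 10 Mb, so the
convention is fixed here and configurable. A segment shorter than the
first bound reaching the classifier is treated as an upstream error, not
silently reclassified.

Every scan result is checked against the segment invariants (SNP count,
length, density, per-individual non-overlap) before being returned. The
test suite additionally holds the scanner equal to a brute-force
enumerator (plain loops, no cumulative sums) on hundreds of randomized
2,000-SNP fixtures, and checks monotonicity: raising `min_length_bp` never
adds segments; forbidding window heterozygotes never adds covered length.

## Inbreeding coefficients

`F_PED` uses the tabular additive-relationship recursion in topological
order; founders (including any parent referenced but not listed) are
assumed non-inbred and unrelated, so F(x) = ½·a(sire, dam). The unit tests
cross-check it against an independent memoised kinship recursion on all
273 valid ≤ 4-member pedigrees (exhaustive) and on random ≤ 8-member
pedigrees, plus the classical full-sib / half-sib line values.

`F_ROH` = Σ segment lengths / `L_auto` with `L_auto` defaulting to
2.26 Gb; per-class components are sums over the same segments restricted
to each length class and therefore equal the total exactly, a property the
tests assert as an identity (not within tolerance). Overlapping segments
for one individual raise rather than being merged: they cannot be produced
by the scanner and indicate corrupted input.

The three SNP estimators use the cohort sample frequency of the counted
allele. A per-individual frequency (what a naive reading of "for this
individual" would require) is not estimable from one genotype; the cohort
frequency is the convention of the GCTA `--ibc` implementation these
estimators come from. SNPs monomorphic in the cohort are excluded (their
2p(1−p) denominator vanishes) with a logged count; an individual's missing
calls drop out of that individual's sum with n reduced accordingly; an
individual with no usable SNP gets NaN plus a warning, never a silent 0.
Under Hardy–Weinberg equilibrium all three estimators have expectation 0,
which the tests verify at N = 500 / 5,000 SNPs within 3 standard errors;
F_SNP2 is identically 1 for a fully homozygous individual (every
Yᵢ(2 − Yᵢ) term vanishes), asserted exactly.

Estimator correlations are Pearson r with two-sided p from the t
transform, pairwise-complete, flagged NaN on zero variance; p-values are
reported uncorrected (the conventional presentation for an 8 × 8 estimator
comparison), with a Bonferroni flag.

Diversity: Ho is the mean heterozygote fraction over SNPs, He the mean of
2p(1−p). The effective-size formula implemented as primary is the
equalised-family-size form Nₑ = 16NmNf/(Nm + Nf); with 17 males and 76
females it gives 222.3. This formula is four times the standard
4NmNf/(Nm + Nf) (55.6), and neither reproduces a literature value of 52.6
sometimes quoted for herds of this composition — the inputs behind such
values are typically not stated, so the package simply computes both forms
and leaves the choice to the user.

## ROH islands

Incidence is computed only at mapped (post-QC) SNP positions, with
per-individual deduplication (a SNP inside two ROH of one individual
counts once). The island threshold is the empirical (1 − top_fraction)
order-statistic quantile (`numpy` method `"higher"`), with all ties at the
threshold selected; this is conservative, reproducible, and guarantees at
least ⌈top_fraction · n⌉ selected SNPs. "Adjoining" selected SNPs means
consecutive in map order on one chromosome with no unselected SNP between;
no physical gap limit is applied by default (none is standard), but
`max_gap_bp` exists for users. A uniform track degenerates into one island
per chromosome and warns; single-SNP islands (length 0 under the
end − start convention) are permitted and logged.

Annotation overlap counts any shared base pair (partial containment
included), implemented with an interval tree; gene and QTL interval sets
are handled identically under their category tags. Functional enrichment
is out of scope — the package exports the per-island gene list for
external tools.

## Synthetic cohorts

The generator emulates the *shape* of reduced-representation pig data: 18
autosomes with realistic relative sizes summing to exactly 2.26 Gb, SNPs
uniformly spaced at 12.4 kb (~182k genome-wide), cohort alternate-allele
frequencies ~ Uniform(0.05, 0.5) (QC-compatible by construction),
background genotypes in Hardy–Weinberg proportions, 2% missingness, and
autozygous tracts planted directly per individual. Tract lengths are
exponential with mean 100/(2g) cM under the 1 cM ≈ 1 Mb correspondence
(g = generations to the common ancestor; g = 5 gives 10-Mb tracts typical
of recent inbreeding), floored at 1 Mb, placed without overlap, and the
final tract is truncated so the planted total matches the requested
autozygosity f. Within a tract the individual is homozygous for one
haplotype sampled from the cohort frequencies, flipped to heterozygous at
rate 0.001 — chosen so a 100-SNP window carries at most ~0.1 expected
errors, compatible with the window tolerance of 1.

What the generator does *not* model: linkage disequilibrium, recombination
maps, demography, allele-frequency spectra of real ascertainment, or
sequencing depth. Passing recovery tests therefore demonstrates that the
detector and estimators are correct for well-posed autozygosity signals of
known extent, not that they are robust to every artefact of real
reduced-representation data (in particular, background LD in real data
creates short chance ROH that the 1-Mb length floor exists to suppress).

Island cohorts plant one shared haplotype region in a chosen fraction of
individuals against this background. The island-recovery check runs it
against an otherwise non-autozygous background: the planted region is then
a constant-incidence plateau, the top-1% threshold ties on the plateau
value, and exactly one island spanning the region is called with max
incidence equal to the carrier fraction. With background autozygosity
added, incidence noise stacks on the plateau and the same threshold
fragments the region — a real phenomenon worth knowing about when
interpreting island counts on real data, and the reason island calling
exposes `max_gap_bp`.

Pedigree schemes: `full_sib_line` and `half_sib_line` produce the
classical recurrences (F₁ = 0.25, F₂ = 0.375, …; half-sib offspring
0.125); `random` crosses founder families hierarchically (families merged
pairwise each generation) so that with ≥ 2^(generations+1) founders no
mates share an ancestor and every F is exactly 0 — a deliberate design
that gives an analytic expectation instead of the noisy near-zero of true
random mating.

## Numerical and reporting choices

- Genotype storage is int8; all window statistics are exact integer
  cumulative sums, so detection is fully deterministic and byte-identical
  across reruns (asserted for the pipeline outputs).
- The per-class/total identities (class F_ROH components vs total; class
  counts vs total; total coverage vs sum of class coverages) hold exactly
  or to float-sum rounding and are tested as such, not with loose bands.
- Report tables round percents to 2 dp and coefficients to 3 dp;
  full-precision companions are always written (`*_full.tsv`).
- Problem sizes in the test-suite simulations (cohorts of 10–93
  individuals on 150 Mb–2.26 Gb genomes; 200 randomized oracle fixtures of
  2,000 SNPs) were chosen as the smallest designs at which the statistics
  under test are comfortably identified; the full acceptance recomputation
  runs three 50-individual whole-genome cohorts plus a 93-individual
  island cohort in well under a minute.

## Known limitations

- No LD or recombination-map realism in the simulator (above).
- PED/MAP text input carries no reference-allele designation; the reader
  fixes orientation alphabetically, so sites where only the
  alphabetically-second allele is observed flip orientation relative to a
  VCF rendering of the same data. MAF-based QC and all homozygosity
  statistics are invariant to this flip.
- The merging rule for islands ("adjoining selected SNPs") is fixed and
  deterministic here; published island tables produced by other pipelines
  can differ in how near-adjacent high-incidence runs are merged, so
  island *counts* are not directly comparable across tools even when the
  underlying incidence tracks agree.
- `f_ped` is O(n²) in pedigree size — fine for herd books of a few
  thousand records, not for national evaluations.
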