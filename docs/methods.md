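# Methods

This note documents the models, estimators, defaults and numerical
choices behind domescan, and what the synthetic-data generators do and do
not emulate.

## Selection scan

### Window geometry

Windows are full sliding windows: starts 0, step, 2·step, … while
start + size fits on the contig (a trailing partial window is never
emitted, so every window's π denominator is the same length). Defaults
are 50 kb windows with a 25 kb step — standard practice for resequencing
scans of genomes at this SNP density — and both are configurable.
Coordinates are 0-based half-open internally; VCF input is 1-based, and
all reported tables/BED use the conventional external forms (window and
region TSV 1-based inclusive, BED 0-based half-open).

### Nucleotide diversity

Per site with n called allele copies and alternate-allele frequency q̂,
π_site = (n/(n−1)) · 2p̂q̂, the unbiased per-site heterozygosity, which
equals the mean pairwise difference among the n copies. Window π is the
sum of site values divided by the window length in bp (not the callable
site count; an alternative denominator would require callability masks
the VCF does not carry — this choice is the common one for
whole-genome-resequencing scans and cancels in quantile ranking). Sites
where a group has fewer than `min_called` allele copies (default 4)
are excluded. A window with no usable site reports π = 0 with
n_snps = 0.

### Fst

Two estimators, both computed per window as a ratio of sums over sites
(less biased for sparse windows than averaging per-site ratios):

* **Weir–Cockerham (1984)** variance components for two demes (default),
  using individual counts and observed heterozygote frequencies;
* **Hudson** (Bhatia et al. 2013 form): numerator
  (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) with n the allele-copy
  counts, denominator p₁(1−p₂)+p₂(1−p₁).

Negative window estimates are retained — clamping would distort the
empirical quantiles used for outlier calling. A window is undefined
(excluded from ranking) when it has fewer than `min_snps` usable sites
(default 10) or a zero summed denominator. Numerical tie-break: at fixed
differences the numerator and denominator are analytically equal, but
with unequal sample sizes floating-point evaluation can land at
1 − 1 ulp; sums within 1e−12 relative distance are therefore snapped to
exactly 1.

### Outlier calling

z-scores use the genome-wide mean and sd (ddof = 1) of defined windows;
p_z is the one-sided upper normal tail. Flags use linear-interpolation
empirical quantiles with *strict* inequalities, so ties are never
flagged and an all-equal track flags nothing. Defaults: Fst above the
top-1 % quantile, focal-group π below the lowest-5 % quantile. The
z-test p and the quantile flag are reported separately; region calling
uses the quantiles. A separate top-5 % Fst value is emitted only as a
plotting threshold (`fst_plot_cutoff`), distinct from the calling
cutoff. The low-π filter is computed on the domesticated (focal) group
by default — that is where a domestication sweep removes diversity — and
the focal column is switchable.

When the Fst sd is zero up to rounding noise (≤ 1e−12 relative), z and
p_z are undefined and flags fall back to quantiles alone.

Doubly-flagged windows merge into signature regions while consecutive
window starts differ by at most the step (same contig only); each region
reports its member windows, maximum Fst and minimum focal π.

### Allele-frequency profile

"Frequency of the reference genotype" is ambiguous between allele and
genotype frequency, so the profile emits both: ref-allele frequency
(2·hom_ref + het)/(2·called) and ref-homozygote frequency
hom_ref/called, with missing genotypes excluded from denominators and
NaN when a group has no call at a SNP.

### SNP effect annotation

Codons are reconstructed from the reference sequence (required input —
the VCF alone cannot supply codon context), strand-aware, with the
alternate allele substituted and both codons translated under the
standard genetic code. SNPs outside any CDS are non-coding; a SNP inside
several genes' CDS is annotated once per gene; stop gains/losses are
non-synonymous with `*` in the change string. Genes whose summed CDS
length is not a multiple of 3 are skipped with a warning rather than
guessed at.

## Protein composition screen

Met proportion is 100·n_Met/length with the full-precision value kept
internally and reports rounded half-away-from-zero to 2 decimals (the
convention of typeset tables; banker's rounding would disagree on ties).
Molecular weight is the sum of average residue masses plus one water
(Biopython's mass table), reported in kDa; a monoisotopic option exists.
`X` residues count toward length and the Met denominator but contribute
zero mass. The Met-rich flag threshold defaults to 8 %, which cleanly
separates methionine-rich storage proteins (≈11 %) from
arylphorin-types (< 7 %); it is a reporting threshold only.

## Expression statistics

* **Read QC**: a read is discarded if (1) its N fraction is ≥ 10 %, or
  (2) more than 10 nt align ungapped to the adapter at any offset
  (overhangs allowed) with ≤ 10 % mismatches, or (3) more than 50 % of
  its bases are below Phred 5. Rules are tested in that order and the
  discard is attributed to the first that matches.
* **DEG thresholds**: q < 0.05 AND |log₂FC| > 1, both strict, so
  boundary genes are excluded; direction is the sign of log₂FC.
* **Direction asymmetry**: chi-squared goodness-of-fit against a 50:50
  split with Yates continuity correction clamped at zero,
  2·max(|O−E|−0.5, 0)²/E on 1 df, so balanced counts give exactly 0.
  The statistic is symmetric in its arguments.
* **Expressed background**: genes with mean FPKM strictly > 1 over the
  reference condition (the reference-sample set is selectable; mean was
  chosen over any-sample because it is stable under replicate noise).
* **Enrichment**: one-sided upper hypergeometric tail
  P(X ≥ k) per term (over-representation only), fold =
  (k/n)/(K/N), BH-FDR across the tested terms; k = 0 reports p = 1 and
  terms emptied by background restriction are skipped. DEGs must be a
  subset of the background; violations raise rather than silently
  shrink.
* **FDR**: Benjamini–Hochberg step-up (statsmodels), validated input in
  [0, 1].
* **qPCR**: CT = triplicate mean; ΔCT = CT_target − CT_reference;
  ΔΔCT relative to the calibrator sample; RQ = 2^−ΔΔCT, so the
  calibrator is exactly 1.
* **Split-group phenotype tests**: the larger sample is partitioned in
  input order into near-equal blocks (sizes differ by ≤ 1; 83 samples in
  4 splits gives 21/21/21/20), each block is compared to the smaller
  sample by a two-sided Student t-test, the mean p is reported, and
  BH correction is applied across the trait battery.
* The built-in two-group test behind the synthetic path is a Student
  t-test on log₂(FPKM+1) with BH correction. It exists so the synthetic
  pipeline is self-contained; study-scale differential expression should
  come from a dedicated tool whose per-gene table this package consumes.

## Synthetic-data generators

The generators define the package's test conditions; their defaults are
fixed study-design choices, not tuning knobs.

* **Variants**: SNP positions uniform without replacement over the
  contig; ancestral alternate-allele frequency p ~ Uniform(0.05, 0.95)
  (bounded away from 0/1 to avoid rare-allele degeneracies); each deme's
  frequency Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols, so
  E[Fst] ≈ F, which the calibration tests exploit; F < 1e−12 degenerates
  to frequency = p exactly). Defaults: 19 + 18 diploids, 5 Mb contig,
  5 000 SNPs, background F = 0.1. The planted sweep (2.4–2.6 Mb by
  default) uses F = 0.8 in the domestic deme and, with probability 0.9,
  replaces the draw with Beta(1, 50) near zero — near-fixation of the
  reference allele, chosen because in the emulated study system the
  reference assembly derives from the domesticated lineage, so a sweep
  shows up as wild-specific alternate alleles at high frequency.
  Genotypes are Binomial(2, freq): Hardy–Weinberg within demes.
* **Gene models**: equally spaced non-overlapping single-CDS genes on
  random strands over a random reference; coding SNPs are planted at
  chosen codon offsets with their true effect recorded from the codon
  table; explicit plants (gene, codon, offset, codon, alt) are supported
  for worked examples.
* **Expression**: per-gene baseline log₂ abundance ~ Normal(5, 2),
  replicate noise sd 0.3, FPKM = 2^value; DE genes (default 10 %) are
  shifted ±2 log₂ units in group B, down with probability 0.6 (the
  down-share observed in the emulated knockout comparison). Three
  replicates per group, matching the emulated RNA-seq design.
* **Terms**: 20 terms of 50 genes; one planted term draws half its
  members from the true DE genes (planted fold ≈ 5 at the default DE
  fraction), the rest uniformly.
* **Proteins**: exact planted Met counts, round(fraction × length)
  half-up, remaining residues uniform over the other 19 letters,
  shuffled.

Everything is deterministic given the config seed (identical bytes on
re-run); the CLI `simulate` command spawns per-component sub-seeds from
one master seed via `numpy.random.SeedSequence.spawn`, so components can
be regenerated independently.

**What the simulations do not capture**: linkage disequilibrium and
coalescent genealogies (sites are independent given deme frequencies),
genotyping error and missingness (the scan handles missing data, the
generator never produces it), realistic SNP clustering, count-based
RNA-seq noise (log-normal stands in for the mean–variance relation of
count models), GO-DAG structure (terms are flat sets), and read-level
RNA-seq artifacts. Passing recovery tests therefore demonstrates the
statistical machinery is correct under the stated model, not that the
pipeline is robust to every artifact of real data.

## Problem sizes

The test suite and the acceptance script run the documented defaults:
100 seeds for sweep recovery (5 Mb × 5 000 SNPs each), 20 seeds for Fst
calibration (1 Mb × 1 000 SNPs, sweep disabled by shrinking it to a
1 bp interval that almost surely contains no SNP) and 20 seeds for the
expression calibration (2 000 genes). These sizes give binomial/Monte-
Carlo noise well inside the asserted tolerances (±0.03 on mean Fst at
F = 0.1; ≥ 95/100 sweep recovery) while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* Two populations only; no multi-deme Fst, no phasing, no LD statistics
  (iHS, XP-EHH), no indels or multiallelic sites (skipped on read, with
  a count).
* The π denominator ignores callability; comparisons across datasets
  with very different missingness should use the quantile ranks, not
  absolute π.
* The Weir–Cockerham implementation assumes diploid genotypes; the
  Hudson estimator only needs allele counts.
* The enrichment test treats genes as exchangeable (no gene-length or
  expression-level bias correction).
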