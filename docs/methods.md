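# Methods

## Overview

`asemut` quantifies allele-specific expression (ASE) of somatic mutations in
tumor cohorts by integrating four tables per cohort: somatic mutation calls
with tumor/matched-normal DNA allele depths, RNA allele counts at the mutated
loci, a gene-by-sample raw-count expression matrix, and allele-specific
copy-number segments with tumor purity. Every mutation passing DNA quality
filters is classified as mutant-allele expressed, wild-type-only expressed,
gene-silent, or unevaluable; expressed mutations contribute a
depth-normalized mutant read count and a delta-MAF (RNA minus DNA mutant
allele fraction) after a sample-wise adjustment; cohort summaries cover
expressed tumor mutational burden (TMB), gene-wise mutation-expression
frequency, delta-MAF strata and allelic-imbalance enrichment.

## Classification model

DNA-level filters (all inclusive at the boundary):

* tumor mutant allele fraction `alt / (ref + alt)` >= 0.05,
* tumor coverage >= 15x, matched-normal coverage >= 10x,
* at most one variant read in the normal.

Expression status of a DNA-passing mutation, in precedence order:

1. `GENE_SILENT` if the mutated gene's zFPKM <= -3. This takes precedence
   over any RNA reads observed at the locus: the non-expressed definition
   treats a silent gene as sufficient, and stray locus reads in a background
   gene are more plausibly noise than allele-specific signal.
2. `UNEVALUABLE` if the gene is absent from the expression matrix, no RNA
   count row exists, or RNA locus depth < `min_rna_locus_depth`
   (default 5; the RNA-coverage filter of the original design is a
   supplementary-table lookup we expose as a single configurable depth
   cutoff, with the retained-fraction diagnostic emitted so users can
   calibrate — cohort studies of this kind retain roughly 70% of mutations).
3. `MUT_EXPRESSED` if RNA MAF >= 0.05, else `WT_ONLY`.

RNA MAF uses ref+alt at the locus as the denominator; other alleles are
ignored. Statuses partition the DNA-passing set (asserted by the manifest
and the test suite).

## zFPKM

Per sample, log2 FPKM over genes with FPKM > 0 is density-estimated with a
Gaussian KDE (Silverman bandwidth, FFT evaluation on a 512-point grid
spanning the data range plus 3 bandwidths each side). `mu` is the grid
argmax (on a multimodal density this is the global maximum — deterministic
and aligned with the active-peak intent); `sigma` is the half-Gaussian scale
of the right flank, `mean(x[x > mu] - mu) * sqrt(pi/2)`. Then
`zFPKM = (log2 FPKM - mu) / sigma`, with FPKM = 0 mapping to -inf. Genes at
zFPKM <= -3 are background. Zero-FPKM genes are excluded from the density;
including them would only sharpen a spike far below the active peak and
barely moves `mu` at realistic zero fractions. Fitting is per sample, never
pooled, because the downstream adjustment is sample-wise.

A caveat documented by the tests: the KDE mode estimate carries sd ~0.06
(log2 units) at 40-60k genes and converges far slower than n^(-1/2), so
tail-probability checks of the transform must budget for mode noise, not
just binomial sampling error.

## Sample-wise adjustment and QC

DNA and RNA often come from different extractions of the tumor, shifting all
RNA MAFs of a sample multiplicatively. Assuming most expressed mutations are
not allele-specifically regulated, each sample's adjustment factor is the
median RNA MAF / DNA MAF over its expressed mutations (midpoint median for
even counts); adjusted RNA MAF = RNA MAF / factor, and
`delta_maf = rna_maf_adjusted - dna_maf` (the unadjusted variant is always
emitted alongside). Samples with < 12 expressed mutations or factor > 1.75
are excluded from delta-MAF statistics but keep their classification.
Adjusted MAFs are not clipped to [0, 1]; values above 1 are retained so the
delta-MAF densities are undistorted (clipping is display-only, left to the
caller). Expressed mutations with delta-MAF > 0.25 are flagged highly
overexpressed. The factor is computed on the post-RNA-coverage-filter
expressed set.

## Cohort statistics

* **Expressed TMB** counts amino-acid-changing mutations (missense,
  nonsense, stoploss SNVs, frameshift indels, splice-site SNVs/indels);
  the proportion expressed is over evaluable mutations only. TMB per Mb
  divides by a configurable capture size (default 50 Mb).
* **Gene-wise frequency**: records are first restricted to
  amino-acid-changing classes, then collapsed to one mutated gene per
  sample (expressed mutations preferred; all expressed records retained for
  delta-MAF analyses), then the per-gene fraction of evaluable mutated
  tumors expressing the mutation is computed. Tumors, not mutations, are
  the unit. Restricting before collapsing matters: otherwise an expressed
  synonymous SNV could stand in for a wild-type-only missense in the same
  gene.
* **Delta-MAF strata**: mutation-type group (synonymous, missense,
  truncating = nonsense + frameshift, splice-site with SNVs and indels
  pooled, stoploss, inframe) x cancer-critical gene flag, each with mean,
  Student-t 95% CI, record-level Welch t versus synonymous SNVs of the same
  role group, and a sample-wise paired t on per-sample means over complete
  pairs. Strata under 10 mutations are omitted. Balance-restricted variants
  (balanced-only / imbalanced-only) and an optional linear purity
  residualization (off by default) are provided. All p-values two-sided; no
  multiplicity correction by default (Benjamini-Hochberg optional).
* **Imbalance enrichment**: 2x2 Fisher exact test of cancer-critical x
  allelic imbalance, where a locus is balanced iff total copy number equals
  twice the minor copy number.
* **Mutant dose vs drug sensitivity**: Spearman rank correlation between
  per-model normalized mutant counts (mutant reads per million mapped) and
  externally supplied drug-sensitivity scores; >= 3 shared models required.
* A generic 5'-vs-3' positional contrast (relative CDS position against a
  configurable breakpoint) and per-(sample, gene) double-mutation flags
  support positional ASE analyses.

## Synthetic cohort generator

The generator is first-class, tested code and the canonical input source
(patient-level sequencing of this kind is access-restricted). Per locus:

* DNA: `f_DNA = m*rho / (tcn*rho + 2*(1 - rho))` with purity `rho`, total
  copies `tcn`, mutant copies `m` (normal cells contribute two wild-type
  copies); tumor alt reads ~ Binomial(depth, f_DNA), depth ~ Poisson.
* RNA: mutant copies emit `kappa` transcript units each, wild-type tumor
  copies one, normal cells two:
  `f_RNA = rho*m*kappa / (rho*(m*kappa + tcn - m) + 2*(1 - rho))`;
  locus depth ~ Poisson(scale x the gene's per-sample FPKM), alt reads ~
  Binomial(depth, f_RNA). `kappa = 1` reduces exactly to `f_DNA`.
* Expression: per-gene base log2 FPKM from a two-component mixture
  (active N(4, 1.5), background N(-6, 2), background weight 2/7 matching
  the ~28% non-expressed genes typical of ribodepleted tumor RNA-seq),
  per-sample N(0, 0.25) jitter, Poisson counts given gene length and a
  3e7-read library.

Default study conditions, chosen once: 50 samples; mutations per sample
negative binomial with mean 225 (dispersion 8) and a class mix with 70%
amino-acid-changing, matching a microsatellite-stable colorectal exome
cohort; tumor/normal DNA depth 300x/170x; purity uniform on (0.5, 0.9), a
typical surgical-resection range; copy states 60% balanced with mutant
copies listed explicitly per state (a `m = None` entry samples uniformly
over feasible values with an optional gain-bias weight); normal-sample
error rate 5e-4; RNA library size fixed at 3e7 (affects only normalized
counts); RNA depth scale 3 reads per FPKM unit (median active-gene locus
depth ~50x).

Kappas default to values solved numerically (Brent root-finding on the
analytic expectation integrated over the purity and copy-state
distributions) so the analytic mean delta-MAF per stratum reproduces the
magnitudes reported in patient cohorts: truncating -0.10 (nonsense-mediated
decay), splice-site +0.31 (intron-retaining transcripts), cancer-gene
missense +0.04. With the default mixture these resolve to approximately
kappa_truncating 0.61, kappa_splice 3.87, kappa_missense_cancer 1.20.
Truncating kappa is position-independent.

Every locus's generative parameters (copy state, m, kappa, gene activity,
f_DNA, f_RNA) are written to a truth table aligned row-for-row with the
mutation table.

### What the generator does not emulate

No reference-mapping bias (a known real-data confounder the analysis does
not model either), no RNA-level monoallelic silencing or imprinting beyond
the class-level kappas, no linkage between loci, no subclonal structure,
no read-level artifacts. Because simulated RNA coverage is clean and deep,
wild-type-only calls are rarer than in patient data and the per-tumor
proportion of expressed mutations runs higher (~70%) than the ~34% reported
in real tumors; passing recovery tests therefore demonstrate correctness of
the estimators under the model, not field performance on noisy cohorts.

## Numerical and design choices

* Positions are 1-based; copy segments half-open `[start, end)`; a locus
  outside every segment gets a missing copy state (never a default), and
  the count is reported.
* Multi-allelic VCF rows split into independent records; each record's DNA
  MAF denominator is its own ref+alt depths. Indels are parsimony-trimmed
  (shared suffix then prefix, anchor base kept) — full left-alignment would
  need the reference genome, which is not an input.
* Mutations in genes absent from the expression matrix are unevaluable,
  keeping the status partition exact.
* Floats in hand-written tables use `repr` (shortest round-trip), making
  write -> read -> write byte-identical; pipeline TSVs use `%.10g`.
* Welch/paired t, Fisher exact, Spearman and t-based CIs are delegated to
  scipy/statsmodels; the test suite verifies them against closed forms and
  full hypergeometric enumeration.
* Deterministic KDE (no randomness) plus a single `numpy` Generator seeded
  per cohort make every output reproducible bit-for-bit.

### Experiment sizing in the test suite

Recovery tests size their cohorts by power analysis, decided before
running: the end-to-end kappa recovery uses 20 replicate 50-sample cohorts
(~200 mutations each) and asserts stratum means on the across-replicate
average (SE ~0.002 against a 0.02 tolerance) with per-replicate rank-order
and Welch checks; the inflation-recovery experiment uses a null cohort
(all kappas 1) restricted to heterozygous balanced loci so a 2x MAF
inflation stays in its linear range (doubled fractions below 1), with RNA
depth giving a sample-median SE of ~0.02.

## Known limitations

* The RNA-coverage evaluability rule is a single depth threshold, not a
  zFPKM-dependent lookup table.
* The adjustment factor assumes most expressed mutations are unregulated;
  in cohorts where regulated classes dominate the expressed set, the median
  ratio absorbs part of the signal (visible in the generator as a ~1-2%
  composition shift of per-sample factors).
* No mapping-bias correction for the reference allele.
* Gene roles come from a curated cancer-gene table supplied by the user;
  the built-in synthetic annotation is a stand-in, not a real gene census.
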