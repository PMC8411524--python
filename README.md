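# asemut

Allele-specific expression of somatic mutations in tumor cohorts.

A somatic mutation only matters to the tumor's phenotype if the mutated
allele is actually transcribed. `asemut` integrates tumor exome and RNA-seq
data at every mutated locus to answer that question cohort-wide: it
classifies each mutation as **expressed** (mutant allele detected in RNA),
**wild-type-only**, **gene-silent**, or unevaluable; summarizes the
*expressed tumor mutational burden* per tumor and the *mutation-expression
frequency* per gene; and quantifies allele-specific regulation as
**ΔMAF = RNA MAF<sub>adjusted</sub> − DNA MAF**, stratified by mutation type,
cancer-gene status and allelic copy-number balance. It is written for
cancer-genomics analysts working downstream of standard callers: inputs are
plain TSV/VCF tables (mutation calls with allele depths, RNA allele counts,
a raw-count expression matrix, copy-number segments with purity).

## The model

At a locus with tumor purity ρ, total copy number `tcn` and `m` mutated
copies, the expected DNA mutant allele fraction is

    f_DNA = m·ρ / (tcn·ρ + 2(1 − ρ))

Gene activity is decided per sample by the zFPKM transform: a kernel density
estimate of log2 FPKM locates the active-expression peak μ, a half-Gaussian
fit to its right flank gives σ, and genes with
zFPKM = (log2 FPKM − μ)/σ ≤ −3 are background. A DNA-passing mutation
(MAF ≥ 5%, ≥15×/≥10× tumor/normal coverage, ≤1 normal variant read) is
expressed if its RNA MAF ≥ 5% in an active gene.

Because DNA and RNA often come from different extractions, each sample's
RNA MAFs are divided by an adjustment factor — the median RNA MAF/DNA MAF
over its expressed mutations — before ΔMAF is computed; samples with < 12
expressed mutations or a factor > 1.75 are excluded from ΔMAF statistics.

The package ships a seeded synthetic-cohort generator with per-locus ground
truth. RNA expression of the mutant allele is modulated by a
class-specific multiplier κ
(`f_RNA = ρ·m·κ / (ρ·(m·κ + tcn − m) + 2(1 − ρ))`): κ < 1 for truncating
mutations (nonsense-mediated decay), κ > 1 for splice-site mutations, and
slightly > 1 for missense mutations in cancer-critical genes, calibrated so
the analytic stratum means are −0.10, +0.31 and +0.04 respectively.

## Worked example

```python
from asemut import GeneratorConfig, generate_cohort, analyze_cohort

cfg = GeneratorConfig(n_samples=12, mutations_per_sample_mean=150.0, n_genes=4000)
cohort = generate_cohort(cfg, seed=7)
result = analyze_cohort(
    cohort.calls, cohort.rna_counts, cohort.expression,
    cohort.segments, cohort.annotations,
)

print(f"mutations passing DNA filters: {result.counts['dna_pass']}")
print(f"median proportion expressed: {result.tmb['proportion_expressed'].median():.2f}")
strata = result.strata.query("balance == 'all' and not cancer_critical")
print(strata[["mutation_group", "n", "mean_delta", "welch_p"]].to_string(index=False))
```

prints

```
mutations passing DNA filters: 2010
median proportion expressed: 0.70
mutation_group   n  mean_delta      welch_p
    synonymous 318    0.004664          NaN
      missense 690    0.002584 7.146100e-01
    truncating 160   -0.104414 7.414677e-39
   splice_site  90    0.306113 9.493859e-63
       inframe  75    0.016742 2.161624e-01
```

Reading this: synonymous SNVs show no allele-specific regulation (mean ΔMAF
≈ 0; they are the reference stratum, hence no Welch p); truncating
mutations (nonsense SNVs + frameshift indels) have reduced relative
expression of the mutated allele (mean ΔMAF −0.10, consistent with
nonsense-mediated decay); splice-site mutations show strongly increased
relative mutant-allele expression (+0.31). The Welch p-values compare each
stratum with synonymous SNVs in the same gene-role group.

## Command line

```sh
asemut simulate --config cohort.yaml          # write synthetic input tables + truth
asemut run      --config cohort.yaml          # full analysis -> TSVs + manifest.json
asemut qc       --ase-table out/ase_records.tsv
asemut stats    --ase-table out/ase_records.tsv --balance balanced
```

The YAML config names the input tables, filter thresholds and flags
(adjustment on/off, purity residualization, BH correction, capture size);
`run` writes the master per-mutation table, per-sample QC, TMB,
gene-frequency and stratum tables plus a manifest with the config hash and
per-stage record counts. Reruns of the same config are byte-identical.

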