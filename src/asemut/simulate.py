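"""Seeded synthetic-cohort generator with per-locus ground truth.

The generator emulates the statistical structure a tumor DNA/RNA
allele-integration analysis assumes, at the scale of a real exome/RNA-seq
cohort study:

* per-sample tumor purity rho and per-locus integer allele-specific copy
  states (tcn total, lcn minor, m mutant copies);
* DNA allele counts that are binomial around the purity/ploidy expectation

      f_DNA = m * rho / (tcn * rho + 2 * (1 - rho))

  (normal cells contribute two wild-type copies);
* gene expression as a two-component mixture on log2 FPKM (an active peak
  and a low background component);
* RNA allele counts whose mutant fraction is modulated by a
  mutation-class-specific expression multiplier kappa:

      f_RNA = rho * m * kappa / (rho * (m * kappa + tcn - m) + 2 * (1 - rho))

  kappa < 1 for truncating mutations (nonsense-mediated decay), kappa > 1
  for splice-site mutations (intron-retaining transcripts escaping
  splicing-dependent surveillance), and slightly > 1 for missense mutations
  in cancer-critical genes.

Default kappas are calibrated at construction time so the analytic mean
delta-MAF per stratum reproduces the magnitudes reported for patient
cohorts (truncating -0.10, splice-site +0.31, cancer-gene missense +0.04).
Every generated locus carries its generative parameters in a truth table
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionData, write_expression
from .io_tables import (
    Segment,
    SegmentSet,
    write_allele_counts,
    write_copy_segments,
    write_mutations,
)
from .types import (
    GeneAnnotation,
    GeneRole,
    MutationCall,
    MutationClass,
    RnaAlleleCount,
    SPLICE_SITE,
    TRUNCATING,
)

#: Stratum-level mean delta-MAF targets used to calibrate default kappas.
DEFAULT_TARGET_DELTAS = {
    "truncating": -0.10,
    "splice_site": 0.31,
    "missense_cancer": 0.04,
}

#: Mutation-class frequencies of a typical microsatellite-stable exome:
#: 70% amino-acid changing.
DEFAULT_CLASS_PROBS: dict[MutationClass, float] = {
    MutationClass.SYNONYMOUS_SNV: 0.24,
    MutationClass.MISSENSE_SNV: 0.52,
    MutationClass.NONSENSE_SNV: 0.055,
    MutationClass.STOPLOSS_SNV: 0.005,
    MutationClass.FRAMESHIFT_INDEL: 0.06,
    MutationClass.INFRAME_INDEL: 0.06,
    MutationClass.SPLICE_SITE_SNV: 0.04,
    MutationClass.SPLICE_SITE_INDEL: 0.02,
}

#: (tcn, lcn, m, probability): 60% of loci copy-number balanced.
DEFAULT_COPY_STATES: tuple[tuple[int, int, int, float], ...] = (
    (2, 1, 1, 0.55),
    (2, 0, 1, 0.10),
    (2, 0, 2, 0.05),
    (3, 1, 1, 0.12),
    (3, 1, 2, 0.08),
    (4, 2, 1, 0.03),
    (4, 2, 2, 0.02),
    (4, 1, 2, 0.05),
)

_VARIANT_ALLELES: dict[MutationClass, tuple[str, str]] = {
    MutationClass.SYNONYMOUS_SNV: ("A", "G"),
    MutationClass.MISSENSE_SNV: ("C", "T"),
    MutationClass.NONSENSE_SNV: ("C", "T"),
    MutationClass.STOPLOSS_SNV: ("T", "C"),
    MutationClass.FRAMESHIFT_INDEL: ("AG", "A"),
    MutationClass.INFRAME_INDEL: ("AGGG", "A"),
    MutationClass.SPLICE_SITE_SNV: ("G", "A"),
    MutationClass.SPLICE_SITE_INDEL: ("AT", "A"),
}


def expected_dna_maf(purity: float, tcn: int, m: int) -> float:
    """Expected DNA mutant allele fraction under the purity/ploidy mixture."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0 <= m <= tcn:
        raise ValueError(f"need 0 <= m <= tcn, got m={m}, tcn={tcn}")
    denom = tcn * purity + 2.0 * (1.0 - purity)
    if denom == 0:
        raise ValueError("tcn = 0 in a pure tumor: no DNA at the locus")
    return m * purity / denom


def expected_rna_maf(purity: float, tcn: int, m: int, kappa: float) -> float:
    """Expected RNA mutant allele fraction with expression multiplier kappa.

    Mutant copies contribute kappa transcript units each, wild-type tumor
    copies one, and normal cells two; kappa = 1 reduces exactly to
    :func:`expected_dna_maf`.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not 0 <= m <= tcn:
        raise ValueError(f"need 0 <= m <= tcn, got m={m}, tcn={tcn}")
    denom = purity * (m * kappa + (tcn - m)) + 2.0 * (1.0 - purity)
    if denom == 0:
        raise ValueError("no transcript output at the locus")
    return purity * m * kappa / denom


@dataclass(frozen=True)
class GeneratorConfig:
    """Generative parameters of a synthetic cohort.

    Scale parameters follow a deeply sequenced exome + ribodepleted RNA-seq
    cohort: ~225 mutations per tumor, 300x/170x tumor/normal DNA depth,
    3e7 mapped RNA read pairs, and a log2-FPKM mixture in which two sevenths
    of genes sit in the low background component.  Kappas left at ``None``
    are solved so the analytic stratum means hit
    :data:`DEFAULT_TARGET_DELTAS`.
    """

    n_samples: int = 50
    mutations_per_sample_mean: float = 225.0
    mutations_per_sample_dispersion: float = 8.0
    purity_low: float = 0.5
    purity_high: float = 0.9
    copy_states: tuple[tuple[int, int, int, float], ...] = DEFAULT_COPY_STATES
    tumor_depth_mean: float = 300.0
    normal_depth_mean: float = 170.0
    normal_error_rate: float = 5e-4
    rna_library_size: int = 30_000_000
    rna_depth_per_fpkm: float = 3.0
    kappa_truncating: float | None = None
    kappa_splice: float | None = None
    kappa_missense_cancer: float | None = None
    kappa_default: float = 1.0
    active_mu: float = 4.0
    active_sigma: float = 1.5
    background_mu: float = -6.0
    background_sigma: float = 2.0
    background_fraction: float = 2.0 / 7.0
    sample_noise_sd: float = 0.25
    n_genes: int = 14_000
    cancer_gene_fraction: float = 0.05
    n_flags: int = 100
    silent_mutation_fraction: float | None = None
    class_probs: tuple[tuple[MutationClass, float], ...] = tuple(DEFAULT_CLASS_PROBS.items())

    def __post_init__(self) -> None:
        probs = [p for *_state, p in self.copy_states]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("copy-state probabilities must sum to 1")
        for tcn, lcn, m, _p in self.copy_states:
            if not 0 <= lcn <= tcn - lcn:
                raise ValueError(f"invalid copy state tcn={tcn}, lcn={lcn}")
            if not 1 <= m <= tcn - lcn:
                raise ValueError(
                    f"mutant copies m={m} infeasible for tcn={tcn}, lcn={lcn} "
                    "(mutation sits on the major parental allele)"
                )
        if abs(sum(p for _c, p in self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if not 0 < self.purity_low <= self.purity_high <= 1:
            raise ValueError("need 0 < purity_low <= purity_high <= 1")
        for name in ("kappa_truncating", "kappa_splice", "kappa_missense_cancer"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa_default <= 0:
            raise ValueError("kappa_default must be > 0")


def analytic_mean_delta(cfg: GeneratorConfig, kappa: float, n_purity: int = 201) -> float:
    """Analytic E[f_RNA - f_DNA] for a mutation class with multiplier *kappa*.

    The expectation is over the config's copy-state distribution and a
    uniform purity in [purity_low, purity_high] (trapezoid quadrature; the
    class label itself is independent of copy state and purity).
    """
    if cfg.purity_high == cfg.purity_low:
        grid = np.array([cfg.purity_low])
        weights = np.array([1.0])
    else:
        grid = np.linspace(cfg.purity_low, cfg.purity_high, n_purity)
        weights = np.full(n_purity, 1.0 / (n_purity - 1))
        weights[[0, -1]] /= 2.0
    total = 0.0
    for tcn, lcn, m, p in cfg.copy_states:
        deltas = np.array(
            [expected_rna_maf(rho, tcn, m, kappa) - expected_dna_maf(rho, tcn, m)
             for rho in grid]
        )
        total += p * float(np.sum(weights * deltas))
    return total


def solve_kappa(cfg: GeneratorConfig, target_delta: float) -> float:
    """Expression multiplier whose analytic mean delta-MAF equals the target."""
    lo, hi = 1e-4, 200.0
    f = lambda k: analytic_mean_delta(cfg, k) - target_delta
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"target delta {target_delta} outside the attainable range")
    return float(brentq(f, lo, hi, xtol=1e-10))


def resolve_kappas(cfg: GeneratorConfig) -> GeneratorConfig:
    """Fill in unset kappas by solving for the default stratum targets."""
    updates = {}
    if cfg.kappa_truncating is None:
        updates["kappa_truncating"] = solve_kappa(cfg, DEFAULT_TARGET_DELTAS["truncating"])
    if cfg.kappa_splice is None:
        updates["kappa_splice"] = solve_kappa(cfg, DEFAULT_TARGET_DELTAS["splice_site"])
    if cfg.kappa_missense_cancer is None:
        updates["kappa_missense_cancer"] = solve_kappa(
            cfg, DEFAULT_TARGET_DELTAS["missense_cancer"]
        )
    return replace(cfg, **updates) if updates else cfg


def kappa_for(cfg: GeneratorConfig, mclass: MutationClass, cancer_critical: bool) -> float:
    """Expression multiplier applied to one mutation."""
    if mclass in TRUNCATING:
        assert cfg.kappa_truncating is not None
        return cfg.kappa_truncating
    if mclass in SPLICE_SITE:
        assert cfg.kappa_splice is not None
        return cfg.kappa_splice
    if mclass is MutationClass.MISSENSE_SNV and cancer_critical:
        assert cfg.kappa_missense_cancer is not None
        return cfg.kappa_missense_cancer
    return cfg.kappa_default


TRUTH_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "mutation_class",
    "cancer_critical", "gene_active", "tcn", "lcn", "m", "purity", "kappa",
    "f_dna", "f_rna",
]


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus ground truth, writable to TSV."""

    config: GeneratorConfig
    seed: int
    calls: list[MutationCall]
    rna_counts: dict[tuple, RnaAlleleCount]
    expression: ExpressionData
    segments: SegmentSet
    segment_rows: list[Segment]
    annotations: dict[str, GeneAnnotation]
    cgc_rows: list[tuple[str, str, str]]
    flags_genes: list[str]
    truth: pd.DataFrame
    purities: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": out / "mutations.tsv",
            "rna_counts": out / "rna_counts.tsv",
            "expression_counts": out / "expression_counts.tsv",
            "gene_lengths": out / "gene_lengths.tsv",
            "segments": out / "segments.tsv",
            "cgc": out / "cgc.tsv",
            "flags": out / "flags.txt",
            "truth": out / "truth.tsv",
        }
        write_mutations(self.calls, paths["mutations"])
        write_allele_counts(self.rna_counts.values(), paths["rna_counts"])
        write_expression(self.expression, paths["expression_counts"], paths["gene_lengths"])
        write_copy_segments(self.segment_rows, paths["segments"])
        with open(paths["cgc"], "w") as fh:
            fh.write("gene\trole\tmutation_types\n")
            for gene, role, mtypes in self.cgc_rows:
                fh.write(f"{gene}\t{role}\t{mtypes}\n")
        with open(paths["flags"], "w") as fh:
            for gene in self.flags_genes:
                fh.write(gene + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
        return paths


def generate_cohort(cfg: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Generate one synthetic cohort; identical (cfg, seed) pairs reproduce
    byte-identical output files."""
    cfg = resolve_kappas(cfg)
    rng = np.random.default_rng(seed)

    # --- gene universe -----------------------------------------------------
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    background = rng.random(cfg.n_genes) < cfg.background_fraction
    is_cancer = rng.random(cfg.n_genes) < cfg.cancer_gene_fraction
    role_draw = rng.random(cfg.n_genes)
    cgc_rows: list[tuple[str, str, str]] = []
    annotations: dict[str, GeneAnnotation] = {}
    for i, gene in enumerate(genes):
        if not is_cancer[i]:
            continue
        if role_draw[i] < 0.45:
            role = GeneRole.ONCOGENE
        elif role_draw[i] < 0.90:
            role = GeneRole.TUMOR_SUPPRESSOR
        else:
            role = GeneRole.ONCOGENE_AND_TSG
        # one in ten CGC genes included through non-point-mutation mechanisms
        if rng.random() < 0.10:
            cgc_rows.append((gene, role.value, "translocation,amplification"))
        else:
            cgc_rows.append((gene, role.value, "missense,nonsense,frameshift,splice_site"))
    non_cancer_idx = np.flatnonzero(~is_cancer)
    flags_idx = rng.choice(non_cancer_idx, size=min(cfg.n_flags, non_cancer_idx.size),
                           replace=False)
    flags_genes = sorted(genes[flags_idx].tolist())
    cgc_role_map = {}
    for gene, role, mtypes in cgc_rows:
        tokens = set(mtypes.split(","))
        eff = GeneRole(role) if tokens & {"missense", "nonsense", "frameshift", "splice_site"} else GeneRole.CGC_OTHER
        cgc_role_map[gene] = eff
    flags_set = set(flags_genes)
    for gene in set(cgc_role_map) | flags_set:
        annotations[gene] = GeneAnnotation(
            gene=gene, role=cgc_role_map.get(gene, GeneRole.OTHER),
            flags100=gene in flags_set,
        )

    # --- expression matrix -------------------------------------------------
    base_log2 = np.where(
        background,
        rng.normal(cfg.background_mu, cfg.background_sigma, cfg.n_genes),
        rng.normal(cfg.active_mu, cfg.active_sigma, cfg.n_genes),
    )
    gene_lengths_kb = np.exp(rng.normal(0.9, 0.6, cfg.n_genes))
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    sample_log2 = (
        base_log2[:, None]
        + rng.normal(0.0, cfg.sample_noise_sd, (cfg.n_genes, cfg.n_samples))
    )
    sample_fpkm = np.exp2(sample_log2)
    rate = sample_fpkm * gene_lengths_kb[:, None] * (cfg.rna_library_size / 1e6)
    counts = rng.poisson(rate)
    expression = ExpressionData(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(gene_lengths_kb, index=genes, name="length_kb"),
        pd.Series(float(cfg.rna_library_size), index=samples, name="mapped_reads"),
    )

    # --- per-sample purity and mutation counts -----------------------------
    purities = {
        s: float(rng.uniform(cfg.purity_low, cfg.purity_high)) for s in samples
    }
    r = cfg.mutations_per_sample_dispersion
    p_nb = r / (r + cfg.mutations_per_sample_mean)
    n_muts = rng.negative_binomial(r, p_nb, cfg.n_samples)

    classes = [c for c, _p in cfg.class_probs]
    class_p = np.array([p for _c, p in cfg.class_probs])
    states = np.array([(t, l, m) for t, l, m, _p in cfg.copy_states])
    state_p = np.array([p for *_s, p in cfg.copy_states])
    active_idx = np.flatnonzero(~background)
    background_idx = np.flatnonzero(background)
    gene_fpkm_lookup = pd.DataFrame(sample_fpkm, index=genes, columns=samples)

    calls: list[MutationCall] = []
    rna_counts: dict[tuple, RnaAlleleCount] = {}
    segment_rows: list[Segment] = []
    truth_rows: list[dict] = []
    locus_counter = 0
    for j, sample in enumerate(samples):
        rho = purities[sample]
        n = int(n_muts[j])
        class_idx = rng.choice(len(classes), size=n, p=class_p)
        if cfg.silent_mutation_fraction is None:
            gene_idx = rng.integers(0, cfg.n_genes, size=n)
        else:
            in_silent = rng.random(n) < cfg.silent_mutation_fraction
            gene_idx = np.where(
                in_silent,
                rng.choice(background_idx, size=n),
                rng.choice(active_idx, size=n),
            )
        state_idx = rng.choice(len(states), size=n, p=state_p)
        tumor_depths = np.maximum(rng.poisson(cfg.tumor_depth_mean, n), 1)
        normal_depths = np.maximum(rng.poisson(cfg.normal_depth_mean, n), 1)
        for i in range(n):
            mclass = classes[class_idx[i]]
            gene = str(genes[gene_idx[i]])
            tcn, lcn, m = (int(v) for v in states[state_idx[i]])
            ann = annotations.get(gene)
            cancer_critical = ann is not None and ann.cancer_critical
            kappa = kappa_for(cfg, mclass, cancer_critical)
            f_dna = expected_dna_maf(rho, tcn, m)
            f_rna = expected_rna_maf(rho, tcn, m, kappa)

            locus_counter += 1
            chrom = f"chr{1 + locus_counter % 22}"
            pos = 10_000 + locus_counter * 100
            ref, alt = _VARIANT_ALLELES[mclass]

            t_depth = int(tumor_depths[i])
            t_alt = int(rng.binomial(t_depth, f_dna))
            n_depth = int(normal_depths[i])
            n_alt = int(rng.binomial(n_depth, cfg.normal_error_rate))
            calls.append(
                MutationCall(
                    sample_id=sample, chrom=chrom, pos=pos, ref_allele=ref,
                    alt_allele=alt, gene=gene, mutation_class=mclass,
                    tumor_ref_depth=t_depth - t_alt, tumor_alt_depth=t_alt,
                    normal_ref_depth=n_depth - n_alt, normal_alt_depth=n_alt,
                )
            )
            fpkm_here = float(gene_fpkm_lookup.at[gene, sample])
            rna_depth = int(rng.poisson(cfg.rna_depth_per_fpkm * fpkm_here))
            rna_alt = int(rng.binomial(rna_depth, f_rna)) if rna_depth > 0 else 0
            rna_counts[(sample, chrom, pos, ref, alt)] = RnaAlleleCount(
                sample_id=sample, chrom=chrom, pos=pos, ref_allele=ref,
                alt_allele=alt, rna_ref_depth=rna_depth - rna_alt,
                rna_alt_depth=rna_alt, rna_library_size=cfg.rna_library_size,
            )
            segment_rows.append(
                Segment(sample_id=sample, chrom=chrom, start=pos, end=pos + 1,
                        tcn=tcn, lcn=lcn, purity=rho)
            )
            truth_rows.append(
                {
                    "sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref,
                    "alt": alt, "gene": gene, "mutation_class": mclass.value,
                    "cancer_critical": cancer_critical,
                    "gene_active": bool(~background[gene_idx[i]]),
                    "tcn": tcn, "lcn": lcn, "m": m, "purity": rho,
                    "kappa": kappa, "f_dna": f_dna, "f_rna": f_rna,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SyntheticCohort(
        config=cfg, seed=seed, calls=calls, rna_counts=rna_counts,
        expression=expression, segments=SegmentSet(segment_rows),
        segment_rows=segment_rows, annotations=annotations, cgc_rows=cgc_rows,
        flags_genes=flags_genes, truth=truth, purities=purities,
    )


def inflate_sample_rna(
    rna_counts: dict[tuple, RnaAlleleCount], sample_id: str, c: float
) -> dict[tuple, RnaAlleleCount]:
    """Multiply one sample's RNA mutant allele fractions by *c*.

    Emulates a global DNA/RNA extraction mismatch in a single sample for
    QC-recovery experiments: the sample's adjustment factor should move to
    about *c*, and for c > 1.75 the sample should be excluded.  Totals are
    kept; mutant counts are re-rounded (fractions capped at 1).
    """
    out: dict[tuple, RnaAlleleCount] = {}
    for key, r in rna_counts.items():
        if r.sample_id != sample_id:
            out[key] = r
            continue
        total = r.rna_ref_depth + r.rna_alt_depth
        new_alt = min(total, round(c * r.rna_alt_depth)) if total else 0
        out[key] = RnaAlleleCount(
            sample_id=r.sample_id, chrom=r.chrom, pos=r.pos,
            ref_allele=r.ref_allele, alt_allele=r.alt_allele,
            rna_ref_depth=total - new_alt, rna_alt_depth=new_alt,
            rna_library_size=r.rna_library_size,
        )
    return out


def sample_maf_cell(
    purity: float, tcn: int, m: int, kappa: float,
    depth: int, n: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo DNA and RNA MAF estimates for one (rho, tcn, m, kappa) cell
    at fixed sequencing depth — calibration helper for the generative model."""
    f_dna = expected_dna_maf(purity, tcn, m)
    f_rna = expected_rna_maf(purity, tcn, m, kappa)
    dna = rng.binomial(depth, f_dna, size=n) / depth
    rna = rng.binomial(depth, f_rna, size=n) / depth
    return dna, rna
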