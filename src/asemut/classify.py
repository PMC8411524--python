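"""DNA filtering, DNA/RNA joining, and expression-status classification.

Every somatic call first passes DNA-level quality filters (mutant allele
fraction >= 5%, tumor coverage >= 15x, normal coverage >= 10x, at most one
variant read in the normal).  Passing calls are then joined with RNA allele
counts, the mutated gene's zFPKM and the locus copy state, and assigned one
of four mutually exclusive statuses:

GENE_SILENT     gene zFPKM <= -3 (takes precedence over locus counts: a
                silent gene cannot express its mutation, whatever stray
                reads the locus shows)
UNEVALUABLE     gene absent from the expression matrix, no RNA count row,
                or RNA locus depth below the configured minimum
MUT_EXPRESSED   RNA MAF >= 5%
WT_ONLY         RNA MAF < 5% in an active gene
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .expression import ExpressionData
from .io_tables import SegmentSet, annotate_gene
from .types import (
    AseRecord,
    FilterConfig,
    GeneAnnotation,
    MutationCall,
    RnaAlleleCount,
    Status,
)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""


def dna_filter(call: MutationCall, cfg: FilterConfig = FilterConfig()) -> FilterResult:
    """DNA-level quality filter for one somatic call.

    Boundary values are inclusive where the thresholds read ">=": a DNA MAF
    of exactly 5% passes, as do exactly 15x/10x coverage; a single variant
    read in the normal is accepted.
    """
    tumor_depth = call.tumor_ref_depth + call.tumor_alt_depth
    normal_depth = call.normal_ref_depth + call.normal_alt_depth
    if tumor_depth == 0:
        return FilterResult(False, "no_coverage")
    if tumor_depth < cfg.min_tumor_depth:
        return FilterResult(False, "low_tumor_depth")
    if normal_depth < cfg.min_normal_depth:
        return FilterResult(False, "low_normal_depth")
    if call.normal_alt_depth > cfg.max_normal_alt_reads:
        return FilterResult(False, "normal_variant_reads")
    if call.dna_maf < cfg.min_dna_maf:
        return FilterResult(False, "low_maf")
    return FilterResult(True)


def classify_expression(
    call: MutationCall,
    rna: RnaAlleleCount | None,
    gene_zfpkm: float | None,
    cfg: FilterConfig = FilterConfig(),
) -> Status:
    """Expression status of a DNA-passing mutation.

    ``gene_zfpkm`` of ``None`` means the gene is absent from the expression
    matrix (unevaluable); ``-inf`` (FPKM = 0) is a silent gene.
    """
    if gene_zfpkm is not None and gene_zfpkm <= cfg.zfpkm_silent_threshold:
        return Status.GENE_SILENT
    if gene_zfpkm is None or rna is None:
        return Status.UNEVALUABLE
    locus_depth = rna.rna_ref_depth + rna.rna_alt_depth
    if locus_depth < cfg.min_rna_locus_depth:
        return Status.UNEVALUABLE
    if rna.rna_maf >= cfg.rna_maf_expressed_threshold:
        return Status.MUT_EXPRESSED
    return Status.WT_ONLY


def normalized_mut_count(rna_alt_depth: int, rna_library_size: int) -> float:
    """Depth-normalized mutant read count: alt reads per million mapped reads."""
    if rna_library_size <= 0:
        raise ValueError("rna_library_size must be > 0")
    return rna_alt_depth / rna_library_size * 1e6


def build_ase_records(
    calls: Iterable[MutationCall],
    rna_counts: Mapping[tuple, RnaAlleleCount],
    expression: ExpressionData | None,
    segments: SegmentSet | None = None,
    annotations: Mapping[str, GeneAnnotation] | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[AseRecord], dict[str, int]]:
    """Join, filter and classify a cohort of mutation calls.

    Returns the classified records (DNA-passing calls only) and a stage-count
    dictionary (total, DNA pass/fail by reason, per-status counts) for the
    run manifest.
    """
    records: list[AseRecord] = []
    counts: dict[str, int] = {"total": 0, "dna_pass": 0}
    for call in calls:
        counts["total"] += 1
        res = dna_filter(call, cfg)
        if not res.passed:
            counts[f"dna_fail_{res.reason}"] = counts.get(f"dna_fail_{res.reason}", 0) + 1
            continue
        counts["dna_pass"] += 1
        rna = rna_counts.get(call.key)
        zfpkm = expression.gene_zfpkm(call.gene, call.sample_id) if expression is not None else None
        state = segments.assign_copy_state(call) if segments is not None else None
        ann = annotate_gene(call.gene, annotations) if annotations is not None else GeneAnnotation(call.gene)
        status = classify_expression(call, rna, zfpkm, cfg)
        rec = AseRecord(
            sample_id=call.sample_id, chrom=call.chrom, pos=call.pos,
            ref_allele=call.ref_allele, alt_allele=call.alt_allele,
            gene=call.gene, mutation_class=call.mutation_class,
            tumor_ref_depth=call.tumor_ref_depth, tumor_alt_depth=call.tumor_alt_depth,
            normal_ref_depth=call.normal_ref_depth, normal_alt_depth=call.normal_alt_depth,
            dna_maf=call.dna_maf,
            status=status, role=ann.role, flags100=ann.flags100,
        )
        if zfpkm is not None:
            rec.gene_zfpkm = zfpkm
        if rna is not None:
            rec.rna_ref_depth = rna.rna_ref_depth
            rec.rna_alt_depth = rna.rna_alt_depth
            total = rna.rna_ref_depth + rna.rna_alt_depth
            rec.rna_maf = rna.rna_maf if total > 0 else None
            rec.normalized_mut_count = normalized_mut_count(
                rna.rna_alt_depth, rna.rna_library_size
            )
        if state is not None:
            rec.tcn, rec.lcn = state.tcn, state.lcn
            rec.purity, rec.balanced = state.purity, state.balanced
        records.append(rec)
        counts[status.value] = counts.get(status.value, 0) + 1
    return records, counts


def gene_level_collapse(records: Iterable[AseRecord]) -> list[AseRecord]:
    """Collapse to one mutated gene per sample.

    Each mutated gene counts once per sample; when a gene carries several
    mutations in a sample, the expressed ones are kept (the gene counts as
    expressed-mutated) — otherwise one representative non-expressed record
    is kept, preferring an evaluable one.
    """
    groups: dict[tuple[str, str], list[AseRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.sample_id, rec.gene)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    rank = {
        Status.WT_ONLY: 0,
        Status.GENE_SILENT: 1,
        Status.UNEVALUABLE: 2,
    }
    collapsed: list[AseRecord] = []
    for key in order:
        group = groups[key]
        expressed = [r for r in group if r.status == Status.MUT_EXPRESSED]
        if expressed:
            collapsed.extend(expressed)
        else:
            collapsed.append(min(group, key=lambda r: (rank[r.status], r.pos)))
    return collapsed


def retained_fraction(counts: Mapping[str, int]) -> float:
    """Fraction of DNA-passing mutations that were evaluable in RNA.

    Diagnostic for calibrating the RNA locus-depth cutoff (the study retained
    about 70% of mutations for allele-specific analysis).
    """
    dna_pass = counts.get("dna_pass", 0)
    if dna_pass == 0:
        return math.nan
    return 1.0 - counts.get(Status.UNEVALUABLE.value, 0) / dna_pass
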