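"""End-to-end orchestration: config, staging, outputs and the run manifest."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .adjust import (
    MAX_ADJUSTMENT_FACTOR,
    MIN_EXPRESSED_PER_SAMPLE,
    adjust_cohort,
    write_sample_qc,
)
from .classify import build_ase_records, gene_level_collapse, retained_fraction
from .cohort import (
    balance_enrichment,
    gene_expression_frequency,
    gene_frequency_by_role,
    per_sample_tmb,
    strata_to_frame,
    stratified_delta,
)
from .expression import ExpressionData, read_expression
from .io_tables import (
    read_allele_counts,
    read_copy_segments,
    read_gene_annotations,
    read_mutations,
    write_ase_table,
)
from .types import AseRecord, FilterConfig, SampleQc


@dataclass
class AnalysisResult:
    """Everything one cohort analysis produces."""

    records: list[AseRecord]
    counts: dict[str, int]
    qc: dict[str, SampleQc]
    collapsed: list[AseRecord]
    tmb: pd.DataFrame
    gene_frequency: pd.DataFrame
    gene_frequency_by_role: pd.DataFrame
    strata: pd.DataFrame
    enrichment: dict
    retained_fraction: float


def analyze_cohort(
    calls,
    rna_counts,
    expression: ExpressionData | None,
    segments=None,
    annotations=None,
    filter_cfg: FilterConfig = FilterConfig(),
    adjust: bool = True,
    min_expressed: int = MIN_EXPRESSED_PER_SAMPLE,
    max_factor: float = MAX_ADJUSTMENT_FACTOR,
    capture_size_mb: float = 50.0,
    purity_adjust: bool = False,
    bh_correct: bool = False,
) -> AnalysisResult:
    """Classify, adjust and summarize one cohort held in memory."""
    records, counts = build_ase_records(
        calls, rna_counts, expression, segments, annotations, filter_cfg
    )
    qc = adjust_cohort(records, min_expressed=min_expressed,
                       max_factor=max_factor, adjust=adjust)
    qc_pass = [r for r in records if not qc[r.sample_id].excluded]
    # gene-wise frequency is over amino-acid-changing mutations only, so the
    # one-gene-per-tumor collapse must not let e.g. an expressed synonymous
    # SNV stand in for a wild-type-only missense in the same gene
    collapsed = gene_level_collapse([r for r in records if r.amino_acid_changing])
    strata_frames = []
    for balance in ("all", "balanced", "imbalanced"):
        strata = stratified_delta(qc_pass, balance=balance, purity_adjust=purity_adjust)
        if strata:
            strata_frames.append(strata_to_frame(strata, bh_correct=bh_correct))
    strata_df = (
        pd.concat(strata_frames, ignore_index=True) if strata_frames else pd.DataFrame()
    )
    freq = gene_expression_frequency(collapsed)
    return AnalysisResult(
        records=records,
        counts=counts,
        qc=qc,
        collapsed=collapsed,
        tmb=per_sample_tmb(records, capture_size_mb),
        gene_frequency=freq,
        gene_frequency_by_role=gene_frequency_by_role(freq) if len(freq) else pd.DataFrame(),
        strata=strata_df,
        enrichment=balance_enrichment(records) if records else {},
        retained_fraction=retained_fraction(counts),
    )


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class RunConfig:
    """Validated run configuration loaded from YAML."""

    out_dir: Path
    seed: int = 0
    mutations: Path | None = None
    mutation_format: str = "tsv"
    rna_counts: Path | None = None
    expression_counts: Path | None = None
    gene_lengths: Path | None = None
    totals: Path | None = None
    segments: Path | None = None
    cgc: Path | None = None
    flags: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    adjust: bool = True
    min_expressed: int = MIN_EXPRESSED_PER_SAMPLE
    max_factor: float = MAX_ADJUSTMENT_FACTOR
    capture_size_mb: float = 50.0
    purity_adjust: bool = False
    bh_correct: bool = False
    generator: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        base = Path(path).parent

        def _p(key: str) -> Path | None:
            value = inputs.get(key)
            if value is None:
                return None
            p = Path(value)
            return p if p.is_absolute() else base / p

        cfg = cls(
            out_dir=Path(raw.get("out_dir", "asemut_out")),
            seed=int(raw.get("seed", 0)),
            mutations=_p("mutations"),
            mutation_format=inputs.get("mutation_format", "tsv"),
            rna_counts=_p("rna_counts"),
            expression_counts=_p("expression_counts"),
            gene_lengths=_p("gene_lengths"),
            totals=_p("totals"),
            segments=_p("segments"),
            cgc=_p("cgc"),
            flags=_p("flags"),
            filters=FilterConfig(**raw.get("filters", {})),
            adjust=bool(raw.get("adjust", True)),
            min_expressed=int(raw.get("min_expressed", MIN_EXPRESSED_PER_SAMPLE)),
            max_factor=float(raw.get("max_factor", MAX_ADJUSTMENT_FACTOR)),
            capture_size_mb=float(raw.get("capture_size_mb", 50.0)),
            purity_adjust=bool(raw.get("purity_adjust", False)),
            bh_correct=bool(raw.get("bh_correct", False)),
            generator=raw.get("generator", {}),
            raw=raw,
        )
        return cfg

    def validate_inputs(self) -> None:
        """Fail before any computation when a referenced input is missing."""
        required = {
            "mutations": self.mutations,
            "rna_counts": self.rna_counts,
            "expression_counts": self.expression_counts,
            "gene_lengths": self.gene_lengths,
        }
        for name, p in required.items():
            if p is None:
                raise FileNotFoundError(f"config missing required input {name!r}")
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
        for name in ("totals", "segments", "cgc", "flags"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline from files to files.

    Writes the master per-mutation table, sample QC, TMB, gene-frequency
    and stratum tables plus ``manifest.json`` with the config hash, package
    version and per-stage record counts.  Deterministic for a given config.
    """
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    calls = read_mutations(cfg.mutations, format=cfg.mutation_format)
    rna = read_allele_counts(cfg.rna_counts)
    expression = read_expression(cfg.expression_counts, cfg.gene_lengths, cfg.totals)
    segments = read_copy_segments(cfg.segments) if cfg.segments else None
    annotations = (
        read_gene_annotations(cfg.cgc, cfg.flags) if (cfg.cgc or cfg.flags) else None
    )

    result = analyze_cohort(
        calls, rna, expression, segments, annotations,
        filter_cfg=cfg.filters, adjust=cfg.adjust,
        min_expressed=cfg.min_expressed, max_factor=cfg.max_factor,
        capture_size_mb=cfg.capture_size_mb, purity_adjust=cfg.purity_adjust,
        bh_correct=cfg.bh_correct,
    )

    chash = cfg.config_hash()
    comment = [f"asemut {__version__} config_hash={chash}"]
    write_ase_table(result.records, out / "ase_records.tsv", comments=comment)
    write_sample_qc(result.qc, out / "sample_qc.tsv")
    _write_tsv(result.tmb, out / "per_sample_tmb.tsv", comment)
    _write_tsv(result.gene_frequency, out / "gene_frequency.tsv", comment)
    _write_tsv(result.gene_frequency_by_role, out / "gene_frequency_by_role.tsv", comment)
    _write_tsv(result.strata, out / "strata.tsv", comment)

    status_counts = {
        k: v for k, v in result.counts.items()
        if k in {"MUT_EXPRESSED", "WT_ONLY", "GENE_SILENT", "UNEVALUABLE"}
    }
    manifest = {
        "package": "asemut",
        "version": __version__,
        "config_hash": chash,
        "seed": cfg.seed,
        "counts": result.counts,
        "status_partition_ok": sum(status_counts.values()) == result.counts.get("dna_pass", 0),
        "n_samples": len(result.qc),
        "n_samples_excluded": sum(q.excluded for q in result.qc.values()),
        "retained_fraction": None
        if math.isnan(result.retained_fraction)
        else result.retained_fraction,
        "balance_enrichment": result.enrichment,
        "outputs": [p.name for p in sorted(out.glob("*.tsv"))],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"result": result, "manifest": manifest, "out_dir": out}


def _write_tsv(df: pd.DataFrame, path: Path, comments=()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")
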