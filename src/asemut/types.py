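"""Core domain types for allele-specific mutation-expression analysis.

A cohort is described by four independently produced tables that are joined
on sample and locus keys:

* somatic mutation calls with tumor/normal DNA allele depths,
* RNA allele counts at the mutated loci,
* a gene-by-sample expression matrix (raw counts + gene lengths),
* allele-specific copy-number segments with tumor purity.

Positions are 1-based (VCF convention); copy segments are half-open
``[start, end)``.  Sample identifiers are opaque strings joined exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields


class MutationClass(str, enum.Enum):
    """Functional class of a somatic mutation, Annovar-style granularity."""

    SYNONYMOUS_SNV = "synonymous_snv"
    MISSENSE_SNV = "missense_snv"
    NONSENSE_SNV = "nonsense_snv"
    STOPLOSS_SNV = "stoploss_snv"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE_SNV = "splice_site_snv"
    SPLICE_SITE_INDEL = "splice_site_indel"


#: Classes that change the protein product: missense/nonsense/stoploss SNVs,
#: frameshift indels and splice-site mutations.  Synonymous SNVs and inframe
#: indels do not.
AMINO_ACID_CHANGING: frozenset[MutationClass] = frozenset(
    {
        MutationClass.MISSENSE_SNV,
        MutationClass.NONSENSE_SNV,
        MutationClass.STOPLOSS_SNV,
        MutationClass.FRAMESHIFT_INDEL,
        MutationClass.SPLICE_SITE_SNV,
        MutationClass.SPLICE_SITE_INDEL,
    }
)

#: Truncating mutations: premature-stop-producing classes subject to
#: nonsense-mediated decay (nonsense SNVs and frameshift indels).
TRUNCATING: frozenset[MutationClass] = frozenset(
    {MutationClass.NONSENSE_SNV, MutationClass.FRAMESHIFT_INDEL}
)

SPLICE_SITE: frozenset[MutationClass] = frozenset(
    {MutationClass.SPLICE_SITE_SNV, MutationClass.SPLICE_SITE_INDEL}
)


def is_amino_acid_changing(mutation_class: MutationClass) -> bool:
    """True iff *mutation_class* alters the protein sequence."""
    return MutationClass(mutation_class) in AMINO_ACID_CHANGING


class GeneRole(str, enum.Enum):
    """Cancer Gene Census derived gene role."""

    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    ONCOGENE_AND_TSG = "oncogene_and_tsg"
    CGC_OTHER = "cgc_other"
    OTHER = "other"


#: Roles counted as cancer-critical (oncogene and/or tumor suppressor by
#: relevant mutation types).
CANCER_CRITICAL_ROLES: frozenset[GeneRole] = frozenset(
    {GeneRole.ONCOGENE, GeneRole.TUMOR_SUPPRESSOR, GeneRole.ONCOGENE_AND_TSG}
)


class Status(str, enum.Enum):
    """Expression status of a single somatic mutation.

    MUT_EXPRESSED   mutated allele detected in RNA (RNA MAF >= threshold)
    WT_ONLY         gene active but only the wild-type allele expressed
    GENE_SILENT     the mutated gene itself is not expressed (zFPKM <= -3)
    UNEVALUABLE     insufficient RNA data at the locus (or gene absent from
                    the expression matrix)
    """

    MUT_EXPRESSED = "MUT_EXPRESSED"
    WT_ONLY = "WT_ONLY"
    GENE_SILENT = "GENE_SILENT"
    UNEVALUABLE = "UNEVALUABLE"


@dataclass(frozen=True)
class MutationCall:
    """One somatic variant in one sample with DNA allele depths."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene: str
    mutation_class: MutationClass
    tumor_ref_depth: int
    tumor_alt_depth: int
    normal_ref_depth: int
    normal_alt_depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        for name in ("tumor_ref_depth", "tumor_alt_depth", "normal_ref_depth", "normal_alt_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "mutation_class", MutationClass(self.mutation_class))

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def dna_maf(self) -> float:
        """Tumor DNA mutant allele fraction alt/(ref+alt); NaN at zero depth."""
        total = self.tumor_ref_depth + self.tumor_alt_depth
        return self.tumor_alt_depth / total if total > 0 else math.nan

    @property
    def amino_acid_changing(self) -> bool:
        return self.mutation_class in AMINO_ACID_CHANGING


@dataclass(frozen=True)
class RnaAlleleCount:
    """RNA ref/alt read depths at a mutated locus."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rna_ref_depth: int
    rna_alt_depth: int
    rna_library_size: int  # uniquely mapped read pairs for the sample

    def __post_init__(self) -> None:
        if self.rna_ref_depth < 0 or self.rna_alt_depth < 0:
            raise ValueError("RNA depths must be >= 0")
        if self.rna_library_size <= 0:
            raise ValueError("rna_library_size must be > 0")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def rna_maf(self) -> float:
        total = self.rna_ref_depth + self.rna_alt_depth
        return self.rna_alt_depth / total if total > 0 else math.nan


@dataclass(frozen=True)
class CopyState:
    """Allele-specific copy number and purity at a locus.

    ``balanced`` means the mutated and wild-type parental alleles carry the
    same number of copies, i.e. tcn == 2 * lcn under the convention that the
    mutation sits on one parental allele.
    """

    tcn: int
    lcn: int
    purity: float

    def __post_init__(self) -> None:
        if self.tcn < 0:
            raise ValueError("tcn must be >= 0")
        if not 0 <= self.lcn <= self.tcn - self.lcn:
            raise ValueError(f"lcn must satisfy 0 <= lcn <= tcn/2 (tcn={self.tcn}, lcn={self.lcn})")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    @property
    def balanced(self) -> bool:
        return self.tcn == 2 * self.lcn


@dataclass(frozen=True)
class GeneAnnotation:
    """Cancer Gene Census role plus FLAGS membership for one gene."""

    gene: str
    role: GeneRole = GeneRole.OTHER
    flags100: bool = False

    @property
    def cancer_critical(self) -> bool:
        return self.role in CANCER_CRITICAL_ROLES


@dataclass
class AseRecord:
    """The joined, filtered, classified unit of the analysis.

    Carries the DNA call plus everything the classification added.  Fields
    that are undefined for the record's status are ``None`` (written as
    ``NA`` in tables).
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    mutation_class: MutationClass
    tumor_ref_depth: int
    tumor_alt_depth: int
    normal_ref_depth: int
    normal_alt_depth: int
    dna_maf: float
    rna_ref_depth: int | None = None
    rna_alt_depth: int | None = None
    rna_maf: float | None = None
    gene_zfpkm: float | None = None  # -inf allowed; None = gene absent
    tcn: int | None = None
    lcn: int | None = None
    purity: float | None = None
    balanced: bool | None = None
    status: Status = Status.UNEVALUABLE
    rna_maf_adjusted: float | None = None
    delta_maf: float | None = None  # rna_maf_adjusted - dna_maf
    delta_maf_raw: float | None = None  # rna_maf - dna_maf (no adjustment)
    normalized_mut_count: float | None = None  # mutant reads per million mapped
    high_overexpression: bool = False
    role: GeneRole = GeneRole.OTHER
    flags100: bool = False

    def __post_init__(self) -> None:
        self.mutation_class = MutationClass(self.mutation_class)
        self.status = Status(self.status)
        self.role = GeneRole(self.role)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def amino_acid_changing(self) -> bool:
        return self.mutation_class in AMINO_ACID_CHANGING

    @property
    def cancer_critical(self) -> bool:
        return self.role in CANCER_CRITICAL_ROLES


def ase_field_names() -> list[str]:
    """Stable column order of the master AseRecord table."""
    return [f.name for f in fields(AseRecord)]


@dataclass(frozen=True)
class FilterConfig:
    """DNA- and RNA-level filter thresholds.

    Defaults follow the study design: DNA MAF >= 5% with >= 15x tumor and
    >= 10x normal coverage and at most one variant read in the normal;
    a gene is silent at zFPKM <= -3; a mutated allele counts as expressed
    at RNA MAF >= 5%.  ``min_rna_locus_depth`` is the locus-level RNA
    coverage cutoff below which a mutation is unevaluable.
    """

    min_dna_maf: float = 0.05
    min_tumor_depth: int = 15
    min_normal_depth: int = 10
    max_normal_alt_reads: int = 1
    min_rna_locus_depth: int = 5
    rna_maf_expressed_threshold: float = 0.05
    zfpkm_silent_threshold: float = -3.0

    def __post_init__(self) -> None:
        if not 0 < self.rna_maf_expressed_threshold < 1:
            raise ValueError("rna_maf_expressed_threshold must be in (0, 1)")
        for name in ("min_dna_maf", "min_tumor_depth", "min_normal_depth",
                     "max_normal_alt_reads", "min_rna_locus_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    TOO_FEW_EXPRESSED = "too_few_expressed"
    HIGH_ADJUSTMENT_FACTOR = "high_adjustment_factor"


@dataclass(frozen=True)
class SampleQc:
    """Per-sample adjustment factor and exclusion decision."""

    sample_id: str
    n_expressed: int
    adjustment_factor: float  # NaN when no expressed mutations
    excluded: bool
    exclusion_reason: ExclusionReason


@dataclass(frozen=True)
class ZfpkmFit:
    """Parameters of the zFPKM transform for one sample.

    ``mu`` is the mode of the kernel-density estimate of log2 FPKM over
    genes with FPKM > 0 (the active-expression peak); ``sigma`` is the
    half-Gaussian scale fitted to the right flank.
    """

    mu: float
    sigma: float
    bandwidth: float
    n_genes: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
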