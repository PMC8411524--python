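"""Readers and writers for every table the pipeline touches.

All tables are tab-separated with a mandatory header line and ``NA`` as the
missing-value token.  Variant positions are 1-based; copy-number segments
are half-open ``[start, end)``.  Lines starting with ``#`` are comments.

Table dialects
--------------
mutations       sample_id chrom pos ref alt gene mutation_class
                tumor_ref_depth tumor_alt_depth normal_ref_depth normal_alt_depth
rna_counts      sample_id chrom pos ref alt ref_count alt_count library_size
segments        sample_id chrom start end tcn lcn purity
expression      gene x sample matrix of raw counts (first column ``gene``)
gene_lengths    gene length_kb
cgc             gene role mutation_types   (mutation_types comma-separated)
flags           one gene symbol per line (no header)
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AseRecord,
    CopyState,
    GeneAnnotation,
    GeneRole,
    MutationCall,
    MutationClass,
    RnaAlleleCount,
    Status,
    ase_field_names,
)

NA = "NA"

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "mutation_class",
    "tumor_ref_depth", "tumor_alt_depth", "normal_ref_depth", "normal_alt_depth",
]
RNA_COUNT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "library_size",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "tcn", "lcn", "purity"]

#: CGC mutation-type tokens that make a role assignment "relevant" for
#: amino-acid-changing somatic point mutations.
RELEVANT_CGC_MUTATION_TYPES = {"missense", "nonsense", "frameshift", "splice_site"}


class TableParseError(ValueError):
    """Malformed input table; message names the file and line."""


def _read_rows(path: str | Path, expected: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for data lines after validating the header."""
    path = Path(path)
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != list(expected):
                    raise TableParseError(
                        f"{path}:{lineno}: bad header {header!r}, expected {list(expected)!r}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) != len(expected):
                raise TableParseError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(parts)}"
                )
            yield lineno, parts
        if header is None:
            raise TableParseError(f"{path}: empty file, header required")


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious, reference-free normalization of a variant.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    always keeping at least one base of ref and alt (VCF anchor-base
    convention for indels).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_mutations(
    path: str | Path,
    format: str = "tsv",
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[MutationCall]:
    """Read somatic mutation calls from a TSV table or a VCF.

    VCF records must carry per-sample ``AD`` depths for the tumor and
    matched-normal columns and INFO keys ``GENE`` and ``CLASS`` (the
    mutation class); the VCF file name stem is used as the sample id
    unless an INFO key ``SAMPLE`` is present.  Multi-allelic rows are
    split into one record per alternate allele.
    """
    if format == "tsv":
        return _read_mutations_tsv(path)
    if format == "vcf":
        return _read_mutations_vcf(path, tumor_sample, normal_sample)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_mutations_tsv(path: str | Path) -> list[MutationCall]:
    calls: list[MutationCall] = []
    for lineno, p in _read_rows(path, MUTATION_COLUMNS):
        try:
            pos, ref, alt = normalize_variant(int(p[2]), p[3], p[4])
            calls.append(
                MutationCall(
                    sample_id=p[0], chrom=p[1], pos=pos, ref_allele=ref, alt_allele=alt,
                    gene=p[5], mutation_class=MutationClass(p[6]),
                    tumor_ref_depth=int(p[7]), tumor_alt_depth=int(p[8]),
                    normal_ref_depth=int(p[9]), normal_alt_depth=int(p[10]),
                )
            )
        except ValueError as exc:
            raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def _read_mutations_vcf(path: str | Path, tumor_sample: str, normal_sample: str) -> list[MutationCall]:
    import pysam

    calls: list[MutationCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (tumor_sample, normal_sample):
            if name not in samples:
                raise TableParseError(f"{path}: sample column {name!r} not in VCF ({samples})")
        for rec in vcf:
            info = dict(rec.info)
            gene = str(info.get("GENE", NA))
            mclass = MutationClass(str(info.get("CLASS", "missense_snv")))
            sample_id = str(info.get("SAMPLE", Path(path).stem))
            t_ad = rec.samples[tumor_sample].get("AD")
            n_ad = rec.samples[normal_sample].get("AD")
            if t_ad is None or n_ad is None:
                raise TableParseError(
                    f"{path}: missing AD depths at {rec.chrom}:{rec.pos}"
                )
            for i, alt in enumerate(rec.alts or ()):
                pos, ref_n, alt_n = normalize_variant(rec.pos, rec.ref, alt)
                calls.append(
                    MutationCall(
                        sample_id=sample_id, chrom=rec.chrom, pos=pos,
                        ref_allele=ref_n, alt_allele=alt_n, gene=gene,
                        mutation_class=mclass,
                        tumor_ref_depth=int(t_ad[0]), tumor_alt_depth=int(t_ad[i + 1]),
                        normal_ref_depth=int(n_ad[0]), normal_alt_depth=int(n_ad[i + 1]),
                    )
                )
    return calls


def write_mutations(calls: Iterable[MutationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MUTATION_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.sample_id, c.chrom, str(c.pos), c.ref_allele, c.alt_allele,
                        c.gene, c.mutation_class.value,
                        str(c.tumor_ref_depth), str(c.tumor_alt_depth),
                        str(c.normal_ref_depth), str(c.normal_alt_depth),
                    ]
                )
                + "\n"
            )


def read_allele_counts(path: str | Path) -> dict[tuple, RnaAlleleCount]:
    """Read RNA allele counts keyed by (sample, chrom, pos, ref, alt).

    Duplicate keys are rejected: the table must contain one row per
    mutated locus per sample.
    """
    counts: dict[tuple, RnaAlleleCount] = {}
    for lineno, p in _read_rows(path, RNA_COUNT_COLUMNS):
        try:
            rec = RnaAlleleCount(
                sample_id=p[0], chrom=p[1], pos=int(p[2]), ref_allele=p[3],
                alt_allele=p[4], rna_ref_depth=int(p[5]), rna_alt_depth=int(p[6]),
                rna_library_size=int(p[7]),
            )
        except ValueError as exc:
            raise TableParseError(f"{path}:{lineno}: {exc}") from exc
        if rec.key in counts:
            raise TableParseError(f"{path}:{lineno}: duplicate allele-count key {rec.key}")
        counts[rec.key] = rec
    return counts


def write_allele_counts(counts: Iterable[RnaAlleleCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RNA_COUNT_COLUMNS) + "\n")
        for r in counts:
            fh.write(
                "\t".join(
                    [
                        r.sample_id, r.chrom, str(r.pos), r.ref_allele, r.alt_allele,
                        str(r.rna_ref_depth), str(r.rna_alt_depth), str(r.rna_library_size),
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class Segment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # exclusive
    tcn: int
    lcn: int
    purity: float


class SegmentSet:
    """Per-sample allele-specific copy-number segments with point lookup.

    Segments within a (sample, chrom) must not overlap; lookup of a locus
    not covered by any segment returns ``None`` (never a default state).
    """

    def __init__(self, segments: Iterable[Segment]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[Segment]]] = {}
        grouped: dict[tuple[str, str], list[Segment]] = {}
        for seg in segments:
            if seg.end <= seg.start:
                raise ValueError(f"empty segment {seg}")
            grouped.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        for key, segs in grouped.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping segments in {key[0]} {key[1]}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
            self._by_key[key] = ([s.start for s in segs], segs)

    def assign_copy_state(self, call: MutationCall) -> CopyState | None:
        entry = self._by_key.get((call.sample_id, call.chrom))
        if entry is None:
            return None
        starts, segs = entry
        i = bisect_right(starts, call.pos) - 1
        if i < 0:
            return None
        seg = segs[i]
        if call.pos >= seg.end:
            return None
        return CopyState(tcn=seg.tcn, lcn=seg.lcn, purity=seg.purity)

    def __len__(self) -> int:
        return sum(len(segs) for _, segs in self._by_key.values())


def read_copy_segments(path: str | Path) -> SegmentSet:
    segs = []
    for lineno, p in _read_rows(path, SEGMENT_COLUMNS):
        try:
            segs.append(
                Segment(
                    sample_id=p[0], chrom=p[1], start=int(p[2]), end=int(p[3]),
                    tcn=int(p[4]), lcn=int(p[5]), purity=float(p[6]),
                )
            )
        except ValueError as exc:
            raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return SegmentSet(segs)


def write_copy_segments(segments: Iterable[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                "\t".join(
                    [s.sample_id, s.chrom, str(s.start), str(s.end),
                     str(s.tcn), str(s.lcn), repr(s.purity)]
                )
                + "\n"
            )


def read_gene_annotations(
    cgc_path: str | Path | None, flags_path: str | Path | None
) -> dict[str, GeneAnnotation]:
    """Build the gene -> (role, FLAGS) map from a CGC-style table and a FLAGS list.

    A CGC role assignment counts only when it is based on relevant somatic
    mutation types (missense, nonsense, frameshift, splice site); genes in
    the CGC through other mechanisms (translocation, amplification, ...)
    become ``cgc_other``.
    """
    ann: dict[str, GeneAnnotation] = {}
    roles: dict[str, GeneRole] = {}
    if cgc_path is not None:
        for lineno, p in _read_rows(cgc_path, ["gene", "role", "mutation_types"]):
            gene, role_s, mtypes_s = p
            mtypes = {t.strip() for t in mtypes_s.split(",") if t.strip()}
            try:
                role = GeneRole(role_s)
            except ValueError as exc:
                raise TableParseError(f"{cgc_path}:{lineno}: unknown role {role_s!r}") from exc
            if not mtypes & RELEVANT_CGC_MUTATION_TYPES:
                role = GeneRole.CGC_OTHER
            roles[gene] = role
    flags: set[str] = set()
    if flags_path is not None:
        with open(flags_path) as fh:
            flags = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    for gene in set(roles) | flags:
        ann[gene] = GeneAnnotation(
            gene=gene, role=roles.get(gene, GeneRole.OTHER), flags100=gene in flags
        )
    return ann


def annotate_gene(gene: str, annotations: dict[str, GeneAnnotation]) -> GeneAnnotation:
    """Annotation for *gene*; genes absent from both lists default to `other`."""
    return annotations.get(gene, GeneAnnotation(gene=gene))


# ---------------------------------------------------------------------------
# master AseRecord table

_INT_FIELDS = {
    "pos", "tumor_ref_depth", "tumor_alt_depth", "normal_ref_depth",
    "normal_alt_depth", "rna_ref_depth", "rna_alt_depth", "tcn", "lcn",
}
_FLOAT_FIELDS = {
    "dna_maf", "rna_maf", "gene_zfpkm", "purity", "rna_maf_adjusted",
    "delta_maf", "delta_maf_raw", "normalized_mut_count",
}
_BOOL_FIELDS = {"balanced", "high_overexpression", "flags100"}


def _format_value(name: str, value) -> str:
    if value is None:
        return NA
    if name in _FLOAT_FIELDS:
        if isinstance(value, float) and math.isnan(value):
            return NA
        return repr(float(value))
    if name in _BOOL_FIELDS:
        return "True" if value else "False"
    if isinstance(value, (MutationClass, Status, GeneRole)):
        return value.value
    return str(value)


def _parse_value(name: str, token: str):
    if token == NA:
        return None
    if name in _INT_FIELDS:
        return int(token)
    if name in _FLOAT_FIELDS:
        return float(token)
    if name in _BOOL_FIELDS:
        return token == "True"
    if name == "mutation_class":
        return MutationClass(token)
    if name == "status":
        return Status(token)
    if name == "role":
        return GeneRole(token)
    return token


def write_ase_table(records: Iterable[AseRecord], path: str | Path,
                    comments: Sequence[str] = ()) -> None:
    """Write the master per-mutation table, one row per AseRecord."""
    names = ase_field_names()
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(names) + "\n")
        for rec in records:
            fh.write("\t".join(_format_value(n, getattr(rec, n)) for n in names) + "\n")


def read_ase_table(path: str | Path) -> list[AseRecord]:
    names = ase_field_names()
    records = []
    for lineno, p in _read_rows(path, names):
        kwargs = {n: _parse_value(n, tok) for n, tok in zip(names, p)}
        # False/0 defaults for non-optional fields written as NA-free columns
        if kwargs["high_overexpression"] is None:
            kwargs["high_overexpression"] = False
        if kwargs["flags100"] is None:
            kwargs["flags100"] = False
        try:
            records.append(AseRecord(**kwargs))
        except (TypeError, ValueError) as exc:
            raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def ase_records_to_frame(records: Iterable[AseRecord]) -> pd.DataFrame:
    """Flatten AseRecords into a DataFrame for cohort-level statistics."""
    names = ase_field_names()
    rows = []
    for rec in records:
        row = {n: getattr(rec, n) for n in names}
        row["mutation_class"] = rec.mutation_class.value
        row["status"] = rec.status.value
        row["role"] = rec.role.value
        row["amino_acid_changing"] = rec.amino_acid_changing
        row["cancer_critical"] = rec.cancer_critical
        rows.append(row)
    df = pd.DataFrame(rows, columns=names + ["amino_acid_changing", "cancer_critical"])
    return df
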