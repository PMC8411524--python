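"""Sample-wise RNA MAF adjustment, QC exclusion, and delta-MAF computation.

DNA and RNA are often sequenced from different extractions of the tumor, so
the RNA mutant allele fractions of a sample can be globally shifted relative
to the DNA ones.  Assuming most expressed mutations have no allele-specific
regulation (RNA MAF proportional to DNA MAF), each sample's RNA MAFs are
divided by an adjustment factor: the median RNA MAF / DNA MAF ratio over the
sample's expressed mutations.  Samples with fewer than 12 expressed
mutations or an adjustment factor above 1.75 are excluded from delta-MAF
statistics (their classification results are kept).

Adjusted RNA MAFs are deliberately not clipped to [0, 1]; values above 1 can
arise after division and are retained so the delta-MAF densities are not
distorted.
"""

from __future__ import annotations

import math
from statistics import median
from typing import Iterable, Sequence

from .types import AseRecord, ExclusionReason, SampleQc, Status

#: Delta-MAF above which a mutation is flagged as highly overexpressed.
HIGH_OVEREXPRESSION_DELTA = 0.25

MIN_EXPRESSED_PER_SAMPLE = 12
MAX_ADJUSTMENT_FACTOR = 1.75


def adjustment_factor(expressed: Sequence[AseRecord]) -> float:
    """Median RNA MAF / DNA MAF over one sample's expressed mutations.

    Even counts use the midpoint median.  NaN when the sample has no
    expressed mutations (the sample is flagged, not an exception).
    """
    ratios = [
        r.rna_maf / r.dna_maf
        for r in expressed
        if r.status == Status.MUT_EXPRESSED and r.rna_maf is not None and r.dna_maf > 0
    ]
    if not ratios:
        return math.nan
    return float(median(ratios))


def apply_adjustment(record: AseRecord, factor: float,
                     adjust: bool = True) -> AseRecord:
    """Set rna_maf_adjusted, both delta-MAF variants and the overexpression flag.

    With ``adjust=False`` (samples with same-extraction DNA/RNA, or raw
    analysis) the factor is forced to 1.  Mutates and returns *record*.
    """
    if adjust and not factor > 0:
        raise ValueError(f"adjustment factor must be > 0, got {factor}")
    if record.status != Status.MUT_EXPRESSED or record.rna_maf is None:
        return record
    eff = factor if adjust else 1.0
    record.rna_maf_adjusted = record.rna_maf / eff
    record.delta_maf = record.rna_maf_adjusted - record.dna_maf
    record.delta_maf_raw = record.rna_maf - record.dna_maf
    record.high_overexpression = record.delta_maf > HIGH_OVEREXPRESSION_DELTA
    return record


def sample_qc(
    sample_records: Sequence[AseRecord],
    min_expressed: int = MIN_EXPRESSED_PER_SAMPLE,
    max_factor: float = MAX_ADJUSTMENT_FACTOR,
) -> SampleQc:
    """QC decision for one sample's classified records.

    Excluded iff the sample has fewer than *min_expressed* expressed
    mutations or an adjustment factor strictly above *max_factor*.
    """
    if not sample_records:
        raise ValueError("sample_qc needs at least one record")
    sample_id = sample_records[0].sample_id
    expressed = [r for r in sample_records if r.status == Status.MUT_EXPRESSED]
    factor = adjustment_factor(expressed)
    if len(expressed) < min_expressed:
        return SampleQc(sample_id, len(expressed), factor, True, ExclusionReason.TOO_FEW_EXPRESSED)
    if factor > max_factor:
        return SampleQc(sample_id, len(expressed), factor, True, ExclusionReason.HIGH_ADJUSTMENT_FACTOR)
    return SampleQc(sample_id, len(expressed), factor, False, ExclusionReason.NONE)


def adjust_cohort(
    records: Iterable[AseRecord],
    min_expressed: int = MIN_EXPRESSED_PER_SAMPLE,
    max_factor: float = MAX_ADJUSTMENT_FACTOR,
    adjust: bool = True,
) -> dict[str, SampleQc]:
    """Run QC and adjustment over a whole cohort, sample by sample.

    Delta-MAF fields are filled only for expressed mutations of QC-passing
    samples; excluded samples keep their classification but contribute no
    delta-MAF values.  Returns the per-sample QC table.
    """
    by_sample: dict[str, list[AseRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    qc: dict[str, SampleQc] = {}
    for sample_id, recs in by_sample.items():
        q = sample_qc(recs, min_expressed=min_expressed, max_factor=max_factor)
        qc[sample_id] = q
        if q.excluded:
            continue
        for rec in recs:
            apply_adjustment(rec, q.adjustment_factor, adjust=adjust)
    return qc


def write_sample_qc(qc: dict[str, SampleQc], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_expressed\tadjustment_factor\texcluded\texclusion_reason\n")
        for q in qc.values():
            factor = "NA" if math.isnan(q.adjustment_factor) else repr(q.adjustment_factor)
            fh.write(
                f"{q.sample_id}\t{q.n_expressed}\t{factor}\t{q.excluded}\t{q.exclusion_reason.value}\n"
            )
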