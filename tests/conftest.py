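"""Shared fixtures: record factories and session-scoped synthetic cohorts."""

from __future__ import annotations

import pytest

from asemut.simulate import GeneratorConfig, generate_cohort
from asemut.types import AseRecord, GeneRole, MutationClass, Status


def make_record(
    sample_id="S1",
    gene="GENE1",
    mutation_class=MutationClass.MISSENSE_SNV,
    status=Status.MUT_EXPRESSED,
    dna_maf=0.25,
    rna_maf=None,
    pos=100,
    role=GeneRole.OTHER,
    **kwargs,
) -> AseRecord:
    """AseRecord with sensible defaults for unit tests."""
    rna_kwargs = {}
    if rna_maf is not None:
        total = kwargs.pop("rna_total", 100)
        alt = round(rna_maf * total)
        rna_kwargs = {"rna_ref_depth": total - alt, "rna_alt_depth": alt, "rna_maf": alt / total}
    return AseRecord(
        sample_id=sample_id,
        chrom=kwargs.pop("chrom", "chr1"),
        pos=pos,
        ref_allele=kwargs.pop("ref_allele", "A"),
        alt_allele=kwargs.pop("alt_allele", "T"),
        gene=gene,
        mutation_class=mutation_class,
        tumor_ref_depth=kwargs.pop("tumor_ref_depth", 75),
        tumor_alt_depth=kwargs.pop("tumor_alt_depth", 25),
        normal_ref_depth=kwargs.pop("normal_ref_depth", 50),
        normal_alt_depth=kwargs.pop("normal_alt_depth", 0),
        dna_maf=dna_maf,
        status=status,
        role=role,
        **rna_kwargs,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """10-sample cohort at reduced scale, shared across tests."""
    cfg = GeneratorConfig(
        n_samples=10, mutations_per_sample_mean=120.0, n_genes=3000
    )
    return generate_cohort(cfg, 421)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default study conditions (50 samples, ~225 mutations each)."""
    return generate_cohort(GeneratorConfig(), 421)


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    from asemut.pipeline import analyze_cohort

    c = default_cohort
    return analyze_cohort(c.calls, c.rna_counts, c.expression, c.segments, c.annotations)
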