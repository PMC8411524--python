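"""Cohort summaries: TMB, gene frequency, contrasts, strata, correlations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from asemut.cohort import (
    balance_enrichment,
    dose_drug_correlation,
    double_mutation_flags,
    expressed_tmb,
    gene_expression_frequency,
    maf_group_contrast,
    mutation_group,
    stratified_delta,
    welch_t,
)
from asemut.classify import gene_level_collapse
from asemut.types import MutationClass, Status
from conftest import make_record


def toy_sample_records():
    """6 amino-acid-changing (2 expressed, 1 WT, 2 silent, 1 unevaluable)
    plus 2 synonymous, all in one sample."""
    mk = make_record
    return [
        mk(gene="A", pos=1, status=Status.MUT_EXPRESSED),
        mk(gene="B", pos=2, status=Status.MUT_EXPRESSED,
           mutation_class=MutationClass.FRAMESHIFT_INDEL),
        mk(gene="C", pos=3, status=Status.WT_ONLY),
        mk(gene="D", pos=4, status=Status.GENE_SILENT),
        mk(gene="E", pos=5, status=Status.GENE_SILENT,
           mutation_class=MutationClass.NONSENSE_SNV),
        mk(gene="F", pos=6, status=Status.UNEVALUABLE),
        mk(gene="G", pos=7, status=Status.MUT_EXPRESSED,
           mutation_class=MutationClass.SYNONYMOUS_SNV),
        mk(gene="H", pos=8, status=Status.WT_ONLY,
           mutation_class=MutationClass.SYNONYMOUS_SNV),
    ]


class TestExpressedTmb:
    def test_toy_counts(self):
        out = expressed_tmb(toy_sample_records())
        assert out["tmb"] == 6
        assert out["expressed_tmb"] == 2
        assert out["proportion_expressed"] == pytest.approx(2 / 5)

    def test_empty_sample(self):
        out = expressed_tmb([])
        assert out["tmb"] == 0 and out["expressed_tmb"] == 0
        assert math.isnan(out["proportion_expressed"])

    def test_capture_size_division(self):
        recs = [make_record(pos=i) for i in range(150)]
        out = expressed_tmb(recs, capture_size_mb=50.0)
        assert out["tmb_per_mb"] == pytest.approx(3.0)

    def test_matches_brute_force_on_fuzzed_tables(self):
        """Oracle equivalence against a direct recount."""
        rng = np.random.default_rng(17)
        classes = list(MutationClass)
        statuses = list(Status)
        aa = {MutationClass.MISSENSE_SNV, MutationClass.NONSENSE_SNV,
              MutationClass.STOPLOSS_SNV, MutationClass.FRAMESHIFT_INDEL,
              MutationClass.SPLICE_SITE_SNV, MutationClass.SPLICE_SITE_INDEL}
        for _ in range(25):
            recs = [
                make_record(pos=i, mutation_class=classes[rng.integers(len(classes))],
                            status=statuses[rng.integers(len(statuses))])
                for i in range(int(rng.integers(0, 40)))
            ]
            out = expressed_tmb(recs)
            # independent brute-force recount
            tmb = sum(1 for r in recs if r.mutation_class in aa)
            expr = sum(1 for r in recs
                       if r.mutation_class in aa and r.status is Status.MUT_EXPRESSED)
            ev = sum(1 for r in recs
                     if r.mutation_class in aa and r.status is not Status.UNEVALUABLE)
            assert out["tmb"] == tmb and out["expressed_tmb"] == expr
            if ev:
                assert out["proportion_expressed"] == pytest.approx(expr / ev)


class TestGeneExpressionFrequency:
    def test_three_of_four_tumors(self):
        recs = [
            make_record(sample_id=f"S{i}", gene="A", pos=10 + i,
                        status=Status.MUT_EXPRESSED if i < 3 else Status.WT_ONLY)
            for i in range(4)
        ]
        freq = gene_expression_frequency(recs)
        assert freq.loc[freq.gene == "A", "frequency"].iloc[0] == pytest.approx(0.75)

    def test_unevaluable_only_gene_reported_na(self):
        recs = [make_record(gene="A", status=Status.UNEVALUABLE)]
        freq = gene_expression_frequency(recs)
        assert math.isnan(freq["frequency"].iloc[0])
        assert freq["n_mutated_tumors"].iloc[0] == 1

    def test_everything_expressed_gives_ones(self):
        recs = [make_record(sample_id=f"S{i}", gene=g, pos=i * 10 + j)
                for i in range(3) for j, g in enumerate("ABC")]
        freq = gene_expression_frequency(recs)
        assert (freq["frequency"] == 1.0).all()

    def test_tumors_not_mutations_are_the_unit(self):
        """3 expressed mutations in one tumor contribute 1/1, not 3/3."""
        recs = [make_record(gene="A", pos=p, status=Status.MUT_EXPRESSED)
                for p in (1, 2, 3)]
        freq = gene_expression_frequency(gene_level_collapse(recs))
        row = freq.iloc[0]
        assert row["n_mutated_tumors"] == 1 and row["n_expressed_tumors"] == 1

    def test_synonymous_excluded(self):
        recs = [make_record(gene="A", mutation_class=MutationClass.SYNONYMOUS_SNV)]
        assert len(gene_expression_frequency(recs)) == 0

    def test_frequencies_in_unit_interval(self, small_cohort):
        from asemut.classify import build_ase_records

        records, _ = build_ase_records(
            small_cohort.calls, small_cohort.rna_counts, small_cohort.expression,
            small_cohort.segments, small_cohort.annotations,
        )
        freq = gene_expression_frequency(gene_level_collapse(records))
        valid = freq["frequency"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()


class TestMafGroupContrast:
    def _records(self, rng, mu_a, mu_b, n=200):
        recs = []
        for i in range(n):
            sample = f"S{i % 10}"
            recs.append(make_record(sample_id=sample, pos=i, gene=f"G{i}",
                                    dna_maf=float(rng.normal(mu_a, 0.05)),
                                    status=Status.WT_ONLY))
            recs.append(make_record(sample_id=sample, pos=10_000 + i, gene=f"H{i}",
                                    dna_maf=float(rng.normal(mu_b, 0.05)),
                                    status=Status.MUT_EXPRESSED))
        return recs

    def test_separated_groups_detected(self):
        """Non-expressed loci at mean 0.15 vs expressed at 0.25."""
        rng = np.random.default_rng(23)
        recs = self._records(rng, 0.15, 0.25)
        out = maf_group_contrast(recs, "status", "dna_maf")
        assert out["levels"] == [Status.MUT_EXPRESSED.value, Status.WT_ONLY.value]
        assert out["welch_p"] < 1e-6
        # expressed minus non-expressed: +0.10
        assert out["mean_difference"] == pytest.approx(0.10, abs=0.02)
        assert out["paired_p"] < 1e-4

    def test_null_case(self):
        rng = np.random.default_rng(24)
        recs = self._records(rng, 0.2, 0.2)
        out = maf_group_contrast(recs, "status", "dna_maf")
        assert abs(out["mean_difference"]) < 0.02
        assert out["welch_p"] > 1e-4

    def test_single_sample_paired_is_na(self):
        recs = [
            make_record(pos=1, dna_maf=0.1, status=Status.WT_ONLY),
            make_record(pos=2, dna_maf=0.15, status=Status.WT_ONLY),
            make_record(pos=3, dna_maf=0.3, status=Status.MUT_EXPRESSED),
            make_record(pos=4, dna_maf=0.35, status=Status.MUT_EXPRESSED),
        ]
        out = maf_group_contrast(recs, "status", "dna_maf")
        assert math.isnan(out["paired_p"])
        assert not math.isnan(out["welch_p"])


class TestStratifiedDelta:
    def _cohort(self, rng, shifts, n_per=120, n_samples=15):
        recs = []
        i = 0
        for cls, shift in shifts.items():
            for _ in range(n_per):
                rec = make_record(
                    sample_id=f"S{i % n_samples}", pos=i, gene=f"G{i}",
                    mutation_class=cls, rna_maf=0.3, rna_total=1000,
                )
                rec.delta_maf = float(rng.normal(shift, 0.08))
                recs.append(rec)
                i += 1
        return recs

    def test_stratum_means_recovered(self):
        rng = np.random.default_rng(31)
        recs = self._cohort(rng, {
            MutationClass.SYNONYMOUS_SNV: 0.0,
            MutationClass.NONSENSE_SNV: -0.10,
            MutationClass.SPLICE_SITE_SNV: 0.31,
        })
        strata = {s.mutation_group: s for s in stratified_delta(recs)
                  if not s.cancer_critical}
        assert strata["truncating"].mean_delta == pytest.approx(-0.10, abs=0.03)
        assert strata["splice_site"].mean_delta == pytest.approx(0.31, abs=0.03)
        assert strata["truncating"].welch_p < 1e-6
        assert strata["splice_site"].welch_p < 1e-6
        assert math.isnan(strata["synonymous"].welch_p)  # reference stratum

    def test_null_generator_cis_cover_zero(self):
        rng = np.random.default_rng(32)
        recs = self._cohort(rng, {c: 0.0 for c in (
            MutationClass.SYNONYMOUS_SNV, MutationClass.MISSENSE_SNV,
            MutationClass.NONSENSE_SNV, MutationClass.SPLICE_SITE_SNV)})
        for s in stratified_delta(recs):
            # a 95% CI misses zero for ~1 in 20 strata by construction;
            # twice the half-width (~4 SE) makes the null check reliable
            half = (s.ci_high - s.ci_low) / 2
            assert abs(s.mean_delta) <= 2 * half

    def test_small_strata_omitted(self):
        rng = np.random.default_rng(33)
        recs = self._cohort(rng, {MutationClass.SYNONYMOUS_SNV: 0.0}, n_per=30)
        recs.extend(self._cohort(rng, {MutationClass.STOPLOSS_SNV: 0.1}, n_per=5))
        groups = {s.mutation_group for s in stratified_delta(recs)}
        assert "stoploss" not in groups

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(34)
        recs = self._cohort(rng, {MutationClass.MISSENSE_SNV: 0.05}, n_per=40)
        for s in stratified_delta(recs):
            assert s.ci_low <= s.mean_delta <= s.ci_high

    def test_mutation_group_mapping(self):
        assert mutation_group(MutationClass.NONSENSE_SNV) == "truncating"
        assert mutation_group(MutationClass.FRAMESHIFT_INDEL) == "truncating"
        assert mutation_group(MutationClass.SPLICE_SITE_INDEL) == "splice_site"
        assert mutation_group("synonymous_snv") == "synonymous"


class TestBalanceEnrichment:
    def _rec(self, i, critical, imbalanced):
        from asemut.types import GeneRole

        return make_record(
            pos=i, gene=f"G{i}",
            role=GeneRole.ONCOGENE if critical else GeneRole.OTHER,
            balanced=not imbalanced, tcn=3 if imbalanced else 2,
            lcn=1, purity=0.8,
        )

    def test_odds_ratio_three(self):
        recs = (
            [self._rec(i, True, True) for i in range(30)]
            + [self._rec(100 + i, True, False) for i in range(10)]
            + [self._rec(200 + i, False, True) for i in range(20)]
            + [self._rec(300 + i, False, False) for i in range(20)]
        )
        out = balance_enrichment(recs)
        assert out["table"] == [[30, 10], [20, 20]]
        assert out["odds_ratio"] == pytest.approx(3.0)

    def test_zero_margin_is_na(self):
        recs = [self._rec(i, False, i % 2 == 0) for i in range(10)]
        out = balance_enrichment(recs)
        assert math.isnan(out["odds_ratio"])

    def test_zero_cell_still_has_exact_p(self):
        recs = (
            [self._rec(i, True, True) for i in range(5)]
            + [self._rec(100 + i, False, True) for i in range(5)]
            + [self._rec(200 + i, False, False) for i in range(5)]
        )
        out = balance_enrichment(recs)
        assert "note" in out
        assert 0 <= out["fisher_p"] <= 1


class TestDoseDrugCorrelation:
    def test_perfect_anti_monotone(self):
        doses = {f"M{i}": float(i) for i in range(8)}
        dss = {f"M{i}": float(-i) for i in range(8)}
        out = dose_drug_correlation(doses, dss)
        assert out["rho"] == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(41)
        rhos = []
        for _ in range(30):
            doses = {f"M{i}": float(rng.normal()) for i in range(15)}
            dss = {f"M{i}": float(rng.normal()) for i in range(15)}
            rhos.append(dose_drug_correlation(doses, dss)["rho"])
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_or_constant_is_na(self):
        assert math.isnan(dose_drug_correlation({"A": 1.0}, {"A": 2.0})["rho"])
        doses = {f"M{i}": 1.0 for i in range(5)}
        dss = {f"M{i}": float(i) for i in range(5)}
        assert math.isnan(dose_drug_correlation(doses, dss)["rho"])


def test_purity_residualization_removes_linear_trend():
    """With delta-MAF generated as a linear function of purity plus a class
    shift, residualization shrinks the purity-driven spread of the
    synonymous stratum without destroying the class contrast."""
    rng = np.random.default_rng(51)
    recs = []
    for i in range(300):
        purity = float(rng.uniform(0.4, 0.95))
        cls = MutationClass.SYNONYMOUS_SNV if i % 2 else MutationClass.NONSENSE_SNV
        shift = 0.0 if i % 2 else -0.10
        rec = make_record(sample_id=f"S{i % 10}", pos=i, gene=f"G{i}",
                          mutation_class=cls, purity=purity, tcn=2, lcn=1,
                          balanced=True)
        rec.delta_maf = shift + 0.3 * (purity - 0.675) + float(rng.normal(0, 0.01))
        recs.append(rec)
    raw = {s.mutation_group: s for s in stratified_delta(recs)}
    adj = {s.mutation_group: s for s in stratified_delta(recs, purity_adjust=True)}
    width = lambda s: s.ci_high - s.ci_low
    assert width(adj["synonymous"]) < width(raw["synonymous"])
    assert adj["truncating"].mean_delta - adj["synonymous"].mean_delta == pytest.approx(
        -0.10, abs=0.02
    )


def test_positional_contrast_five_vs_three_prime():
    """Mutations 3' of the CDS breakpoint with higher delta-MAF are detected."""
    from asemut.cohort import positional_contrast

    rng = np.random.default_rng(52)
    recs, rel = [], {}
    for i in range(200):
        threeprime = i % 2 == 0
        rec = make_record(sample_id=f"S{i % 8}", pos=i, gene=f"G{i}",
                          rna_maf=0.3, rna_total=100)
        rec.delta_maf = float(rng.normal(0.15 if threeprime else 0.0, 0.05))
        recs.append(rec)
        rel[rec.key] = 0.9 if threeprime else 0.2
    out = positional_contrast(recs, rel, breakpoint=0.5)
    assert out["welch_p"] < 1e-6
    assert abs(abs(out["mean_difference"]) - 0.15) < 0.03


def test_double_mutation_flags():
    recs = [make_record(gene="A", pos=1), make_record(gene="A", pos=2),
            make_record(gene="B", pos=3)]
    flags = double_mutation_flags(recs)
    assert flags[("S1", "A")] and not flags[("S1", "B")]


def test_welch_is_two_sided():
    rng = np.random.default_rng(42)
    a = rng.normal(0, 1, 50)
    b = rng.normal(0.5, 1, 50)
    _, p_ab = welch_t(a, b)
    _, p_ba = welch_t(b, a)
    assert p_ab == pytest.approx(p_ba)
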