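"""Generative model: analytic MAF expectations, calibration, determinism."""

from __future__ import annotations

import numpy as np
import pytest

from asemut.adjust import adjust_cohort
from asemut.classify import build_ase_records
from asemut.simulate import (
    GeneratorConfig,
    analytic_mean_delta,
    expected_dna_maf,
    expected_rna_maf,
    generate_cohort,
    inflate_sample_rna,
    resolve_kappas,
    solve_kappa,
)


class TestExpectedMaf:
    @pytest.mark.parametrize(
        "rho,tcn,m,expected",
        [
            (1.0, 2, 1, 0.5),  # heterozygous pure tumor
            (0.5, 2, 1, 0.25),
            (0.5, 3, 2, 0.4),  # 1.0 / 2.5
            (1.0, 1, 1, 1.0),  # LOH, pure
        ],
    )
    def test_dna_values(self, rho, tcn, m, expected):
        assert expected_dna_maf(rho, tcn, m) == pytest.approx(expected)

    def test_dna_errors(self):
        with pytest.raises(ValueError):
            expected_dna_maf(1.0, 0, 0)  # no DNA in a pure tumor
        with pytest.raises(ValueError):
            expected_dna_maf(0.5, 2, 3)  # m > tcn

    def test_kappa_one_reduces_to_dna(self):
        for rho in (0.3, 0.7, 1.0):
            for tcn, m in ((2, 1), (3, 2), (4, 1)):
                assert expected_rna_maf(rho, tcn, m, 1.0) == pytest.approx(
                    expected_dna_maf(rho, tcn, m)
                )

    def test_kappa_zero_fully_degraded(self):
        assert expected_rna_maf(1.0, 2, 1, 0.0) == 0.0

    def test_kappa_three(self):
        assert expected_rna_maf(1.0, 2, 1, 3.0) == pytest.approx(0.75)

    def test_monotone_in_kappa(self):
        values = [expected_rna_maf(0.7, 3, 1, k) for k in (0.2, 0.5, 1, 2, 5)]
        assert values == sorted(values)


class TestConfigValidation:
    def test_infeasible_mutant_copies_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(copy_states=((2, 1, 2, 1.0),))  # m=2 > tcn-lcn=1

    def test_probabilities_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(copy_states=((2, 1, 1, 0.5),))

    def test_bad_purity_range(self):
        with pytest.raises(ValueError):
            GeneratorConfig(purity_low=0.9, purity_high=0.5)


class TestKappaSolver:
    def test_solved_kappas_hit_targets(self):
        cfg = resolve_kappas(GeneratorConfig())
        assert analytic_mean_delta(cfg, cfg.kappa_truncating) == pytest.approx(-0.10, abs=1e-6)
        assert analytic_mean_delta(cfg, cfg.kappa_splice) == pytest.approx(0.31, abs=1e-6)
        assert analytic_mean_delta(cfg, cfg.kappa_missense_cancer) == pytest.approx(0.04, abs=1e-6)

    def test_round_trip_arbitrary_target(self):
        cfg = GeneratorConfig()
        k = solve_kappa(cfg, -0.05)
        assert analytic_mean_delta(cfg, k) == pytest.approx(-0.05, abs=1e-8)
        assert k < 1.0

    def test_unattainable_target_errors(self):
        with pytest.raises(ValueError, match="range"):
            solve_kappa(GeneratorConfig(), 0.99)


class TestGenerateCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_samples=3, mutations_per_sample_mean=30.0, n_genes=500)
        a = generate_cohort(cfg, 9).write(tmp_path / "a")
        b = generate_cohort(cfg, 9).write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        cfg = GeneratorConfig(n_samples=3, mutations_per_sample_mean=30.0, n_genes=500)
        a = generate_cohort(cfg, 9).write(tmp_path / "a")
        b = generate_cohort(cfg, 10).write(tmp_path / "b")
        assert a["mutations"].read_bytes() != b["mutations"].read_bytes()

    def test_outputs_parse_through_io(self, tmp_path, small_cohort):
        from asemut.io_tables import (
            read_allele_counts,
            read_copy_segments,
            read_gene_annotations,
            read_mutations,
        )
        from asemut.expression import read_expression

        paths = small_cohort.write(tmp_path)
        calls = read_mutations(paths["mutations"])
        assert len(calls) == len(small_cohort.calls)
        counts = read_allele_counts(paths["rna_counts"])
        assert len(counts) == len(small_cohort.rna_counts)
        segs = read_copy_segments(paths["segments"])
        assert len(segs) == len(small_cohort.segment_rows)
        expr = read_expression(paths["expression_counts"], paths["gene_lengths"])
        assert expr.counts.shape == small_cohort.expression.counts.shape
        ann = read_gene_annotations(paths["cgc"], paths["flags"])
        assert ann.keys() == small_cohort.annotations.keys()
        assert len(small_cohort.truth) == len(calls)

    def test_truth_aligned_row_for_row(self, small_cohort):
        for call, (_, row) in zip(small_cohort.calls, small_cohort.truth.iterrows()):
            assert (call.sample_id, call.chrom, call.pos) == (
                row["sample_id"], row["chrom"], row["pos"]
            )
            assert call.mutation_class.value == row["mutation_class"]

    def test_null_kappa_mean_delta_near_zero(self):
        """With every multiplier at 1, RNA and DNA MAF agree on average."""
        cfg = GeneratorConfig(
            n_samples=8, mutations_per_sample_mean=150.0, n_genes=2000,
            kappa_truncating=1.0, kappa_splice=1.0, kappa_missense_cancer=1.0,
        )
        cohort = generate_cohort(cfg, 55)
        diffs = []
        for call in cohort.calls:
            rna = cohort.rna_counts[call.key]
            total = rna.rna_ref_depth + rna.rna_alt_depth
            if total >= 20 and call.dna_maf > 0:
                diffs.append(rna.rna_maf - call.dna_maf)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se

    def test_silent_fraction_recovered_through_pipeline(self):
        """40% of mutations in background genes -> ~40% GENE_SILENT calls."""
        cfg = GeneratorConfig(
            n_samples=8, mutations_per_sample_mean=150.0, n_genes=2000,
            silent_mutation_fraction=0.40,
        )
        cohort = generate_cohort(cfg, 56)
        records, counts = build_ase_records(
            cohort.calls, cohort.rna_counts, cohort.expression,
            cohort.segments, cohort.annotations,
        )
        n = counts["dna_pass"]
        frac = counts.get("GENE_SILENT", 0) / n
        se = np.sqrt(0.4 * 0.6 / n)
        # zFPKM misclassification near the -3 boundary adds a small bias on
        # top of binomial noise; 3 SE + 2% absolute covers it
        assert abs(frac - 0.40) <= 3 * se + 0.02

    def test_empirical_dna_maf_matches_expectation(self, small_cohort):
        """Cohort-level check: binomial DNA counts center on f_DNA."""
        truth = small_cohort.truth
        obs = []
        for call, f in zip(small_cohort.calls, truth["f_dna"]):
            obs.append(call.dna_maf - f)
        obs = np.asarray(obs)
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean()) <= 3 * se


class TestInflationRecovery:
    def test_injected_factor_recovered_and_excluded(self):
        """A 2x RNA-MAF inflation in one sample moves its adjustment factor
        to ~2 and triggers exclusion (2 > 1.75)."""
        cfg = GeneratorConfig(
            n_samples=6, mutations_per_sample_mean=150.0, n_genes=2000,
            kappa_truncating=1.0, kappa_splice=1.0, kappa_missense_cancer=1.0,
            rna_depth_per_fpkm=12.0,
        )
        cohort = generate_cohort(cfg, 57)
        target = cohort.calls[0].sample_id
        inflated = inflate_sample_rna(cohort.rna_counts, target, 2.0)
        records, _ = build_ase_records(
            cohort.calls, inflated, cohort.expression,
            cohort.segments, cohort.annotations,
        )
        qc = adjust_cohort(records)
        assert qc[target].adjustment_factor == pytest.approx(2.0, abs=0.1)
        assert qc[target].excluded
        others = [q for s, q in qc.items() if s != target]
        assert all(not q.excluded for q in others)
        assert all(abs(q.adjustment_factor - 1.0) < 0.1 for q in others)
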