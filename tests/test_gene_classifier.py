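"""Percentile criteria, gene verdicts, and cross-cohort aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsilence.containers import BetaMatrix, CpGAnnotation, GeneEpigeneticCall
from methsilence.gene_classifier import (
    activation_criteria,
    aggregate_across_cohorts,
    call_genes,
    calls_to_frame,
    percentile,
    silencing_criteria,
    summaries_to_frame,
)
from oracles import oracle_percentile


class TestPercentile:
    def test_worked_interpolation_example(self):
        # h = 4.8 -> 0.4 + 0.8 * (0.5 - 0.4) = 0.48
        assert percentile([0.1, 0.2, 0.3, 0.4, 0.5], 95) == pytest.approx(0.48, abs=1e-12)

    def test_q100_is_maximum(self):
        assert percentile([3.0, 1.0, 2.0], 100) == 3.0

    def test_constant_vector(self):
        assert percentile([0.4] * 7, 37.5) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 95)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 25), st.floats(0, 100))
    def test_matches_order_statistic_formula(self, seed, n, q):
        values = np.random.default_rng(seed).random(n)
        assert percentile(values, q) == pytest.approx(
            oracle_percentile(list(values), q), abs=1e-12
        )


class TestCriteria:
    def test_silencing_all_three_pass(self):
        normal = [0.10, 0.12, 0.15, 0.14, 0.11]
        tumor = [0.30, 0.60, 0.70, 0.25, 0.35]
        out = silencing_criteria(normal, tumor)
        assert out.passed and out.a and out.b and out.c

    def test_silencing_fails_on_high_normal_percentile(self):
        normal = [0.25, 0.26, 0.24, 0.25, 0.26]  # p95 >= 0.2
        tumor = [0.60, 0.70, 0.65, 0.55, 0.62]
        out = silencing_criteria(normal, tumor)
        assert not out.passed and not out.a and out.b and out.c

    def test_silencing_fails_on_low_tumor_maximum(self):
        normal = [0.10, 0.11, 0.12, 0.10, 0.13]
        tumor = [0.45, 0.40, 0.42, 0.44, 0.41]  # max <= 0.5
        out = silencing_criteria(normal, tumor)
        assert not out.passed and out.a and not out.b and out.c

    def test_activation_mirror_case(self):
        normal = [0.55, 0.80, 0.45, 0.60, 0.50]
        tumor = [0.08, 0.10, 0.12, 0.09, 0.11]
        out = activation_criteria(normal, tumor)
        assert out.passed

    def test_activation_fails_on_high_tumor_percentile(self):
        out = activation_criteria([0.55, 0.80, 0.45], [0.30, 0.10, 0.12])
        assert not out.passed and not out.a

    def test_identical_low_groups_fail_both_directions(self):
        flat = [0.10, 0.09, 0.11, 0.10]
        assert not silencing_criteria(flat, flat).passed
        assert not activation_criteria(flat, flat).passed

    def test_boundaries_are_strict(self):
        # normal p95 exactly 0.2 fails criterion (a)
        out = silencing_criteria([0.2] * 5, [0.6, 0.7, 0.3, 0.4, 0.35])
        assert not out.a


def _single_gene_setup(normal_betas, tumor_betas):
    n_t, n_n = len(tumor_betas), len(normal_betas)
    samples = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
    groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples, name="group")
    beta = BetaMatrix(
        pd.DataFrame([list(tumor_betas) + list(normal_betas)], index=["cg0"], columns=samples),
        groups,
    )
    ann = CpGAnnotation(
        pd.DataFrame([("cg0", "gA", "TSS200")], columns=["cpg_id", "gene", "region"])
    )
    return beta, ann


class TestCallGenes:
    def test_qualifying_cpg_makes_gene_silenced(self):
        beta, ann = _single_gene_setup(
            normal_betas=[0.10, 0.12, 0.15, 0.14],
            tumor_betas=[0.30, 0.60, 0.70, 0.25, 0.35],
        )
        assoc = pd.DataFrame(
            [("cg0", "gA", -0.5, 1e-4, 9)], columns=["cpg_id", "gene", "r", "p", "n"]
        )
        calls = call_genes(beta, assoc, ann, "cohortX")
        assert calls[0].verdict == "silenced"
        assert calls[0].supporting_cpgs[0].cpg_id == "cg0"
        assert calls[0].supporting_cpgs[0].max_tumor == pytest.approx(0.70)

    def test_failing_correlation_screen_means_none(self):
        beta, ann = _single_gene_setup(
            normal_betas=[0.10, 0.12, 0.15, 0.14],
            tumor_betas=[0.30, 0.60, 0.70, 0.25, 0.35],
        )
        # associations already filtered: nothing survived the screen
        empty = pd.DataFrame(columns=["cpg_id", "gene", "r", "p", "n"])
        calls = call_genes(beta, empty, ann, "cohortX")
        assert calls[0].verdict == "none"

    def test_flat_cohort_yields_no_calls(self):
        rng = np.random.default_rng(2)
        beta, ann = _single_gene_setup(
            normal_betas=rng.uniform(0.08, 0.12, 6), tumor_betas=rng.uniform(0.08, 0.12, 8)
        )
        assoc = pd.DataFrame(
            [("cg0", "gA", -0.9, 1e-6, 14)], columns=["cpg_id", "gene", "r", "p", "n"]
        )
        calls = call_genes(beta, assoc, ann, "cohortX")
        assert calls[0].verdict == "none"

    def test_gene_without_cpgs_in_matrix_is_none(self):
        beta, _ = _single_gene_setup([0.1, 0.1, 0.1], [0.6, 0.7, 0.6])
        ann = CpGAnnotation(
            pd.DataFrame(
                [("cg0", "gA", "TSS200"), ("cg_missing", "gB", "Body")],
                columns=["cpg_id", "gene", "region"],
            )
        )
        empty = pd.DataFrame(columns=["cpg_id", "gene", "r", "p", "n"])
        verdicts = {c.gene: c.verdict for c in call_genes(beta, empty, ann, "x")}
        assert verdicts["gB"] == "none"

    def test_no_gene_both_silenced_and_activated(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n_cpgs, n_s = int(rng.integers(2, 10)), int(rng.integers(6, 12))
            samples = [f"s{i}" for i in range(n_s)]
            n_t = int(rng.integers(3, n_s - 2))
            groups = pd.Series(["tumor"] * n_t + ["normal"] * (n_s - n_t),
                               index=samples, name="group")
            beta = BetaMatrix(
                pd.DataFrame(rng.random((n_cpgs, n_s)),
                             index=[f"cg{i}" for i in range(n_cpgs)], columns=samples),
                groups,
            )
            ann = CpGAnnotation(pd.DataFrame(
                [(f"cg{i}", f"g{i % 3}", "TSS200") for i in range(n_cpgs)],
                columns=["cpg_id", "gene", "region"],
            ))
            assoc = pd.DataFrame(
                [(f"cg{i}", f"g{i % 3}", -0.5, 0.01, n_s) for i in range(n_cpgs)],
                columns=["cpg_id", "gene", "r", "p", "n"],
            )
            for call in call_genes(beta, assoc, ann, "x"):
                assert call.verdict in ("silenced", "activated", "none")

    def test_weakening_r_cut_never_shrinks_silenced_set(self, clean_cohort):
        from methsilence.association import correlate_cpg_expression, significant_negative
        from methsilence.preprocess import log_transform_expression

        cohort = clean_cohort
        expr_log = log_transform_expression(cohort.expression)
        records = correlate_cpg_expression(cohort.beta, expr_log, cohort.annotation)
        previous: set[str] = set()
        for r_cut in (-0.6, -0.4, -0.2, -0.05):
            sig = significant_negative(records, r_cut=r_cut)
            calls = call_genes(cohort.beta, sig, cohort.annotation, "x")
            silenced = {c.gene for c in calls if c.verdict == "silenced"}
            assert previous <= silenced
            previous = silenced


def _call(gene, cohort, verdict):
    return GeneEpigeneticCall(gene=gene, cohort=cohort, verdict=verdict)


class TestAggregate:
    def test_counts_and_sorting(self):
        calls = {
            "A": [_call("g1", "A", "silenced"), _call("g2", "A", "silenced")],
            "B": [_call("g1", "B", "silenced")],
            "C": [_call("g1", "C", "silenced"), _call("g2", "C", "activated")],
        }
        out = aggregate_across_cohorts(calls, min_cohorts=2)
        assert len(out) == 1
        assert out[0].gene == "g1" and out[0].n_silenced == 3
        frame = summaries_to_frame(out)
        assert frame.loc[0, "cohorts"] == "A,B,C"

    def test_min_cohorts_one_with_single_cohort_is_identity(self):
        calls = {"A": [_call("g1", "A", "silenced"), _call("g2", "A", "none")]}
        out = aggregate_across_cohorts(calls, min_cohorts=1)
        assert [s.gene for s in out] == ["g1"]

    def test_min_cohorts_above_cohort_count_warns_and_is_empty(self, caplog):
        calls = {"A": [_call("g1", "A", "silenced")]}
        with caplog.at_level("WARNING"):
            out = aggregate_across_cohorts(calls, min_cohorts=3)
        assert out == []
        assert any("min_cohorts" in rec.message for rec in caplog.records)

    def test_ties_sorted_by_descending_count_then_gene(self):
        calls = {
            "A": [_call("g2", "A", "silenced"), _call("g1", "A", "silenced")],
            "B": [_call("g2", "B", "silenced")],
        }
        out = aggregate_across_cohorts(calls, min_cohorts=1)
        assert [s.gene for s in out] == ["g2", "g1"]

    def test_calls_to_frame_picks_most_negative_cpg(self):
        from methsilence.containers import SupportingCpG

        sup = [
            SupportingCpG("cgA", -0.4, 0.01, 0.1, 0.5, 0.8, 0.2, 0.4, 0.1),
            SupportingCpG("cgB", -0.9, 0.001, 0.1, 0.5, 0.8, 0.2, 0.4, 0.1),
        ]
        call = GeneEpigeneticCall(gene="g", cohort="A", verdict="silenced", supporting_cpgs=sup)
        frame = calls_to_frame([call])
        assert frame.loc[0, "best_cpg"] == "cgB"
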