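"""Normalization, probe summarization and differential-expression rules."""

import numpy as np
import pandas as pd
import pytest

from lumenstarve.genome_io import GeneAnnotation
from lumenstarve.microarray import (
    call_differential,
    group_operons,
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    summarize_genes,
    two_sample_t,
)
from lumenstarve.synthetic_data import simulate_expression_experiment


def textbook_median_polish(block, tol=0.01, max_iter=10):
    """Independently coded sweep-by-sweep median polish (test oracle)."""
    block = [list(map(float, row)) for row in block]
    nr, nc = len(block), len(block[0])
    overall, row_eff, col_eff = 0.0, [0.0] * nr, [0.0] * nc
    med = lambda xs: float(np.median(xs))
    prev = sum(abs(v) for row in block for v in row)
    for _ in range(max_iter):
        for i in range(nr):
            m = med(block[i])
            block[i] = [v - m for v in block[i]]
            row_eff[i] += m
        d = med(col_eff)
        col_eff = [c - d for c in col_eff]
        overall += d
        for j in range(nc):
            m = med([block[i][j] for i in range(nr)])
            for i in range(nr):
                block[i][j] -= m
            col_eff[j] += m
        d = med(row_eff)
        row_eff = [r - d for r in row_eff]
        overall += d
        cur = sum(abs(v) for row in block for v in row)
        if prev - cur < tol:
            break
        prev = cur
    return overall, row_eff, col_eff, block


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_worked_two_by_two(self):
        out = quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_idempotent_and_postcondition(self, rng):
        for _ in range(20):
            m = rng.lognormal(6, 1, size=(50, 4))
            once = quantile_normalize(m)
            twice = quantile_normalize(once)
            np.testing.assert_allclose(once, twice)
            ref = np.sort(once, axis=0)
            for j in range(1, 4):
                np.testing.assert_allclose(ref[:, j], ref[:, 0])

    def test_ties_get_mean_of_spanned_quantiles(self):
        m = np.array([[1.0, 1.0], [1.0, 2.0], [4.0, 3.0]])
        out = quantile_normalize(m)
        ref = np.sort(m, axis=0).mean(axis=1)  # [1.0, 1.5, 3.5]
        # column 0 ties on 1.0 across the two lowest quantiles
        np.testing.assert_allclose(out[:, 0], [1.25, 1.25, 3.5])
        np.testing.assert_allclose(out[:, 1], ref)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_preserves_dataframe_labels(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"], columns=["a", "b"])
        out = quantile_normalize(df)
        assert list(out.index) == ["p1", "p2"] and list(out.columns) == ["a", "b"]


class TestMedianPolish:
    def test_pure_additive_block_recovered(self):
        r = np.array([0.0, 1.0, -1.0])
        c = np.array([5.0, 6.0, 7.0, 8.0])
        block = r[:, None] + c[None, :]
        summaries = median_polish_summarize(block)
        np.testing.assert_allclose(summaries, c, atol=1e-12)

    def test_single_probe_passthrough(self):
        block = np.array([[3.0, 4.0, 5.0]])
        np.testing.assert_allclose(median_polish_summarize(block), [3.0, 4.0, 5.0])

    def test_decomposition_identity_and_oracle(self, rng):
        for _ in range(20):
            block = rng.normal(8, 1, size=(5, 3))
            fit = median_polish(block)
            np.testing.assert_allclose(
                fit.fitted() + fit.residuals, block, atol=1e-12
            )
            overall, row_eff, col_eff, resid = textbook_median_polish(block)
            assert fit.overall == pytest.approx(overall)
            np.testing.assert_allclose(fit.row_effects, row_eff, atol=1e-12)
            np.testing.assert_allclose(fit.col_effects, col_eff, atol=1e-12)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.empty((0, 3)))


class TestTwoSampleT:
    def test_identical_groups_null(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_large_shift_significant_and_matches_closed_form(self):
        a = np.array([11.0, 12.0, 13.0])
        b = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_t(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected_t)
        assert p < 0.001

    def test_zero_variance_conventions(self):
        _, p = two_sample_t([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        _, p = two_sample_t([2.0, 2.0], [1.0, 1.0])
        assert p == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


def make_genes(spec):
    """spec: list of (start, end, strand)."""
    return [GeneAnnotation(f"g{i}", s, e, st) for i, (s, e, st) in enumerate(spec)]


class TestGroupOperons:
    def test_three_gene_run(self):
        genes = make_genes([(1, 100, "+"), (101, 200, "+"), (211, 300, "+")])
        (op,) = group_operons(genes)
        assert op.gene_ids == ("g0", "g1", "g2") and op.max_gap == 10

    def test_large_gap_breaks_run(self):
        genes = make_genes([(1, 100, "+"), (601, 700, "+")])
        assert group_operons(genes) == []

    def test_strand_switch_breaks_run(self):
        genes = make_genes([(1, 100, "+"), (101, 200, "-")])
        assert group_operons(genes) == []

    def test_unsorted_input_rejected(self):
        genes = make_genes([(500, 600, "+"), (1, 100, "+")])
        with pytest.raises(ValueError):
            group_operons(genes)


def summaries_frame(rows):
    """rows: (gene_id, log2_fold, p_value)."""
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "log2_fold": lf,
                "fold_change": 2.0**lf,
                "p_value": p,
            }
            for g, lf, p in rows
        ]
    ).set_index("gene_id")


class TestCallDifferential:
    def test_single_gene_two_fold_rule(self):
        summ = summaries_frame([("a", np.log2(2.5), 0.01)])
        (call,) = call_differential(summ)
        assert call.rule_used == "single_2fold" and call.direction == "up_in_A"
        assert call.fold == pytest.approx(2.5)

    def test_isolated_sub_threshold_gene_not_called(self):
        summ = summaries_frame([("a", np.log2(1.8), 0.001)])
        assert call_differential(summ) == []

    def test_downregulated_gene_uses_reciprocal_fold(self):
        summ = summaries_frame([("a", -np.log2(2.5), 0.01)])
        (call,) = call_differential(summ)
        assert call.direction == "up_in_B" and call.fold == pytest.approx(2.5)

    def test_operon_rule(self):
        from lumenstarve.microarray import OperonGroup

        summ = summaries_frame(
            [("a", np.log2(1.7), 0.02), ("b", np.log2(1.8), 0.01), ("c", np.log2(1.9), 0.03)]
        )
        operon = OperonGroup(("a", "b", "c"), "+", 5)
        (call,) = call_differential(summ, [operon])
        assert call.rule_used == "operon_1.7fold"
        assert set(call.unit) == {"a", "b", "c"}

    def test_operon_with_discordant_member_not_called(self):
        from lumenstarve.microarray import OperonGroup

        summ = summaries_frame(
            [("a", np.log2(1.8), 0.02), ("b", -np.log2(1.8), 0.01)]
        )
        assert call_differential(summ, [OperonGroup(("a", "b"), "+", 0)]) == []

    def test_bad_thresholds_rejected(self):
        summ = summaries_frame([("a", 1.0, 0.01)])
        with pytest.raises(ValueError):
            call_differential(summ, alpha=1.5)
        with pytest.raises(ValueError):
            call_differential(summ, fc_single=0.9)


class TestPipelineProperties:
    def test_scale_equivariance(self):
        experiment, annotations, _ = simulate_expression_experiment(
            30,
            de_spec=[{"genes": ["g00005"], "fold": 2.5, "direction": "up_in_light"}],
            seed=11,
        )
        base = summarize_genes(experiment)
        scaled_intensities = experiment.intensities * 8.0
        from lumenstarve.microarray import ExpressionExperiment

        scaled = summarize_genes(
            ExpressionExperiment(
                scaled_intensities, experiment.probe_to_gene, experiment.samples
            )
        )
        np.testing.assert_allclose(
            scaled["mean_log2_a"], base["mean_log2_a"] + 3.0, atol=1e-9
        )
        np.testing.assert_allclose(scaled["fold_change"], base["fold_change"], atol=1e-9)
        ops = group_operons(annotations)
        calls_scaled = call_differential(scaled, ops)
        calls_base = call_differential(base, ops)
        assert [(c.unit, c.rule_used, c.direction) for c in calls_scaled] == [
            (c.unit, c.rule_used, c.direction) for c in calls_base
        ]
        np.testing.assert_allclose(
            [c.fold for c in calls_scaled], [c.fold for c in calls_base], rtol=1e-9
        )
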