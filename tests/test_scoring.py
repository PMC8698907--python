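"""HDAC SCORE computation, ranking, and cross-cohort intersections."""

import numpy as np
import pytest

from hdacnet import (
    AML_PATIENT_TOP15,
    LEUKEMIA_CELL_LINE_TOP15,
    NB_CELL_LINE_TOP15,
    NB_PATIENT_TOP15,
    CVConfig,
    ExpressionMatrix,
    GenePanel,
    InputError,
    compute_scores,
    fit_rtk_models,
    intersect_top,
    score_vs_expression,
    top_k,
)
from hdacnet.elastic_net import ElasticNetModel
from hdacnet.scoring import RTKScoreRecord, records_to_frame, records_to_long_frame

HDACS = tuple(f"HDAC{i}" for i in range(1, 9))


def _model_from_std_weights(w_std):
    """Model whose standardised weights are exactly w_std (scales = 1)."""
    w = np.asarray(w_std, dtype=float)
    return ElasticNetModel(
        intercept=0.0, weights=w, alpha=0.1, l1_ratio=0.5, n_iter=1, converged=True,
        predictor_means=np.zeros(8), predictor_scales=np.ones(8), predictor_names=HDACS,
    )


def _expr_for(genes, n_samples=4, value=5.0):
    return ExpressionMatrix(list(genes), [f"s{i}" for i in range(n_samples)],
                            np.full((len(genes), n_samples), value))


class TestComputeScores:
    def test_score_arithmetic_from_definition(self):
        models = [("KIT", _model_from_std_weights([1, 0, 0, 0, 0, 2, 0, 3]))]
        panel = GenePanel(rtk_genes=("KIT",))
        recs = compute_scores(models, panel, _expr_for(["KIT"]))
        assert recs[0].score == pytest.approx(14.0)  # 1 + 4 + 9 over HDAC1,2,3,6,8
        assert recs[0].score_i == pytest.approx(10.0)  # 1 + 9 over HDAC1,2,3,8

    def test_all_zero_coefficients_score_zero(self):
        models = [("KIT", _model_from_std_weights(np.zeros(8)))]
        recs = compute_scores(models, GenePanel(rtk_genes=("KIT",)), _expr_for(["KIT"]))
        assert recs[0].score == 0.0 and recs[0].score_i == 0.0

    def test_random_vectors_match_brute_force(self, rng):
        """50 random coefficient vectors: SCORE equals an independent
        brute-force sum of squares over the named subsets."""
        score_idx = [0, 1, 2, 5, 7]  # HDAC1,2,3,6,8
        score_i_idx = [0, 1, 2, 7]
        genes = [f"G{i}" for i in range(50)]
        W = rng.normal(size=(50, 8))
        models = [(g, _model_from_std_weights(w)) for g, w in zip(genes, W)]
        panel = GenePanel(rtk_genes=tuple(genes))
        recs = {r.gene: r for r in compute_scores(models, panel, _expr_for(genes))}
        for g, w in zip(genes, W):
            assert recs[g].score == pytest.approx(sum(w[i] ** 2 for i in score_idx))
            assert recs[g].score_i == pytest.approx(sum(w[i] ** 2 for i in score_i_idx))
            assert recs[g].score_i <= recs[g].score + 1e-12

    def test_ranks_are_permutation_sorted_by_score(self, rng):
        genes = [f"G{i}" for i in range(10)]
        models = [(g, _model_from_std_weights(rng.normal(size=8))) for g in genes]
        recs = compute_scores(models, GenePanel(rtk_genes=tuple(genes)), _expr_for(genes))
        assert [r.rank for r in recs] == list(range(1, 11))
        scores = [r.score for r in recs]
        assert scores == sorted(scores, reverse=True)

    def test_empty_sample_set_errors(self):
        models = [("KIT", _model_from_std_weights(np.ones(8)))]
        expr = ExpressionMatrix(["KIT"], [], np.empty((1, 0)))
        with pytest.raises(InputError):
            compute_scores(models, GenePanel(rtk_genes=("KIT",)), expr)


class TestTopKAndIntersect:
    def _records(self, scores):
        return [
            RTKScoreRecord(gene=g, coefficients={}, score=s, score_i=s, mean_expression=0.0)
            for g, s in scores
        ]

    def test_top_k_largest(self, rng):
        genes = [f"G{i:02d}" for i in range(20)]
        scores = rng.permutation(20).astype(float)
        recs = self._records(list(zip(genes, scores)))
        got = top_k(recs, k=15)
        expect = [g for g, s in sorted(zip(genes, scores), key=lambda t: -t[1])][:15]
        assert got == expect

    def test_tie_break_alphabetical_at_boundary(self):
        recs = self._records([("B", 2.0), ("A", 1.0), ("C", 1.0)])
        assert top_k(recs, k=2) == ["B", "A"]

    def test_k_equals_n_and_k_too_large(self):
        recs = self._records([("A", 3.0), ("B", 1.0)])
        assert top_k(recs, k=2) == ["A", "B"]
        with pytest.raises(InputError):
            top_k(recs, k=3)

    def test_patient_cohort_intersection(self):
        shared = intersect_top(AML_PATIENT_TOP15, NB_PATIENT_TOP15)
        assert set(shared) == {"TIE1", "KIT", "NTRK1", "FGFR3", "CSF1R", "INSRR"}
        # reported in the order of the first list
        assert shared == ["TIE1", "KIT", "NTRK1", "FGFR3", "CSF1R", "INSRR"]

    def test_cell_line_cohort_intersection(self):
        shared = intersect_top(LEUKEMIA_CELL_LINE_TOP15, NB_CELL_LINE_TOP15)
        assert set(shared) == {
            "FLT3", "NTRK1", "INSR", "FGFR1", "ROR2", "FGFR3", "RET", "DDR2", "DDR1",
        }

    def test_four_way_intersection(self):
        shared = intersect_top(
            AML_PATIENT_TOP15, NB_PATIENT_TOP15,
            LEUKEMIA_CELL_LINE_TOP15, NB_CELL_LINE_TOP15,
        )
        assert set(shared) == {"NTRK1", "FGFR3"}

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            intersect_top(["KIT"], [])


class TestFitRtkModels:
    def test_planted_weight_recovery(self, small_cohort_blocks):
        """An RTK planted on HDAC1/2/3/8 is recovered with coefficients
        near truth and near-zero weights on the unused HDACs."""
        hdac_block, rtk_block, panel, truth = small_cohort_blocks
        models = dict(fit_rtk_models(hdac_block, rtk_block, seed=1))
        for gene, (y0, w_true) in truth.planted.items():
            coefs = models[gene].coefficients()
            for j, hdac in enumerate(HDACS):
                if w_true[j] != 0:
                    assert abs(coefs[hdac] - w_true[j]) < 0.5
                else:
                    assert abs(coefs[hdac]) < 0.2

    def test_null_rtk_scores_below_planted(self, small_cohort_blocks):
        hdac_block, rtk_block, panel, truth = small_cohort_blocks
        models = fit_rtk_models(hdac_block, rtk_block, seed=1)
        recs = {r.gene: r for r in compute_scores(models, panel, rtk_block)}
        min_planted = min(recs[g].score for g in truth.planted)
        max_null = max(recs[g].score for g in truth.null_rtks)
        assert max_null < min_planted

    def test_constant_response_zero_weights(self, small_cohort_blocks):
        hdac_block, _, _, _ = small_cohort_blocks
        const = ExpressionMatrix(["CONSTRTK"], hdac_block.sample_ids,
                                 np.full((1, hdac_block.n_samples), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            models = fit_rtk_models(hdac_block, const,
                                    CVConfig(penalties=(0.1, 0.5)), seed=0)
        assert np.all(models[0][1].weights == 0.0)

    def test_mismatched_sample_order_rejected(self, small_cohort_blocks):
        hdac_block, rtk_block, _, _ = small_cohort_blocks
        flipped = ExpressionMatrix(rtk_block.gene_ids, rtk_block.sample_ids[::-1],
                                   rtk_block.values)
        with pytest.raises(InputError):
            fit_rtk_models(hdac_block, flipped)

    def test_deterministic_given_seed(self, small_cohort_blocks):
        hdac_block, rtk_block, _, _ = small_cohort_blocks
        cfg = CVConfig(alpha_grid=(0.01, 0.1), l1_grid=(0.5,), k=5)
        m1 = fit_rtk_models(hdac_block, rtk_block, cfg, seed=8)
        m2 = fit_rtk_models(hdac_block, rtk_block, cfg, seed=8)
        for (g1, a), (g2, b) in zip(m1, m2):
            assert g1 == g2
            np.testing.assert_array_equal(a.weights, b.weights)


class TestScoreInvariances:
    def test_score_invariant_to_sample_and_row_order(self, small_cohort_blocks):
        hdac_block, rtk_block, panel, _ = small_cohort_blocks
        cfg = CVConfig(penalties=(0.05, 0.5))
        base = {r.gene: r.score for r in compute_scores(
            fit_rtk_models(hdac_block, rtk_block, cfg), panel, rtk_block)}

        perm = np.random.default_rng(0).permutation(hdac_block.n_samples)
        hdac_p = ExpressionMatrix(hdac_block.gene_ids,
                                  [hdac_block.sample_ids[i] for i in perm],
                                  hdac_block.values[:, perm])
        rtk_p = ExpressionMatrix(rtk_block.gene_ids,
                                 [rtk_block.sample_ids[i] for i in perm],
                                 rtk_block.values[:, perm])
        permuted = {r.gene: r.score for r in compute_scores(
            fit_rtk_models(hdac_p, rtk_p, cfg), panel, rtk_p)}
        for g in base:
            assert permuted[g] == pytest.approx(base[g], rel=1e-8)

        rev = ExpressionMatrix(rtk_block.gene_ids[::-1], rtk_block.sample_ids,
                               rtk_block.values[::-1])
        reordered = {r.gene: r.score for r in compute_scores(
            fit_rtk_models(hdac_block, rev, cfg), panel, rev)}
        for g in base:
            assert reordered[g] == pytest.approx(base[g], rel=1e-8)

    def test_score_and_score_i_rankings_agree_on_planted_set(self, small_cohort_blocks):
        """Dependencies planted only on SCORE I HDACs (1/2/3/8): both
        statistics pick out the same planted genes."""
        hdac_block, rtk_block, panel, truth = small_cohort_blocks
        models = fit_rtk_models(hdac_block, rtk_block, CVConfig(penalties=(0.05, 0.5)))
        recs = compute_scores(models, panel, rtk_block)
        n = len(truth.planted)
        assert set(top_k(recs, k=n, by="score")) == set(top_k(recs, k=n, by="score_i"))

    def test_label_permutation_collapses_planted_scores(self, small_cohort_blocks):
        """Breaking the HDAC-RTK sample pairing destroys the planted
        association: median planted SCORE drops below 10% of baseline."""
        hdac_block, rtk_block, panel, truth = small_cohort_blocks
        cfg = CVConfig(penalties=(0.05, 0.5))
        base = {r.gene: r.score for r in compute_scores(
            fit_rtk_models(hdac_block, rtk_block, cfg), panel, rtk_block)}
        ratios = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(rtk_block.n_samples)
            shuffled = ExpressionMatrix(rtk_block.gene_ids, rtk_block.sample_ids,
                                        rtk_block.values[:, perm])
            perm_scores = {r.gene: r.score for r in compute_scores(
                fit_rtk_models(hdac_block, shuffled, cfg), panel, shuffled)}
            for g in truth.planted:
                ratios.append(perm_scores[g] / base[g])
        assert np.median(ratios) < 0.10


def test_score_vs_expression_table(small_cohort_blocks):
    hdac_block, rtk_block, panel, truth = small_cohort_blocks
    models = fit_rtk_models(hdac_block, rtk_block, CVConfig(penalties=(0.05, 0.5)))
    recs = compute_scores(models, panel, rtk_block)
    tbl = score_vs_expression(recs)
    assert set(tbl.columns) == {"gene", "mean_expression", "score"}
    assert len(tbl) == rtk_block.n_genes
    # null RTKs are N(8, 1): cohort means within 3 standard errors
    se = 1.0 / np.sqrt(rtk_block.n_samples)
    for g in truth.null_rtks:
        mean = float(tbl.loc[tbl.gene == g, "mean_expression"].iloc[0])
        assert abs(mean - 8.0) < 3 * se


def test_constant_expression_row_mean():
    models = [("KIT", _model_from_std_weights(np.ones(8)))]
    recs = compute_scores(models, GenePanel(rtk_genes=("KIT",)), _expr_for(["KIT"], value=5.0))
    assert recs[0].mean_expression == 5.0


def test_output_frames(small_cohort_blocks):
    hdac_block, rtk_block, panel, _ = small_cohort_blocks
    models = fit_rtk_models(hdac_block, rtk_block, CVConfig(penalties=(0.05, 0.5)))
    recs = compute_scores(models, panel, rtk_block)
    wide = records_to_frame(recs)
    assert {"gene", "SCORE", "SCORE_I", "rank", "mean_expression"} <= set(wide.columns)
    long = records_to_long_frame(recs)
    assert list(long.columns) == ["gene", "hdac", "coefficient"]
    assert len(long) == len(recs) * 8
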