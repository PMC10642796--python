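"""CPM engine: elementary ops against oracles, CV protocols, permutation test."""

import numpy as np
import pytest
from scipy import stats
from sklearn.model_selection import LeaveOneOut
from sklearn.utils.estimator_checks import check_estimator

import rumiconn as rc
from rumiconn.cpm import CPMRegressor, _loocv_core

from conftest import noiseless_single_edge_cohort


class TestEdgeBehaviorCorrelations:
    @pytest.mark.parametrize(
        "edge,scores,exp_r",
        [
            ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
        ],
    )
    def test_perfect_linear_relations(self, edge, scores, exp_r):
        tbl = rc.CohortEdgeTable(
            edges=np.array(edge, float)[:, None], scores=np.array(scores, float)
        )
        sel = rc.edge_behavior_correlations(tbl)
        assert sel.r[0] == pytest.approx(exp_r)
        assert sel.p[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_contrast(self):
        tbl = rc.CohortEdgeTable(
            edges=np.array([1.0, 0.0, 1.0, 0.0])[:, None],
            scores=np.array([2.0, 1.0, 1.0, 2.0]),
        )
        sel = rc.edge_behavior_correlations(tbl)
        assert sel.r[0] == pytest.approx(0.0, abs=1e-12)
        assert sel.p[0] == pytest.approx(1.0)

    def test_constant_edge_gets_r0_p1(self):
        tbl = rc.CohortEdgeTable(
            edges=np.ones((6, 1)), scores=np.arange(6, dtype=float)
        )
        sel = rc.edge_behavior_correlations(tbl)
        assert sel.r[0] == 0.0 and sel.p[0] == 1.0

    def test_zero_score_variance_errors(self):
        tbl = rc.CohortEdgeTable(edges=np.random.rand(5, 3), scores=np.ones(5))
        with pytest.raises(ValueError, match="variance"):
            rc.edge_behavior_correlations(tbl)

    def test_agrees_with_per_edge_pearsonr_loop(self, small_edge_table):
        """Brute-force oracle: scipy.stats.pearsonr per edge column."""
        sel = rc.edge_behavior_correlations(small_edge_table)
        for e in range(0, small_edge_table.n_edges, 7):
            r, p = stats.pearsonr(
                small_edge_table.edges[:, e], small_edge_table.scores
            )
            assert sel.r[e] == pytest.approx(r, abs=1e-12)
            assert sel.p[e] == pytest.approx(p, abs=1e-12)


class TestSelection:
    def test_sign_split(self):
        sel = rc.EdgeSelection(
            r=np.array([0.9, -0.9, 0.1]), p=np.array([0.001, 0.001, 0.8])
        )
        out = rc.select_edges(sel, alpha=0.01)
        assert out.pos_mask.tolist() == [True, False, False]
        assert out.neg_mask.tolist() == [False, True, False]

    def test_alpha_boundary_is_strict(self):
        sel = rc.EdgeSelection(r=np.array([0.5]), p=np.array([0.01]))
        out = rc.select_edges(sel, alpha=0.01)
        assert not out.pos_mask[0]

    def test_all_nonsignificant_is_allowed(self):
        sel = rc.EdgeSelection(r=np.array([0.5, -0.5]), p=np.array([0.5, 0.9]))
        out = rc.select_edges(sel, alpha=0.01)
        assert not out.pos_mask.any() and not out.neg_mask.any()


class TestStrengthAndModel:
    def test_strength_sums(self):
        edges = np.array([[0.2, 0.3, 0.5]])
        assert rc.network_strength(edges, np.array([True] * 3))[0] == pytest.approx(1.0)
        assert rc.network_strength(edges, np.array([False] * 3))[0] == 0.0
        assert rc.network_strength(edges, np.array([False, False, True]))[0] == 0.5

    @pytest.mark.parametrize(
        "strengths,scores,exp_int,exp_slope",
        [
            ([1, 2, 3], [2, 4, 6], 0.0, 2.0),
            ([1, 1, 1], [1, 2, 3], 2.0, 0.0),  # degenerate: training mean
        ],
    )
    def test_ols_examples(self, strengths, scores, exp_int, exp_slope):
        model = rc.fit_strength_model(np.array(strengths, float), np.array(scores, float))
        assert model.intercept == pytest.approx(exp_int, abs=1e-12)
        assert model.slope == pytest.approx(exp_slope, abs=1e-12)

    def test_degenerate_flag_set(self):
        model = rc.fit_strength_model(np.ones(4), np.arange(4, dtype=float))
        assert model.degenerate

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            rc.fit_strength_model(np.ones(4), np.ones(3))

    def test_agrees_with_closed_form_on_random_instances(self):
        """Oracle: slope = cov/var, intercept = ybar - slope*xbar."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(3, 40)
            s = rng.normal(size=n)
            y = rng.normal(size=n)
            model = rc.fit_strength_model(s, y)
            slope = np.cov(s, y, ddof=1)[0, 1] / np.var(s, ddof=1)
            assert model.slope == pytest.approx(slope, abs=1e-12)
            assert model.intercept == pytest.approx(
                y.mean() - slope * s.mean(), abs=1e-12
            )

    def test_predict(self):
        model = rc.CPMModel(intercept=0.0, slope=2.0, sign="positive",
                            edge_mask=np.zeros(1, bool))
        assert rc.predict_scores(model, np.array([4.0]))[0] == 8.0
        assert rc.predict_scores(model, np.array([])).size == 0


class TestEvaluatePrediction:
    def test_identity_and_affine_invariance(self):
        obs = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert rc.evaluate_prediction(obs, obs).r == pytest.approx(1.0)
        assert rc.evaluate_prediction(3 * obs + 1, obs).r == pytest.approx(1.0)

    def test_partial_correlation_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        n = 40
        cov = rng.normal(size=(n, 2))
        pred = rng.normal(size=n) + cov @ [0.5, -0.3]
        obs = rng.normal(size=n) + cov @ [0.2, 0.4] + 0.5 * pred
        score = rc.evaluate_prediction(pred, obs, covariates=cov)
        df = pd.DataFrame({"pred": pred, "obs": obs, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pingouin.partial_corr(df, x="pred", y="obs", covar=["c1", "c2"])
        assert score.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert score.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_degenerate_residuals_return_zero(self):
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        score = rc.evaluate_prediction(c, c, covariates=c)
        assert score.r == 0.0 and score.degenerate

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            rc.evaluate_prediction(np.ones(4), np.ones(5))


class TestCPMRegressor:
    def test_sklearn_estimator_contract(self):
        # run the subset of sklearn's checks compatible with the >=4-subject
        # and non-constant-score requirements
        est = CPMRegressor(alpha=0.5, sign="positive")
        from sklearn.base import clone

        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_recovers_planted_edge(self):
        tbl = noiseless_single_edge_cohort()
        est = CPMRegressor(alpha=0.01, sign="positive").fit(tbl.edges, tbl.scores)
        assert est.edge_mask_[0] and est.edge_mask_.sum() == 1
        np.testing.assert_allclose(est.predict(tbl.edges), tbl.scores, atol=1e-9)

    def test_degenerate_fit_predicts_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        est = CPMRegressor(alpha=1e-9, sign="negative").fit(X, y)
        assert est.degenerate_
        np.testing.assert_allclose(est.predict(X), np.full(20, y.mean()))


class TestLOOCV:
    def test_prediction_count_and_consensus_subset(self, small_edge_table):
        results = rc.run_loocv(small_edge_table)
        for res in results.values():
            assert res.predicted.shape == (small_edge_table.n_subjects,)
            # consensus is the intersection of every per-iteration mask
            np.testing.assert_array_equal(
                res.consensus_mask, res.iteration_masks.all(axis=0)
            )
            assert np.all(~res.consensus_mask | res.iteration_masks.all(axis=0))

    def test_matches_naive_estimator_loop(self, small_edge_table):
        """Oracle: refit CPMRegressor on every sklearn LeaveOneOut split."""
        edges, scores = small_edge_table.edges, small_edge_table.scores
        core = _loocv_core(edges, scores, 0.01, want_masks=True)
        for sign in ("positive", "negative"):
            pred = np.empty(len(scores))
            for i, (tr, te) in enumerate(LeaveOneOut().split(edges)):
                est = CPMRegressor(alpha=0.01, sign=sign).fit(edges[tr], scores[tr])
                pred[te] = est.predict(edges[te])
            np.testing.assert_allclose(core[sign]["predicted"], pred, atol=1e-10)

    def test_noiseless_cohort_predicts_perfectly(self):
        tbl = noiseless_single_edge_cohort()
        res = rc.run_loocv(tbl)["positive"]
        assert res.r_pred > 0.99

    def test_too_few_subjects(self):
        tbl = rc.CohortEdgeTable(edges=np.random.rand(5, 3), scores=np.arange(5.0))
        with pytest.raises(ValueError, match="at least 10"):
            rc.run_loocv(tbl)

    def test_null_cohort_completes_with_degenerate_folds(self):
        c = rc.generate_null_cohort(n_subjects=30, n_rois=8, planted_edges=2, seed=4)
        tbl = rc.CohortEdgeTable.from_matrices(c.fc, c.table)
        results = rc.run_loocv(tbl)
        for res in results.values():
            assert res.predicted.shape == (30,)
            assert np.all(np.isfinite(res.predicted))


class TestKFold:
    def test_fold_sizes_near_equal(self):
        # 25 subjects in 10 folds -> five folds of 3 and five of 2
        sizes = sorted(len(f) for f in np.array_split(np.arange(25), 10))
        assert sizes == [2, 2, 2, 2, 2, 3, 3, 3, 3, 3]

    def test_same_seed_reproduces(self, small_edge_table):
        a = rc.run_kfold(small_edge_table, k=5, repeats=3, seed=9)
        b = rc.run_kfold(small_edge_table, k=5, repeats=3, seed=9)
        for sign in a:
            assert a[sign].r_pred == b[sign].r_pred
            np.testing.assert_array_equal(a[sign].predicted, b[sign].predicted)

    def test_noiseless_cohort_mean_r_above_099(self):
        tbl = noiseless_single_edge_cohort()
        res = rc.run_kfold(tbl, k=10, repeats=5, seed=1)["positive"]
        assert res.r_pred > 0.99

    def test_k_larger_than_n_errors(self):
        tbl = rc.CohortEdgeTable(edges=np.random.rand(5, 3), scores=np.arange(5.0))
        with pytest.raises(ValueError, match="exceeds"):
            rc.run_kfold(tbl, k=10, repeats=1, seed=0)

    def test_consensus_intersects_every_fold(self, small_edge_table):
        res = rc.run_kfold(small_edge_table, k=5, repeats=4, seed=2)
        for sign in res:
            np.testing.assert_array_equal(
                res[sign].consensus_mask, res[sign].iteration_masks.all(axis=0)
            )


class TestPermutation:
    def test_p_formula_boundaries(self):
        # observed above every null value -> p = 0; below every one -> p = 1
        null = np.array([0.1, 0.2, 0.3])
        assert (null > 0.9).sum() / 3 == 0.0
        assert (null > -0.9).sum() / 3 == 1.0

    def test_planted_effect_detected(self):
        c = rc.generate_cohort(n_subjects=80, n_rois=10, planted_edges=4, seed=6)
        tbl = rc.CohortEdgeTable.from_matrices(c.fc, c.table)
        perm = rc.permutation_test(tbl, cv="loocv", n_perm=50, seed=6)
        assert perm["negative"].observed_r > 0
        assert perm["negative"].p_perm < 0.05
        assert perm["negative"].null_r.shape == (50,)

    def test_add_one_variant(self):
        c = rc.generate_cohort(n_subjects=40, n_rois=8, planted_edges=3, seed=8)
        tbl = rc.CohortEdgeTable.from_matrices(c.fc, c.table)
        perm = rc.permutation_test(
            tbl, cv="loocv", n_perm=20, seed=8, counting="add_one"
        )
        for res in perm.values():
            assert 0 < res.p_perm <= 1.0

    def test_nperm_validation(self, small_edge_table):
        with pytest.raises(ValueError, match="n_perm"):
            rc.permutation_test(small_edge_table, n_perm=0, seed=0)
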