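"""Stratified split plans, the AUC matrix, selection and nested validation."""

import numpy as np
import pandas as pd
import pytest

import rbcscore as rs
from rbcscore.resampling import AUCMatrix, _inner_seed

from conftest import make_cohort


def _cohort_with_event_counts(n_events, n_nonevents, seed=0):
    cfg = rs.default_config(n=n_events + n_nonevents, seed=seed)
    cfg.missingness = {}
    cohort = rs.generate(cfg)
    rng = np.random.default_rng(seed)
    y = np.zeros(cohort.n, dtype=int)
    y[rng.choice(cohort.n, size=n_events, replace=False)] = 1
    df = cohort.data.copy()
    df["transfused"] = pd.Categorical(np.where(y == 1, "yes", "no"),
                                      categories=("no", "yes"))
    return rs.Cohort(df, name="fixed-events")


class TestSplitPlan:
    def test_study_class_counts_give_49_events_153_nonevents_in_training(self):
        cohort = _cohort_with_event_counts(61, 191)
        plan = rs.make_split_plan(cohort, J=10, train_fraction=0.8, seed=1)
        for tr, te in plan.splits:
            y_tr, y_te = cohort.y[tr], cohort.y[te]
            assert (y_tr.sum(), (1 - y_tr).sum()) == (49, 153)
            assert (y_te.sum(), (1 - y_te).sum()) == (12, 38)
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 252

    def test_same_seed_reproduces_the_split(self):
        cohort = _cohort_with_event_counts(20, 60)
        a = rs.make_split_plan(cohort, J=1, train_fraction=0.8, seed=9)
        b = rs.make_split_plan(cohort, J=1, train_fraction=0.8, seed=9)
        assert all(
            np.array_equal(x, y)
            for (x1, y1), (x2, y2) in zip(a.splits, b.splits)
            for x, y in ((x1, x2), (y1, y2))
        )

    def test_four_record_balanced_toy_stratifies_both_halves(self):
        cohort = make_cohort(
            [{"transfused": t} for t in ("yes", "no", "yes", "no")]
        )
        plan = rs.make_split_plan(cohort, J=5, train_fraction=0.5, seed=2)
        for tr, te in plan.splits:
            assert cohort.y[tr].sum() == 1 and cohort.y[te].sum() == 1

    def test_class_too_small_to_split_is_an_error(self):
        cohort = make_cohort(
            [{"transfused": "yes"}] + [{"transfused": "no"}] * 9
        )
        with pytest.raises(rs.SelectionError):
            rs.make_split_plan(cohort, J=2, train_fraction=0.8, seed=0)


class TestEvaluateModels:
    def test_null_model_scores_half_on_every_split(self):
        cohort = _cohort_with_event_counts(20, 60, seed=3)
        space = rs.enumerate_models(["hb"], 1)
        plan = rs.make_split_plan(cohort, J=4, train_fraction=0.8, seed=3)
        matrix = rs.evaluate_models(cohort, space, plan)
        null_idx = next(i for i, m in enumerate(space) if m.size == 0)
        assert np.allclose(matrix.values[:, null_idx], 0.5)

    def test_deterministic_predictor_attains_auc_one(self):
        cfg = rs.default_config(n=120, seed=6)
        cfg.missingness = {}
        cohort = rs.generate(cfg)
        df = cohort.data.copy()
        df["transfused"] = pd.Categorical(
            np.where(df["hb"] < df["hb"].median(), "yes", "no"),
            categories=("no", "yes"),
        )
        cohort = rs.Cohort(df)
        space = rs.enumerate_models(["hb"], 1)
        plan = rs.make_split_plan(cohort, J=5, train_fraction=0.8, seed=6)
        matrix = rs.evaluate_models(cohort, space, plan)
        hb_idx = next(i for i, m in enumerate(space) if m.predictors == ("hb",))
        assert np.allclose(matrix.values[:, hb_idx], 1.0)

    def test_matrix_matches_independent_statsmodels_oracle(self):
        """Every (split, model) AUC equals one computed by a straightforward
        statsmodels-based reimplementation on the same splits."""
        sm = pytest.importorskip("statsmodels.api")
        cohort = _cohort_with_event_counts(16, 24, seed=8)
        space = rs.enumerate_models(["hb", "age"], 2)  # null, hb, age, hb+age
        plan = rs.make_split_plan(cohort, J=3, train_fraction=0.8, seed=8)
        matrix = rs.evaluate_models(cohort, space, plan)
        y_all = cohort.y.astype(float)
        for m_idx, model in enumerate(space):
            cols = list(model.predictors)
            X_all = cohort.data[cols].to_numpy(dtype=float) if cols else np.empty((cohort.n, 0))
            for j, (tr, te) in enumerate(plan.splits):
                Xi = sm.add_constant(X_all, has_constant="add")
                res = sm.Logit(y_all[tr], Xi[tr]).fit(disp=0, method="newton", tol=1e-10)
                eta = Xi[te] @ res.params
                from conftest import auc_pair_counting
                expected = auc_pair_counting(eta, cohort.y[te])
                assert matrix.values[j, m_idx] == pytest.approx(expected, abs=1e-6)

    def test_values_lie_in_unit_interval_and_flags_are_closed_set(self):
        cohort = _cohort_with_event_counts(15, 45, seed=9)
        space = rs.enumerate_models(["hb", "vbr", "stages"], 2)
        plan = rs.make_split_plan(cohort, J=6, train_fraction=0.8, seed=9)
        matrix = rs.evaluate_models(cohort, space, plan)
        vals = matrix.values[~np.isnan(matrix.values)]
        assert ((vals >= 0) & (vals <= 1)).all()
        assert set(matrix.reasons.values()) <= set(rs.resampling.FLAG_REASONS)


class TestSelectBest:
    def _matrix(self, columns, labels):
        values = np.array(columns, dtype=float).T
        return AUCMatrix(values=values, reasons={}, model_labels=tuple(labels))

    def _space(self, *preds):
        return rs.CandidateModelSpace(
            models=[rs.CandidateModel(p) for p in preds],
            k_max=2,
            predictor_pool=("a", "b"),
        )

    def test_higher_mean_wins_over_higher_max(self):
        space = self._space(("a",), ("b",))
        matrix = self._matrix([[0.9, 0.9], [0.95, 0.80]], ["a", "b"])
        sel = rs.select_best(matrix, space)
        assert sel.best_model.predictors == ("a",)
        assert sel.mean_auc == pytest.approx(0.90)
        assert (sel.min_auc, sel.max_auc) == (0.9, 0.9)

    def test_exact_tie_prefers_fewer_predictors(self):
        space = self._space(("a", "b"), ("a",))
        matrix = self._matrix([[0.8, 0.9], [0.8, 0.9]], ["a+b", "a"])
        sel = rs.select_best(matrix, space)
        assert sel.best_model.predictors == ("a",)
        assert sorted(sel.ties) == [0, 1]

    def test_mostly_flagged_model_is_disqualified(self):
        space = self._space((), ("a",))
        values = np.array([[0.6, np.nan], [0.6, np.nan], [0.6, 0.99]])
        matrix = AUCMatrix(values=values, reasons={}, model_labels=("<null>", "a"))
        sel = rs.select_best(matrix, space)
        assert sel.best_model.predictors == ()
        assert sel.disqualified == [1]

    def test_no_valid_entries_is_an_error(self):
        space = self._space(("a",))
        matrix = AUCMatrix(values=np.full((2, 1), np.nan), reasons={},
                           model_labels=("a",))
        with pytest.raises(rs.SelectionError):
            rs.select_best(matrix, space)

    def test_selection_invariant_under_model_permutation(self):
        cohort = _cohort_with_event_counts(20, 60, seed=12)
        space = rs.enumerate_models(["hb", "age", "sex"], 2)
        plan = rs.make_split_plan(cohort, J=5, train_fraction=0.8, seed=12)
        matrix = rs.evaluate_models(cohort, space, plan)
        sel = rs.select_best(matrix, space)
        perm = list(reversed(range(len(space))))
        space_p = rs.CandidateModelSpace(
            models=[space.models[i] for i in perm],
            k_max=space.k_max,
            predictor_pool=space.predictor_pool,
        )
        matrix_p = AUCMatrix(values=matrix.values[:, perm], reasons={},
                             model_labels=tuple(matrix.model_labels[i] for i in perm))
        sel_p = rs.select_best(matrix_p, space_p)
        assert sel_p.best_model.predictors == sel.best_model.predictors


class TestPipeline:
    def test_full_selection_is_bit_reproducible(self):
        cohort = _cohort_with_event_counts(25, 75, seed=14)
        space = rs.enumerate_models(["hb", "age", "vbr"], 2)
        a, mat_a = rs.run_selection(cohort, space, J=6, seed=14)
        b, mat_b = rs.run_selection(cohort, space, J=6, seed=14)
        assert a.best_model == b.best_model
        assert a.mean_auc == b.mean_auc
        np.testing.assert_array_equal(mat_a.values, mat_b.values)

    def test_strong_signal_recovers_true_covariates(self):
        cfg = rs.default_config(n=400, seed=21)
        cohort = rs.generate(cfg)
        pool = ["surgery_type", "vbr", "stages", "hb", "sex", "age"]
        space = rs.enumerate_models(pool, 4)
        sel, _ = rs.run_selection(cohort, space, J=8, seed=21)
        overlap = {"surgery_type", "vbr", "stages", "hb"} & set(sel.best_model.predictors)
        assert len(overlap) >= 2

    def test_pre_split_mode_filters_once_on_the_pool(self):
        cfg = rs.default_config(n=300, seed=15)
        cohort = rs.generate(cfg)
        space = rs.enumerate_models(["vbr", "hb"], 1)
        sel, matrix = rs.run_selection(cohort, space, J=4, seed=15,
                                       complete_case_mode="pre_split")
        n_complete = rs.complete_cases(cohort, ["vbr", "hb"]).n
        # with pre-filtering, every model sees the same record count per split
        assert matrix.J == 4
        assert np.isfinite(matrix.values).all()
        assert sel.mean_auc >= 0.0

    def test_nested_with_k1_is_one_selection_on_an_80pct_subsample(self):
        cohort = _cohort_with_event_counts(25, 75, seed=16)
        space = rs.enumerate_models(["hb", "age"], 1)
        nv = rs.nested_validate(cohort, space, K=1, J=5, seed=16)
        outer = rs.make_split_plan(cohort, 1, 0.8, 16)
        sub = cohort.subset(outer.splits[0][0])
        sel, _ = rs.run_selection(sub, space, J=5, seed=_inner_seed(16, 0))
        assert nv.selected_models[0] == sel.best_model
        assert nv.inner_mean_auc[0] == pytest.approx(sel.mean_auc)
        assert nv.auc_values.shape == (1,)

    def test_nested_summary_is_consistent_with_stored_values(self):
        cohort = _cohort_with_event_counts(30, 90, seed=18)
        space = rs.enumerate_models(["hb", "age"], 1)
        nv = rs.nested_validate(cohort, space, K=4, J=4, seed=18)
        assert nv.mean_auc == pytest.approx(float(nv.auc_values.mean()))
        assert nv.min_auc <= nv.mean_auc <= nv.max_auc
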