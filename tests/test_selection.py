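"""Subset enumeration, CV plans, nested CV, selection rules, enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ernapredict.selection import (SelectionReport, SubsetResult,
                                   compare_m_performance, enumerate_subsets,
                                   make_cv_plan, mark_enrichment,
                                   nested_cv_evaluate, rank_results,
                                   select_top_models)


class TestEnumerate:
    def test_counts(self):
        marks = ["a", "b", "c", "d"]
        assert len(enumerate_subsets(marks, 2)) == 6
        assert enumerate_subsets(marks, 4) == [("a", "b", "c", "d")]

    def test_lexicographic_order(self):
        subs = enumerate_subsets(["a", "b", "c"], 2)
        assert subs == [("a", "b"), ("a", "c"), ("b", "c")]

    @pytest.mark.parametrize("m", [0, 5])
    def test_out_of_range_rejected(self, m):
        with pytest.raises(ValueError):
            enumerate_subsets(["a", "b", "c", "d"], m)


class TestCvPlan:
    def _labels(self, n_pos, n_neg):
        ids = [f"e{i}" for i in range(n_pos + n_neg)]
        return pd.Series([1] * n_pos + [0] * n_neg, index=ids)

    def test_equal_fold_sizes(self):
        plan = make_cv_plan(self._labels(50, 50), k=10, seed=0)
        assert sorted(len(f) for f in plan.folds) == [10] * 10

    def test_stratification_under_imbalance(self):
        plan = make_cv_plan(self._labels(80, 20), k=10, seed=1)
        y = self._labels(80, 20)
        for fold in plan.folds:
            n_pos = int(y.loc[fold].sum())
            assert 7 <= n_pos <= 9 and 1 <= len(fold) - n_pos <= 3

    def test_deterministic_under_seed(self):
        a = make_cv_plan(self._labels(30, 30), k=5, seed=7)
        b = make_cv_plan(self._labels(30, 30), k=5, seed=7)
        assert a.folds == b.folds
        c = make_cv_plan(self._labels(30, 30), k=5, seed=8)
        assert a.folds != c.folds

    def test_folds_partition_the_labeled_set(self):
        labels = self._labels(33, 27)
        plan = make_cv_plan(labels, k=7, seed=2)
        assert sorted(plan.ids) == sorted(labels.index)


class TestNestedCv:
    def test_single_subset_reduces_to_plain_kfold(self, small_data):
        from ernapredict.logit import fit_logistic, predict_proba
        from ernapredict.metrics import auc_score
        signal, labels = small_data.signal, small_data.labels
        sub = ("H3K27ac", "H3K27me3")
        plan = make_cv_plan(labels, k=5, inner_k=3, seed=3)
        res = nested_cv_evaluate(signal, labels, [sub], plan, top_n_inner=1)[0]
        # plain K-fold with the same folds must give identical outer AUCs
        y = labels.binary()
        for f in range(plan.k):
            test_ids = plan.folds[f]
            train_ids = [i for g in range(plan.k) if g != f
                         for i in plan.folds[g]]
            model = fit_logistic(signal, y.loc[train_ids], list(sub))
            p = predict_proba(model, signal.subset_rows(test_ids))
            assert res.fold_aucs[f] == pytest.approx(
                auc_score(y.loc[test_ids], p), abs=1e-12)

    def test_deterministic_under_seed(self, small_data):
        signal, labels = small_data.signal, small_data.labels
        subs = enumerate_subsets(["H3K27ac", "H3K9ac", "H3K27me3"], 2)
        plan = make_cv_plan(labels, k=4, inner_k=3, seed=5)
        r1 = nested_cv_evaluate(signal, labels, subs, plan, top_n_inner=2)
        r2 = nested_cv_evaluate(signal, labels, subs, plan, top_n_inner=2)
        assert [(r.subset, r.fold_aucs) for r in r1] == \
               [(r.subset, r.fold_aucs) for r in r2]

    def test_nested_estimate_not_optimistic(self, small_data):
        # nested-CV outer AUC must not exceed the resubstitution AUC by
        # more than small-sample noise
        from ernapredict.logit import fit_logistic, predict_proba
        from ernapredict.metrics import auc_score
        signal, labels = small_data.signal, small_data.labels
        sub = ("H3K27ac", "H3K9ac", "H3K27me3")
        plan = make_cv_plan(labels, k=5, inner_k=3, seed=6)
        res = nested_cv_evaluate(signal, labels, [sub], plan, top_n_inner=1)[0]
        model = fit_logistic(signal, labels, list(sub))
        p = predict_proba(model, signal.subset_rows(labels.training_ids))
        full_auc = auc_score(labels.binary(), p)
        assert res.mean_auc <= full_auc + 0.02

    def test_unknown_mark_rejected(self, small_data):
        plan = make_cv_plan(small_data.labels, k=3, inner_k=2, seed=0)
        with pytest.raises(ValueError, match="nope"):
            nested_cv_evaluate(small_data.signal, small_data.labels,
                               [("nope",)], plan)


def _fake_results(n, seed=0):
    """n fake subset results with AUC and MCC rankings aligned."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = 0.95 - i * 0.002
        aucs = {f: base + rng.normal(0, 1e-6) for f in range(5)}
        mccs = {f: base - 0.3 for f in range(5)}
        out.append(SubsetResult((f"m{i:03d}",), aucs, mccs))
    return out


class TestSelectTopModels:
    def test_aligned_rankings_select_exact_fraction(self):
        rep = select_top_models(_fake_results(100), "top_fraction",
                                top_fraction=0.05)
        assert len(rep.selected) == 5
        assert rep.selected[0] == ("m000",)

    def test_disjoint_rankings_select_nothing(self):
        results = _fake_results(40)
        # invert MCC ranking so top-5% sets are disjoint
        for i, r in enumerate(results):
            r.fold_mccs = {f: 0.1 + i * 0.01 for f in range(5)}
        rep = select_top_models(results, "top_fraction", top_fraction=0.05)
        assert rep.selected == []

    def test_relative_rule_arithmetic(self):
        r = SubsetResult(("x",), {0: 0.86}, {0: 0.58})
        rep = select_top_models([r], "relative", full_auc=0.90, full_mcc=0.60)
        assert rep.selected == [("x",)]          # 0.86>=0.855 and 0.58>=0.57
        r2 = SubsetResult(("y",), {0: 0.85}, {0: 0.58})
        rep2 = select_top_models([r2], "relative", full_auc=0.90,
                                 full_mcc=0.60)
        assert rep2.selected == []

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            select_top_models(_fake_results(5), "best_ever")


class TestEnrichment:
    def _report(self, selected):
        return SelectionReport([], selected, "manual")

    def test_mark_in_every_subset_gives_p_one(self):
        all_subs = [("a", "b"), ("a", "c"), ("a", "d")]
        rep = self._report([("a", "b")])
        assert mark_enrichment(rep, all_subs, "a") == pytest.approx(1.0)

    def test_hand_computed_hypergeometric(self):
        # N=10 subsets, 5 contain the mark, 4 selected all containing it:
        # p = C(5,4)C(5,0)/C(10,4) = 5/210
        all_subs = [(f"x{i}", "M") for i in range(5)] + \
                   [(f"x{i}", "y") for i in range(5, 10)]
        rep = self._report(all_subs[:4])
        assert mark_enrichment(rep, all_subs, "M") == pytest.approx(5 / 210)

    def test_absent_mark_rejected(self):
        rep = self._report([("a",)])
        with pytest.raises(ValueError):
            mark_enrichment(rep, [("a",), ("b",)], "z")

    def test_matches_exhaustive_enumeration(self):
        # oracle: enumerate all C(N, n) equally likely selections
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_pop = int(rng.integers(3, 13))
            k_pop = int(rng.integers(1, n_pop + 1))
            n_sel = int(rng.integers(1, n_pop + 1))
            pop = [(f"s{i}", "M" if i < k_pop else "o") for i in range(n_pop)]
            chosen = [pop[i] for i in
                      rng.choice(n_pop, size=n_sel, replace=False)]
            k_obs = sum("M" in s for s in chosen)
            tail = sum(
                1 for combo in itertools.combinations(range(n_pop), n_sel)
                if sum(1 for i in combo if i < k_pop) >= k_obs)
            expected = tail / comb(n_pop, n_sel)
            rep = self._report(chosen)
            assert mark_enrichment(rep, pop, "M") == pytest.approx(
                expected, abs=1e-12)


class TestCompareM:
    def _res(self, scores):
        return [SubsetResult(("s",), dict(enumerate(scores)),
                             dict(enumerate(scores)))]

    def test_identical_scores_give_p_one(self):
        scores = [0.9, 0.8, 0.85]
        assert compare_m_performance(self._res(scores),
                                     self._res(scores)) == 1.0

    def test_uniform_improvement_exact_tail(self):
        a = [0.80 + 0.001 * i for i in range(10)]
        b = [x + 0.05 + 0.001 * i for i, x in enumerate(a)]   # all greater
        p = compare_m_performance(self._res(a), self._res(b))
        assert p == pytest.approx(2 / 1024, rel=1e-9)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            compare_m_performance(self._res([0.9]), self._res([0.95]))

    def test_mismatched_folds_rejected(self):
        a = [SubsetResult(("s",), {0: 0.9, 1: 0.8}, {0: 0.5, 1: 0.4})]
        b = [SubsetResult(("s",), {0: 0.9, 2: 0.8}, {0: 0.5, 2: 0.4})]
        with pytest.raises(ValueError):
            compare_m_performance(a, b)


def test_rank_results_deterministic_tiebreak():
    r1 = SubsetResult(("b",), {0: 0.9}, {0: 0.5})
    r2 = SubsetResult(("a",), {0: 0.9}, {0: 0.5})
    assert [r.subset for r in rank_results([r1, r2])] == [("a",), ("b",)]
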