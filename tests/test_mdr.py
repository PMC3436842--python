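"""Cox-MDR engine: cells, classification, balanced accuracy, CV, search."""

import itertools

import numpy as np
import pytest

from coxmdr.mdr import (
    CoxMDR,
    assign_cells,
    balanced_accuracy,
    classify_cells,
    evaluate_combo,
    fold_assignments,
    permutation_pvalue,
    search_best,
)
from coxmdr.survival import DegenerateDataError, fit_cox_null

from conftest import make_cohort, random_cohort


# ----------------------------------------------------------------------
# Straight-line oracle: literal re-implementation of the CV evaluation,
# sharing only the fold splits with the engine under test.


def literal_mean_test_ba(cohort, combo, folds, repeats, seed):
    nf = fit_cox_null(cohort)
    res = nf.residuals
    case = res > 0
    fold_ids = fold_assignments(cohort.n, folds, repeats, seed,
                                stratify=cohort.status)
    k = len(combo)
    bas = []
    for r in range(repeats):
        for f in range(folds):
            te = fold_ids[r] == f
            tr = ~te
            sums = {}
            for i in np.flatnonzero(tr):
                cell = sum(int(cohort.genotypes[i, s]) * 3**j
                           for j, s in enumerate(combo))
                sums[cell] = sums.get(cell, 0.0) + res[i]
            tp = fn = tn = fp = 0
            for i in np.flatnonzero(te):
                cell = sum(int(cohort.genotypes[i, s]) * 3**j
                           for j, s in enumerate(combo))
                high = sums.get(cell, -1.0) >= 0  # absent cell -> low
                if case[i] and high:
                    tp += 1
                elif case[i]:
                    fn += 1
                elif high:
                    fp += 1
                else:
                    tn += 1
            sens = tp / (tp + fn) if tp + fn else 0.0
            spec = tn / (tn + fp) if tn + fp else 0.0
            if tp + fn + tn + fp:
                bas.append(0.5 * (sens + spec))
            else:
                bas.append(np.nan)
    return float(np.nanmean(bas))


class TestCells:
    def test_encoding_endpoints(self):
        G = np.array([[0, 0], [2, 2], [1, 2]])
        cells = assign_cells(G, (0, 1))
        assert cells.tolist() == [0, 8, 7]

    def test_two_snps_give_nine_cells(self, rng):
        G = rng.choice(3, size=(200, 2))
        cells = assign_cells(G, (0, 1))
        assert set(cells) <= set(range(9))
        labels, _, _ = classify_cells(rng.normal(size=200), cells, 2)
        assert labels.shape == (9,)

    def test_missing_genotype_marks_subject(self):
        G = np.array([[0, -1], [1, 1]])
        assert assign_cells(G, (0, 1)).tolist() == [-1, 4]

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            assign_cells(np.zeros((2, 2), int), (1, 1))


class TestClassify:
    def test_sign_of_sum(self):
        labels, _, _ = classify_cells([0.5, -0.2], [0, 0], 1)
        assert labels[0]

    def test_zero_sum_is_high(self):
        labels, _, _ = classify_cells([0.5, -0.5], [2, 2], 1)
        assert labels[2]

    def test_empty_cell_is_low(self):
        labels, _, _ = classify_cells([1.0], [0], 1)
        assert not labels[1] and not labels[2]


class TestBalancedAccuracy:
    def test_worked_confusion_table(self):
        # TP=4, FN=1, TN=3, FP=2 -> (0.8 + 0.6) / 2
        pred = [True] * 4 + [False] * 1 + [False] * 3 + [True] * 2
        case = [True] * 5 + [False] * 5
        assert balanced_accuracy(pred, case) == pytest.approx(0.7)

    def test_perfect_prediction(self):
        case = np.array([True, False, True])
        assert balanced_accuracy(case, case) == 1.0

    def test_constant_predictor_is_half(self):
        case = np.array([True, False, True, False])
        assert balanced_accuracy(np.ones(4, bool), case) == 0.5

    def test_label_flip_complements(self, rng):
        pred = rng.random(50) < 0.4
        case = rng.random(50) < 0.5
        ba = balanced_accuracy(pred, case)
        assert balanced_accuracy(~pred, case) == pytest.approx(1 - ba)

    def test_absent_class_flagged(self):
        ba, flag = balanced_accuracy([True, False], [True, True],
                                     return_flag=True)
        assert flag and ba == 0.25  # (sens 0.5 + absent-class term 0) / 2

    def test_no_subjects_fails(self):
        with pytest.raises(DegenerateDataError):
            balanced_accuracy([], [])


class TestEvaluateCombo:
    def test_seeded_reproducibility(self, rng):
        co = random_cohort(rng, n=30, M=3)
        a = evaluate_combo(co, (0, 1), folds=3, repeats=2, seed=5)
        b = evaluate_combo(co, (0, 1), folds=3, repeats=2, seed=5)
        assert a.mean_test_ba == b.mean_test_ba
        np.testing.assert_array_equal(a.test_ba, b.test_ba)

    def test_leave_one_out_ignores_seed(self, rng):
        co = random_cohort(rng, n=12, M=3)
        a = evaluate_combo(co, (0, 1), folds=12, repeats=1, seed=1)
        b = evaluate_combo(co, (0, 1), folds=12, repeats=1, seed=99)
        assert a.mean_test_ba == pytest.approx(b.mean_test_ba)

    def test_matches_straight_line_oracle(self, rng):
        co = random_cohort(rng, n=12, M=3)
        ev = evaluate_combo(co, (0, 2), folds=2, repeats=1, seed=7)
        oracle = literal_mean_test_ba(co, (0, 2), 2, 1, 7)
        assert ev.mean_test_ba == pytest.approx(oracle)

    def test_two_fold_hundred_repeats_supported(self, rng):
        co = random_cohort(rng, n=24, M=2)
        ev = evaluate_combo(co, (0, 1), folds=2, repeats=100, seed=3)
        assert ev.test_ba.shape == (100, 2)


class TestSearch:
    def test_single_candidate(self, rng):
        co = random_cohort(rng, n=20, M=2)
        ranked = search_best(co, k=2, folds=2, repeats=1, seed=0)
        assert len(ranked) == 1
        assert ranked[0][0].snp_indices == (0, 1)

    def test_matches_exhaustive_literal_oracle(self, rng):
        co = random_cohort(rng, n=20, M=4)
        ranked = search_best(co, k=2, folds=4, repeats=2, seed=11)
        oracle = []
        for combo in itertools.combinations(range(4), 2):
            oracle.append((combo, literal_mean_test_ba(co, combo, 4, 2, 11)))
        # engine's ranking must agree with the independent scores
        for attr, ev in ranked:
            lit = dict(oracle)[attr.snp_indices]
            assert ev.mean_test_ba == pytest.approx(lit)
        best_lit = max(oracle, key=lambda t: t[1])
        assert ranked[0][1].mean_test_ba == pytest.approx(best_lit[1])

    def test_invariant_to_column_permutation(self, rng):
        co = random_cohort(rng, n=30, M=4)
        perm = [2, 0, 3, 1]
        co2 = make_cohort(co.time, co.status, co.covariates,
                          co.genotypes[:, perm])
        r1 = search_best(co, k=2, folds=3, repeats=2, seed=4)
        r2 = search_best(co2, k=2, folds=3, repeats=2, seed=4)
        remap = {old: new for new, old in enumerate(perm)}
        seen1 = {tuple(sorted(remap[j] for j in a.snp_indices)):
                 ev.mean_test_ba for a, ev in r1}
        seen2 = {tuple(sorted(a.snp_indices)): ev.mean_test_ba for a, ev in r2}
        assert seen1 == pytest.approx(seen2)

    def test_too_few_snps_fails(self, rng):
        with pytest.raises(ValueError):
            search_best(random_cohort(rng, n=20, M=1), k=2)

    def test_candidate_cap_enforced(self, rng):
        with pytest.raises(ValueError):
            search_best(random_cohort(rng, n=20, M=4), k=2, max_candidates=2)


class TestPerFoldResiduals:
    def test_sensitivity_mode_runs_and_differs(self, rng):
        co = random_cohort(rng, n=40, M=3, q=1)
        a = evaluate_combo(co, (0, 1), folds=4, repeats=1, seed=2,
                           per_fold_residuals=False)
        b = evaluate_combo(co, (0, 1), folds=4, repeats=1, seed=2,
                           per_fold_residuals=True)
        assert np.isfinite(b.mean_test_ba)
        # same fold geometry either way
        assert a.test_ba.shape == b.test_ba.shape


class TestPermutation:
    def test_pvalue_bounds_and_determinism(self, rng):
        co = random_cohort(rng, n=40, M=3)
        r1 = permutation_pvalue(co, (0, 1), B=49, seed=3)
        r2 = permutation_pvalue(co, (0, 1), B=49, seed=3)
        assert r1.p_value == r2.p_value
        assert 1 / 50 <= r1.p_value <= 1.0

    def test_degenerate_attribute_reports_one(self, rng):
        # all subjects in one genotype cell -> constant attribute
        co = random_cohort(rng, n=20, M=2)
        co.genotypes[:] = 1
        r = permutation_pvalue(co, (0, 1), B=19, seed=0)
        assert r.degenerate and r.p_value == 1.0


class TestModelFrontend:
    def test_fit_returns_ranking_and_summary(self, rng):
        co = random_cohort(rng, n=40, M=4, q=1)
        res = CoxMDR(co, k=2, covariates="all").fit(folds=4, repeats=2, seed=1)
        df = res.ranking()
        assert list(df.columns) == ["rank", "snps", "train_ba", "test_ba",
                                    "cv_consistency"]
        assert len(df) == 6
        assert (df["test_ba"].values[:-1] >= df["test_ba"].values[1:] - 1e-12).all()
        text = res.summary(3)
        assert "Cox-MDR" in text and "cv_consistency" in text
        high, ok = res.attribute()
        assert high.shape == (co.n,) and ok.all()


class TestFolds:
    def test_stratified_and_balanced(self, rng):
        status = (rng.random(50) < 0.4).astype(int)
        ids = fold_assignments(50, 5, 3, seed=0, stratify=status)
        assert ids.shape == (3, 50)
        for r in range(3):
            sizes = np.bincount(ids[r], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_loo_gives_singleton_folds(self, rng):
        status = (rng.random(12) < 0.5).astype(int)
        ids = fold_assignments(12, 12, 1, seed=3, stratify=status)
        assert sorted(ids[0]) == list(range(12))
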