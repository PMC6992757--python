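"""Metrics, split protocols, paired t-test and report aggregation."""

import numpy as np
import pytest
from scipy import stats as sps

from vtloc.augment import augment_corpus
from vtloc.evaluation import (DegenerateInputError, DistanceRecord,
                              build_report, euclidean_distance, make_cv_splits,
                              make_loso_splits, outlier_rate, paired_ttest, rmse)


def _records(errors):
    return [DistanceRecord(f"im{i}", "s", "ANS", dx, dy)
            for i, (dx, dy) in enumerate(errors)]


class TestDistances:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=2), rng.normal(size=2)
            assert euclidean_distance(a, a) == 0.0
            assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_rmse_closed_form(self):
        # records with d = 0 and d = 5 -> sqrt((0 + 25)/2)
        recs = _records([(0.0, 0.0), (3.0, 4.0)])
        assert rmse(recs) == pytest.approx(np.sqrt(12.5))

    def test_rmse_zero_for_perfect(self):
        assert rmse(_records([(0, 0)] * 5)) == 0.0

    def test_rmse_matches_brute_force(self):
        rng = np.random.default_rng(1)
        err = rng.normal(size=(50, 2))
        recs = _records(err)
        brute = np.sqrt(np.mean([r.d ** 2 for r in recs]))
        assert rmse(recs) == pytest.approx(brute, abs=1e-12)
        # conservation: rmse^2 * Q equals the sum of squared coordinate errors
        assert rmse(recs) ** 2 * len(recs) == pytest.approx((err ** 2).sum())

    def test_rmse_permutation_invariant(self):
        rng = np.random.default_rng(2)
        err = rng.normal(size=(30, 2))
        assert rmse(_records(err)) == pytest.approx(
            rmse(_records(err[::-1])), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([])
        with pytest.raises(ValueError):
            outlier_rate([])


class TestOutlierRate:
    def test_strict_threshold(self):
        assert outlier_rate([5.1, 4.9, 5.0]) == pytest.approx(100 / 3)

    def test_boundary_and_zeros(self):
        assert outlier_rate([0.0, 0.0, 0.0]) == 0.0
        assert outlier_rate([5.0, 5.0]) == 0.0     # strictly greater than


class TestSplits:
    def test_cv_partition_properties(self, small_corpus):
        aug = augment_corpus(small_corpus, seed=0)   # 66 items
        plan = make_cv_splits(aug, k=10, seed=3)
        assert plan.scheme == "CV10" and len(plan.folds) == 10
        all_test = [k for _, te in plan.folds for k in te]
        assert sorted(all_test) == sorted(it.key for it in aug.items)
        sizes = [len(te) for _, te in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        for tr, te in plan.folds:
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == len(aug)

    def test_cv_requires_k_at_least_two(self, small_corpus):
        aug = augment_corpus(small_corpus, seed=0)
        with pytest.raises(ValueError):
            make_cv_splits(aug, k=1, seed=0)

    def test_loso_subject_disjoint(self, small_corpus):
        aug = augment_corpus(small_corpus, seed=0)
        plan = make_loso_splits(aug, small_corpus)
        subjects = sorted({it.subject_id for it in small_corpus})
        assert len(plan.folds) == len(subjects)
        by_key = {it.key: it for it in aug.items}
        for (tr, te), subj in zip(plan.folds, subjects):
            # test side: only the held-out subject's originals
            assert all(by_key[k].subject_id == subj for k in te)
            assert all(by_key[k].augmentation_tag == "orig" for k in te)
            assert len(te) == 3                       # n_classes originals
            # train side: every item of every other subject
            assert all(by_key[k].subject_id != subj for k in tr)
            assert len(tr) == (len(subjects) - 1) * 3 * 11

    def test_loso_single_subject_rejected(self, small_corpus):
        solo = [it for it in small_corpus if it.subject_id == "S00"]
        aug = augment_corpus(solo, seed=0)
        with pytest.raises(ValueError):
            make_loso_splits(aug, solo)


class TestPairedTTest:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(5, 2, size=40)
        b = a + rng.normal(0.5, 1, size=40)
        t, p = paired_ttest(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), len(d) - 1)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_identical_inputs_degenerate(self):
        a = np.arange(10, dtype=float)
        with pytest.raises(DegenerateInputError):
            paired_ttest(a, a)
        with pytest.raises(DegenerateInputError):
            paired_ttest(a, a + 3.0)    # constant shift: zero variance too

    def test_shifted_with_jitter_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, size=500)
        b = a + 1.0 + rng.normal(0, 0.1, size=500)
        _, p = paired_ttest(a, b)
        assert p < 1e-50

    def test_type_i_error_calibration(self):
        # under the null (equal means), p < 0.05 in about 5% of replicates
        rng = np.random.default_rng(123)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            _, p = paired_ttest(a, b)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.04


class TestBuildReport:
    def test_perfect_predictions_zero_matrices(self, small_corpus):
        preds = {it.key: it.landmarks.copy() for it in small_corpus}
        rep = build_report(small_corpus, preds)
        assert rep.overall_rmse_px == 0.0
        assert rep.overall_outlier_pct == 0.0
        assert (rep.per_landmark["rmse_px"] == 0).all()
        assert (rep.per_subject["rmse_px"] == 0).all()

    def test_cm_conversion(self, small_corpus):
        preds = {it.key: it.landmarks + np.array([3.0, 4.0])
                 for it in small_corpus}
        rep = build_report(small_corpus, preds, resolution_mm_per_px=1.0)
        assert rep.overall_rmse_px == pytest.approx(5.0)
        assert rep.overall_rmse_cm == pytest.approx(0.5)

    def test_totals_match_brute_force(self, small_corpus):
        rng = np.random.default_rng(4)
        preds = {it.key: it.landmarks + rng.normal(0, 2, size=(21, 2))
                 for it in small_corpus}
        rep = build_report(small_corpus, preds)
        errs = np.concatenate([it.landmarks - preds[it.key]
                               for it in small_corpus])
        assert rep.overall_rmse_px == pytest.approx(
            np.sqrt((errs ** 2).sum(axis=1).mean()), abs=1e-10)
        d = np.sqrt((errs ** 2).sum(axis=1))
        assert rep.overall_outlier_pct == pytest.approx(
            100 * (d > 5).mean(), abs=1e-10)

    def test_missing_predictions_rejected(self, small_corpus):
        preds = {it.key: it.landmarks for it in small_corpus[1:]}
        with pytest.raises(ValueError, match="missing predictions"):
            build_report(small_corpus, preds)

    def test_report_serialization(self, small_corpus, tmp_path):
        preds = {it.key: it.landmarks + 1.0 for it in small_corpus}
        rep = build_report(small_corpus, preds)
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "lm.csv", tmp_path / "subj.csv")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert (tmp_path / "lm.csv").read_text().count("\n") == 22  # header + 21
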