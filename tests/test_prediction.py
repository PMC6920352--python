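"""Cohort filtering, labelling, CV models and the evaluation statistics."""

import numpy as np
import pandas as pd
import pytest

from keyfeat import prediction as pred


def _roster(n, reasons):
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "recurrence_months": np.nan,
        "followup_months": 60.0,
        "exclude_reason": "",
    })
    i = 0
    for reason, count in reasons.items():
        df.loc[i:i + count - 1, "exclude_reason"] = reason
        i += count
    return df


def _separable(n=80, n_pos=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n_pos), np.zeros(n - n_pos)].astype(int)
    x = rng.normal(size=(n, 4))
    x[:, 0] += 8 * y
    return pd.DataFrame(x, columns=list("abcd")), y


FAST = dict(c_grid=(1.0,), inner_cv=3)


class TestCohortFilter:
    def test_nmsh_like_cascade_leaves_842(self):
        roster = _roster(1007, {"neoadjuvant": 115, "adjuvant": 7,
                                "lost_followup": 43})
        kept, log = pred.apply_cohort_filter(roster)
        assert len(kept) == 842
        assert [len(log[r]) for r in ("neoadjuvant", "adjuvant",
                                      "lost_followup")] == [115, 7, 43]

    def test_external_like_cascade_leaves_95(self):
        roster = _roster(102, {"neoadjuvant": 1, "missing_slides": 1,
                               "lost_followup": 5})
        kept, _ = pred.apply_cohort_filter(roster)
        assert len(kept) == 95

    def test_empty_flags_identity(self):
        roster = _roster(10, {})
        kept, log = pred.apply_cohort_filter(roster)
        assert len(kept) == 10 and log == {}

    def test_unknown_reason_rejected(self):
        roster = _roster(4, {})
        roster.loc[0, "exclude_reason"] = "martian"
        with pytest.raises(ValueError, match="martian"):
            pred.apply_cohort_filter(roster)


class TestLabels:
    @pytest.mark.parametrize("rec,fup,horizon,expected", [
        (6.0, 40.0, 12.0, 1),
        (np.nan, 60.0, 12.0, 0),
        (np.nan, 8.0, 12.0, None),       # censored before the horizon
        (30.0, 70.0, 12.0, 0),           # late recurrence, 1-year label 0
        (30.0, 70.0, 60.0, 1),           # same patient at the 5-year horizon
    ])
    def test_horizon_labelling(self, rec, fup, horizon, expected):
        assert pred.define_label(rec, fup, horizon) == expected

    def test_missing_everything_rejected(self):
        with pytest.raises(ValueError, match="recurrence or follow-up"):
            pred.define_label(np.nan, np.nan, 12.0)

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pred.define_label(5.0, 10.0, 0.0)


class TestFoldBookkeeping:
    def test_742_patients_40_positive(self):
        """Stratified 10-fold: exactly 4 positives per fold, 70.2 negatives."""
        y = np.r_[np.ones(40), np.zeros(702)]
        comp = pred.fold_composition(y, n_folds=10, seed=0)
        assert comp["n_positive"].mean() == pytest.approx(4.00)
        assert comp["n_positive"].std(ddof=1) == pytest.approx(0.0)
        assert comp["n_negative"].mean() == pytest.approx(70.2)


class TestRankAuc:
    def test_matches_all_pairs_oracle_on_hand_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        labels = np.array([1, 0, 1, 0, 0, 0])
        wins = sum((si > sj) + 0.5 * (si == sj)
                   for si, li in zip(scores, labels) if li == 1
                   for sj, lj in zip(scores, labels) if lj == 0)
        assert pred.rank_auc(scores, labels) == pytest.approx(wins / (2 * 4))

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 4, 30).astype(float)  # many ties
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        n1, n0 = labels.sum(), (1 - labels).sum()
        wins = sum((si > sj) + 0.5 * (si == sj)
                   for si, li in zip(scores, labels) if li == 1
                   for sj, lj in zip(scores, labels) if lj == 0)
        assert pred.rank_auc(scores, labels) == pytest.approx(wins / (n1 * n0))

    def test_perfect_and_anti_ranked(self):
        labels = np.array([0, 0, 1, 1])
        assert pred.rank_auc(labels.astype(float), labels) == 1.0
        assert pred.rank_auc(-labels.astype(float), labels) == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        base = pred.rank_auc(scores, labels)
        assert pred.rank_auc(np.exp(scores), labels) == pytest.approx(base)
        assert pred.rank_auc(3 * scores - 7, labels) == pytest.approx(base)


class TestEvaluate:
    def test_constant_scores_warn_and_return_half(self):
        with pytest.warns(UserWarning, match="constant"):
            res = pred.evaluate(np.ones(20), np.r_[np.ones(5), np.zeros(15)])
        assert res.auc == 0.5

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = labels + rng.normal(0, 0.8, 60)
        res = pred.evaluate(scores, labels)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_pseudo_r2_grows_with_separation(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(30), np.zeros(30)].astype(int)
        weak = labels + rng.normal(0, 2.0, 60)
        strong = labels + rng.normal(0, 0.3, 60)
        r2_weak, _ = pred.nagelkerke_r2(weak, labels)
        r2_strong, p_strong = pred.nagelkerke_r2(strong, labels)
        assert r2_strong > r2_weak
        assert p_strong < 0.01

    def test_perfectly_separated_scores_approach_r2_one(self):
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        r2, p = pred.nagelkerke_r2(labels.astype(float), labels)
        assert r2 > 0.95 and p < 1e-4


class TestCrossValidation:
    @pytest.mark.parametrize("model", ["lasso", "ridge", "svm"])
    def test_separable_features_reach_auc_one(self, model):
        x, y = _separable()
        spec = pred.ModelSpec(model=model, seed=0, **FAST)
        res = pred.crossval_predict(x, y, spec, n_folds=5, seed=0)
        assert res.auc == pytest.approx(1.0)

    def test_permuted_labels_sit_in_null_band(self):
        """Fold-mean AUC over 10 permutation seeds stays near 0.5."""
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(80, 4)))
        aucs = []
        for s in range(10):
            y = np.r_[np.ones(30), np.zeros(50)].astype(int)
            rng.shuffle(y)
            spec = pred.ModelSpec(model="lasso", seed=s, **FAST)
            aucs.append(pred.crossval_predict(x, y, spec, n_folds=5, seed=s).auc)
        # null sd per run ~ 0.1, mean of 10 ~ 0.033
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_too_few_positives_rejected(self):
        x, y = _separable(n=30, n_pos=5)
        with pytest.raises(ValueError, match="at least 10"):
            pred.crossval_predict(x, y, pred.ModelSpec(**FAST), n_folds=10)

    def test_deterministic_given_seed(self):
        x, y = _separable(n=60, n_pos=25, seed=5)
        x.iloc[:, 0] = np.random.default_rng(6).normal(size=60) + y  # noisy
        spec = pred.ModelSpec(model="ridge", seed=3, **FAST)
        a = pred.crossval_predict(x, y, spec, n_folds=5, seed=3)
        b = pred.crossval_predict(x, y, spec, n_folds=5, seed=3)
        assert a.auc == b.auc and np.array_equal(a.fold_aucs, b.fold_aucs)


class TestGleasonAndCombined:
    def test_monotone_scores_in_grade(self):
        rng = np.random.default_rng(7)
        grades = rng.integers(1, 6, 100)
        labels = (rng.random(100) < (grades / 6.0)).astype(int)
        model = pred.fit_gleason_model(grades, labels)
        scores = model.predict_proba(np.arange(1, 6, dtype=float)[:, None])[:, 1]
        assert (np.diff(scores) > 0).all()

    def test_grade_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            pred.fit_gleason_model([0, 2, 3], [0, 1, 0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            pred.fit_gleason_model([1, 2, 3], [1, 1, 1])

    def test_constant_grade_reduces_combined_to_features_only(self):
        x, y = _separable(n=60, n_pos=20, seed=8)
        combined = pred.combine_features(x, np.full(60, 3))
        spec_f = pred.ModelSpec(model="lasso", seed=0, **FAST)
        spec_c = pred.ModelSpec(model="combined", base_model="lasso", seed=0,
                                **FAST)
        auc_f = pred.crossval_predict(x, y, spec_f, n_folds=5, seed=0).auc
        auc_c = pred.crossval_predict(combined, y, spec_c, n_folds=5, seed=0).auc
        assert auc_c == pytest.approx(auc_f)


class TestExternalValidation:
    def test_copy_of_train_scores_perfectly(self):
        x, y = _separable(n=60, n_pos=20, seed=9)
        res = pred.external_validate(x, y, x, y,
                                     pred.ModelSpec(model="svm", seed=0, **FAST),
                                     train_ids=[f"a{i}" for i in range(60)],
                                     test_ids=[f"b{i}" for i in range(60)])
        assert res.auc == pytest.approx(1.0)

    def test_overlapping_ids_rejected(self):
        x, y = _separable(n=20, n_pos=8)
        with pytest.raises(ValueError, match="overlap"):
            pred.external_validate(x, y, x, y, pred.ModelSpec(**FAST),
                                   train_ids=["a", "b"], test_ids=["b", "c"])

    def test_permuted_test_labels_near_half(self):
        x, y = _separable(n=120, n_pos=50, seed=10)
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        res = pred.external_validate(x[:60], y[:60], x[60:], y_perm[60:],
                                     pred.ModelSpec(model="lasso", seed=0,
                                                    **FAST))
        assert abs(res.auc - 0.5) < 0.25


class TestCohortStats:
    def _cohort_from_2x2(self, table):
        """Patient-level frame reproducing a printed variable-by-outcome table."""
        (a, b), (c, d) = table  # rows: outcome 1/0, cols: variable yes/no
        var = [True] * a + [False] * b + [True] * c + [False] * d
        y = [1] * (a + b) + [0] * (c + d)
        return pd.DataFrame({"flag": var}), np.array(y)

    def test_gleason_high_table_reproduces_printed_p(self):
        cohort, y = self._cohort_from_2x2([[57, 22], [231, 532]])
        out = pred.cohort_stats(cohort, y, categorical=["flag"])
        assert out.loc[0, "p_value"] == pytest.approx(5.2e-13, rel=0.05)

    def test_clinical_recurrence_table_reproduces_printed_p(self):
        cohort, y = self._cohort_from_2x2([[14, 65], [9, 754]])
        out = pred.cohort_stats(cohort, y, categorical=["flag"])
        assert out.loc[0, "p_value"] == pytest.approx(5.5e-10, rel=0.05)

    def test_balanced_table_gives_p_one(self):
        cohort, y = self._cohort_from_2x2([[5, 5], [5, 5]])
        out = pred.cohort_stats(cohort, y, categorical=["flag"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_category_skipped_with_note(self):
        cohort, y = self._cohort_from_2x2([[10, 0], [12, 0]])
        out = pred.cohort_stats(cohort, y, categorical=["flag"])
        assert "skipped" in out.loc[0, "note"]
        assert np.isnan(out.loc[0, "p_value"])

    def test_shifted_continuous_variable_detected(self):
        rng = np.random.default_rng(12)
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        cohort = pd.DataFrame({"psa": np.r_[rng.lognormal(3, 0.5, 40),
                                            rng.lognormal(2.2, 0.5, 40)]})
        out = pred.cohort_stats(cohort, y, continuous=["psa"])
        assert out.loc[0, "test"] == "wilcoxon_rank_sum"
        assert out.loc[0, "p_value"] < 1e-4
        assert out.loc[0, "significant_at_0.05"]
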