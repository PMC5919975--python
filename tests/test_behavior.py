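"""Behavioral updating statistics: bin summaries, ANOVA, regressions,
false-memory comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import toy_trials
from sempe import behavior
from sempe.config import ParadigmConfig, substream
from sempe.paradigm import simulate_cohort


class TestSubsequentAccuracy:
    def test_arithmetic(self):
        rows = [dict(test1_confidence=40, test2_outcome="incorrect")] * 3 + [
            dict(test1_confidence=40, test2_outcome="correct",
                 test2_confidence=80)
        ]
        acc = behavior.subsequent_accuracy(toy_trials(rows))
        med = acc[acc["bin"] == "medium"]
        assert med["subsequent_accuracy"].iloc[0] == 25.0
        assert med["n_trials"].iloc[0] == 4

    def test_all_corrected_is_100(self):
        rows = [
            dict(test1_confidence=80, test2_outcome="correct",
                 test2_confidence=90)
        ] * 3
        acc = behavior.subsequent_accuracy(toy_trials(rows))
        assert acc.loc[acc["bin"] == "high", "subsequent_accuracy"].iloc[0] == 100.0

    def test_empty_bins_marked_missing(self):
        rows = [dict(test1_confidence=40, test2_outcome="correct",
                     test2_confidence=50)]
        acc = behavior.subsequent_accuracy(toy_trials(rows))
        assert acc.loc[acc["bin"] == "high", "subsequent_accuracy"].isna().all()
        assert (acc.loc[acc["bin"] == "high", "n_trials"] == 0).all()

    def test_invariant_to_trial_order(self, recall_kept):
        a = behavior.subsequent_accuracy(recall_kept, prepared=True)
        shuffled = recall_kept.sample(frac=1.0, random_state=0)
        b = behavior.subsequent_accuracy(shuffled, prepared=True)
        pd.testing.assert_frame_equal(
            a.sort_values(["subject_id", "bin"]).reset_index(drop=True),
            b.sort_values(["subject_id", "bin"]).reset_index(drop=True),
        )


class TestOverallUpdating:
    def test_half_corrected_at_mean_confidence_50_scores_25(self):
        rows = [
            dict(test1_confidence=40, test2_outcome="correct", test2_confidence=40),
            dict(test1_confidence=40, test2_outcome="correct", test2_confidence=60),
            dict(test1_confidence=40, test2_outcome="incorrect"),
            dict(test1_confidence=40, test2_outcome="incorrect"),
        ]
        ou = behavior.overall_updating(toy_trials(rows))
        assert ou["score"].iloc[0] == 25.0

    def test_all_corrected_at_confidence_100_scores_100(self):
        rows = [
            dict(test1_confidence=40, test2_outcome="correct",
                 test2_confidence=100)
        ] * 4
        ou = behavior.overall_updating(toy_trials(rows))
        assert ou["score"].iloc[0] == 100.0

    def test_none_corrected_scores_0(self):
        rows = [dict(test1_confidence=40, test2_outcome="incorrect")] * 4
        ou = behavior.overall_updating(toy_trials(rows))
        assert ou["score"].iloc[0] == 0.0

    def test_pe_values_without_incorrect_trials_absent(self):
        rows = [dict(test1_correct=True, test1_confidence=30,
                     test2_outcome="correct", test2_confidence=80)]
        ou = behavior.overall_updating(toy_trials(rows))
        assert ou.empty

    def test_bounded_and_dominated_by_accuracy(self, recognition_kept):
        ou = behavior.overall_updating(recognition_kept, prepared=True)
        assert ou["score"].between(0, 100).all()
        # overall updating <= subsequent accuracy (confidence <= 100)
        t = recognition_kept[~recognition_kept["test1_correct"]]
        corrected = (t["transition"] == "incorrect-to-correct").astype(float)
        acc = (
            t.assign(c=corrected)
            .groupby(["subject_id", "pe"])["c"]
            .mean()
            .mul(100.0)
        )
        merged = ou.set_index(["subject_id", "pe"])["score"]
        assert (merged <= acc.reindex(merged.index) + 1e-9).all()


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        mat = pd.DataFrame(
            {"a": [10.0, 20, 30, 40], "b": [10.0, 20, 30, 40]},
            index=pd.Index(range(4), name="subject_id"),
        )
        res = behavior.rm_anova(mat)
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_two_level_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.normal(50, 10, size=(12, 2)),
            columns=["low", "high"],
            index=pd.Index(range(12), name="subject_id"),
        )
        res = behavior.rm_anova(mat)
        t, _ = stats.ttest_rel(mat["low"], mat["high"])
        assert res.F == pytest.approx(t**2, rel=1e-8)

    def test_imputed_cell_equals_column_mean(self):
        mat = pd.DataFrame(
            {"a": [10.0, 20, np.nan], "b": [30.0, 40, 50]},
            index=pd.Index(range(3), name="subject_id"),
        )
        filled, n = behavior.impute_condition_mean(mat)
        assert n == 1
        assert filled.loc[2, "a"] == 15.0

    def test_all_missing_bin_errors(self):
        mat = pd.DataFrame(
            {"a": [np.nan, np.nan], "b": [1.0, 2.0]},
            index=pd.Index(range(2), name="subject_id"),
        )
        with pytest.raises(ValueError):
            behavior.rm_anova(mat)

    def test_bonferroni_capped_and_monotone(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.normal(0, 1, size=(8, 4)),
            columns=list("abcd"),
            index=pd.Index(range(8), name="subject_id"),
        )
        res = behavior.rm_anova(mat)
        ph = res.posthoc
        assert (ph["p_corrected"] <= 1.0).all()
        assert (ph["p_corrected"] >= ph["p_raw"] - 1e-15).all()
        # correction is monotone in the raw p value (ties at the cap allowed)
        by_raw = ph.sort_values("p_raw")["p_corrected"].to_numpy()
        assert (np.diff(by_raw) >= -1e-15).all()

    def test_degrees_of_freedom(self, recall_kept):
        acc = behavior.subsequent_accuracy(recall_kept, prepared=True)
        mat = behavior.subject_bin_matrix(acc, "subsequent_accuracy")
        res = behavior.rm_anova(mat)
        n, k = mat.shape
        assert (res.df_effect, res.df_error) == (k - 1, (k - 1) * (n - 1))


class TestPERegressions:
    def test_exactly_linear_medians_give_r2_of_1(self):
        rows = []
        for sid in range(3):
            for conf, p_corr in [(0, 20), (50, 45), (100, 70)]:
                for i in range(20):
                    corrected = (i / 20 * 100) < p_corr
                    rows.append(
                        dict(
                            subject_id=sid,
                            test1_confidence=conf,
                            test2_outcome="correct" if corrected else "incorrect",
                            test2_confidence=50 if corrected else 0,
                        )
                    )
        res = behavior.pe_regressions(toy_trials_multi(rows), "accuracy")
        assert res.group_median.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.group_median.beta == pytest.approx(0.5, abs=1e-9)

    def test_constant_outcome_gives_zero_slope(self):
        rows = []
        for sid in range(5):
            for conf in (0, 30, 60, 90):
                rows.append(
                    dict(subject_id=sid, test1_confidence=conf,
                         test2_outcome="incorrect")
                )
        res = behavior.pe_regressions(toy_trials_multi(rows), "accuracy")
        assert res.mean_beta == pytest.approx(0.0, abs=1e-12)
        assert abs(res.t_statistic) < 1e-6

    def test_subject_with_single_pe_value_dropped_with_warning(self):
        rows = [
            dict(subject_id=0, test1_confidence=40, test2_outcome="incorrect"),
            dict(subject_id=0, test1_confidence=40, test2_outcome="correct",
                 test2_confidence=50),
        ]
        for sid in (1, 2):
            for conf in (20, 40, 60):
                rows.append(
                    dict(subject_id=sid, test1_confidence=conf,
                         test2_outcome="incorrect")
                )
        with pytest.warns(UserWarning, match="dropped"):
            res = behavior.pe_regressions(toy_trials_multi(rows), "accuracy")
        assert len(res.subject_results) == 2

    def test_confidence_slope_recovery(self):
        # planted d = 0.43 %/unit; the confidence readout is continuous, so
        # the group-median estimator is unbiased
        cfg = ParadigmConfig.recognition(n_subjects=27)
        t = simulate_cohort(cfg, substream(31, "rec"))
        res = behavior.pe_regressions(t, "confidence")
        assert abs(res.group_median.beta - 0.43) < 0.15


def toy_trials_multi(rows):
    out = toy_trials(rows)
    out["question_id"] = np.arange(len(out))
    return out


class TestFalseMemory:
    @staticmethod
    def _cohort(adopt_low, adopt_med, n_subj=10, n_each=10, conf_low=60,
                conf_med=60):
        rows = []
        for sid in range(n_subj):
            for i in range(n_each):
                for conf, p_adopt, c2 in ((30, adopt_low, conf_low),
                                          (65, adopt_med, conf_med)):
                    adopted = (i / n_each) < p_adopt
                    rows.append(
                        dict(
                            subject_id=sid,
                            test1_correct=True,
                            test1_confidence=conf,
                            feedback_kind="false",
                            test2_outcome=(
                                "false_feedback_answer" if adopted else "correct"
                            ),
                            test2_confidence=c2 if adopted else conf,
                        )
                    )
        return toy_trials_multi(rows)

    def test_identical_adoption_gives_zero_t(self):
        res = behavior.false_memory_tests(self._cohort(0.4, 0.4))
        assert res.paired_t == pytest.approx(0.0, abs=1e-12)

    def test_adoption_difference_detected(self):
        res = behavior.false_memory_tests(self._cohort(0.2, 0.7))
        assert res.paired_t > 0 and res.paired_p < 0.05
        assert res.adoption["medium"].mean() > res.adoption["low"].mean()

    def test_subject_missing_a_bin_dropped_from_paired_kept_in_pooled(self):
        t = self._cohort(0.5, 0.5, n_subj=4)
        # subject 3 loses all medium-PE trials
        t = t[~((t["subject_id"] == 3) & (t["test1_confidence"] == 65))]
        res = behavior.false_memory_tests(t)
        assert res.n_subjects_paired == 3
        assert res.n_subjects_dropped == 1
        n_adopted = (
            (t["test2_outcome"] == "false_feedback_answer").sum()
        )
        assert res.pooled_confidence["n"].sum() == n_adopted

    def test_pooled_confidence_comparison(self):
        res = behavior.false_memory_tests(
            self._cohort(0.5, 0.5, conf_low=50, conf_med=80)
        )
        assert res.pooled_t > 0 and res.pooled_p < 0.05

    def test_generative_slope_yields_higher_medium_adoption(self):
        cfg = ParadigmConfig.recall(n_subjects=40)
        t = simulate_cohort(cfg, substream(32, "fm"))
        res = behavior.false_memory_tests(t)
        assert res.adoption["medium"].mean() > res.adoption["low"].mean()

    def test_too_few_paired_subjects_errors(self):
        t = self._cohort(0.5, 0.5, n_subj=1)
        with pytest.raises(ValueError):
            behavior.false_memory_tests(t)
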