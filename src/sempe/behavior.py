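"""Behavioral updating statistics.

Implements the analyses linking prediction error to memory updating:
bin-wise subsequent accuracy and Test2 confidence (with repeated-measures
ANOVA over PE bins, mean imputation of missing cells, and Bonferroni post
hocs), the overall-updating score combining correction rate and confidence,
per-subject and group-median regressions of updating measures on |PE|, and
the false-memory comparisons (adoption rate and pooled confidence, low vs
medium PE).

All analyses operate on the exclusion-filtered trial table; percentages are
on the 0-100 scale throughout. Tests are two-tailed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import pe as pe_mod

__all__ = [
    "prepare",
    "subsequent_accuracy",
    "confidence_updating",
    "subject_bin_matrix",
    "impute_condition_mean",
    "overall_updating",
    "rm_anova",
    "AnovaResult",
    "PERegression",
    "PERegressionResults",
    "RegressionResult",
    "false_memory_tests",
    "FalseMemoryResult",
]


def _onesample_t(values) -> tuple[float, float]:
    """One-sample t against zero; a zero-variance zero-mean sample is no
    evidence at all (t = 0, p = 1) rather than NaN."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        if values[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(values[0]) * np.inf), 0.0
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


def _paired_t(a, b) -> tuple[float, float]:
    return _onesample_t(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def prepare(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive PE, apply exclusions, and attach transition labels."""
    if "pe" not in trials.columns:
        trials = pe_mod.add_derived(trials)
    if "transition" in trials.columns and "excluded" in trials.columns:
        return trials.loc[~trials["excluded"]].copy()
    return pe_mod.kept(trials)


def _bin_order(scheme: str) -> list[str]:
    return {
        "four_bin": pe_mod.FOUR_BIN_LABELS,
        "false_two_bin": pe_mod.TWO_BIN_LABELS,
        "rank_tertile": pe_mod.TERTILE_LABELS,
    }[scheme]


def subsequent_accuracy(
    trials: pd.DataFrame, scheme: str = "four_bin", prepared: bool = False
) -> pd.DataFrame:
    """Per subject x PE bin: percent of Test1-incorrect trials corrected.

    The score is 100 x (#incorrect-to-correct) / (#Test1-incorrect) in the
    bin; feedback-referenced, so supplying an adopted false-feedback answer
    counts as corrected. Bins with no trials are reported with NaN accuracy.
    """
    t = trials if prepared else prepare(trials)
    t = t[~t["test1_correct"]]
    t = pe_mod.assign_bins(t, scheme)
    col = f"bin_{scheme}"
    t = t[t[col].notna()]
    corrected = t["transition"] == "incorrect-to-correct"
    g = t.assign(corrected=corrected).groupby(["subject_id", col], observed=True)
    agg = g.agg(n_trials=("corrected", "size"), n_corrected=("corrected", "sum"))
    agg["subsequent_accuracy"] = 100.0 * agg["n_corrected"] / agg["n_trials"]
    agg = agg.reset_index().rename(columns={col: "bin"})
    return _complete_bins(agg, t["subject_id"].unique(), _bin_order(scheme))


def confidence_updating(
    trials: pd.DataFrame, scheme: str = "four_bin", prepared: bool = False
) -> pd.DataFrame:
    """Per subject x PE bin: mean Test2 confidence of corrected trials."""
    t = trials if prepared else prepare(trials)
    t = t[~t["test1_correct"]]
    t = pe_mod.assign_bins(t, scheme)
    col = f"bin_{scheme}"
    t = t[t[col].notna() & (t["transition"] == "incorrect-to-correct")]
    g = t.groupby(["subject_id", col], observed=True)
    agg = g.agg(
        n_trials=("test2_confidence", "size"),
        mean_test2_confidence=("test2_confidence", "mean"),
    )
    agg = agg.reset_index().rename(columns={col: "bin"})
    return _complete_bins(agg, t["subject_id"].unique(), _bin_order(scheme))


def _complete_bins(agg, subjects, bins):
    full = pd.MultiIndex.from_product(
        [sorted(subjects), bins], names=["subject_id", "bin"]
    )
    agg = agg.set_index(["subject_id", "bin"]).reindex(full).reset_index()
    agg["n_trials"] = agg["n_trials"].fillna(0).astype(int)
    return agg


def subject_bin_matrix(
    summaries: pd.DataFrame, value: str, bins: list[str] | None = None
) -> pd.DataFrame:
    """Pivot a bin-summary table to a subjects x bins matrix."""
    mat = summaries.pivot(index="subject_id", columns="bin", values=value)
    if bins is not None:
        mat = mat[bins]
    return mat


def impute_condition_mean(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing cells by the bin's across-subject mean.

    Returns the complete matrix and the number of imputed cells; raises if a
    bin is missing for every subject.
    """
    if matrix.isna().all(axis=0).any():
        empty = list(matrix.columns[matrix.isna().all(axis=0)])
        raise ValueError(f"bins missing for all subjects: {empty}")
    n_missing = int(matrix.isna().to_numpy().sum())
    return matrix.fillna(matrix.mean(axis=0)), n_missing


def overall_updating(trials: pd.DataFrame, prepared: bool = False) -> pd.DataFrame:
    """Overall updating score per subject and unique Test1 PE value.

    For the Test1-incorrect trials at one PE value, the score sums the Test2
    confidence of each corrected answer (0 for those remaining incorrect) and
    divides by the number of incorrect trials. It equals
    (fraction corrected) x (mean confidence among corrected): half the
    trials corrected at mean confidence 50 scores 25; all corrected at
    confidence 100 scores 100. PE values with no incorrect trials are simply
    absent (undefined, not 0).
    """
    t = trials if prepared else prepare(trials)
    t = t[~t["test1_correct"]]
    contrib = np.where(
        t["transition"] == "incorrect-to-correct", t["test2_confidence"], 0.0
    )
    g = t.assign(contrib=contrib).groupby(["subject_id", "pe"])
    agg = g.agg(n_incorrect=("contrib", "size"), total=("contrib", "sum"))
    agg["score"] = agg["total"] / agg["n_incorrect"]
    return agg.reset_index()[["subject_id", "pe", "n_incorrect", "score"]]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA

@dataclass
class AnovaResult:
    """One-way RM-ANOVA with Bonferroni-corrected paired post hocs."""

    F: float
    df_effect: int
    df_error: int
    p_value: float
    posthoc: pd.DataFrame
    n_imputed: int = 0

    def summary(self) -> str:
        lines = [
            f"One-way repeated-measures ANOVA: "
            f"F({self.df_effect},{self.df_error}) = {self.F:.3g}, "
            f"p = {self.p_value:.4g} "
            f"({self.n_imputed} cells mean-imputed)",
            "Post hoc paired t-tests (Bonferroni corrected):",
        ]
        for _, r in self.posthoc.iterrows():
            lines.append(
                f"  {r['pair']}: t({r['df']}) = {r['t']:.3g}, "
                f"p_corrected = {r['p_corrected']:.4g}"
            )
        return "\n".join(lines)


def rm_anova(
    matrix: pd.DataFrame, impute: bool = True, drop_incomplete: bool = False
) -> AnovaResult:
    """One-way repeated-measures ANOVA over PE bins.

    ``matrix`` is subjects x bins. Missing cells are replaced by the bin's
    across-subject mean before fitting (the default), or incomplete subjects
    are dropped entirely with ``drop_incomplete=True`` (a sensitivity mode).
    No sphericity correction is applied; dfs are (k-1, (k-1)(n-1)). Post hoc
    p values are multiplied by the number of pairwise comparisons, capped
    at 1.
    """
    from statsmodels.stats.anova import AnovaRM

    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 bins and 2 subjects")
    n_imputed = 0
    if drop_incomplete:
        matrix = matrix.dropna(axis=0)
        if matrix.shape[0] < 2:
            raise ValueError("fewer than 2 complete subjects")
    elif impute:
        matrix, n_imputed = impute_condition_mean(matrix)
    elif matrix.isna().any().any():
        raise ValueError("missing cells; use impute=True or drop_incomplete=True")

    long = matrix.reset_index().melt(
        id_vars="subject_id", var_name="bin", value_name="value"
    )
    fit = AnovaRM(long, depvar="value", subject="subject_id", within=["bin"]).fit()
    row = fit.anova_table.iloc[0]
    F = float(row["F Value"])
    df1, df2 = int(row["Num DF"]), int(row["Den DF"])
    p = float(row["Pr > F"])

    pairs = list(itertools.combinations(matrix.columns, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p_raw = stats.ttest_rel(matrix[a], matrix[b])
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "t": float(t),
                "df": matrix.shape[0] - 1,
                "p_raw": float(p_raw),
                "p_corrected": min(1.0, float(p_raw) * m),
            }
        )
    return AnovaResult(
        F=F, df_effect=df1, df_error=df2, p_value=p,
        posthoc=pd.DataFrame(rows), n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# PE regressions (recognition-style fine-grained PE grid)

@dataclass
class RegressionResult:
    """A single OLS fit of an updating measure on |PE| (percent per unit)."""

    beta: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    level: str  # 'subject' or 'group_median'


@dataclass
class PERegressionResults:
    """Subject-level slopes, their one-sample t, and the group-median fit."""

    outcome: str
    subject_results: pd.DataFrame
    t_statistic: float
    t_df: int
    t_p_value: float
    mean_beta: float
    group_median: RegressionResult
    medians: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        gm = self.group_median
        return (
            f"PE regression of {self.outcome} (|PE| in PE units, outcome in %)\n"
            f"  subjects: n = {len(self.subject_results)}, "
            f"mean beta = {self.mean_beta:.3g}, "
            f"one-sample t({self.t_df}) = {self.t_statistic:.3g}, "
            f"p = {self.t_p_value:.4g}\n"
            f"  group median: beta = {gm.beta:.3g}, "
            f"intercept = {gm.intercept:.3g}, R^2 = {gm.r_squared:.3g}, "
            f"p = {gm.p_value:.4g} ({gm.n_points} PE values)"
        )


class PERegression:
    """Linear models of an updating measure against |PE|.

    Built from a (recognition-style) trial table; ``fit`` computes, per
    subject, the outcome at each observed |PE| value — Test2 accuracy (%),
    mean Test2 confidence of corrected trials, or the overall-updating
    score — regresses it on |PE| by OLS, tests the subject slopes against
    zero with a one-sample t, and fits an unweighted OLS to the
    across-subject median outcome per |PE| value.
    """

    OUTCOMES = ("accuracy", "confidence", "overall_updating")

    def __init__(self, trials: pd.DataFrame, outcome: str = "accuracy",
                 prepared: bool = False):
        if outcome not in self.OUTCOMES:
            raise ValueError(f"outcome must be one of {self.OUTCOMES}")
        self.outcome = outcome
        self.trials = trials if prepared else prepare(trials)

    def _per_subject_table(self) -> pd.DataFrame:
        t = self.trials[~self.trials["test1_correct"]].copy()
        t["mag"] = -t["pe"]
        corrected = t["transition"] == "incorrect-to-correct"
        if self.outcome == "accuracy":
            t["y"] = 100.0 * corrected
            agg = t.groupby(["subject_id", "mag"])["y"].mean()
        elif self.outcome == "confidence":
            sub = t[corrected]
            agg = sub.groupby(["subject_id", "mag"])["test2_confidence"].mean()
        else:  # overall_updating
            t["contrib"] = np.where(corrected, t["test2_confidence"], 0.0)
            agg = t.groupby(["subject_id", "mag"])["contrib"].mean()
        return agg.rename("y").reset_index()

    def fit(self) -> PERegressionResults:
        table = self._per_subject_table()
        rows = []
        for sid, grp in table.groupby("subject_id"):
            if grp["mag"].nunique() < 2:
                warnings.warn(
                    f"subject {sid} has <2 distinct PE values; dropped",
                    stacklevel=2,
                )
                continue
            res = stats.linregress(grp["mag"], grp["y"])
            rows.append(
                {
                    "subject_id": sid,
                    "beta": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.rvalue**2,
                    "p_value": res.pvalue,
                    "n_points": len(grp),
                }
            )
        subj = pd.DataFrame(rows)
        if len(subj) < 2:
            raise ValueError("need at least 2 subjects with fitted slopes")
        t_stat, t_p = _onesample_t(subj["beta"])

        med = table.groupby("mag")["y"].median().rename("median_y").reset_index()
        gm = stats.linregress(med["mag"], med["median_y"])
        group_median = RegressionResult(
            beta=float(gm.slope),
            intercept=float(gm.intercept),
            r_squared=float(gm.rvalue**2),
            p_value=float(gm.pvalue),
            n_points=len(med),
            level="group_median",
        )
        return PERegressionResults(
            outcome=self.outcome,
            subject_results=subj,
            t_statistic=t_stat,
            t_df=len(subj) - 1,
            t_p_value=t_p,
            mean_beta=float(subj["beta"].mean()),
            group_median=group_median,
            medians=med,
        )


def pe_regressions(
    trials: pd.DataFrame, outcome: str = "accuracy", prepared: bool = False
) -> PERegressionResults:
    """Functional wrapper around :class:`PERegression`."""
    return PERegression(trials, outcome=outcome, prepared=prepared).fit()


# ---------------------------------------------------------------------------
# False-memory comparisons

@dataclass
class FalseMemoryResult:
    """Low- vs medium-PE comparisons for correct trials given false feedback."""

    adoption: pd.DataFrame          # subject x bin adoption %
    paired_t: float
    paired_df: int
    paired_p: float
    n_subjects_paired: int
    n_subjects_dropped: int
    pooled_confidence: pd.DataFrame  # bin, n, mean confidence
    pooled_t: float
    pooled_df: int
    pooled_p: float

    def summary(self) -> str:
        means = self.adoption.mean(axis=0)
        pc = self.pooled_confidence.set_index("bin")
        return (
            "False-feedback adoption (correct Test1 trials):\n"
            f"  mean adoption low = {means.get('low', float('nan')):.1f}%, "
            f"medium = {means.get('medium', float('nan')):.1f}%; "
            f"paired t({self.paired_df}) = {self.paired_t:.3g}, "
            f"p = {self.paired_p:.4g} "
            f"({self.n_subjects_dropped} subjects lacking a bin excluded)\n"
            f"  pooled Test2 confidence of adopted false answers: "
            f"low = {pc.loc['low', 'mean_confidence']:.1f}, "
            f"medium = {pc.loc['medium', 'mean_confidence']:.1f}; "
            f"fixed-effects t({self.pooled_df}) = {self.pooled_t:.3g}, "
            f"p = {self.pooled_p:.4g}"
        )


def false_memory_tests(
    trials: pd.DataFrame, two_bin_edge: int = 49, prepared: bool = False
) -> FalseMemoryResult:
    """Does stronger accurate memory invite false-memory adoption?

    On the correct + false-feedback subset, split by the two-bin scheme
    (|PE| 1-49 low, 50-70 medium): (1) paired t across subjects of the
    per-subject percentage of Test2 answers matching the false feedback,
    dropping subjects lacking either bin (mean replacement is unsuitable for
    a two-condition within-subject test); (2) fixed-effects two-sample t of
    the Test2 confidences of adopted-false-answer trials pooled across
    subjects per bin.
    """
    t = trials if prepared else prepare(trials)
    t = t[
        t["test1_correct"]
        & (t.get("feedback_kind", pd.Series(index=t.index, dtype=object)) == "false")
    ].copy()
    t = pe_mod.assign_bins(t, "false_two_bin", two_bin_edge=two_bin_edge)
    t = t[t["bin_false_two_bin"].notna()]
    t["adopted"] = t["transition"] == "correct-to-false"

    per = (
        t.groupby(["subject_id", "bin_false_two_bin"], observed=True)["adopted"]
        .mean()
        .mul(100.0)
        .unstack("bin_false_two_bin")
    )
    for b in pe_mod.TWO_BIN_LABELS:
        if b not in per.columns:
            per[b] = np.nan
    per = per[pe_mod.TWO_BIN_LABELS]

    both = per.dropna(axis=0)
    n_dropped = len(per) - len(both)
    if len(both) < 2:
        raise ValueError("paired test needs >= 2 subjects with both bins")
    paired_t, paired_p = _paired_t(both["medium"], both["low"])

    adopted = t[t["adopted"]]
    lo = adopted.loc[
        adopted["bin_false_two_bin"] == "low", "test2_confidence"
    ].to_numpy(dtype=float)
    md = adopted.loc[
        adopted["bin_false_two_bin"] == "medium", "test2_confidence"
    ].to_numpy(dtype=float)
    pooled = stats.ttest_ind(md, lo)
    pooled_df = len(lo) + len(md) - 2
    pooled_table = pd.DataFrame(
        {
            "bin": ["low", "medium"],
            "n": [len(lo), len(md)],
            "mean_confidence": [
                float(np.mean(lo)) if len(lo) else np.nan,
                float(np.mean(md)) if len(md) else np.nan,
            ],
        }
    )
    return FalseMemoryResult(
        adoption=per,
        paired_t=paired_t,
        paired_df=len(both) - 1,
        paired_p=paired_p,
        n_subjects_paired=len(both),
        n_subjects_dropped=n_dropped,
        pooled_confidence=pooled_table,
        pooled_t=float(pooled.statistic),
        pooled_df=pooled_df,
        pooled_p=float(pooled.pvalue),
    )
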