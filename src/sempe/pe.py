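"""Trial-level prediction errors, transitions, exclusions, and PE binning.

The prediction error treats the confidence rating as the expectancy that the
upcoming feedback will confirm the answer: feedback to an incorrect answer is
a worse-than-expected outcome (PE = -confidence), feedback to a correct answer
a better-than-expected one (PE = 100 - confidence). For correct answers met
with false feedback the outcome *appears* wrong, so the elicited PE is again
-confidence.

Three binning schemes are provided:

* ``four_bin`` — zero / low (|PE| 1-33) / medium (34-66) / high (67-100), for
  Test1-incorrect trials.
* ``false_two_bin`` — low (|PE| 1-49) / medium (50-70), for Test1-correct
  trials that received false feedback (false feedback is capped at
  confidence 70). The stated edges overlap at 49; the closed-left convention
  assigns |PE| = 49 to the low bin (configurable via ``two_bin_edge``).
* ``rank_tertile`` — within-subject ranking of the nonzero PEs into three
  equal-count groups, plus the zero bin; a control for unequal bin sizes.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = [
    "compute_pe",
    "add_derived",
    "classify_transition",
    "apply_exclusions",
    "assign_bin",
    "assign_bins",
    "FOUR_BIN_LABELS",
    "TWO_BIN_LABELS",
    "SCHEMES",
]

FOUR_BIN_LABELS = ["zero", "low", "medium", "high"]
TWO_BIN_LABELS = ["low", "medium"]
TERTILE_LABELS = ["zero", "t1", "t2", "t3"]
SCHEMES = ("four_bin", "false_two_bin", "rank_tertile")

#: exclusion reasons, in precedence order (a trial carries exactly one)
EXCLUSION_REASONS = (
    "timeout",
    "mistake",
    "answer_matches_false_feedback",
    "correct_wrt_text_after_false",
    "correct_zero_confidence",
)


def _check_confidence(confidence) -> int:
    if isinstance(confidence, (bool, np.bool_)) or not isinstance(
        confidence, numbers.Integral
    ):
        raise ValueError(f"confidence must be an integer, got {confidence!r}")
    c = int(confidence)
    if not (0 <= c <= 100):
        raise ValueError(f"confidence must be in [0, 100], got {c}")
    return c


def compute_pe(test1_correct: bool, confidence: int) -> int:
    """Signed prediction error of the feedback to one Test1 answer.

    Incorrect answers yield PE = -confidence (worse than expected), correct
    answers PE = 100 - confidence (better than expected). An incorrect answer
    held with 90% certainty therefore evokes a PE of -90, one held with 30%
    certainty a PE of -30.
    """
    c = _check_confidence(confidence)
    return 100 - c if test1_correct else -c


def add_derived(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the derived ``pe`` column.

    Correct answers met with false feedback receive PE = -confidence (the
    feedback disconfirms the — actually correct — answer); all other trials
    follow :func:`compute_pe`.
    """
    out = trials.copy()
    conf = out["test1_confidence"].to_numpy()
    if ((conf < 0) | (conf > 100)).any():
        bad = int(np.flatnonzero((conf < 0) | (conf > 100))[0])
        raise ValueError(f"confidence out of range at row {bad}")
    correct = out["test1_correct"].to_numpy(dtype=bool)
    pe = np.where(correct, 100 - conf, -conf)
    if "feedback_kind" in out.columns:
        false_correct = correct & (out["feedback_kind"].to_numpy() == "false")
        pe = np.where(false_correct, -conf, pe)
    out["pe"] = pe.astype(int)
    return out


def classify_transition(
    test1_correct: bool,
    test2_outcome: str,
    feedback_kind: str = "veridical",
) -> str:
    """Joint Test1 -> Test2 outcome label for one trial.

    Test2 accuracy is scored with respect to the feedback, not the original
    text: an incorrect answer met with false feedback counts as corrected
    ("incorrect-to-correct") when the false-feedback answer is supplied in
    Test2, and a correct answer supplanted by adopted false feedback is
    "correct-to-false".
    """
    if test2_outcome is None or (isinstance(test2_outcome, float) and np.isnan(test2_outcome)):
        raise ValueError("missing Test2 outcome")
    if test2_outcome not in (
        "correct", "incorrect", "false_feedback_answer", "correct_wrt_text"
    ):
        raise ValueError(f"unknown Test2 outcome {test2_outcome!r}")
    if test1_correct:
        if test2_outcome == "false_feedback_answer":
            return "correct-to-false"
        if test2_outcome == "correct":
            return "correct-to-correct"
        return "correct-to-incorrect"
    # Test1 incorrect: feedback-referenced scoring
    if test2_outcome == "correct":
        return "incorrect-to-correct"
    if test2_outcome == "false_feedback_answer" and feedback_kind == "false":
        return "incorrect-to-correct"
    return "incorrect-to-incorrect"


def _classify_frame(trials: pd.DataFrame) -> pd.Series:
    fk = (
        trials["feedback_kind"]
        if "feedback_kind" in trials.columns
        else pd.Series("veridical", index=trials.index)
    )
    return pd.Series(
        [
            classify_transition(c, o, k)
            for c, o, k in zip(trials["test1_correct"], trials["test2_outcome"], fk)
        ],
        index=trials.index,
        dtype=object,
    )


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag the infrequent trial types removed from every analysis.

    Excluded are: recognition timeouts and selection mistakes (in either
    test); incorrect answers identical to the ensuing false feedback; Test2
    answers correct with respect to the original text despite false feedback;
    and correct Test1 answers rated with zero confidence (hence no +100 PE
    events). Returns ``(trials_with_flags, exclusion_log)``; the log has one
    row per excluded trial with its single reason. Idempotent.
    """
    out = trials.copy()
    n = len(out)
    reason = np.full(n, "", dtype=object)

    def col(name):
        if name in out.columns:
            return out[name].fillna(False).to_numpy(dtype=bool)
        return np.zeros(n, dtype=bool)

    timeout = col("test1_timeout") | col("test2_timeout")
    mistake = col("test1_mistake") | col("test2_mistake")
    correct = out["test1_correct"].to_numpy(dtype=bool)
    false_fb = (
        (out["feedback_kind"].to_numpy() == "false")
        if "feedback_kind" in out.columns
        else np.zeros(n, dtype=bool)
    )
    matches = col("answer_matches_false_feedback") & ~correct & false_fb
    wrt_text = (
        (out["test2_outcome"].to_numpy() == "correct_wrt_text") & ~correct & false_fb
        if "test2_outcome" in out.columns
        else np.zeros(n, dtype=bool)
    )
    zero_conf = correct & (out["test1_confidence"].to_numpy() == 0)

    for mask, why in [
        (timeout, "timeout"),
        (mistake, "mistake"),
        (matches, "answer_matches_false_feedback"),
        (wrt_text, "correct_wrt_text_after_false"),
        (zero_conf, "correct_zero_confidence"),
    ]:
        reason[mask & (reason == "")] = why

    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    log = out.loc[out["excluded"], ["subject_id", "question_id", "exclusion_reason"]]
    return out, log.reset_index(drop=True)


def kept(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials surviving exclusion, with transition labels attached."""
    flagged, _ = apply_exclusions(trials)
    keep = flagged.loc[~flagged["excluded"]].copy()
    if "test2_outcome" in keep.columns:
        keep["transition"] = _classify_frame(keep)
    return keep


def assign_bin(pe: int, scheme: str, all_pes=None, two_bin_edge: int = 49) -> str:
    """Bin label of one PE value under a binning scheme.

    ``rank_tertile`` needs the subject's full list of eligible PEs in
    ``all_pes``; ties are broken by position for determinism.
    """
    if scheme == "four_bin":
        if pe > 0:
            raise ValueError(
                "four_bin applies to non-positive PEs (Test1-incorrect trials)"
            )
        m = -pe
        if m == 0:
            return "zero"
        if m <= 33:
            return "low"
        if m <= 66:
            return "medium"
        if m <= 100:
            return "high"
        raise ValueError(f"PE {pe} outside [-100, 0]")
    if scheme == "false_two_bin":
        m = -pe
        if not (1 <= m <= 70):
            raise ValueError(
                "false_two_bin applies to PEs in [-70, -1] "
                "(false feedback is capped at confidence 70)"
            )
        return "low" if m <= two_bin_edge else "medium"
    if scheme == "rank_tertile":
        if all_pes is None:
            raise ValueError("rank_tertile needs the subject's full PE list")
        if pe == 0:
            return "zero"
        all_pes = np.asarray(all_pes)
        hits = np.flatnonzero(all_pes == pe)
        if hits.size == 0:
            raise ValueError(f"PE {pe} not among the supplied PEs")
        return _tertile_labels(all_pes)[hits[0]]
    raise ValueError(f"unknown scheme {scheme!r}")


def assign_bins(
    trials: pd.DataFrame, scheme: str, two_bin_edge: int = 49
) -> pd.DataFrame:
    """Vectorised binning: adds a ``bin_<scheme>`` column.

    ``four_bin`` and ``rank_tertile`` operate on the Test1-incorrect subset,
    ``false_two_bin`` on correct trials that received false feedback; rows
    outside the scheme's domain get a null label.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = trials.copy()
    col = f"bin_{scheme}"
    labels = pd.Series(pd.NA, index=out.index, dtype=object)
    pe = out["pe"].to_numpy()
    correct = out["test1_correct"].to_numpy(dtype=bool)

    if scheme in ("four_bin", "rank_tertile"):
        eligible = ~correct
    else:
        false_fb = (
            (out["feedback_kind"].to_numpy() == "false")
            if "feedback_kind" in out.columns
            else np.zeros(len(out), dtype=bool)
        )
        eligible = correct & false_fb & (pe != 0)

    if scheme == "four_bin":
        m = -pe
        lab = np.select(
            [m == 0, m <= 33, m <= 66, m <= 100],
            FOUR_BIN_LABELS,
            default="",
        )
        labels[eligible] = lab[eligible]
    elif scheme == "false_two_bin":
        m = -pe
        lab = np.where(m <= two_bin_edge, "low", "medium")
        labels[eligible] = lab[eligible]
    else:  # rank_tertile, per subject
        elig = out.loc[eligible]
        for _, grp in elig.groupby("subject_id"):
            labels[grp.index] = _tertile_labels(grp["pe"].to_numpy())
    out[col] = labels
    return out


def _tertile_labels(sub_pe: np.ndarray) -> np.ndarray:
    """Per-row tertile label for one subject's PE vector (zeros -> 'zero')."""
    out = np.full(len(sub_pe), "zero", dtype=object)
    nz_idx = np.flatnonzero(sub_pe != 0)
    mags = np.abs(sub_pe[nz_idx])
    order = np.argsort(mags, kind="stable")
    k = len(order)
    sizes = [k // 3 + (1 if r < k % 3 else 0) for r in range(3)]
    start = 0
    for lbl, s in zip(("t1", "t2", "t3"), sizes):
        out[nz_idx[order[start:start + s]]] = lbl
        start += s
    return out
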