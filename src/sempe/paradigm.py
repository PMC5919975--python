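"""Synthetic cohorts for the two-test feedback-learning paradigm.

The generator emulates a study in which participants learn a factual text,
answer 100 questions two days later with 0-100 confidence ratings (Test1),
receive feedback — sometimes deliberately false — and are retested a week
later (Test2). The statistical structure planted here is the one the analysis
stack assumes: the probability and confidence of Test2 correction both rise
linearly with the absolute prediction error of the Test1 feedback, and
false feedback supplants accurate memories more readily the stronger they
were held.

Each trial has a latent knowledge strength z ~ N(0, 1). Test1 correctness is
Bernoulli with a logistic link in z (offset calibrated so the marginal hit
rate equals ``p_correct_test1``), and confidence is a noisy linear readout of
z snapped to the paradigm's rating grid — the simplest model that yields the
observed confidence-accuracy coupling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from .config import ConfigError, ParadigmConfig, TimingConfig, VoxelSpec

__all__ = [
    "simulate_test1",
    "assign_feedback",
    "simulate_test2",
    "simulate_cohort",
    "generate_event_schedule",
    "jitter_distribution",
    "simulate_bold",
]


# ---------------------------------------------------------------------------
# Test1

def _marginal_logit_offset(p: float, k: float) -> float:
    """Offset o such that E_z[expit(o + k z)] = p for z ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    wsum = weights.sum()

    def marginal(o):
        return float(np.dot(weights, special.expit(o + k * nodes)) / wsum)

    return optimize.brentq(lambda o: marginal(o) - p, -40.0, 40.0, xtol=1e-10)


def _snap(raw: np.ndarray, step: int) -> np.ndarray:
    """Clip to [0, 100] and round to the confidence grid."""
    g = np.clip(np.round(raw / step) * step, 0, 100)
    return g.astype(int)


def simulate_test1(config: ParadigmConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per (subject, question) with the Test1 fields filled.

    Skipped trials (no answer supplied) carry confidence 0 and are incorrect.
    Recognition cohorts additionally receive rare timeout and
    selection-mistake flags, which downstream exclusion rules remove.
    """
    n = config.n_subjects * config.n_questions
    subj = np.repeat(np.arange(config.n_subjects), config.n_questions)
    quest = np.tile(np.arange(config.n_questions), config.n_subjects)

    z = rng.standard_normal(n)
    p = config.p_correct_test1
    if p <= 0.0:
        correct = np.zeros(n, dtype=bool)
    elif p >= 1.0:
        correct = np.ones(n, dtype=bool)
    else:
        offset = _marginal_logit_offset(p, config.knowledge_scale)
        correct = rng.random(n) < special.expit(offset + config.knowledge_scale * z)

    raw = (
        config.confidence_mean
        + config.confidence_gain * z
        + rng.normal(0.0, config.confidence_sd, n)
    )
    conf = _snap(raw, config.confidence_step)
    skipped = (
        (conf == 0) & ~correct & (rng.random(n) < config.p_skip_given_zero)
    )

    trials = pd.DataFrame(
        {
            "subject_id": subj,
            "question_id": quest,
            "test1_correct": correct,
            "test1_confidence": conf,
            "skipped": skipped,
        }
    )
    if config.paradigm == "recognition":
        timeout = rng.random(n) < config.timeout_rate
        mistake = ~timeout & (rng.random(n) < config.mistake_rate)
        trials.loc[timeout, ["test1_correct", "skipped"]] = [False, False]
        trials.loc[timeout | mistake, "test1_confidence"] = 0
        trials["test1_timeout"] = timeout
        trials["test1_mistake"] = mistake
    return trials


# ---------------------------------------------------------------------------
# Feedback assignment (recall only)

def assign_feedback(
    trials: pd.DataFrame, config: ParadigmConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign veridical/false feedback by the confidence-dependent rule.

    No false feedback is ever shown above confidence 70 (participants must
    stay naive to the manipulation); below 60 the false answer is shown on
    75% of trials, between 60 and 70 inclusive on 60% of trials, regardless
    of accuracy (which is unknown at feedback time for typed answers).
    """
    if config.paradigm != "recall":
        raise ConfigError("false feedback exists only in the recall paradigm")
    out = trials.copy()
    conf = out["test1_confidence"].to_numpy()
    p_false = np.where(
        conf > 70, 0.0, np.where(conf < 60, config.p_false_low, config.p_false_mid)
    )
    is_false = rng.random(len(out)) < p_false
    out["feedback_kind"] = np.where(is_false, "false", "veridical")
    # rare: an incorrect typed answer happens to match the false feedback
    matches = (
        is_false
        & ~out["test1_correct"].to_numpy(dtype=bool)
        & (rng.random(len(out)) < config.p_answer_matches_false)
    )
    out["answer_matches_false_feedback"] = matches
    return out


# ---------------------------------------------------------------------------
# Test2

def simulate_test2(
    trials: pd.DataFrame, config: ParadigmConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill the Test2 outcome and confidence columns.

    For Test1-incorrect trials the correction probability is
    clamp(a + b |PE|, 0, 1) and corrected trials draw their confidence from
    clamp(c + d |PE| + noise) on the rating grid. Correct veridical trials
    revert to incorrect at a small fixed rate; correct trials met with false
    feedback adopt the false answer with probability increasing in |PE|.
    """
    out = trials.copy()
    if "feedback_kind" not in out.columns:
        if config.paradigm == "recall":
            raise ValueError("feedback must be assigned before simulating Test2")
        out["feedback_kind"] = "veridical"
    n = len(out)
    correct1 = out["test1_correct"].to_numpy(dtype=bool)
    conf1 = out["test1_confidence"].to_numpy()
    false_fb = out["feedback_kind"].to_numpy() == "false"
    mag = np.where(correct1 & false_fb, conf1, np.where(correct1, 0, conf1))

    outcome = np.empty(n, dtype=object)
    conf2 = np.zeros(n, dtype=float)

    # Test1 incorrect (including skips): learn the feedback answer or not
    inc = ~correct1
    p2 = np.clip(
        config.updating_intercept + config.updating_slope * mag, 0.0, 1.0
    )
    corrected = inc & (rng.random(n) < p2)
    outcome[corrected] = np.where(
        false_fb[corrected], "false_feedback_answer", "correct"
    )
    conf2[corrected] = (
        config.confidence_updating_intercept
        + config.confidence_updating_slope * mag[corrected]
        + rng.normal(0.0, config.confidence_updating_sd, int(corrected.sum()))
    )
    uncorr = inc & ~corrected
    outcome[uncorr] = "incorrect"
    conf2[uncorr] = rng.normal(
        config.uncorrected_confidence_mean,
        config.uncorrected_confidence_sd,
        int(uncorr.sum()),
    )
    # rare: despite false feedback, the originally studied answer resurfaces
    resurface = uncorr & false_fb & (rng.random(n) < config.p_correct_wrt_text)
    outcome[resurface] = "correct_wrt_text"

    # Test1 correct, veridical feedback: mostly retained
    cv = correct1 & ~false_fb
    revert = cv & (rng.random(n) < config.reversion_rate)
    outcome[revert] = "incorrect"
    conf2[revert] = rng.normal(
        config.reverted_confidence_mean, config.confidence_sd, int(revert.sum())
    )
    retain = cv & ~revert
    outcome[retain] = "correct"
    conf2[retain] = conf1[retain] + rng.normal(
        0.0, config.retained_confidence_drift_sd, int(retain.sum())
    )

    # Test1 correct, false feedback: misinformation may supplant the memory
    cf = correct1 & false_fb
    p_adopt = np.clip(
        config.false_adoption_intercept + config.false_adoption_slope * mag,
        0.0,
        1.0,
    )
    adopt = cf & (rng.random(n) < p_adopt)
    outcome[adopt] = "false_feedback_answer"
    conf2[adopt] = (
        config.false_confidence_intercept
        + config.false_confidence_slope * mag[adopt]
        + rng.normal(0.0, config.confidence_updating_sd, int(adopt.sum()))
    )
    keep = cf & ~adopt
    revert2 = keep & (rng.random(n) < config.reversion_rate)
    outcome[revert2] = "incorrect"
    conf2[revert2] = rng.normal(
        config.reverted_confidence_mean, config.confidence_sd, int(revert2.sum())
    )
    keep2 = keep & ~revert2
    outcome[keep2] = "correct"
    conf2[keep2] = conf1[keep2] + rng.normal(
        0.0, config.retained_confidence_drift_sd, int(keep2.sum())
    )

    out["test2_outcome"] = outcome
    out["test2_confidence"] = _snap(conf2, config.confidence_step)
    if config.paradigm == "recognition":
        timeout = rng.random(n) < config.timeout_rate
        mistake = ~timeout & (rng.random(n) < config.mistake_rate)
        out["test2_timeout"] = timeout
        out["test2_mistake"] = mistake
    return out


def simulate_cohort(
    config: ParadigmConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Full two-test cohort: Test1, feedback (recall), Test2."""
    trials = simulate_test1(config, rng)
    if config.paradigm == "recall":
        trials = assign_feedback(trials, config, rng)
    return simulate_test2(trials, config, rng)


# ---------------------------------------------------------------------------
# Event schedules

def jitter_distribution(
    lo: float, hi: float, median: float, grid: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized truncated-exponential jitter with the requested median.

    Support is the ``grid``-spaced points of [lo, hi]; weights decay
    geometrically (right-skewed, as is conventional for fMRI jitter). The
    decay rate is tuned to the midpoint of the interval over which the
    population median equals the target median: the CDF crosses 0.5 exactly
    at the requested value.
    """
    values = np.round(np.arange(lo, hi + grid / 2, grid), 6)
    k = np.searchsorted(values, median, side="right")
    if k == 0 or k > len(values):
        raise ConfigError("median outside jitter range")

    def cdf_at(lam: float, j: int) -> float:
        w = np.exp(-lam * (values - lo))
        w /= w.sum()
        return float(w[:j].sum())

    # feasible lam: CDF(median) > 0.5 and CDF(median - grid) < 0.5
    lam_hi_bound = 50.0
    if cdf_at(0.0, k) >= 0.5:
        lam_min = 0.0
    else:
        lam_min = optimize.brentq(
            lambda l: cdf_at(l, k) - 0.5, 0.0, lam_hi_bound, xtol=1e-12
        )
    if k == 1:
        lam_max = lam_min + 1.0
    else:
        if cdf_at(lam_hi_bound, k - 1) < 0.5:
            raise ConfigError(f"cannot place median {median} on grid [{lo}, {hi}]")
        lam_max = optimize.brentq(
            lambda l: cdf_at(l, k - 1) - 0.5, 0.0, lam_hi_bound, xtol=1e-12
        )
    if lam_max <= lam_min:
        raise ConfigError(f"cannot place median {median} on grid [{lo}, {hi}]")
    lam = 0.5 * (lam_min + lam_max)
    probs = np.exp(-lam * (values - lo))
    probs /= probs.sum()
    cdf = np.cumsum(probs)
    below = cdf[k - 2] if k >= 2 else 0.0
    if not (below < 0.5 <= cdf[k - 1]):
        raise ConfigError(f"cannot place median {median} on grid [{lo}, {hi}]")
    return values, probs


def _draw_jitter(rng, n, lo, hi, median):
    values, probs = jitter_distribution(lo, hi, median)
    return rng.choice(values, size=n, p=probs)


def _lognormal_rt(rng, n, median, sigma, lo, hi):
    return np.clip(rng.lognormal(np.log(median), sigma, n), lo, hi)


def generate_event_schedule(
    trials: pd.DataFrame,
    timing: TimingConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Jittered event-related timeline for one subject's Test1 session.

    Trials are taken in row order and chunked into ``n_runs`` runs of
    ``run_length_trials``. Each trial contributes four events — question
    (duration = response time), response (selection highlight), confidence,
    and feedback (fixed duration) — separated by jittered gaps whose range
    and median follow the timing configuration. Onsets restart at zero in
    each run. Trial metadata needed by the GLM stage (accuracy, PE,
    transition, Test2 confidence, nuisance flags) is carried along.
    """
    if trials["subject_id"].nunique() != 1:
        raise ValueError("schedules are generated per subject")
    need = timing.n_runs * timing.run_length_trials
    if len(trials) < need:
        raise ValueError(
            f"need {need} trials for {timing.n_runs} runs of "
            f"{timing.run_length_trials}, got {len(trials)}"
        )
    trials = trials.iloc[:need]
    n = len(trials)

    q_rt = _lognormal_rt(
        rng, n, timing.question_rt_median, timing.question_rt_sigma,
        1.5, timing.question_rt_max,
    )
    c_rt = _lognormal_rt(
        rng, n, timing.confidence_rt_median, timing.confidence_rt_sigma,
        0.5, timing.confidence_rt_max,
    )
    g_rc = _draw_jitter(rng, n, *timing.resp_to_conf_range, timing.resp_to_conf_median)
    g_cf = _draw_jitter(
        rng, n, *timing.conf_to_feedback_range, timing.conf_to_feedback_median
    )
    iti = _draw_jitter(rng, n, *timing.iti_range, timing.iti_median)

    has_pe = "pe" in trials.columns
    nuis = np.zeros(n, dtype=bool)
    for c in ("test1_timeout", "test1_mistake"):
        if c in trials.columns:
            nuis |= trials[c].to_numpy(dtype=bool)

    rows = []
    for run in range(timing.n_runs):
        t = timing.lead_in
        for j in range(timing.run_length_trials):
            i = run * timing.run_length_trials + j
            tr_row = trials.iloc[i]
            meta = dict(
                run=run,
                trial=j,
                question_id=tr_row["question_id"],
                test1_correct=bool(tr_row["test1_correct"]),
                pe=int(tr_row["pe"]) if has_pe else np.nan,
                test2_outcome=tr_row.get("test2_outcome", np.nan),
                test2_confidence=tr_row.get("test2_confidence", np.nan),
                nuisance=bool(nuis[i]),
            )
            q_on = t
            r_on = q_on + q_rt[i]
            conf_on = r_on + g_rc[i]
            fb_on = conf_on + c_rt[i] + g_cf[i]
            rows.append({**meta, "event_type": "question", "onset": q_on,
                         "duration": q_rt[i]})
            rows.append({**meta, "event_type": "response", "onset": r_on,
                         "duration": timing.response_duration})
            rows.append({**meta, "event_type": "confidence", "onset": conf_on,
                         "duration": c_rt[i]})
            rows.append({**meta, "event_type": "feedback", "onset": fb_on,
                         "duration": timing.feedback_duration})
            t = fb_on + timing.feedback_duration + iti[i]
    sched = pd.DataFrame(rows)
    sched["onset"] = sched["onset"].round(4)
    sched["duration"] = sched["duration"].round(4)
    return sched


def n_volumes_per_run(schedule: pd.DataFrame, timing: TimingConfig) -> list[int]:
    """Volumes needed to cover each run plus the post-run rest period."""
    out = []
    for run in range(timing.n_runs):
        s = schedule[schedule["run"] == run]
        end = (s["onset"] + s["duration"]).max() + timing.post_run_rest
        out.append(int(np.ceil(end / timing.tr)))
    return out


# ---------------------------------------------------------------------------
# BOLD simulation

def simulate_bold(
    schedule: pd.DataFrame,
    voxel_spec: VoxelSpec,
    timing: TimingConfig,
    rng: np.random.Generator,
):
    """Forward-model BOLD data with planted voxel populations.

    Each voxel's series is (ground-truth design) x (population betas) plus
    stationary AR(1) Gaussian noise. The ground-truth design is the union of
    the PE-encoding and subsequent-memory design columns (no spike zeroing),
    so populations can load on modulators from either model. Returns
    ``(data, labels, info)`` where data is voxel x time over the concatenated
    runs and labels gives each voxel's population name.
    """
    from .glm import DesignSpec, build_design_matrix

    nvols = n_volumes_per_run(schedule, timing)
    pe_dm = build_design_matrix(schedule, DesignSpec(model="pe"), timing.tr, nvols)
    mem_dm = build_design_matrix(
        schedule, DesignSpec(model="memory"), timing.tr, nvols
    )
    truth = pe_dm.frame.copy()
    for c in mem_dm.frame.columns:
        if c not in truth.columns:
            truth[c] = mem_dm.frame[c]

    n_t = len(truth)
    n_vox = voxel_spec.n_total
    labels = voxel_spec.labels()

    beta_mat = np.zeros((n_vox, truth.shape[1]))
    colindex = {c: i for i, c in enumerate(truth.columns)}
    i = 0
    for pop in voxel_spec.populations:
        for cname, amp in pop.betas.items():
            if cname not in colindex:
                raise ValueError(f"unknown design column {cname!r} in population "
                                 f"{pop.name!r}")
            beta_mat[i:i + pop.n_voxels, colindex[cname]] = amp
        i += pop.n_voxels

    data = beta_mat @ truth.to_numpy().T
    if voxel_spec.noise_sd > 0:
        white = rng.standard_normal((n_vox, n_t))
        rho = voxel_spec.ar1
        if rho > 0:
            innov_sd = voxel_spec.noise_sd * np.sqrt(1.0 - rho**2)
            noise = signal.lfilter([1.0], [1.0, -rho], white, axis=1) * innov_sd
        else:
            noise = white * voxel_spec.noise_sd
        data = data + noise
    info = {
        "n_volumes_per_run": nvols,
        "tr": timing.tr,
        "shape": voxel_spec.shape,
        "columns": list(truth.columns),
    }
    return data, labels, info
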