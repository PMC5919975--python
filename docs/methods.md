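# Methods

`sempe` models declarative (semantic) learning as prediction-error-driven
updating, in the style of Rescorla–Wagner reinforcement learning, and packages
the full analysis chain for a two-test feedback paradigm: trial-level PE
computation, behavioral updating statistics, and event-related fMRI GLMs with
conjunction inference. Because no raw study data are deposited anywhere, the
package ships a synthetic-data generator whose defaults encode the paradigm's
stated conditions; every analysis is exercised and validated against planted
ground truth.

## The prediction-error model

On Test1 a participant answers a factual question and rates their confidence
c ∈ [0, 100], a proxy for the strength of the memory-based expectation that
the upcoming feedback will confirm the answer. The feedback then elicits a
signed prediction error:

* incorrect answer: PE = −c (the outcome is worse than expected);
* correct answer: PE = 100 − c (better than expected);
* correct answer met with deliberately **false** feedback: PE = −c — the
  feedback disconfirms an answer that was in fact right, so the sign follows
  the *apparent* outcome. (The scalar `compute_pe` implements the two-branch
  rule; the table-level derivation applies the false-feedback override.)

PEs therefore span −100…+99 in the recall paradigm; +100 cannot occur because
correct answers rated with zero confidence are excluded as trivially
anomalous.

Binning schemes for the recall analyses:

* `four_bin`: zero PE (skips and zero-confidence errors), low (|PE| 1–33),
  medium (34–66), high (67–100);
* `false_two_bin` (correct + false feedback only, |PE| ≤ 70 by the design's
  naivety cap): low |PE| 1–49, medium 50–70. The printed bin edges overlap at
  49; we adopt the closed-left convention (−49 → low) and expose
  `two_bin_edge` to flip it;
* `rank_tertile`: within-subject ranks of the nonzero PEs split into three
  equal-count groups (stable sort for determinism) — a control for unequal
  bin occupancy.

## Synthetic behavioral cohorts

Each trial carries a latent knowledge strength z ~ N(0, 1).

* Test1 accuracy: Bernoulli with a logistic link, P(correct | z) =
  expit(o + k·z); the offset o is solved by Gauss–Hermite quadrature so the
  *marginal* hit rate equals `p_correct_test1` (0.36 recall, 0.59
  recognition).
* Test1 confidence: linear readout `confidence_mean + confidence_gain·z`
  plus N(0, `confidence_sd`) noise, clipped to [0, 100] and snapped to the
  rating grid (integers for recall, steps of 10 for the in-scanner
  visual-analog scale). The defaults (recall 32 + 60·z, sd 15, k = 2;
  recognition 55 + 40·z, sd 15, k = 2) were calibrated once against the
  reported marginals — mean confidence ≈ 70 for correct recall answers, ~56%
  of correct answers above the false-feedback cap of 70, ~29% zero-confidence
  trials in recall vs ~12% in recognition — and then frozen.
* Skips: an incorrect trial whose snapped confidence is 0 is a skip with
  probability 0.9 (answered-with-zero-confidence errors are rare but exist).
  Skips are eligible for false feedback (the 0-confidence < 60 arm), since
  answer veracity is unknown at feedback time.
* False feedback (recall only): confidence > 70 → always veridical (hard
  cap); confidence < 60 → false with probability 0.75; 60 ≤ confidence ≤ 70 →
  false with probability 0.60, independently across trials.
* Test2 updating for Test1-incorrect trials: P(corrected) =
  clamp(a + b·|PE|, 0, 1) with recall defaults a = 0.20, b = 0.004 and
  recognition defaults a = 0.292, b = 0.0055 (the reported fitted lines on
  the percent scale: intercept 29.2%, slope 0.55%/unit). Corrected trials
  draw Test2 confidence from clamp(c + d·|PE| + noise) on the grid
  (recognition c = 45, d = 0.43). When the feedback was false, "corrected"
  means adopting the false answer — Test2 accuracy is scored against the
  feedback, not the original text.
* Test1-correct trials revert to incorrect at fixed rates (11.9% recall,
  8.6% recognition). Correct trials given false feedback adopt it with
  probability clamp(0.18 + 0.0056·|PE|), with adopted-answer confidence
  rising in |PE|; these defaults reproduce the reported low/medium adoption
  contrast (≈32% vs ≈52%).
* Rare nuisance events are planted so the exclusion rules have work to do:
  recognition timeouts and selection mistakes (1% each), incorrect answers
  matching the false feedback (1%), and original-text answers resurfacing
  after false feedback (2%).

What the generator does **not** emulate: question content and semantic
similarity between answers and feedback, item-level difficulty structure,
session-order effects, and any dependence between trials. Passing tests
therefore demonstrate that the analysis chain is correct and calibrated under
the assumed generative structure, not that the substantive findings hold in
real data.

## Event schedules and BOLD simulation

The in-scanner session is two runs of 50 trials (TR 2 s). Each trial emits
four events — question (duration = response time), response highlight
(0.5 s), confidence rating, feedback (4.5 s; 5.5 s in the recall timing) —
separated by jittered gaps with the stated range/median: response→confidence
1–3 s (median 2), confidence→feedback 3–10 s (median 5), intertrial 3–7 s
(median 4). Only ranges and medians are stated, so the jitter law is a
choice: a truncated, discretized (0.5 s grid) exponential whose decay rate is
solved (midpoint of the feasible interval) so the population median sits
exactly on the stated value. Response times, never reported, are log-normal
(median 6 s for the question phase, 2.5 s for the rating; both truncated).
Runs come out at ≈ 640 volumes (21 min), matching the stated 20–25 min.

BOLD data are forward-modelled as design × betas + AR(1) Gaussian noise
(stationary sd 1, lag-1 correlation 0.3). Planted populations occupy
contiguous blocks of a 3-D grid (so true effects form clusters) and load on
named design columns:

| population | loadings (BOLD units) |
|---|---|
| signed_pe | +0.4 feedback-correct, −0.4 feedback-incorrect, +0.01/PE-unit on both parametric modulators |
| unsigned_pe | +0.01 on the correct-side modulator, −0.01 on the incorrect-side (V-shaped in PE) |
| inverse_unsigned | the negation (largest response to small PEs) |
| memory_confidence | −0.008/confidence-point on the Test2-confidence modulators |
| memory_accuracy | +0.4 incorrect-to-correct, −0.4 incorrect-to-incorrect |

A modulator loading of 0.01 BOLD units per PE unit against unit noise yields
single-subject parametric t values of a few — the regime of a solid
event-related effect — and was fixed once as the default signal strength.

## Design matrices and GLM

Events are modelled as boxcars of their duration convolved with a canonical
double-gamma HRF (main lobe peaking at 5 s, undershoot at 15 s, undershoot
1/6 the peak amplitude, unit-peak normalized; convolution on a 0.1 s grid,
sampled at the TR). Parametric modulators (trial PE, or Test2 confidence in
the subsequent-memory model) scale the boxcar and are mean-centred within
their parent condition per run, decorrelating modulation from the mean event
response. Nuisance feedback events (timeouts, selection mistakes) get their
own regressor; per-run constants complete the design. Rows at motion-spike
volumes and their ±1 neighbours are zeroed across all columns and dropped
from the fit; residual dof = volumes used − rank(design).

Estimation is per-voxel OLS (classical t statistics; no prewhitening — the
group level absorbs within-subject serial correlation because subject-level
estimates enter a between-subject one-sample t). `EventRelatedGLM.fit()`
returns a results object exposing betas, arbitrary contrasts, and their
t/p maps; a test verifies equality with a direct normal-equations solve to
1e−8, and the HRF convolution is cross-checked against nilearn's regressor
builder.

## Conjunction inference

Group maps are summary-statistics random effects: a one-sample t across
subjects' contrast effect images. A conjunction admits a voxel only when
every component map is individually significant *in its required direction*
at the per-map threshold α = p^(1/n), so the combined null rate is p = αⁿ
(n = 3 and p = 0.001 give α = 0.1). Thresholds are one-sided, which is what
makes the combined rate exactly αⁿ under the null. Components:

* signed PE (n = 3): feedback-correct > feedback-incorrect, +correct-side
  modulator, +incorrect-side modulator — activity rising monotonically from
  large negative to large positive PE;
* unsigned PE (n = 2): +correct-side, −incorrect-side modulator (V-shaped
  salience response);
* inverse-unsigned: both signs flipped.

Surviving voxels are cluster-filtered (18-neighbour connectivity, minimum 10
voxels; both configurable) and inventoried (size, peak voxel, peak
statistic). ROI-restricted subsequent-memory tests then take subject-mean
betas per ROI from the memory-model GLM: a paired t of incorrect-to-correct
vs incorrect-to-incorrect feedback betas and a one-sample t of the
Test2-confidence modulator betas, both two-tailed at 0.05.

## Behavioral statistics

* Subsequent accuracy per subject × bin: 100 × corrected / Test1-incorrect.
* One-way repeated-measures ANOVA over bins (statsmodels `AnovaRM`), with
  missing cells replaced by the bin's across-subject mean before fitting; no
  degrees-of-freedom adjustment and no sphericity correction (dfs are k−1,
  (k−1)(n−1)). A `drop_incomplete` sensitivity mode deletes incomplete
  subjects instead. Post hoc paired t tests are Bonferroni-corrected by the
  number of pairs (6 for four bins), capped at 1.
* Overall updating per unique Test1 PE value: Σ(Test2 confidence of corrected
  answers, 0 if uncorrected) / #incorrect — equal to correction rate × mean
  confidence among corrected; undefined (absent), not 0, where no incorrect
  trials exist.
* PE regressions (recognition's 11-value grid): per-subject OLS of the
  outcome on |PE|, a one-sample t on the subject slopes, and an unweighted
  OLS on the across-subject median outcome per |PE| value. Subjects with
  fewer than two distinct PE values are dropped with a warning. All tests
  two-tailed.
* False-memory comparisons on the correct + false-feedback subset: paired t
  of per-subject adoption percentages (medium vs low bin), dropping subjects
  lacking either bin (mean replacement is unsuitable for a two-condition
  within-subject test); and a fixed-effects two-sample t of Test2
  confidences of adopted answers pooled across subjects.

Zero-variance degenerate inputs (identical conditions) yield t = 0, p = 1
rather than NaN, matching the natural "no evidence" reading.

### A note on the group-median slope

The group-median regression is faithful to the reported analysis but is not
an unbiased estimator of the generative accuracy slope: at high |PE| each
subject contributes only one or two incorrect trials, so the across-subject
median of per-subject proportions saturates at 100% (the same saturation is
visible in the reported median of 100% at −100 PE against a fitted line
reaching 84%). Under the default recognition conditions the median-path
slope estimate runs ≈ 0.2 above the planted 0.55%/unit. The recovery tests
therefore assert unbiased recovery on the subject-level mean slope (and on
the continuous confidence slope), and check the group-median slope against a
Monte-Carlo band of its own sampling distribution. The confidence outcome,
being continuous, does not saturate.

## Reproducibility and problem sizes

A single seed is fanned out to named substreams
(`substream(seed, stage)` via `SeedSequence` spawn keys), so adding a
pipeline stage never perturbs earlier stages' draws; identical
(config, seed) pairs give byte-identical tables and arrays. The shipped
validation sizes were chosen to give stable Monte-Carlo statistics at
interactive runtimes: 10,000 draws for the feedback-rate checks, 12,500 null
voxels × 8 subjects for the conjunction null calibration, 500 replicate
cohorts for the type-I-error check, and 12 subjects × 2,000 voxels × 2 runs
for the end-to-end recovery experiment.

## Known limitations

* Confidence distributions beyond the reported means are guesswork; only the
  marginals listed above are calibrated.
* The semantic-content dimension of PEs (how *wrong* an answer is, not just
  how confidently held) is out of scope.
* OLS with AR(1) noise slightly miscalibrates single-subject p values; all
  shipped inference is group-level, where calibration is exact by
  construction, and the single-subject calibration test uses white noise.
* No spatial preprocessing (motion correction, smoothing, normalization) is
  modelled; cluster geometry in the simulations is idealized.
* Whether the confidence-rating epoch carried its own modulator, and the
  scanner's exact HRF parameters, are unknowable from the available
  description; the defaults above are conventional choices exposed in
  `HRFParams`/`DesignSpec`.
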