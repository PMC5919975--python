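# sempe — semantic prediction errors and declarative memory updating

`sempe` is a simulation-and-analysis toolkit for studying whether declarative
(factual) learning follows the same prediction-error rules as reinforcement
learning. It targets a two-test feedback paradigm: participants study a
factual text, answer 100 questions with 0–100 confidence ratings (Test1),
receive feedback — occasionally deliberately false — and are retested a week
later (Test2). The confidence rating acts as the expectation term, so each
feedback event carries a signed prediction error

```
PE = −confidence          (incorrect answer: worse than expected)
PE = 100 − confidence     (correct answer: better than expected)
```

and the package quantifies how strongly |PE| drives later memory: correction
of errors, confidence in corrected answers, adoption of misinformation in
place of accurate memories, and — in the in-scanner variant — voxelwise BOLD
responses that track signed or unsigned PE.

It is aimed at computational cognitive neuroscientists who want a tested,
reproducible implementation of this analysis chain, with a synthetic-data
generator (planted ground truth) standing in for the undeposited study data.

## What's inside

* `sempe.paradigm` — synthetic cohorts: latent-knowledge model for Test1
  accuracy/confidence, the confidence-capped false-feedback rule (75% below
  confidence 60, 60% between 60 and 70, never above 70), |PE|-linear Test2
  updating, jittered event-related scan timelines, and BOLD forward
  simulation with five planted voxel populations plus null filler.
* `sempe.pe` — trial PEs, Test1→Test2 transition labels (feedback-referenced
  scoring), exclusion rules, and three PE binning schemes (four-bin,
  false-feedback two-bin, rank tertiles).
* `sempe.behavior` — bin-wise subsequent accuracy and confidence,
  repeated-measures ANOVA with condition-mean imputation and Bonferroni post
  hocs, the overall-updating score, per-subject and group-median PE
  regressions (`PERegression(...).fit()` → results with `summary()`), and
  the false-memory comparisons.
* `sempe.glm` — double-gamma HRF, duration-convolved design matrices with
  mean-centred parametric modulators and spike-row zeroing, and massively
  univariate OLS (`EventRelatedGLM(...).fit()` → betas, contrasts, t maps).
* `sempe.group` — random-effects group t maps, α = p^(1/n) conjunction
  inference (signed, unsigned, inverse-unsigned PE), cluster filtering, and
  ROI-restricted subsequent-memory tests.
* `sempe.pipeline` / `sempe.cli` — seeded, reproducible end-to-end runs
  (`sempe run`, `sempe simulate behavior|bold`, `sempe analyze
  behavior|fmri`).

See `docs/methods.md` for the model, parameter defaults, and validation
design.

## Worked example

Simulate the recall study at its native size (20 subjects × 100 questions)
and run the behavioral analyses:

```bash
sempe run --seed 2 --out demo/
cat demo/report.txt
```

```
One-way repeated-measures ANOVA: F(3,57) = 30.4, p = 7.37e-12 (0 cells mean-imputed)
Post hoc paired t-tests (Bonferroni corrected):
  high vs low: t(19) = 6.23, p_corrected = 3.297e-05
  high vs medium: t(19) = 4.5, p_corrected = 0.001477
  high vs zero: t(19) = 9.89, p_corrected = 3.748e-08
  low vs medium: t(19) = -1.67, p_corrected = 0.6709
  low vs zero: t(19) = 2.47, p_corrected = 0.14
  medium vs zero: t(19) = 4.33, p_corrected = 0.002158

False-feedback adoption (correct Test1 trials):
  mean adoption low = 38.3%, medium = 57.0%; paired t(19) = 2.3, p = 0.03272 (0 subjects lacking a bin excluded)
  pooled Test2 confidence of adopted false answers: low = 60.4, medium = 71.2; fixed-effects t(91) = 3.54, p = 0.0006433
```

Reading this: Test2 accuracy for initially wrong answers climbs with the PE
of the feedback (the high-|PE| bin is corrected far more often than the
zero-PE bin — the hypercorrection pattern), and accurate memories held with
medium confidence are *more* readily supplanted by false feedback than
weakly held ones, with higher confidence in the implanted false memory.

The same entry point runs the in-scanner variant with BOLD simulation and
conjunction inference:

```python
from sempe.pipeline import RunConfig, run_pipeline

run_pipeline(RunConfig(seed=2, out_dir="demo_fmri", paradigm="recognition",
                       n_subjects=27, run_fmri=True))
```

which writes, alongside the behavioral regressions (per-subject slopes of
Test2 accuracy/confidence on |PE| and their group tests), the conjunction
masks (`conjunction_maps.npz`), cluster inventories (`clusters_signed.tsv`,
…) and ROI subsequent-memory statistics (`roi_memory_stats.tsv`).

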