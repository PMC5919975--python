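"""End-to-end reproducible runs: simulate, analyze, write artifacts.

A :class:`RunConfig` plus a single seed fully determines every output. The
global seed is fanned out to named per-stage substreams, so adding a stage
never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, io
from . import pe as pe_mod
from .config import (
    ParadigmConfig,
    TimingConfig,
    VoxelSpec,
    default_voxel_populations,
    substream,
)
from .glm import DesignSpec, build_design_matrix, fit_glm, subject_pe_contrasts
from .group import pe_conjunctions, subsequent_memory_tests
from .paradigm import (
    generate_event_schedule,
    n_volumes_per_run,
    simulate_bold,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "default_timing"]

logger = logging.getLogger("sempe")


def default_timing(paradigm: str) -> TimingConfig:
    """Feedback lasts 4.5 s in the scanner, 5.5 s in the recall study."""
    return TimingConfig(feedback_duration=4.5 if paradigm == "recognition" else 5.5)


@dataclass
class RunConfig:
    """Everything one pipeline run needs besides the seed."""

    seed: int = 0
    out_dir: str = "sempe_run"
    paradigm: str = "recall"
    n_subjects: int = 20
    paradigm_overrides: dict = field(default_factory=dict)
    timing_overrides: dict = field(default_factory=dict)
    scheme: str = "four_bin"
    run_fmri: bool = False
    fmri_n_subjects: int = 8
    fmri_voxels_per_population: int = 30
    combined_p: float = 0.001
    min_cluster_voxels: int = 10
    verbosity: str = "info"

    _KEYS = (
        "seed", "out_dir", "paradigm", "n_subjects", "paradigm_overrides",
        "timing_overrides", "scheme", "run_fmri", "fmri_n_subjects",
        "fmri_voxels_per_population", "combined_p", "min_cluster_voxels",
        "verbosity",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_yaml_config(path, cls._KEYS))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._KEYS}

    def paradigm_config(self) -> ParadigmConfig:
        factory = (
            ParadigmConfig.recognition
            if self.paradigm == "recognition"
            else ParadigmConfig.recall
        )
        return factory(n_subjects=self.n_subjects, **self.paradigm_overrides)

    def timing_config(self) -> TimingConfig:
        base = default_timing(self.paradigm).to_dict()
        base.update(self.timing_overrides)
        for k in ("iti_range", "resp_to_conf_range", "conf_to_feedback_range"):
            base[k] = tuple(base[k])
        return TimingConfig(**base)


def _setup_logging(out: Path, verbosity: str) -> None:
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    logger.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(out / "log.txt", mode="w")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _behavior_stage(config: RunConfig, out: Path) -> pd.DataFrame:
    pcfg = config.paradigm_config()
    rng = substream(config.seed, "behavior")
    trials = simulate_cohort(pcfg, rng)
    io.write_trials(out / "trials.tsv", trials)
    logger.info("simulated %d trials (%d subjects, %s paradigm)",
                len(trials), pcfg.n_subjects, pcfg.paradigm)

    derived = pe_mod.add_derived(trials)
    derived, exclusions = pe_mod.apply_exclusions(derived)
    kept = behavior.prepare(derived)
    for scheme in ("four_bin", "rank_tertile"):
        kept = pe_mod.assign_bins(kept, scheme)
    io.write_trials(out / "derived.tsv", kept)
    logger.info("excluded %d trials (%s)", len(exclusions),
                dict(exclusions["exclusion_reason"].value_counts()))

    results: dict = {"n_trials": len(trials), "n_excluded": len(exclusions)}
    acc = behavior.subsequent_accuracy(kept, config.scheme, prepared=True)
    acc.to_csv(out / "subsequent_accuracy.tsv", sep="\t", index=False)
    mat = behavior.subject_bin_matrix(acc, "subsequent_accuracy")
    report = []
    if config.paradigm == "recall":
        anova = behavior.rm_anova(mat)
        results["accuracy_anova"] = {
            "F": anova.F, "df": [anova.df_effect, anova.df_error],
            "p": anova.p_value, "n_imputed": anova.n_imputed,
        }
        report.append(anova.summary())
        fm = behavior.false_memory_tests(kept, prepared=True)
        results["false_memory"] = {
            "paired_t": fm.paired_t, "paired_p": fm.paired_p,
            "pooled_t": fm.pooled_t, "pooled_p": fm.pooled_p,
        }
        report.append(fm.summary())
    else:
        for outcome in ("accuracy", "confidence", "overall_updating"):
            reg = behavior.pe_regressions(kept, outcome, prepared=True)
            results[f"{outcome}_regression"] = {
                "mean_beta": reg.mean_beta,
                "t": reg.t_statistic, "p": reg.t_p_value,
                "group_median_beta": reg.group_median.beta,
                "group_median_intercept": reg.group_median.intercept,
                "group_median_r_squared": reg.group_median.r_squared,
            }
            report.append(reg.summary())
    (out / "behavior_results.json").write_text(json.dumps(results, indent=1))
    (out / "report.txt").write_text("\n\n".join(report) + "\n")
    logger.info("behavioral analyses written")
    return kept


def _fmri_stage(config: RunConfig, out: Path) -> None:
    pcfg = ParadigmConfig.recognition(
        n_subjects=config.fmri_n_subjects, **config.paradigm_overrides
    )
    timing = config.timing_config()
    vspec = VoxelSpec(
        populations=default_voxel_populations(config.fmri_voxels_per_population),
    )
    rng = substream(config.seed, "fmri")
    trials = pe_mod.add_derived(simulate_cohort(pcfg, rng))

    contrasts: dict[str, list] = {}
    mem_betas: dict[str, list] = {}
    labels = vspec.labels()
    for sid, sub in trials.groupby("subject_id"):
        sched = generate_event_schedule(sub, timing, rng)
        if sid == 0:
            for r in range(timing.n_runs):
                io.write_events(out / f"events_run{r}.tsv", sched, run=r)
        data, labels, info = simulate_bold(sched, vspec, timing, rng)
        nvols = info["n_volumes_per_run"]
        pe_res = fit_glm(
            data, build_design_matrix(sched, DesignSpec(model="pe"),
                                      timing.tr, nvols)
        )
        for k, v in subject_pe_contrasts(pe_res).items():
            contrasts.setdefault(k, []).append(v)
        mem_res = fit_glm(
            data, build_design_matrix(sched, DesignSpec(model="memory"),
                                      timing.tr, nvols)
        )
        for k in ("feedback_itc", "feedback_iti", "feedback_itc_x_conf2"):
            mem_betas.setdefault(k, []).append(mem_res.beta(k))
        logger.info("fMRI subject %d fitted (%d voxels, %d volumes)",
                    sid, data.shape[0], data.shape[1])

    stacks = {k: np.vstack(v) for k, v in contrasts.items()}
    conj = pe_conjunctions(
        stacks, vspec.shape, config.combined_p, config.min_cluster_voxels
    )
    masks = {}
    for name, res in conj.items():
        masks[name] = res.mask
        res.clusters.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
        logger.info("%s conjunction: %d voxels in %d clusters",
                    name, res.n_voxels, len(res.clusters))
    np.savez_compressed(
        out / "conjunction_maps.npz", labels=labels.astype(str), **masks
    )

    rois = {
        name: res.roi_indices() for name, res in conj.items() if res.n_voxels
    }
    if rois:
        stats_table = subsequent_memory_tests(
            {k: np.vstack(v) for k, v in mem_betas.items()}, rois
        )
        stats_table.to_csv(out / "roi_memory_stats.tsv", sep="\t", index=False)
        logger.info("ROI subsequent-memory stats written")


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; outputs land in ``config.out_dir``.

    The directory receives a config snapshot and log; a ``INCOMPLETE``
    marker file is left behind if any stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.verbosity)
    (out / "config_snapshot.yaml").write_text(yaml.safe_dump(config.to_dict()))
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or failed\n")
    logger.info("sempe %s, seed %d, numpy %s",
                __version__, config.seed, np.__version__)
    try:
        _behavior_stage(config, out)
        if config.run_fmri:
            _fmri_stage(config, out)
    except Exception:
        logger.exception("pipeline failed")
        raise
    marker.unlink()
    logger.info("run complete")
    return out
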