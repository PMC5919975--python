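"""Configuration objects for the simulated paradigms.

Two study variants are supported:

* ``recall`` — typed cued-recall answers, free 0-100 confidence, false feedback
  allowed on low/medium-confidence trials.
* ``recognition`` — four-alternative forced choice in the scanner, confidence on
  a 0-100 visual-analog scale restricted to steps of 10, no false feedback.

Defaults encode the study conditions: 100 questions, two tests, false feedback
on 75% of sub-60-confidence trials and 60% of 60-70-confidence trials with a
hard veridical cap above confidence 70, and updating probabilities/confidences
that rise linearly with the absolute prediction error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "ParadigmConfig",
    "TimingConfig",
    "VoxelPopulation",
    "VoxelSpec",
    "ConfigError",
    "substream",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named, independent random substream derived from a single global seed.

    Each stage of the pipeline draws from its own stream, so adding a stage
    never perturbs the draws of earlier stages.
    """
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class ParadigmConfig:
    """Generative parameters for one behavioral cohort.

    The latent-knowledge model gives each trial a scalar strength z ~ N(0, 1);
    Test1 correctness follows a logistic link with offset chosen to hit
    ``p_correct_test1`` marginally, and confidence is a linear readout of z
    plus noise, clipped to [0, 100] and rounded to the confidence grid.

    Updating parameters are on the scale the behavioral results are reported
    on: ``updating_slope`` is the increase in Test2 correction *probability*
    per unit |PE| (0.0055 corresponds to the 0.55 percent-per-unit group
    slope), and the confidence intercept/slope are in confidence points.
    """

    n_subjects: int = 20
    n_questions: int = 100
    paradigm: str = "recall"  # or "recognition"
    confidence_step: int = 1
    p_correct_test1: float = 0.36

    # latent knowledge -> confidence readout
    knowledge_scale: float = 2.0
    confidence_mean: float = 32.0
    confidence_gain: float = 60.0
    confidence_sd: float = 15.0
    p_skip_given_zero: float = 0.9

    # Test2 updating for Test1-incorrect trials
    updating_intercept: float = 0.20   # a: P(correct2) at |PE| = 0
    updating_slope: float = 0.004      # b: dP/d|PE|
    confidence_updating_intercept: float = 55.0  # c
    confidence_updating_slope: float = 0.22      # d
    confidence_updating_sd: float = 15.0
    uncorrected_confidence_mean: float = 20.0
    uncorrected_confidence_sd: float = 15.0

    # Test1-correct trials
    reversion_rate: float = 0.119
    reverted_confidence_mean: float = 30.0
    retained_confidence_drift_sd: float = 10.0

    # false-feedback arm (recall only)
    p_false_low: float = 0.75
    p_false_mid: float = 0.60
    false_adoption_intercept: float = 0.18
    false_adoption_slope: float = 0.0056
    false_confidence_intercept: float = 45.0
    false_confidence_slope: float = 0.50
    p_answer_matches_false: float = 0.01
    p_correct_wrt_text: float = 0.02

    # recognition-only nuisance events
    timeout_rate: float = 0.01
    mistake_rate: float = 0.01

    seed: int | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in ("recall", "recognition"):
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")
        if self.n_subjects < 1 or self.n_questions < 1:
            raise ConfigError("n_subjects and n_questions must be positive")
        if self.confidence_step < 1 or 100 % self.confidence_step != 0:
            raise ConfigError("confidence_step must be a positive divisor of 100")
        for name in (
            "p_correct_test1", "p_skip_given_zero", "updating_intercept",
            "reversion_rate", "p_false_low", "p_false_mid",
            "false_adoption_intercept", "p_answer_matches_false",
            "p_correct_wrt_text", "timeout_rate", "mistake_rate",
        ):
            _check_prob(getattr(self, name), name)
        for name in ("confidence_sd", "confidence_updating_sd",
                     "uncorrected_confidence_sd", "retained_confidence_drift_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @classmethod
    def recall(cls, n_subjects: int = 20, **overrides) -> "ParadigmConfig":
        """Cued-recall defaults (behavioral study conditions)."""
        return cls(n_subjects=n_subjects, paradigm="recall", **overrides)

    @classmethod
    def recognition(cls, n_subjects: int = 27, **overrides) -> "ParadigmConfig":
        """In-scanner recognition defaults: coarser confidence grid, easier
        questions, steeper updating line, no false feedback."""
        defaults = dict(
            paradigm="recognition",
            confidence_step=10,
            p_correct_test1=0.59,
            confidence_mean=55.0,
            confidence_gain=40.0,
            updating_intercept=0.292,
            updating_slope=0.0055,
            confidence_updating_intercept=45.0,
            confidence_updating_slope=0.43,
            reversion_rate=0.086,
        )
        defaults.update(overrides)
        return cls(n_subjects=n_subjects, **defaults)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **changes) -> "ParadigmConfig":
        return replace(self, **changes)


@dataclass
class TimingConfig:
    """Event timing for the in-scanner paradigm (seconds).

    Jittered gaps are drawn from a truncated, discretized (0.5 s grid)
    exponential tuned so the population median equals the stated median.
    """

    tr: float = 2.0
    feedback_duration: float = 4.5
    iti_range: tuple[float, float] = (3.0, 7.0)
    iti_median: float = 4.0
    resp_to_conf_range: tuple[float, float] = (1.0, 3.0)
    resp_to_conf_median: float = 2.0
    conf_to_feedback_range: tuple[float, float] = (3.0, 10.0)
    conf_to_feedback_median: float = 5.0
    run_length_trials: int = 50
    n_runs: int = 2

    # response-time model (invented plumbing; the tests were self-paced)
    question_rt_median: float = 6.0
    question_rt_sigma: float = 0.4
    question_rt_max: float = 50.0
    response_duration: float = 0.5
    confidence_rt_median: float = 2.5
    confidence_rt_sigma: float = 0.4
    confidence_rt_max: float = 10.0
    lead_in: float = 4.0
    post_run_rest: float = 10.0

    def __post_init__(self) -> None:
        for rng_, med, name in (
            (self.iti_range, self.iti_median, "iti"),
            (self.resp_to_conf_range, self.resp_to_conf_median, "resp_to_conf"),
            (self.conf_to_feedback_range, self.conf_to_feedback_median,
             "conf_to_feedback"),
        ):
            lo, hi = rng_
            if not (0 < lo < hi):
                raise ConfigError(f"{name}_range must be positive and increasing")
            if not (lo <= med <= hi):
                raise ConfigError(f"{name}_median must lie inside {name}_range")
        if self.tr <= 0 or self.feedback_duration <= 0:
            raise ConfigError("tr and feedback_duration must be positive")
        if self.run_length_trials < 1 or self.n_runs < 1:
            raise ConfigError("run_length_trials and n_runs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("iti_range", "resp_to_conf_range", "conf_to_feedback_range"):
            d[k] = list(d[k])
        return d


@dataclass
class VoxelPopulation:
    """One planted voxel population with its true loadings.

    ``betas`` maps design-matrix column names to true amplitudes (BOLD units
    per regressor unit; modulator loadings are per PE unit or per confidence
    point). Unlisted columns load zero.
    """

    name: str
    n_voxels: int
    betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_voxels < 0:
            raise ConfigError("n_voxels must be >= 0")


@dataclass
class VoxelSpec:
    """Layout and noise model of the simulated voxel array.

    Populations occupy consecutive blocks of the flattened grid (so each
    planted population forms one spatial cluster when reshaped to ``shape``);
    remaining voxels are null.
    """

    populations: list[VoxelPopulation]
    shape: tuple[int, int, int] = (20, 10, 10)
    noise_sd: float = 1.0
    ar1: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise ConfigError("ar1 must be in [0, 1)")
        if self.n_voxels > int(np.prod(self.shape)):
            raise ConfigError("populations do not fit in the voxel grid")

    @property
    def n_voxels(self) -> int:
        return sum(p.n_voxels for p in self.populations)

    @property
    def n_total(self) -> int:
        return int(np.prod(self.shape))

    def labels(self) -> np.ndarray:
        """Per-voxel population label for the flattened grid ('null' filler)."""
        out = np.full(self.n_total, "null", dtype=object)
        i = 0
        for pop in self.populations:
            out[i:i + pop.n_voxels] = pop.name
            i += pop.n_voxels
        return out


# Default planted amplitudes. Modulator loadings of ~0.01 BOLD units per PE
# unit with unit noise give single-subject parametric t-values of a few —
# the regime of a solid event-related effect.
_PE_AMP = 0.01
_COND_AMP = 0.4
_CONF_AMP = 0.008


def default_voxel_populations(n_per_population: int = 60) -> list[VoxelPopulation]:
    """The five planted response profiles plus implicit null filler.

    * ``signed_pe`` — activity rises linearly with signed PE: positive loading
      on both parametric modulators and a positive correct>incorrect offset.
    * ``unsigned_pe`` — V-shaped |PE| response: positive on the correct-side
      modulator, negative on the incorrect-side modulator.
    * ``inverse_unsigned`` — the negation (greatest response to small PEs).
    * ``memory_confidence`` — deactivates in proportion to later Test2
      confidence (subsequent-memory design only).
    * ``memory_accuracy`` — separates later-corrected from uncorrected
      feedback events.
    """
    n = n_per_population
    return [
        VoxelPopulation("signed_pe", n, {
            "feedback_correct": _COND_AMP, "feedback_incorrect": -_COND_AMP,
            "feedback_correct_x_pe": _PE_AMP, "feedback_incorrect_x_pe": _PE_AMP,
        }),
        VoxelPopulation("unsigned_pe", n, {
            "feedback_correct_x_pe": _PE_AMP, "feedback_incorrect_x_pe": -_PE_AMP,
        }),
        VoxelPopulation("inverse_unsigned", n, {
            "feedback_correct_x_pe": -_PE_AMP, "feedback_incorrect_x_pe": _PE_AMP,
        }),
        VoxelPopulation("memory_confidence", n, {
            "feedback_itc_x_conf2": -_CONF_AMP, "feedback_iti_x_conf2": -_CONF_AMP,
        }),
        VoxelPopulation("memory_accuracy", n, {
            "feedback_itc": _COND_AMP, "feedback_iti": -_COND_AMP,
        }),
    ]
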