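"""Event-related design matrices and per-voxel GLM fitting.

Every trial event (question, response, confidence, feedback) is modelled as a
boxcar of its duration convolved with a canonical double-gamma HRF and
sampled at the TR. Feedback events carry parametric modulators — the trial's
prediction error in the PE-encoding model, or the Test2 confidence rating in
the subsequent-memory model — mean-centred within their parent condition per
run so the modulation is decorrelated from the mean event response. Design
rows at motion-spike volumes (and their neighbours) are zeroed across all
columns and dropped from the fit.

The two models:

* ``pe`` — feedback split by Test1 accuracy (feedback_correct /
  feedback_incorrect), each with a signed-PE modulator.
* ``memory`` — feedback split by subsequent memory (correct /
  incorrect-to-correct / incorrect-to-incorrect), the latter two with a
  Test2-confidence modulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HRFParams",
    "canonical_hrf",
    "DesignSpec",
    "DesignMatrix",
    "build_design_matrix",
    "EventRelatedGLM",
    "GLMResults",
    "ContrastResult",
    "fit_glm",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF: main lobe peaking at ``peak_time`` s, undershoot
    peaking at ``undershoot_time`` s, undershoot 1/``ratio`` the peak size."""

    peak_time: float = 5.0
    undershoot_time: float = 15.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0

    def __post_init__(self):
        if self.peak_disp <= 0 or self.undershoot_disp <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.ratio <= 0:
            raise ValueError("HRF undershoot ratio must be positive")


def canonical_hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Canonical HRF sampled on ``t`` (seconds), normalized to unit peak."""
    params = params or HRFParams()
    t = np.asarray(t, dtype=float)
    a1 = params.peak_time / params.peak_disp + 1.0
    a2 = params.undershoot_time / params.undershoot_disp + 1.0
    h = (
        stats.gamma.pdf(t, a1, scale=params.peak_disp)
        - stats.gamma.pdf(t, a2, scale=params.undershoot_disp) / params.ratio
    )
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


@dataclass
class DesignSpec:
    """What to put in the design matrix."""

    model: str = "pe"  # or "memory"
    hrf: HRFParams = field(default_factory=HRFParams)
    mean_center_modulators: bool = True
    spike_volumes: tuple[int, ...] = ()  # global (concatenated) volume indices
    spike_halo: int = 1  # also zero this many adjacent volumes
    dt: float = 0.1  # convolution grid (s)

    def __post_init__(self):
        if self.model not in ("pe", "memory"):
            raise ValueError(f"unknown design model {self.model!r}")


@dataclass
class DesignMatrix:
    """HRF-convolved design with nuisance bookkeeping.

    ``frame`` holds one row per volume over the concatenated runs (spike rows
    already zeroed); ``spike_rows`` marks them; ``run_index`` maps rows to
    runs. ``rank_deficient`` flags collinear columns detected at build time.
    """

    frame: pd.DataFrame
    spike_rows: np.ndarray
    run_index: np.ndarray
    tr: float
    model: str
    rank_deficient: bool = False

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def _feedback_condition(row, model: str) -> str:
    if row["nuisance"]:
        return "feedback_nuisance"
    if model == "pe":
        return "feedback_correct" if row["test1_correct"] else "feedback_incorrect"
    if row["test1_correct"]:
        return "feedback_correct"
    corrected = row["test2_outcome"] in ("correct", "false_feedback_answer")
    return "feedback_itc" if corrected else "feedback_iti"


_MODULATOR_PARENT = {
    "pe": {"feedback_correct": "pe", "feedback_incorrect": "pe"},
    "memory": {"feedback_itc": "test2_confidence", "feedback_iti": "test2_confidence"},
}


def build_design_matrix(
    schedule: pd.DataFrame,
    spec: DesignSpec,
    tr: float,
    n_volumes: list[int] | int,
) -> DesignMatrix:
    """Assemble the per-run convolved design and concatenate runs.

    ``n_volumes`` gives the volume count of each run (or a single count for
    every run). Raises if any event extends beyond its run's scan end.
    """
    runs = sorted(schedule["run"].unique())
    if np.isscalar(n_volumes):
        n_volumes = [int(n_volumes)] * len(runs)
    if len(n_volumes) != len(runs):
        raise ValueError("n_volumes must give one count per run")

    cond_of = {}
    fb = schedule[schedule["event_type"] == "feedback"]
    for idx, row in fb.iterrows():
        cond_of[idx] = _feedback_condition(row, spec.model)

    base_conds = ["question", "response", "confidence"]
    fb_conds = (
        ["feedback_correct", "feedback_incorrect"]
        if spec.model == "pe"
        else ["feedback_correct", "feedback_itc", "feedback_iti"]
    )
    has_nuisance = any(c == "feedback_nuisance" for c in cond_of.values())
    conds = base_conds + fb_conds + (["feedback_nuisance"] if has_nuisance else [])
    mod_parents = _MODULATOR_PARENT[spec.model]
    mod_cols = {
        f"{parent}_x_{'pe' if spec.model == 'pe' else 'conf2'}": parent
        for parent in fb_conds
        if parent in mod_parents
    }

    hrf_t = np.arange(0.0, 32.0 + spec.dt, spec.dt)
    kernel = canonical_hrf(hrf_t, spec.hrf)

    pieces = []
    run_index = []
    for run, nv in zip(runs, n_volumes):
        ev = schedule[schedule["run"] == run]
        run_dur = nv * tr
        if ((ev["onset"] + ev["duration"]) > run_dur + 1e-9).any():
            raise ValueError(f"events extend beyond scan end of run {run}")
        n_fine = int(np.ceil(run_dur / spec.dt)) + 1
        vol_t = np.arange(nv) * tr
        cols = {}

        def convolved(onsets, durations, amplitudes):
            box = np.zeros(n_fine)
            for o, d, a in zip(onsets, durations, amplitudes):
                i0 = int(np.round(o / spec.dt))
                i1 = max(i0 + 1, int(np.round((o + d) / spec.dt)))
                box[i0:i1] += a
            conv = np.convolve(box, kernel)[:n_fine] * spec.dt
            return np.interp(vol_t, np.arange(n_fine) * spec.dt, conv)

        for cond in conds:
            if cond == "question":
                sel = ev[ev["event_type"] == "question"]
            elif cond == "response":
                sel = ev[ev["event_type"] == "response"]
            elif cond == "confidence":
                sel = ev[ev["event_type"] == "confidence"]
            else:
                sel = ev[
                    (ev["event_type"] == "feedback")
                    & (ev.index.map(cond_of.get) == cond)
                ]
            cols[cond] = (
                convolved(sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                          np.ones(len(sel)))
                if len(sel)
                else np.zeros(nv)
            )

        for mcol, parent in mod_cols.items():
            sel = ev[
                (ev["event_type"] == "feedback")
                & (ev.index.map(cond_of.get) == parent)
            ]
            if len(sel) == 0:
                cols[mcol] = np.zeros(nv)
                continue
            vals = sel[mod_parents[parent]].to_numpy(dtype=float)
            if spec.mean_center_modulators:
                vals = vals - vals.mean()
            cols[mcol] = convolved(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), vals
            )

        frame = pd.DataFrame(cols)
        for r2 in runs:
            frame[f"constant_run{r2}"] = 1.0 if r2 == run else 0.0
        pieces.append(frame)
        run_index.extend([run] * nv)

    frame = pd.concat(pieces, ignore_index=True)
    run_index = np.asarray(run_index)

    total = len(frame)
    spike_rows = np.zeros(total, dtype=bool)
    for v in spec.spike_volumes:
        lo = max(0, v - spec.spike_halo)
        hi = min(total, v + spec.spike_halo + 1)
        spike_rows[lo:hi] = True
    frame.loc[spike_rows, :] = 0.0

    X = frame.to_numpy()[~spike_rows]
    deficient = np.linalg.matrix_rank(X) < frame.shape[1]
    if deficient:
        warnings.warn("design matrix is rank deficient", stacklevel=2)
    return DesignMatrix(
        frame=frame,
        spike_rows=spike_rows,
        run_index=run_index,
        tr=tr,
        model=spec.model,
        rank_deficient=deficient,
    )


@dataclass
class ContrastResult:
    """c'beta with its classical t statistic per voxel."""

    name: str
    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    dof: int

    @property
    def p(self) -> np.ndarray:
        """Two-sided p value."""
        return 2.0 * stats.t.sf(np.abs(self.t), self.dof)

    def p_one_sided(self, sign: int = 1) -> np.ndarray:
        """One-sided p for the effect being positive (sign=+1) or negative."""
        return stats.t.sf(sign * self.t, self.dof)


class GLMResults:
    """Per-voxel OLS estimates with contrast machinery."""

    def __init__(self, params, sigma2, xtx_inv, dof, columns):
        self.params = params        # (n_vox, k)
        self.sigma2 = sigma2        # (n_vox,)
        self.xtx_inv = xtx_inv      # (k, k)
        self.dof = dof
        self.columns = list(columns)

    def _vector(self, contrast) -> np.ndarray:
        if isinstance(contrast, dict):
            c = np.zeros(len(self.columns))
            for name, w in contrast.items():
                if name not in self.columns:
                    raise KeyError(f"no design column named {name!r}")
                c[self.columns.index(name)] = w
            return c
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(self.columns),):
            raise ValueError("contrast vector length mismatch")
        return c

    def contrast(self, contrast, name: str = "contrast") -> ContrastResult:
        c = self._vector(contrast)
        effect = self.params @ c
        var_unit = float(c @ self.xtx_inv @ c)
        se = np.sqrt(self.sigma2 * var_unit)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, 0.0)
        return ContrastResult(name=name, effect=effect, se=se, t=t, dof=self.dof)

    def beta(self, column: str) -> np.ndarray:
        return self.params[:, self.columns.index(column)]

    def summary(self) -> pd.DataFrame:
        """Mean beta and its across-voxel dispersion per regressor."""
        return pd.DataFrame(
            {
                "mean_beta": self.params.mean(axis=0),
                "sd_beta": self.params.std(axis=0),
            },
            index=self.columns,
        )


class EventRelatedGLM:
    """Massively univariate OLS of voxel time series on a design matrix.

    Spike-zeroed volumes are excluded from the fit; the residual degrees of
    freedom are (volumes used) - rank(design).
    """

    def __init__(self, data: np.ndarray, design: DesignMatrix):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] != design.n_volumes:
            raise ValueError(
                f"data has {data.shape[1]} volumes, design {design.n_volumes}"
            )
        self.data = data
        self.design = design

    def fit(self) -> GLMResults:
        keep = ~self.design.spike_rows
        X = self.design.frame.to_numpy()[keep]
        Y = self.data[:, keep]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns via near-zero R diagonal of a QR
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [
                self.design.columns[i]
                for i in np.where(diag < 1e-8 * diag.max())[0]
            ]
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (collinear columns: {bad})"
            )
        beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        dof = X.shape[0] - rank
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        return GLMResults(beta.T, sigma2, xtx_inv, dof, self.design.columns)


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMResults:
    """Functional wrapper around :class:`EventRelatedGLM`."""
    return EventRelatedGLM(data, design).fit()


def subject_pe_contrasts(results: GLMResults) -> dict[str, np.ndarray]:
    """The three component effect maps of the PE conjunction analyses."""
    return {
        "correct_gt_incorrect": results.contrast(
            {"feedback_correct": 1.0, "feedback_incorrect": -1.0}
        ).effect,
        "mod_correct": results.beta("feedback_correct_x_pe"),
        "mod_incorrect": results.beta("feedback_incorrect_x_pe"),
    }
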