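"""Group-level random-effects inference: conjunctions, clusters, ROI tests.

Group maps are summary-statistics random effects: a one-sample t across
subjects' contrast effect images, per voxel. A conjunction admits a voxel
only if every component map is individually significant in its required
direction at alpha = combined_p**(1/n), so that the combined false-positive
rate of the conjunction is combined_p = alpha^n (for n = 3 and combined
p = 0.001, each map is thresholded at alpha = 0.1). Surviving voxels are
then cluster-filtered (default: 18-neighbour connectivity, minimum 10
voxels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ConjunctionSpec",
    "ConjunctionResult",
    "group_onesample",
    "conjunction_map",
    "cluster_filter",
    "pe_conjunctions",
    "subsequent_memory_tests",
]

#: component contrasts (map name, required sign) of each conjunction
SIGNED_CONJUNCTION = (
    ("correct_gt_incorrect", +1),
    ("mod_correct", +1),
    ("mod_incorrect", +1),
)
UNSIGNED_CONJUNCTION = (("mod_correct", +1), ("mod_incorrect", -1))
INVERSE_UNSIGNED_CONJUNCTION = (("mod_correct", -1), ("mod_incorrect", +1))


@dataclass(frozen=True)
class ConjunctionSpec:
    """Threshold rule for a conjunction of directional contrast maps."""

    conjuncts: tuple[tuple[str, int], ...]
    combined_p: float = 0.001
    min_cluster_voxels: int = 10
    connectivity: int = 18

    def __post_init__(self):
        if len(self.conjuncts) < 1:
            raise ValueError("a conjunction needs at least one component")
        if not (0.0 < self.combined_p < 1.0):
            raise ValueError("combined_p must be in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18, or 26")

    @property
    def n(self) -> int:
        return len(self.conjuncts)

    @property
    def alpha(self) -> float:
        """Per-map threshold: alpha**n equals combined_p."""
        return self.combined_p ** (1.0 / self.n)


@dataclass
class ConjunctionResult:
    """Boolean inclusion map with its cluster inventory."""

    spec: ConjunctionSpec
    mask_pre_filter: np.ndarray  # flat boolean, before cluster filtering
    mask: np.ndarray             # flat boolean, after cluster filtering
    clusters: pd.DataFrame
    shape: tuple[int, int, int]
    group_t: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def roi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def group_onesample(stack: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t across subjects (rows) per voxel; returns (t, dof)."""
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t, n - 1


def conjunction_map(
    t_maps: dict[str, np.ndarray],
    dof: int,
    spec: ConjunctionSpec,
) -> np.ndarray:
    """Flat boolean map: every component significant in its direction.

    A component passes at a voxel when the one-sided p of (sign * t) is
    below the per-map alpha.
    """
    shapes = {m.shape for m in t_maps.values()}
    if len(shapes) != 1:
        raise ValueError("component maps must share one voxel grid")
    t_crit = stats.t.isf(spec.alpha, dof)
    mask = None
    for name, sign in spec.conjuncts:
        if name not in t_maps:
            raise KeyError(f"missing component map {name!r}")
        ok = sign * t_maps[name] > t_crit
        mask = ok if mask is None else (mask & ok)
    return mask


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_filter(
    mask: np.ndarray,
    shape: tuple[int, int, int] | None = None,
    min_size: int = 10,
    connectivity: int = 18,
    stat: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove connected components smaller than ``min_size`` voxels.

    Returns the filtered flat mask and a cluster inventory (size, peak voxel
    coordinates, and peak statistic when ``stat`` is given).
    """
    flat = np.asarray(mask).ravel().astype(bool)
    if shape is None:
        if np.asarray(mask).ndim != 3:
            raise ValueError("supply `shape` for a flattened mask")
        shape = mask.shape
    vol = flat.reshape(shape)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labelled, n_comp = ndimage.label(vol, structure=structure)
    rows = []
    keep = np.zeros(shape, dtype=bool)
    stat_vol = None if stat is None else np.asarray(stat).ravel().reshape(shape)
    for lbl in range(1, n_comp + 1):
        comp = labelled == lbl
        size = int(comp.sum())
        if size < min_size:
            continue
        keep |= comp
        if stat_vol is not None:
            idx = np.argmax(np.where(comp, stat_vol, -np.inf))
            peak = np.unravel_index(idx, shape)
            peak_stat = float(stat_vol[peak])
        else:
            peak = tuple(int(c[0]) for c in np.nonzero(comp))
            peak_stat = np.nan
        rows.append(
            {
                "cluster": len(rows) + 1,
                "size": size,
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_stat": peak_stat,
            }
        )
    inventory = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_x", "peak_y", "peak_z", "peak_stat"]
    )
    return keep.ravel(), inventory


def pe_conjunctions(
    subject_contrasts: dict[str, np.ndarray],
    shape: tuple[int, int, int],
    combined_p: float = 0.001,
    min_cluster_voxels: int = 10,
    connectivity: int = 18,
) -> dict[str, ConjunctionResult]:
    """Signed, unsigned, and inverse-unsigned PE conjunction maps.

    ``subject_contrasts`` maps the component names (correct_gt_incorrect,
    mod_correct, mod_incorrect) to subject x voxel effect arrays. The signed
    map requires a positive correct>incorrect difference plus positive
    loadings on both PE modulators (three conjuncts); the unsigned map a
    positive loading on the correct-side and negative on the incorrect-side
    modulator (two conjuncts); the inverse map is the negation.
    """
    t_maps = {}
    dof = None
    for name, stack in subject_contrasts.items():
        t, dof = group_onesample(stack)
        t_maps[name] = t

    out = {}
    for label, conjuncts in (
        ("signed", SIGNED_CONJUNCTION),
        ("unsigned", UNSIGNED_CONJUNCTION),
        ("inverse_unsigned", INVERSE_UNSIGNED_CONJUNCTION),
    ):
        spec = ConjunctionSpec(
            conjuncts=conjuncts,
            combined_p=combined_p,
            min_cluster_voxels=min_cluster_voxels,
            connectivity=connectivity,
        )
        pre = conjunction_map(t_maps, dof, spec)
        # rank clusters by the first conjunct's group t
        stat = spec.conjuncts[0][1] * t_maps[spec.conjuncts[0][0]]
        mask, clusters = cluster_filter(
            pre, shape, spec.min_cluster_voxels, spec.connectivity, stat=stat
        )
        out[label] = ConjunctionResult(
            spec=spec,
            mask_pre_filter=pre,
            mask=mask,
            clusters=clusters,
            shape=shape,
            group_t={k: v for k, v in t_maps.items()},
        )
    return out


def subsequent_memory_tests(
    subject_betas: dict[str, np.ndarray],
    rois: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ROI-restricted subsequent-memory statistics.

    For each ROI (a flat voxel index array), subject-wise mean betas are
    extracted and two tests run at two-tailed ``alpha``: a paired t of
    incorrect-to-correct vs incorrect-to-incorrect feedback betas (updated >
    not updated), and a one-sample t of the Test2-confidence parametric
    betas of incorrect-to-correct trials. Empty ROIs are skipped with a
    warning.
    """
    for key in ("feedback_itc", "feedback_iti", "feedback_itc_x_conf2"):
        if key not in subject_betas:
            raise KeyError(f"missing subject beta maps for {key!r}")
    rows = []
    for name, idx in rois.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            warnings.warn(f"ROI {name!r} is empty; skipped", stacklevel=2)
            continue
        itc = subject_betas["feedback_itc"][:, idx].mean(axis=1)
        iti = subject_betas["feedback_iti"][:, idx].mean(axis=1)
        conf = subject_betas["feedback_itc_x_conf2"][:, idx].mean(axis=1)
        from .behavior import _onesample_t, _paired_t

        paired = _paired_t(itc, iti)
        one = _onesample_t(conf)
        rows.append(
            {
                "roi": name,
                "n_voxels": int(idx.size),
                "mean_beta_itc": float(itc.mean()),
                "mean_beta_iti": float(iti.mean()),
                "paired_t": paired[0],
                "paired_p": paired[1],
                "paired_significant": bool(paired[1] < alpha),
                "mean_beta_conf2": float(conf.mean()),
                "conf_t": one[0],
                "conf_p": one[1],
                "conf_significant": bool(one[1] < alpha),
            }
        )
    return pd.DataFrame(rows)
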