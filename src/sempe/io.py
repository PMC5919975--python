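"""File formats: trial-table TSV, BIDS-style events, BOLD arrays, configs.

Trial tables are UTF-8 TSV with one row per (subject, question); event
schedules are written as events.tsv per run with onset/duration/trial_type/
modulation columns; BOLD data travels as a flat voxel x time NPZ (with a JSON
sidecar carrying ground-truth labels) or as NIfTI-1 when a 3D grid shape is
known.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "write_events",
    "read_events",
    "write_bold_npz",
    "read_bold_npz",
    "write_bold_nifti",
    "load_yaml_config",
]

REQUIRED_TRIAL_COLUMNS = [
    "subject_id",
    "question_id",
    "test1_correct",
    "test1_confidence",
    "skipped",
    "feedback_kind",
    "test2_outcome",
    "test2_confidence",
]

_BOOL_COLUMNS = [
    "test1_correct", "skipped", "excluded",
    "test1_timeout", "test1_mistake", "test2_timeout", "test2_mistake",
    "answer_matches_false_feedback",
]


class TrialTableError(ValueError):
    """Malformed trial table."""


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table TSV, validating columns and confidence ranges.

    Raises :class:`TrialTableError` naming the first offending row (1-based,
    excluding the header) for out-of-range confidences.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")
    for c in _BOOL_COLUMNS:
        if c in df.columns and df[c].dtype != bool:
            df[c] = (
                df[c].astype(str).str.strip().str.lower()
                .map({"true": True, "false": False, "1": True, "0": False})
                .astype(bool)
            )
    for col in ("test1_confidence", "test2_confidence"):
        vals = df[col].to_numpy()
        bad = np.flatnonzero((vals < 0) | (vals > 100))
        if bad.size:
            raise TrialTableError(
                f"{path}: {col} out of range [0, 100] at row {int(bad[0]) + 1} "
                f"(value {vals[bad[0]]})"
            )
    return df


def write_trials(path, trials: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, sep="\t", index=False)


def write_events(path, schedule: pd.DataFrame, run: int | None = None) -> None:
    """Write a BIDS-style events.tsv (one run, or all runs if run is None).

    ``trial_type`` is the event type; the ``modulation`` column carries the
    trial's PE for feedback events and 'n/a' elsewhere.
    """
    s = schedule if run is None else schedule[schedule["run"] == run]
    out = pd.DataFrame(
        {
            "onset": s["onset"],
            "duration": s["duration"],
            "trial_type": s["event_type"],
            "modulation": np.where(
                s["event_type"] == "feedback", s["pe"], np.nan
            ),
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_bold_npz(path, data: np.ndarray, labels: np.ndarray, info: dict) -> None:
    """Flat voxel x time BOLD with a JSON sidecar of ground-truth labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, data=data)
    sidecar = dict(info)
    sidecar["labels"] = [str(x) for x in labels]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_bold_npz(path):
    path = Path(path)
    data = np.load(path)["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    labels = np.asarray(sidecar.pop("labels"), dtype=object)
    return data, labels, sidecar


def write_bold_nifti(path, data: np.ndarray, shape, tr: float) -> None:
    """Write flat voxel x time data as a 4D NIfTI-1 volume."""
    import nibabel as nib

    vol = np.asarray(data).reshape(*shape, data.shape[-1]).astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def load_yaml_config(path, allowed_keys) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    unknown = sorted(set(cfg) - set(allowed_keys))
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return cfg
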