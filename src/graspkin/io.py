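"""Reading and writing trial CSVs and cohort manifests.

One CSV per trial with columns ``t,ix,iy,iz,tx,ty,tz,wx,wy,wz`` (seconds and
millimetres) in the canonical frame: origin at the hand start position, +y
from start toward the grasp location, +z up, +x completing a right-handed
frame.  A cohort manifest CSV has one row per trial (metadata + ground truth
+ file path).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort, GroundTruth, TrialMeta, TrialRecording

__all__ = ["read_trial_csv", "write_trial_csv", "write_cohort",
           "read_cohort_manifest"]

TRIAL_COLUMNS = ["t", "ix", "iy", "iz", "tx", "ty", "tz", "wx", "wy", "wz"]


class TrialFormatError(ValueError):
    """A trial CSV does not match the expected dialect."""


def write_trial_csv(trial: TrialRecording, path: str | Path) -> None:
    trial.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trial_csv(path: str | Path,
                   meta: TrialMeta | None = None) -> TrialRecording:
    """Read a trial CSV; extra columns are accepted with a warning."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        raise TrialFormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TrialFormatError(f"{path}: time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise TrialFormatError(f"{path}: mixed sample rates in time column")
    if meta is None:
        meta = TrialMeta(participant_id=Path(path).stem, group="unknown",
                         task="unknown", object_length_mm=0, fins="none",
                         block=0, trial=0)
    return TrialRecording(
        t=t,
        index_tip=df[["ix", "iy", "iz"]].to_numpy(float),
        thumb_tip=df[["tx", "ty", "tz"]].to_numpy(float),
        wrist=df[["wx", "wy", "wz"]].to_numpy(float),
        meta=meta)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one CSV per trial plus the manifest; returns the manifest path."""
    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in cohort.trials:
        p = trials_dir / f"{trial.meta.trial_id}.csv"
        write_trial_csv(trial, p)
        paths.append(str(p.relative_to(out)))
    manifest = cohort.manifest.copy()
    manifest["path"] = paths
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort_manifest(manifest_path: str | Path) -> list[TrialRecording]:
    """Load all trials listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    trials = []
    for row in manifest.itertuples(index=False):
        meta = TrialMeta(participant_id=row.participant_id, group=row.group,
                         task=row.task, object_length_mm=int(row.object_length_mm),
                         fins=row.fins, block=int(row.block), trial=int(row.trial))
        trial = read_trial_csv(root / row.path, meta=meta)
        if hasattr(row, "onset_s") and not pd.isna(row.onset_s):
            trial.ground_truth = GroundTruth(
                onset_s=float(row.onset_s), end_s=float(row.end_s),
                ma_true_mm=float(row.ma_true_mm),
                perceived_length_mm=float(row.perceived_length_mm),
                mt_s=float(row.mt_true_s), pv_mm_s=float(row.pv_true_mm_s))
        trials.append(trial)
    return trials
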