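"""Per-trial kinematic measures, exclusion rules and normalised profiles.

From a segmented trial this module extracts the three standard reach-to-grasp
measures:

* MA — maximum hand aperture: the largest index-thumb separation (mm)
  between movement onset and movement end;
* MT — movement time: the elapsed time (s) between onset and end;
* PV — peak velocity: the maximum absolute wrist speed (mm/s) between onset
  and end;

applies the trial-exclusion criteria (aperture above 20 mm at the first
sample, hand moved before the measurement started, missing marker data,
segmentation failure), and resamples aperture onto a 0-100 % normalised
movement-time axis for profile averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExclusionRules, SignalOptions
from .segmentation import SegmentationResult, derive_signals
from .synth import TrialRecording

__all__ = ["KinematicSummary", "ExclusionDecision", "apply_exclusions",
           "summarize_trial", "time_normalise_aperture", "summaries_to_frame"]

EXCLUSION_REASONS = ("none", "aperture_at_start_gt_20", "premature_movement",
                     "missing_data", "segmentation_failure")


@dataclass(frozen=True)
class ExclusionDecision:
    excluded: bool
    reason: str  # one of EXCLUSION_REASONS


@dataclass(frozen=True)
class KinematicSummary:
    """MA/MT/PV of one trial plus its validity flag."""

    trial_id: str
    ma_mm: float
    mt_s: float
    pv_mm_s: float
    valid: bool
    exclusion_reason: str = "none"

    def __post_init__(self):
        if self.valid != (self.exclusion_reason == "none"):
            raise ValueError("valid flag must mirror exclusion_reason")


def _invalid(trial_id: str, reason: str) -> KinematicSummary:
    return KinematicSummary(trial_id=trial_id, ma_mm=np.nan, mt_s=np.nan,
                            pv_mm_s=np.nan, valid=False, exclusion_reason=reason)


def apply_exclusions(trial: TrialRecording,
                     rules: ExclusionRules | None = None) -> ExclusionDecision:
    """Decide whether a trial must be excluded before measurement.

    A trial is dropped when the hand aperture at the first sample exceeds
    20 mm, when the wrist travels more than 5 mm within the first 50 ms
    (the hand was already moving when the measurement started), or when any
    marker series contains missing samples.
    """
    rules = rules or ExclusionRules()
    for m in (trial.index_tip, trial.thumb_tip, trial.wrist):
        if np.isnan(m).any():
            return ExclusionDecision(True, "missing_data")
    aperture0 = float(np.linalg.norm(trial.index_tip[0] - trial.thumb_tip[0]))
    if aperture0 > rules.start_aperture_max_mm:
        return ExclusionDecision(True, "aperture_at_start_gt_20")
    early = trial.t - trial.t[0] <= rules.early_window_s
    disp = np.linalg.norm(trial.wrist[early] - trial.wrist[0], axis=1)
    if float(np.max(disp, initial=0.0)) > rules.early_displacement_max_mm:
        return ExclusionDecision(True, "premature_movement")
    return ExclusionDecision(False, "none")


def summarize_trial(trial: TrialRecording, segmentation: SegmentationResult,
                    exclusion: ExclusionDecision | None = None,
                    options: SignalOptions | None = None,
                    signals=None) -> KinematicSummary:
    """Turn a segmented trial into a KinematicSummary (or an exclusion)."""
    trial_id = trial.meta.trial_id
    if exclusion is not None and exclusion.excluded:
        return _invalid(trial_id, exclusion.reason)
    if not segmentation.ok:
        return _invalid(trial_id, "segmentation_failure")
    i0, i1 = segmentation.onset_idx, segmentation.end_idx
    if signals is None:
        signals = derive_signals(trial, options)
    window = slice(i0, i1 + 1)
    ma = float(np.max(signals.aperture[window]))
    mt = float((i1 - i0) / signals.sample_rate)
    pv = float(np.max(signals.wrist_speed[window]))
    return KinematicSummary(trial_id=trial_id, ma_mm=ma, mt_s=mt, pv_mm_s=pv,
                            valid=True)


def time_normalise_aperture(trial: TrialRecording,
                            segmentation: SegmentationResult,
                            n_points: int = 101) -> np.ndarray:
    """Aperture linearly resampled onto ``n_points`` fractions of [onset, end].

    The first and last points equal the raw aperture at onset and end.
    """
    if not segmentation.ok:
        raise ValueError("cannot normalise a trial whose segmentation failed")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    i0, i1 = segmentation.onset_idx, segmentation.end_idx
    if i1 - i0 < 2:
        raise ValueError("movement spans fewer than 2 samples")
    aperture = trial.aperture()
    src_t = trial.t[i0:i1 + 1]
    frac = np.linspace(src_t[0], src_t[-1], n_points)
    return np.interp(frac, src_t, aperture[i0:i1 + 1])


def summaries_to_frame(trials: list[TrialRecording],
                       summaries: list[KinematicSummary]) -> pd.DataFrame:
    """Combine trial metadata and summaries into one analysis table."""
    rows = []
    for tr, sm in zip(trials, summaries):
        rows.append({
            "trial_id": sm.trial_id, "participant_id": tr.meta.participant_id,
            "group": tr.meta.group, "task": tr.meta.task,
            "object_length_mm": tr.meta.object_length_mm, "fins": tr.meta.fins,
            "block": tr.meta.block, "trial": tr.meta.trial,
            "ma_mm": sm.ma_mm, "mt_s": sm.mt_s, "pv_mm_s": sm.pv_mm_s,
            "valid": sm.valid, "exclusion_reason": sm.exclusion_reason,
        })
    return pd.DataFrame(rows)
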