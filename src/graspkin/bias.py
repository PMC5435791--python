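"""Grip-scaling slopes and the slope-corrected illusory-bias statistic.

For each participant and task the five condition means of maximum aperture
(60/80/100 mm plain bars, 80 mm fins-in, 80 mm fins-out) are computed over
valid trials.  The uncorrected illusory bias is

    uncorrected % = 100 * (MA_fins-in - MA_fins-out) / MA_plain-80

and, because normal and pantomime grasping scale aperture to size with
different gains, the headline statistic divides by the participant's
grip-scaling slope — the least-squares slope of mean MA against the plain
bar lengths, computed from the *same task's* trials:

    corrected % = uncorrected % / slope.

Slopes and biases are computed per participant and then averaged; a
group-mean-based slope is exposed only as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FINS_SIZE, GROUPS, PLAIN_SIZES, TASKS

__all__ = ["ParticipantBias", "condition_means", "grip_slope", "illusory_bias", "participant_biases",
           "participant_bias_table", "group_bias_table"]

log = logging.getLogger(__name__)

CONDITIONS = [(60, "none"), (80, "none"), (100, "none"),
              (FINS_SIZE, "in"), (FINS_SIZE, "out")]


class IncompleteParticipantError(ValueError):
    """A participant x task cell has no valid trial in some condition."""


@dataclass(frozen=True)
class ParticipantBias:
    participant_id: str
    group: str
    task: str
    mean_ma: dict[tuple[int, str], float]   # (length, fins) -> mm
    slope: float                            # mm aperture per mm object
    bias_uncorrected: float                 # percent
    bias_corrected: float                   # percent; NaN when slope <= 0
    slope_valid: bool                       # False when slope <= 0


def condition_means(trials: pd.DataFrame) -> dict[tuple[int, str], float]:
    """Mean MA over valid trials per condition for one participant x task.

    ``trials`` must carry columns object_length_mm, fins, ma_mm, valid.
    Raises :class:`IncompleteParticipantError` when a condition is empty.
    """
    valid = trials[trials["valid"].astype(bool)]
    out: dict[tuple[int, str], float] = {}
    for length, fins in CONDITIONS:
        cell = valid[(valid["object_length_mm"] == length) & (valid["fins"] == fins)]
        if len(cell) == 0:
            raise IncompleteParticipantError(
                f"no valid trial for condition {length} mm fins={fins}")
        out[(length, fins)] = float(cell["ma_mm"].mean())
    return out


def grip_slope(means: dict[tuple[int, str], float]) -> float:
    """OLS slope of mean MA against the plain bar lengths (60, 80, 100 mm)."""
    x = np.asarray(PLAIN_SIZES, dtype=float)
    y = np.asarray([means[(s, "none")] for s in PLAIN_SIZES], dtype=float)
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def illusory_bias(means: dict[tuple[int, str], float],
                  slope: float) -> tuple[float, float]:
    """(uncorrected %, corrected %) from the five condition means.

    The corrected bias is NaN when the slope is non-positive; callers flag
    the participant and keep the uncorrected value.
    """
    ma80 = means[(FINS_SIZE, "none")]
    if ma80 <= 0:
        raise ValueError("mean MA for the plain 80 mm bar must be positive")
    uncorrected = 100.0 * (means[(FINS_SIZE, "in")] - means[(FINS_SIZE, "out")]) / ma80
    corrected = uncorrected / slope if slope > 0 else float("nan")
    return uncorrected, corrected


def participant_biases(kinematics: pd.DataFrame) -> list[ParticipantBias]:
    """Per participant x task bias records from the trial-level table.

    Participants with an empty condition in some task are dropped from that
    task (and logged); participants with a non-positive slope keep their
    uncorrected bias but have ``slope_valid == False``.
    """
    records = []
    for (pid, task), sub in kinematics.groupby(["participant_id", "task"], sort=True):
        group = sub["group"].iloc[0]
        try:
            means = condition_means(sub)
        except IncompleteParticipantError as exc:
            log.warning("dropping %s/%s from group statistics: %s", pid, task, exc)
            continue
        slope = grip_slope(means)
        uncorrected, corrected = illusory_bias(means, slope)
        if slope <= 0:
            log.warning("%s/%s: non-positive grip slope %.3f; corrected bias "
                        "undefined", pid, task, slope)
        records.append(ParticipantBias(
            participant_id=pid, group=group, task=task, mean_ma=means,
            slope=slope, bias_uncorrected=uncorrected,
            bias_corrected=corrected, slope_valid=slope > 0))
    return records


def participant_bias_table(kinematics: pd.DataFrame) -> pd.DataFrame:
    """:func:`participant_biases` flattened into an analysis DataFrame."""
    rows = []
    for rec in participant_biases(kinematics):
        row = {"participant_id": rec.participant_id, "group": rec.group,
               "task": rec.task, "slope": rec.slope,
               "slope_valid": rec.slope_valid,
               "bias_uncorrected": rec.bias_uncorrected,
               "bias_corrected": rec.bias_corrected}
        for (length, fins), value in rec.mean_ma.items():
            suffix = f"{length}{fins if fins != 'none' else ''}"
            row[f"ma_{suffix}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def group_bias_table(participant_bias: pd.DataFrame) -> pd.DataFrame:
    """Group x task mean (SD) of uncorrected and corrected biases.

    Mirrors the layout of the published bias table: one row per group, columns
    for each task's uncorrected and corrected mean and SD across participants.
    SD is reported as NaN for single-participant groups; participants with an
    invalid slope are excluded from the corrected aggregation only.
    """
    rows = []
    for group in GROUPS:
        row: dict[str, float | str] = {"group": group}
        sub_g = participant_bias[participant_bias["group"] == group]
        for task in TASKS:
            sub = sub_g[sub_g["task"] == task]
            u = sub["bias_uncorrected"].to_numpy(float)
            c = sub.loc[sub["slope_valid"], "bias_corrected"].to_numpy(float)
            row[f"uncorrected_{task}_mean"] = float(np.mean(u)) if len(u) else np.nan
            row[f"uncorrected_{task}_sd"] = float(np.std(u, ddof=1)) if len(u) > 1 else np.nan
            row[f"corrected_{task}_mean"] = float(np.mean(c)) if len(c) else np.nan
            row[f"corrected_{task}_sd"] = float(np.std(c, ddof=1)) if len(c) > 1 else np.nan
            row[f"n_{task}"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)
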