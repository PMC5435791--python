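"""Synthetic reach-to-grasp marker trajectories with known ground truth.

The generator emulates a two-group (inexperienced participants, magicians) by
two-task (normal grasp, displaced pantomime grasp) design with five objects
per task (60/80/100 mm plain bars plus an 80 mm bar with inward- or
outward-pointing fins forming a Muller-Lyer figure) and ten trials per cell.

Each trial is a sequence of phases on a uniform 200 Hz grid:

rest -> transport -> settle -> lift -> hold

* transport: minimum-jerk wrist displacement of ``reach_distance`` along +y
  with a low vertical arc, lasting ``1.875 * reach / PV`` so the peak wrist
  speed equals the participant's drawn peak velocity;
* settle: the wrist is still while the grip closes onto the (perceived)
  object; transport + settle together last the drawn movement time MT;
* lift: minimum-jerk rise of ``lift_height`` along +z.

The grip aperture opens from its rest value to the trial's true maximum
aperture ``MA = a + s * perceived_size (+ noise)`` at 70 % of MT, with an
opening-velocity profile shaped like a Beta(1.5, 3) density (a steep,
abrupt-onset bell, as observed at aperture-opening onset), then closes onto
the perceived object length by movement end with a minimum-jerk profile.

Ground truth (movement onset = transport start, movement end = lift start,
true MA) is stored on every trial, which is what makes the cohort usable for
parameter-recovery testing of the segmentation and bias pipeline.

The illusory manipulation is parameterised *in units of the corrected bias*:
for each participant the configured per-participant corrected-bias truth
``B`` is converted into a perceived-length shift ``delta = B * (a + 80 s) /
100`` split between the fins-in (share ``w``) and fins-out (share ``1 - w``)
configurations, so that running the full analysis pipeline on a noise-free
cohort returns exactly ``B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import betainc

from .config import FINS_SIZE, GROUPS, OBJECTS, PLAIN_SIZES, TASKS, GeneratorConfig

__all__ = [
    "TrialMeta", "GroundTruth", "TrialRecording", "ParticipantParams",
    "Cohort", "generate_trial", "generate_cohort", "iter_cohort_trials",
    "min_jerk_position", "min_jerk_speed_peak",
]


class TrialGenerationError(ValueError):
    """A trial could not be constructed from the drawn parameters."""


@dataclass(frozen=True)
class TrialMeta:
    participant_id: str
    group: str            # "inexperienced" | "magician"
    task: str             # "normal" | "pantomime"
    object_length_mm: int
    fins: str             # "none" | "in" | "out"
    block: int
    trial: int

    @property
    def trial_id(self) -> str:
        return (f"{self.participant_id}-{self.task}-{self.object_length_mm}"
                f"{self.fins if self.fins != 'none' else ''}-b{self.block}t{self.trial}")


@dataclass(frozen=True)
class GroundTruth:
    onset_s: float
    end_s: float
    ma_true_mm: float
    perceived_length_mm: float
    mt_s: float
    pv_mm_s: float


@dataclass
class TrialRecording:
    """Time-indexed 3D positions of the three analysis markers (mm)."""

    t: np.ndarray                 # (n,) seconds, uniform grid
    index_tip: np.ndarray         # (n, 3) mm
    thumb_tip: np.ndarray         # (n, 3) mm
    wrist: np.ndarray             # (n, 3) mm
    meta: TrialMeta
    ground_truth: GroundTruth | None = None

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def aperture(self) -> np.ndarray:
        """Euclidean index-thumb tip distance (mm) at every sample."""
        return np.linalg.norm(self.index_tip - self.thumb_tip, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "ix": self.index_tip[:, 0], "iy": self.index_tip[:, 1], "iz": self.index_tip[:, 2],
            "tx": self.thumb_tip[:, 0], "ty": self.thumb_tip[:, 1], "tz": self.thumb_tip[:, 2],
            "wx": self.wrist[:, 0], "wy": self.wrist[:, 1], "wz": self.wrist[:, 2],
        })


@dataclass
class ParticipantParams:
    """One participant's true parameters for one task."""

    participant_id: str
    group: str
    task: str
    ma_intercept: float            # a, mm
    ma_slope: float                # s, mm/mm
    mt_s: dict[int, float]         # per plain object size
    pv_mm_s: float
    bias_corrected_true: float     # percent, this participant's truth
    rest_aperture: float           # mm
    delta_mm: float                # total perceived-length shift fins-in vs fins-out

    def perceived_length(self, object_length: int, fins: str, share: float) -> float:
        if fins == "none":
            return float(object_length)
        if fins == "in":
            return float(object_length) + share * self.delta_mm
        return float(object_length) - (1.0 - share) * self.delta_mm


@dataclass
class Cohort:
    config: GeneratorConfig
    participants: list[ParticipantParams]
    trials: list[TrialRecording]
    manifest: pd.DataFrame = field(repr=False)


def min_jerk_position(s: np.ndarray | float) -> np.ndarray | float:
    """Normalised minimum-jerk position profile on s in [0, 1]."""
    return 10.0 * s ** 3 - 15.0 * s ** 4 + 6.0 * s ** 5


def min_jerk_speed_peak(distance: float, duration: float) -> float:
    """Closed-form peak speed of a minimum-jerk point-to-point movement."""
    return 1.875 * distance / duration


#: initial grip-opening speed (mm/s); the digits leave the rest posture at a
#: brisk, roughly amplitude-independent rate before the main opening bell
OPENING_INIT_SPEED = 75.0
#: delay (s) between opening onset and the start of the main opening bell
OPENING_BELL_DELAY = 0.015


def _opening_profile(s: np.ndarray, lam: float, s0: float) -> np.ndarray:
    """Normalised aperture-opening position profile on s in [0, 1].

    A blend of a decaying linear ramp (initial velocity 5*lam, zero velocity
    at the peak) and a front-loaded Beta(1.5, 5) velocity bell that starts at
    ``s0``; both components reach 1 at s = 1 with zero slope, so the aperture
    attains its maximum exactly at the end of the opening phase.
    """
    s = np.clip(s, 0.0, 1.0)
    ramp = 1.0 - (1.0 - s) ** 5
    sb = np.clip((s - s0) / max(1.0 - s0, 1e-9), 0.0, 1.0)
    return lam * ramp + (1.0 - lam) * betainc(1.5, 5.0, sb)


def _trial_sampling_sd(cfg: GeneratorConfig, p: "GroupTaskParams") -> float:  # noqa: F821
    """Analytic SD of the *estimated* corrected bias induced by trial noise.

    Used to discount the configured between-participant SD so that the
    realized spread of estimated biases matches the configured value.
    """
    k = cfg.trials_per_cell
    sigma = cfg.trial_noise_sd_ma
    if sigma == 0:
        return 0.0
    s = p.ma_slope_mean
    ma80 = p.ma_intercept_mean + 80.0 * s
    sxx = float(np.sum((np.asarray(PLAIN_SIZES, float) - np.mean(PLAIN_SIZES)) ** 2))
    var_u = (100.0 / ma80) ** 2 * 2.0 * sigma ** 2 / k          # numerator noise
    var_slope = sigma ** 2 / (k * sxx)
    var_c = var_u / s ** 2 + (p.bias_corrected_true / s) ** 2 * var_slope
    return float(np.sqrt(var_c))


#: correlation of a participant's aperture intercept, movement times and peak
#: velocity across the two tasks (stable individual differences)
TASK_CORRELATION = 0.7


def draw_participants(config: GeneratorConfig, rng: np.random.Generator,
                      ) -> list[ParticipantParams]:
    """Draw per-participant true parameters in deterministic (sorted) order.

    Aperture intercepts, movement times and peak velocities share a common
    per-participant component across tasks (correlation
    :data:`TASK_CORRELATION`), emulating stable individual differences in
    hand size and movement tempo.
    """
    out: list[ParticipantParams] = []
    counts = config.group_sizes()
    rho = TASK_CORRELATION
    w_shared, w_own = np.sqrt(rho), np.sqrt(1.0 - rho)
    idx = 0
    for group in GROUPS:
        for _ in range(counts[group]):
            idx += 1
            pid = f"P{idx:02d}"
            rest_ap = float(np.clip(
                rng.normal(config.rest_aperture_mean, config.rest_aperture_sd),
                18.1, 18.9))
            z_a = rng.standard_normal()
            z_mt = {size: rng.standard_normal() for size in PLAIN_SIZES}
            z_pv = rng.standard_normal()
            for task in TASKS:
                p = config.params[group][task]
                slope = float(np.clip(rng.normal(p.ma_slope_mean, p.ma_slope_sd),
                                      0.2, None))
                # intercept: hand must be able to overshoot the largest object
                p_max = max(PLAIN_SIZES)
                a_floor = p_max + 3.0 - slope * p_max
                za_task = w_shared * z_a + w_own * rng.standard_normal()
                intercept = p.ma_intercept_mean + p.ma_intercept_sd * za_task
                for _ in range(100):
                    if intercept >= a_floor:
                        break
                    intercept = p.ma_intercept_mean + \
                        p.ma_intercept_sd * rng.standard_normal()
                intercept = float(max(intercept, a_floor))
                zpv_task = w_shared * z_pv + w_own * rng.standard_normal()
                pv = float(np.clip(p.pv_mean + p.pv_sd * zpv_task, 150.0, None))
                mt: dict[int, float] = {}
                t_reach = min_jerk_speed_peak(config.reach_distance, 1.0) / pv
                for size in PLAIN_SIZES:
                    zmt_task = w_shared * z_mt[size] + w_own * rng.standard_normal()
                    draw = p.mt_mean[size] + p.mt_sd[size] * zmt_task
                    mt[size] = float(max(draw, t_reach + 0.03, 0.10))
                sd_eff = np.sqrt(max(
                    0.0, p.bias_corrected_sd ** 2 - _trial_sampling_sd(config, p) ** 2))
                bias = float(rng.normal(p.bias_corrected_true, sd_eff))
                delta = bias * (intercept + FINS_SIZE * slope) / 100.0
                out.append(ParticipantParams(
                    participant_id=pid, group=group, task=task,
                    ma_intercept=intercept, ma_slope=slope, mt_s=mt,
                    pv_mm_s=pv, bias_corrected_true=bias,
                    rest_aperture=rest_ap, delta_mm=delta))
    return out


def generate_trial(config: GeneratorConfig, meta: TrialMeta,
                   params: ParticipantParams, rng: np.random.Generator,
                   ) -> TrialRecording:
    """Construct one trial from a participant's true parameters.

    Raises :class:`TrialGenerationError` when the implied maximum aperture
    cannot exceed the perceived object length or MT spans fewer than 5
    samples.
    """
    fs = config.sample_rate
    perceived = params.perceived_length(meta.object_length_mm, meta.fins,
                                        config.fins_in_share)
    ma_mean = params.ma_intercept + params.ma_slope * perceived
    if ma_mean <= perceived:
        raise TrialGenerationError(
            f"{meta.trial_id}: implied MA {ma_mean:.1f} mm <= perceived object "
            f"length {perceived:.1f} mm")
    ma_true = ma_mean + rng.normal(0.0, config.trial_noise_sd_ma) \
        if config.trial_noise_sd_ma > 0 else ma_mean
    ma_true = float(max(ma_true, perceived + 0.5))

    mt = params.mt_s[meta.object_length_mm]
    n_mt = int(round(mt * fs))
    if n_mt <= 4:
        raise TrialGenerationError(f"{meta.trial_id}: MT covers only {n_mt} samples")

    rest_s = rng.uniform(*config.rest_duration_range)
    n_rest = max(1, int(round(rest_s * fs)))
    t_reach = min_jerk_speed_peak(config.reach_distance, 1.0) / params.pv_mm_s
    n_reach = int(np.clip(round(t_reach * fs), 10, n_mt - 2))
    n_open = max(2, int(round(0.7 * n_mt)))
    n_close = n_mt - n_open
    n_lift = max(2, int(round(config.lift_duration * fs)))
    n_hold = int(round(config.hold_duration * fs))
    n = n_rest + n_mt + n_lift + n_hold + 1

    t = np.arange(n) / fs
    y = np.zeros(n)
    z = np.zeros(n)
    ap = np.full(n, params.rest_aperture)

    # transport: min-jerk along +y with a low sinusoidal arc in z
    i0 = n_rest
    s = np.arange(n_reach + 1) / n_reach
    y[i0:i0 + n_reach + 1] = config.reach_distance * min_jerk_position(s)
    y[i0 + n_reach + 1:] = config.reach_distance
    # vertical arc with a brisk lift-off: hands leave the tabletop with a
    # fast initial upward velocity (exponent < 2 sharpens the rise)
    z[i0:i0 + n_reach + 1] = config.arc_height * np.sin(np.pi * s) ** 1.2

    # aperture: abrupt-onset bell opening to MA at 0.7 MT, min-jerk closing
    so = np.arange(n_open + 1) / n_open
    amp = ma_true - params.rest_aperture
    t_open = n_open / fs
    lam = float(np.clip(OPENING_INIT_SPEED * t_open / (5.0 * amp), 0.0, 0.5))
    s0 = float(np.clip(OPENING_BELL_DELAY / t_open, 0.0, 0.2))
    ap[i0:i0 + n_open + 1] = params.rest_aperture + \
        amp * _opening_profile(so, lam, s0)
    if n_close > 0:
        sc = np.arange(n_close + 1) / n_close
        ap[i0 + n_open:i0 + n_mt + 1] = ma_true - \
            (ma_true - perceived) * min_jerk_position(sc)
    ap[i0 + n_mt:] = perceived if n_close > 0 else ma_true

    # lift: min-jerk along +z, then hold
    i1 = n_rest + n_mt
    sl = np.arange(n_lift + 1) / n_lift
    z[i1:i1 + n_lift + 1] = config.lift_height * min_jerk_position(sl)
    z[i1 + n_lift + 1:] = config.lift_height

    # marker layout: aperture opens along x, all markers share y(t), z(t);
    # constant anatomical offsets do not matter because the analysis uses
    # displacement from the first sample.
    center = np.column_stack([np.zeros(n), y + 70.0, z + 10.0])
    index_tip = center + np.column_stack([ap / 2.0, np.zeros(n), np.zeros(n)])
    thumb_tip = center - np.column_stack([ap / 2.0, np.zeros(n), np.zeros(n)])
    wrist = np.column_stack([np.zeros(n), y, z])

    if config.marker_jitter_sd > 0:
        index_tip = index_tip + rng.normal(0.0, config.marker_jitter_sd, (n, 3))
        thumb_tip = thumb_tip + rng.normal(0.0, config.marker_jitter_sd, (n, 3))
        wrist = wrist + rng.normal(0.0, config.marker_jitter_sd, (n, 3))

    gt = GroundTruth(onset_s=n_rest / fs, end_s=(n_rest + n_mt) / fs,
                     ma_true_mm=ma_true, perceived_length_mm=perceived,
                     mt_s=n_mt / fs, pv_mm_s=params.pv_mm_s)
    return TrialRecording(t=t, index_tip=index_tip, thumb_tip=thumb_tip,
                          wrist=wrist, meta=meta, ground_truth=gt)


def _trial_metas(config: GeneratorConfig, pid: str, group: str, task: str,
                 rng: np.random.Generator) -> Iterator[TrialMeta]:
    reps = config.trials_per_cell // config.blocks
    extra = config.trials_per_cell - reps * config.blocks
    counter: dict[tuple, int] = {}
    for block in range(1, config.blocks + 1):
        n_reps = reps + (1 if block <= extra else 0)
        order = [obj for obj in OBJECTS for _ in range(n_reps)]
        rng.shuffle(order)  # objects presented in random order within a block
        for length, fins in order:
            key = (length, fins)
            counter[key] = counter.get(key, 0) + 1
            yield TrialMeta(participant_id=pid, group=group, task=task,
                            object_length_mm=length, fins=fins,
                            block=block, trial=counter[key])


def iter_cohort_trials(config: GeneratorConfig,
                       participants: list[ParticipantParams],
                       rng: np.random.Generator) -> Iterator[TrialRecording]:
    by_key = {(p.participant_id, p.task): p for p in participants}
    pids = sorted({p.participant_id for p in participants})
    for pid in pids:
        for task in TASKS:
            params = by_key[(pid, task)]
            for meta in _trial_metas(config, pid, params.group, task, rng):
                yield generate_trial(config, meta, params, rng)


def generate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Generate a full cohort plus a manifest of all true parameter draws."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    participants = draw_participants(config, rng)
    trials = list(iter_cohort_trials(config, participants, rng))
    rows = []
    for tr in trials:
        gt = tr.ground_truth
        rows.append({
            "trial_id": tr.meta.trial_id, "participant_id": tr.meta.participant_id,
            "group": tr.meta.group, "task": tr.meta.task,
            "object_length_mm": tr.meta.object_length_mm, "fins": tr.meta.fins,
            "block": tr.meta.block, "trial": tr.meta.trial,
            "onset_s": gt.onset_s, "end_s": gt.end_s, "ma_true_mm": gt.ma_true_mm,
            "perceived_length_mm": gt.perceived_length_mm,
            "mt_true_s": gt.mt_s, "pv_true_mm_s": gt.pv_mm_s,
        })
    manifest = pd.DataFrame(rows)
    return Cohort(config=config, participants=participants, trials=trials,
                  manifest=manifest)
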