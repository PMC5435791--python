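"""Maximum-likelihood movement segmentation from multiple sources of information.

Movement onset and end are found by evaluating, at every sample, a battery of
objective functions with values in [0, 1] — binary gates (elapsed time,
distance from the start region, aperture bounds, end-position bounds) and
graded functions of velocity and aperture rate of change — and taking the
sample at which their product (the combined likelihood) is maximal.

Six onset functions:

1. time gate: t < 2.0 s;
2. start-region gate: index and thumb displacement in y and z < 15 mm;
3. aperture gate: aperture <= 20 mm;
4. low-but-nonzero hand velocity: (sqrt(v~_y) - v~_y)(sqrt(v~_z) - v~_z)
   with v~ the mean marker velocity normalised by its trial maximum;
5. product over the three markers of (1 - D~_y)(1 - D~_z), displacements
   normalised by their trial maxima (three factors of one function);
6. aperture opening rate normalised by its maximum, clipped at 0.

Six end functions (movement end = the instance the object is lifted):

1. window gate: tMA < t < time of the hand's highest point, t <= 4.75 s;
2. position gate: finger y-displacement > 190 mm and z-displacement < 20 mm;
3. aperture gate: aperture >= 45 mm;
4. 1 - wrist y-velocity normalised by its maximum;
5. sqrt(v~_z) - v~_z for the mean marker z-velocity;
6. 1 - |aperture rate| normalised by its maximum.

Normalisers use the per-trial maximum over the full recording; negative
relative velocities are clipped to 0 so every value stays in [0, 1].  Argmax
ties are broken toward the earliest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .config import ObjectiveThresholds, SignalOptions
from .synth import TrialRecording

__all__ = [
    "DerivedSignals", "SegmentationResult", "SegmentationError",
    "derive_signals", "onset_objectives", "end_objectives", "segment_trial",
]


class SegmentationError(ValueError):
    """Segmentation could not be performed on this trial."""


@dataclass
class DerivedSignals:
    """Per-sample kinematic signals derived from the three markers."""

    t: np.ndarray
    sample_rate: float
    aperture: np.ndarray          # mm
    ap_rate: np.ndarray           # AV, mm/s (signed; >0 = opening)
    disp_y: dict[str, np.ndarray]  # |displacement from first sample|, per marker
    disp_z: dict[str, np.ndarray]
    vel_y: dict[str, np.ndarray]   # mm/s, per marker
    vel_z: dict[str, np.ndarray]
    av_vel_y: np.ndarray          # mean over the three markers
    av_vel_z: np.ndarray
    wrist_speed: np.ndarray       # 3D wrist speed, mm/s
    finger_z_mean: np.ndarray     # mean index/thumb z displacement ("hand height")

    @property
    def n(self) -> int:
        return len(self.t)


def _lowpass(x: np.ndarray, fs: float, opts: SignalOptions) -> np.ndarray:
    nyq = fs / 2.0
    if opts.cutoff_hz >= nyq:
        return x
    b, a = butter(opts.filter_order, opts.cutoff_hz / nyq)
    return filtfilt(b, a, x, axis=0)


def _velocity(pos: np.ndarray, fs: float, opts: SignalOptions) -> np.ndarray:
    """Central-difference velocity, low-pass filtered forward-backward.

    The series is extended by constant padding before differentiation so that
    filter warm-up transients do not leak spurious velocity into the first
    and last samples (recordings begin and end with the hand at rest).
    """
    pad = max(4, int(round(0.25 * fs)))
    first = np.repeat(pos[:1], pad, axis=0)
    last = np.repeat(pos[-1:], pad, axis=0)
    ext = np.concatenate([first, pos, last], axis=0)
    v = np.gradient(ext, axis=0) * fs
    v = _lowpass(v, fs, opts)
    return v[pad:-pad]


def derive_signals(trial: TrialRecording,
                   options: SignalOptions | None = None) -> DerivedSignals:
    """Compute aperture, displacements and filtered velocities for one trial."""
    options = options or SignalOptions()
    t = np.asarray(trial.t, dtype=float)
    if len(t) < 5:
        raise SegmentationError("trial too short: need at least 5 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SegmentationError("non-uniform time grid")
    markers = {"index": trial.index_tip, "thumb": trial.thumb_tip,
               "wrist": trial.wrist}
    for name, m in markers.items():
        if np.isnan(m).any():
            raise SegmentationError(f"NaN samples in {name} marker")
    fs = 1.0 / float(dt[0])

    aperture = trial.aperture()
    ap_rate = _velocity(aperture, fs, options)
    disp_y, disp_z, vel_y, vel_z = {}, {}, {}, {}
    for name, m in markers.items():
        disp_y[name] = np.abs(m[:, 1] - m[0, 1])
        disp_z[name] = np.abs(m[:, 2] - m[0, 2])
        v = _velocity(m, fs, options)
        vel_y[name] = v[:, 1]
        vel_z[name] = v[:, 2]
    av_vel_y = (vel_y["index"] + vel_y["thumb"] + vel_y["wrist"]) / 3.0
    av_vel_z = (vel_z["index"] + vel_z["thumb"] + vel_z["wrist"]) / 3.0
    wrist_speed = np.linalg.norm(_velocity(markers["wrist"], fs, options), axis=1)
    finger_z = ((markers["index"][:, 2] - markers["index"][0, 2]) +
                (markers["thumb"][:, 2] - markers["thumb"][0, 2])) / 2.0
    return DerivedSignals(t=t, sample_rate=fs, aperture=aperture, ap_rate=ap_rate,
                          disp_y=disp_y, disp_z=disp_z, vel_y=vel_y, vel_z=vel_z,
                          av_vel_y=av_vel_y, av_vel_z=av_vel_z,
                          wrist_speed=wrist_speed, finger_z_mean=finger_z)


def _rel(x: np.ndarray, name: str) -> np.ndarray:
    """Normalise by the positive trial maximum, clipped into [0, 1]."""
    m = float(np.max(x))
    if m <= 0:
        warnings.warn(f"{name}: non-positive maximum, objective set to zero",
                      stacklevel=3)
        return np.zeros_like(x)
    return np.clip(x / m, 0.0, 1.0)


def _peak_fn(rel: np.ndarray) -> np.ndarray:
    """sqrt(x) - x: a [0, 1] bell over x in [0, 1] peaking at x = 1/4."""
    return np.sqrt(rel) - rel


def onset_objectives(signals: DerivedSignals,
                     thresholds: ObjectiveThresholds | None = None,
                     ) -> dict[str, np.ndarray]:
    """The six onset objective-function series, each in [0, 1]."""
    th = thresholds or ObjectiveThresholds()
    s = signals
    f1 = (s.t < th.t_onset_max).astype(float)
    f2 = ((s.disp_y["index"] < th.start_region_mm)
          & (s.disp_z["index"] < th.start_region_mm)
          & (s.disp_y["thumb"] < th.start_region_mm)
          & (s.disp_z["thumb"] < th.start_region_mm)).astype(float)
    f3 = (s.aperture <= th.aperture_onset_max_mm).astype(float)
    f4 = _peak_fn(_rel(s.av_vel_y, "avV_y")) * _peak_fn(_rel(s.av_vel_z, "avV_z"))
    f5 = np.ones(s.n)
    for marker in ("index", "thumb", "wrist"):
        f5 = f5 * (1.0 - _rel(s.disp_y[marker], f"{marker} D_y")) \
                * (1.0 - _rel(s.disp_z[marker], f"{marker} D_z"))
    f6 = _rel(s.ap_rate, "AV")
    return {"f1_time": f1, "f2_start_region": f2, "f3_aperture": f3,
            "f4_velocity": f4, "f5_displacement": f5, "f6_opening": f6}


def end_objectives(signals: DerivedSignals, t_ma: float,
                   thresholds: ObjectiveThresholds | None = None,
                   ) -> dict[str, np.ndarray]:
    """The six movement-end objective-function series, each in [0, 1]."""
    th = thresholds or ObjectiveThresholds()
    s = signals
    if not (s.t[0] <= t_ma <= s.t[-1]):
        raise SegmentationError(f"t_ma = {t_ma:.3f} s outside the recording")
    i_highest = int(np.argmax(s.finger_z_mean))
    t_highest = float(s.t[i_highest])
    t_lo = t_ma + (th.post_ma_delay_s if th.enforce_post_ma_delay else 0.0)
    g1 = ((s.t > t_lo) & (s.t < t_highest) & (s.t <= th.t_end_max)).astype(float)
    g2 = ((s.disp_y["index"] > th.end_y_min_mm)
          & (s.disp_y["thumb"] > th.end_y_min_mm)
          & (s.disp_z["index"] < th.end_z_max_mm)
          & (s.disp_z["thumb"] < th.end_z_max_mm)).astype(float)
    g3 = (s.aperture >= th.aperture_end_min_mm).astype(float)
    g4 = 1.0 - _rel(s.vel_y["wrist"], "wrist V_y")
    g5 = _peak_fn(_rel(s.av_vel_z, "avV_z"))
    av_abs_max = float(np.max(np.abs(s.ap_rate)))
    if av_abs_max <= 0:
        warnings.warn("AV: non-positive maximum, g6 set to one", stacklevel=2)
        g6 = np.ones(s.n)
    else:
        g6 = 1.0 - np.abs(s.ap_rate) / av_abs_max
    return {"g1_window": g1, "g2_position": g2, "g3_aperture": g3,
            "g4_wrist_still": g4, "g5_lift_velocity": g5, "g6_aperture_still": g6}


@dataclass
class SegmentationResult:
    """Chosen onset/end samples plus the full likelihood traces."""

    status: str                       # "ok" | "no_onset" | "no_end"
    onset_idx: int | None
    end_idx: int | None
    onset_likelihood: np.ndarray
    end_likelihood: np.ndarray
    per_function_values: dict[str, np.ndarray] = field(repr=False)
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def segment_trial(trial: TrialRecording,
                  thresholds: ObjectiveThresholds | None = None,
                  options: SignalOptions | None = None,
                  signals: DerivedSignals | None = None) -> SegmentationResult:
    """Segment one trial: onset then end, each by likelihood argmax.

    Failures ("no onset found" / "no end found") are reported in
    ``SegmentationResult.status`` rather than raised, so batch callers can
    record them as trial-level exclusions.  Pass ``signals`` to reuse an
    already-derived signal bundle.
    """
    th = thresholds or ObjectiveThresholds()
    if signals is None:
        signals = derive_signals(trial, options)

    onset_fns = onset_objectives(signals, th)
    onset_like = np.ones(signals.n)
    for series in onset_fns.values():
        onset_like = onset_like * series
    if not np.any(onset_like > 0):
        return SegmentationResult("no_onset", None, None, onset_like,
                                  np.zeros(signals.n), onset_fns)
    onset_idx = int(np.argmax(onset_like))  # argmax takes the earliest tie

    # tMA: aperture maximum after the chosen onset, within the end-time bound.
    window = (np.arange(signals.n) > onset_idx) & (signals.t <= th.t_end_max)
    if not window.any():
        return SegmentationResult("no_end", onset_idx, None, onset_like,
                                  np.zeros(signals.n), onset_fns)
    ap_win = np.where(window, signals.aperture, -np.inf)
    i_ma = int(np.argmax(ap_win))
    t_ma = float(signals.t[i_ma])

    end_fns = end_objectives(signals, t_ma, th)
    end_like = np.ones(signals.n)
    for series in end_fns.values():
        end_like = end_like * series
    end_like[:onset_idx + 1] = 0.0      # enforce onset < end
    per_fn = {**onset_fns, **end_fns}
    diagnostics = {"t_ma": t_ma,
                   "t_highest": float(signals.t[int(np.argmax(signals.finger_z_mean))]),
                   "onset_s": float(signals.t[onset_idx])}
    if not np.any(end_like > 0):
        return SegmentationResult("no_end", onset_idx, None, onset_like,
                                  end_like, per_fn, diagnostics)
    end_idx = int(np.argmax(end_like))
    diagnostics["end_s"] = float(signals.t[end_idx])
    return SegmentationResult("ok", onset_idx, end_idx, onset_like, end_like,
                              per_fn, diagnostics)
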