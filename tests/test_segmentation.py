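"""Objective functions and the maximum-likelihood onset/end selection."""

import numpy as np
import pytest

from graspkin import ObjectiveThresholds, derive_signals, segment_trial
from graspkin.segmentation import (SegmentationError, end_objectives,
                                   onset_objectives, _peak_fn)
from graspkin.synth import GroundTruth, TrialMeta, TrialRecording, \
    min_jerk_position, min_jerk_speed_peak

from conftest import make_config, trials_from


def make_trial(index, thumb, wrist, fs=200.0):
    n = len(wrist)
    meta = TrialMeta("T", "inexperienced", "normal", 80, "none", 1, 1)
    return TrialRecording(t=np.arange(n) / fs, index_tip=np.asarray(index, float),
                         thumb_tip=np.asarray(thumb, float),
                         wrist=np.asarray(wrist, float), meta=meta)


def stationary_trial(n=400, aperture=10.0):
    wrist = np.zeros((n, 3))
    index = np.tile([aperture / 2, 0, 0], (n, 1))
    thumb = np.tile([-aperture / 2, 0, 0], (n, 1))
    return make_trial(index, thumb, wrist)


class TestDeriveSignals:
    def test_stationary_trial_all_velocities_zero(self):
        sig = derive_signals(stationary_trial())
        assert np.allclose(sig.av_vel_y, 0) and np.allclose(sig.av_vel_z, 0)
        assert np.allclose(sig.ap_rate, 0)
        assert np.allclose(sig.aperture, 10.0)

    def test_linear_motion_velocity(self):
        n, fs = 400, 200.0
        y = 100.0 * np.arange(n) / fs       # 100 mm/s along +y
        wrist = np.column_stack([np.zeros(n), y, np.zeros(n)])
        index = wrist + [5, 0, 0]
        thumb = wrist + [-5, 0, 0]
        sig = derive_signals(make_trial(index, thumb, wrist))
        interior = slice(60, -60)
        assert np.allclose(sig.vel_y["wrist"][interior], 100.0, atol=1.0)

    def test_min_jerk_peak_speed_within_one_percent(self):
        n, fs, d, dur = 401, 200.0, 200.0, 1.0
        s = np.clip(np.arange(n) / fs / dur, 0, 1)
        y = d * min_jerk_position(s)
        wrist = np.column_stack([np.zeros(n), y, np.zeros(n)])
        sig = derive_signals(make_trial(wrist + [5, 0, 0], wrist + [-5, 0, 0],
                                        wrist))
        assert sig.wrist_speed.max() == pytest.approx(
            min_jerk_speed_peak(d, dur), rel=0.01)

    def test_errors_on_bad_input(self):
        trial = stationary_trial(n=3)
        with pytest.raises(SegmentationError, match="5 samples"):
            derive_signals(trial)
        trial = stationary_trial()
        trial.t = trial.t ** 1.01
        with pytest.raises(SegmentationError, match="non-uniform"):
            derive_signals(trial)
        trial = stationary_trial()
        trial.wrist[10, 2] = np.nan
        with pytest.raises(SegmentationError, match="NaN"):
            derive_signals(trial)


class TestObjectiveValues:
    def test_peak_function_hand_value(self):
        # (sqrt(0.25) - 0.25)^2 = 0.0625, the global maximum of the product
        assert _peak_fn(0.25) * _peak_fn(0.25) == pytest.approx(0.0625)
        grid = np.linspace(0, 1, 1001)
        assert (_peak_fn(grid) * _peak_fn(grid)).max() <= 0.0625 + 1e-12

    def test_time_gate_closes_after_two_seconds(self, small_cohort_trials):
        sig = derive_signals(small_cohort_trials[0])
        f = onset_objectives(sig)
        late = sig.t > 2.0
        if late.any():
            assert np.all(f["f1_time"][late] == 0.0)
        assert np.all(f["f1_time"][sig.t < 2.0] == 1.0)

    def test_stationary_trial_degenerate_normalisers_warn(self):
        # a fully static trial has zero-maximum normalisers: the affected
        # functions collapse to zero with a warning rather than NaN
        sig = derive_signals(stationary_trial())
        with pytest.warns(UserWarning):
            f = onset_objectives(sig)
        # zero displacement everywhere: every (1 - Drel) factor stays 1
        assert set(np.unique(f["f5_displacement"])) <= {1.0}
        # zero velocity everywhere: the velocity peak-function collapses to 0
        assert set(np.unique(f["f4_velocity"])) <= {0.0}

    def test_f5_is_one_at_start_for_moving_trial(self, small_cohort_trials):
        trial = small_cohort_trials[0]
        sig = derive_signals(trial)
        f = onset_objectives(sig)
        assert f["f5_displacement"][0] == pytest.approx(1.0, abs=0.05)

    def test_end_function_values(self, small_cohort_trials):
        trial = small_cohort_trials[0]
        sig = derive_signals(trial)
        g = end_objectives(sig, t_ma=float(sig.t[np.argmax(sig.aperture)]))
        # where wrist y-velocity peaks, g4 = 1 - 1 = 0
        assert g["g4_wrist_still"][np.argmax(sig.vel_y["wrist"])] == \
            pytest.approx(0.0, abs=1e-12)
        # where mean z-velocity peaks, g5 = sqrt(1) - 1 = 0
        assert g["g5_lift_velocity"][np.argmax(sig.av_vel_z)] == \
            pytest.approx(0.0, abs=1e-12)
        # where the aperture rate is (near) zero after tMA, g6 ~ 1
        assert g["g6_aperture_still"][np.argmin(np.abs(sig.ap_rate))] == \
            pytest.approx(1.0, abs=0.01)

    def test_t_ma_outside_series_raises(self, small_cohort_trials):
        sig = derive_signals(small_cohort_trials[0])
        with pytest.raises(SegmentationError):
            end_objectives(sig, t_ma=1e6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_objective_values_in_unit_interval(self, seed):
        trials = trials_from(make_config(seed=seed, trials_per_cell=1),
                             limit=12)
        for trial in trials:
            sig = derive_signals(trial)
            fns = onset_objectives(sig)
            fns.update(end_objectives(
                sig, t_ma=float(sig.t[np.argmax(sig.aperture)])))
            for name, series in fns.items():
                assert np.all(series >= -1e-12), name
                assert np.all(series <= 1 + 1e-12), name


class TestSegmentTrial:
    def test_translation_invariance(self, small_cohort_trials):
        trial = small_cohort_trials[0]
        shifted = TrialRecording(
            t=trial.t, index_tip=trial.index_tip + [100, -50, 30],
            thumb_tip=trial.thumb_tip + [100, -50, 30],
            wrist=trial.wrist + [100, -50, 30], meta=trial.meta)
        a = segment_trial(trial)
        b = segment_trial(shifted)
        assert (a.onset_idx, a.end_idx) == (b.onset_idx, b.end_idx)

    def test_short_reach_never_satisfies_end_gate(self):
        # a movement that stops 100 mm short of the grasp region can never
        # open the end-position gate (fingers must pass 190 mm)
        trials = trials_from(make_config(seed=2, reach_distance=100.0),
                             limit=3)
        for trial in trials:
            res = segment_trial(trial)
            assert res.status == "no_end"

    def test_argmax_tie_takes_earliest(self):
        like = np.array([0.0, 0.5, 0.5, 0.2])
        assert int(np.argmax(like)) == 1  # documents the tie-break rule

    def test_recovery_on_clean_trials(self):
        trials = trials_from(make_config(seed=17, n_inexperienced=3,
                                         n_magicians=2), limit=100)
        onset_err, end_err = [], []
        for trial in trials:
            seg = segment_trial(trial)
            assert seg.ok
            gt = trial.ground_truth
            onset_err.append(abs(trial.t[seg.onset_idx] - gt.onset_s))
            end_err.append(abs(trial.t[seg.end_idx] - gt.end_s))
        assert np.mean(np.asarray(onset_err) <= 0.025) >= 0.95
        assert np.mean(np.asarray(end_err) <= 0.050) >= 0.95

    def test_error_degrades_gracefully_with_jitter(self):
        medians = []
        for jitter in (0.0, 0.5, 2.0):
            cfg = make_config(seed=5, marker_jitter_sd=jitter)
            errs = []
            for trial in trials_from(cfg, limit=30):
                seg = segment_trial(trial)
                if seg.ok:
                    errs.append(abs(trial.t[seg.onset_idx]
                                    - trial.ground_truth.onset_s))
            medians.append(np.median(errs))
        assert medians[0] <= medians[-1] + 1e-9
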