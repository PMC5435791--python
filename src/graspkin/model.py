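"""Model/Results objects tying the whole analysis together.

:class:`GraspStudy` is built from per-trial marker recordings (simulated or
loaded from CSV) plus the analysis settings; :meth:`GraspStudy.fit` runs
segmentation -> kinematics -> bias -> statistics in a single pass over the
trials and returns a :class:`GraspStudyResults` carrying the trial-level
tables, per-participant bias estimates, group summaries shaped like the
published tables, the statistical battery, and (for synthetic cohorts)
segmentation-recovery diagnostics against ground truth.

Typical use::

    study = GraspStudy.simulate(GeneratorConfig(seed=7))
    res = study.fit()
    print(res.summary())
    res.table_bias()          # group x task bias means (SD)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import stats as stats_mod
from .config import (ExclusionRules, GeneratorConfig, ObjectiveThresholds,
                     PipelineConfig, SignalOptions)
from .kinematics import (KinematicSummary, apply_exclusions, summarize_trial,
                         time_normalise_aperture)
from .segmentation import SegmentationError, derive_signals, segment_trial
from .synth import (Cohort, TrialMeta, TrialRecording, draw_participants,
                    iter_cohort_trials)

__all__ = ["GraspStudy", "GraspStudyResults"]


class GraspStudy:
    """A reach-to-grasp study: trials plus analysis settings.

    Parameters
    ----------
    trials
        Trial recordings, or a zero-argument callable returning a fresh
        iterator over them (used by :meth:`simulate` so cohorts can be
        streamed without holding every trajectory in memory).
    thresholds, signal_options, exclusion_rules
        Segmentation and filtering settings; defaults follow the published
        constants.
    """

    def __init__(self,
                 trials: Iterable[TrialRecording] | Callable[[], Iterator[TrialRecording]],
                 thresholds: ObjectiveThresholds | None = None,
                 signal_options: SignalOptions | None = None,
                 exclusion_rules: ExclusionRules | None = None,
                 n_normalised_points: int = 101):
        self._trials = trials
        self.thresholds = thresholds or ObjectiveThresholds()
        self.signal_options = signal_options or SignalOptions()
        self.exclusion_rules = exclusion_rules or ExclusionRules()
        self.n_normalised_points = n_normalised_points

    # ------------------------------------------------------------------ build
    @classmethod
    def simulate(cls, config: GeneratorConfig | None = None,
                 seed: int | None = None, **kwargs) -> "GraspStudy":
        """Build a study over a streamed synthetic cohort."""
        config = config or GeneratorConfig()
        if seed is not None:
            config.seed = seed
        config.validate()

        def factory() -> Iterator[TrialRecording]:
            rng = np.random.default_rng(config.seed)
            participants = draw_participants(config, rng)
            return iter_cohort_trials(config, participants, rng)

        study = cls(factory, **kwargs)
        study.generator_config = config
        return study

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "GraspStudy":
        study = cls(cohort.trials, **kwargs)
        study.generator_config = cohort.config
        return study

    @classmethod
    def from_pipeline_config(cls, config: PipelineConfig) -> "GraspStudy":
        config.validate()
        gen = config.generator
        gen.seed = config.seed
        return cls.simulate(gen, thresholds=config.thresholds,
                            signal_options=config.signals,
                            exclusion_rules=config.exclusions,
                            n_normalised_points=config.n_normalised_points)

    def _iter(self) -> Iterator[TrialRecording]:
        if callable(self._trials):
            return self._trials()
        return iter(self._trials)

    # -------------------------------------------------------------------- fit
    def fit(self, run_stats: bool = True) -> "GraspStudyResults":
        """Segment every trial, extract measures, compute biases and stats."""
        kin_rows: list[KinematicSummary] = []
        trial_meta: list[TrialMeta] = []
        seg_rows: list[dict] = []
        profiles: dict[tuple, tuple[np.ndarray, int]] = {}
        recovery_rows: list[dict] = []
        n_trials = 0

        for trial in self._iter():
            n_trials += 1
            meta = trial.meta
            exclusion = apply_exclusions(trial, self.exclusion_rules)
            seg = None
            signals = None
            if not exclusion.excluded:
                try:
                    signals = derive_signals(trial, self.signal_options)
                    seg = segment_trial(trial, self.thresholds, signals=signals)
                except SegmentationError:
                    seg = None
            if seg is None:
                from .segmentation import SegmentationResult
                seg = SegmentationResult("no_onset", None, None,
                                         np.zeros(1), np.zeros(1), {})
            summary = summarize_trial(trial, seg, exclusion,
                                      signals=signals)
            kin_rows.append(summary)
            trial_meta.append(meta)
            seg_rows.append({
                "trial_id": meta.trial_id, "status": seg.status if not
                exclusion.excluded else f"excluded:{exclusion.reason}",
                "onset_s": trial.t[seg.onset_idx] if seg.onset_idx is not None else np.nan,
                "end_s": trial.t[seg.end_idx] if seg.end_idx is not None else np.nan,
                "t_ma": seg.diagnostics.get("t_ma", np.nan),
            })
            if summary.valid and seg.ok:
                key = (meta.task, meta.object_length_mm, meta.fins)
                prof = time_normalise_aperture(trial, seg,
                                               self.n_normalised_points)
                if key in profiles:
                    acc, cnt = profiles[key]
                    profiles[key] = (acc + prof, cnt + 1)
                else:
                    profiles[key] = (prof.copy(), 1)
                if trial.ground_truth is not None:
                    gt = trial.ground_truth
                    recovery_rows.append({
                        "trial_id": meta.trial_id,
                        "onset_error_s": float(trial.t[seg.onset_idx] - gt.onset_s),
                        "end_error_s": float(trial.t[seg.end_idx] - gt.end_s),
                        "ma_error_mm": float(summary.ma_mm - gt.ma_true_mm),
                    })
        kinematics = pd.DataFrame([{
            "trial_id": sm.trial_id, "participant_id": m.participant_id,
            "group": m.group, "task": m.task,
            "object_length_mm": m.object_length_mm, "fins": m.fins,
            "block": m.block, "trial": m.trial,
            "ma_mm": sm.ma_mm, "mt_s": sm.mt_s, "pv_mm_s": sm.pv_mm_s,
            "valid": sm.valid, "exclusion_reason": sm.exclusion_reason,
        } for m, sm in zip(trial_meta, kin_rows)])
        segments = pd.DataFrame(seg_rows)
        participant_bias = bias_mod.participant_bias_table(kinematics) \
            if len(kinematics) else pd.DataFrame()
        group_bias = bias_mod.group_bias_table(participant_bias) \
            if len(participant_bias) else pd.DataFrame()

        stat_results: list[stats_mod.StatResult] = []
        if run_stats and len(participant_bias) and \
                kinematics["group"].nunique() == 2:
            try:
                stat_results = stats_mod.run_statistical_battery(
                    kinematics, participant_bias)
            except ValueError as exc:
                import logging
                logging.getLogger(__name__).warning(
                    "statistical battery skipped: %s", exc)
                stat_results = []

        prof_rows = []
        for (task, length, fins), (acc, cnt) in sorted(profiles.items()):
            mean_prof = acc / cnt
            for i, val in enumerate(mean_prof):
                prof_rows.append({"task": task, "object_length_mm": length,
                                  "fins": fins,
                                  "pct_movement": 100.0 * i / (len(mean_prof) - 1),
                                  "aperture_mm": val, "n_trials": cnt})
        aperture_profiles = pd.DataFrame(prof_rows)

        reasons = kinematics["exclusion_reason"].value_counts().to_dict() \
            if len(kinematics) else {}
        return GraspStudyResults(
            study=self, n_trials=n_trials, kinematics=kinematics,
            segments=segments, participant_bias=participant_bias,
            group_bias=group_bias, stat_results=stat_results,
            aperture_profiles=aperture_profiles,
            recovery=pd.DataFrame(recovery_rows),
            exclusion_counts=reasons)


@dataclass
class GraspStudyResults:
    """Fitted results: tables, bias estimates, statistics and diagnostics."""

    study: GraspStudy
    n_trials: int
    kinematics: pd.DataFrame
    segments: pd.DataFrame
    participant_bias: pd.DataFrame
    group_bias: pd.DataFrame
    stat_results: list = field(default_factory=list)
    aperture_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    recovery: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusion_counts: dict = field(default_factory=dict)

    # ------------------------------------------------------------- summaries
    def _measure_table(self, column: str) -> pd.DataFrame:
        """Group x task x size mean (SE across participants), plain bars."""
        valid = self.kinematics[self.kinematics["valid"].astype(bool)]
        plain = valid[valid["fins"] == "none"]
        per_part = (plain.groupby(
            ["group", "task", "object_length_mm", "participant_id"],
            observed=True)[column].mean().reset_index())
        out = (per_part.groupby(["group", "task", "object_length_mm"],
                                observed=True)[column]
               .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n="count")
               .reset_index())
        return out

    def table_ma(self) -> pd.DataFrame:
        return self._measure_table("ma_mm")

    def table_mt(self) -> pd.DataFrame:
        return self._measure_table("mt_s")

    def table_pv(self) -> pd.DataFrame:
        return self._measure_table("pv_mm_s")

    def table_bias(self) -> pd.DataFrame:
        return self.group_bias

    def stats_frame(self) -> pd.DataFrame:
        return stats_mod.results_to_frame(self.stat_results) \
            if self.stat_results else pd.DataFrame()

    def summary(self) -> str:
        """A plain-text report of the fitted study."""
        lines = ["Grasp-kinematics study summary",
                 "=" * 34,
                 f"trials analysed: {self.n_trials}"]
        exc = {k: v for k, v in self.exclusion_counts.items() if k != "none"}
        lines.append(f"excluded trials: {sum(exc.values())} {exc if exc else ''}".rstrip())
        for label, table, fmt in (("Maximum aperture (mm)", self.table_ma(), ".1f"),
                                  ("Movement time (s)", self.table_mt(), ".2f"),
                                  ("Peak velocity (mm/s)", self.table_pv(), ".0f")):
            if len(table) == 0:
                continue
            lines.append("")
            lines.append(label + " — mean (SE) per group x task x size")
            for _, r in table.iterrows():
                lines.append(f"  {r['group']:<14}{r['task']:<11}"
                             f"{int(r['object_length_mm'])} mm: "
                             f"{r['mean']:{fmt}} ({r['se']:{fmt}})")
        if len(self.group_bias):
            lines.append("")
            lines.append("Illusory bias (%) — mean (SD) across participants")
            for _, r in self.group_bias.iterrows():
                for task in ("normal", "pantomime"):
                    lines.append(
                        f"  {r['group']:<14}{task:<11}"
                        f"uncorrected {r[f'uncorrected_{task}_mean']:5.2f} "
                        f"({r[f'uncorrected_{task}_sd']:.2f})   "
                        f"corrected {r[f'corrected_{task}_mean']:5.2f} "
                        f"({r[f'corrected_{task}_sd']:.2f})")
        sig = [r for r in self.stat_results
               if r.test == "one_sample_t" and not r.degenerate]
        if sig:
            lines.append("")
            lines.append("One-sample t tests of corrected bias vs 0 (Bonferroni)")
            for r in sig:
                lines.append(f"  {r.name}: t({r.df:.0f}) = {r.statistic:.2f}, "
                             f"p = {r.p_value:.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------ plots
    def plot_aperture_profiles(self, task: str = "pantomime", ax=None):
        """Mean time-normalised aperture of the 80 mm bar by fins config."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.aperture_profiles
        sub = prof[(prof["task"] == task) & (prof["object_length_mm"] == 80)]
        styles = {"none": "-", "in": ":", "out": "--"}
        for fins, style in styles.items():
            line = sub[sub["fins"] == fins]
            if len(line):
                ax.plot(line["pct_movement"], line["aperture_mm"], style,
                        label={"none": "plain", "in": "fins-in",
                               "out": "fins-out"}[fins])
        ax.set_xlabel("movement time (%)")
        ax.set_ylabel("hand aperture (mm)")
        ax.set_title(f"{task} grasping, 80 mm bar")
        ax.legend()
        return ax

    def plot_bias(self, ax=None):
        """Corrected bias per group and task with SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pb = self.participant_bias
        offset = {"inexperienced": -0.05, "magician": 0.05}
        marker = {"inexperienced": "o", "magician": "s"}
        for group, sub in pb.groupby("group"):
            xs, means, ses = [], [], []
            for i, task in enumerate(("normal", "pantomime")):
                vals = sub[sub["task"] == task]["bias_corrected"].dropna()
                xs.append(i + offset.get(group, 0))
                means.append(vals.mean())
                ses.append(vals.std(ddof=1) / np.sqrt(len(vals)))
            ax.errorbar(xs, means, yerr=ses, fmt=marker.get(group, "o"),
                        capsize=4, label=group)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks([0, 1], ["normal", "pantomime"])
        ax.set_ylabel("corrected illusory bias (%)")
        ax.legend()
        return ax
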