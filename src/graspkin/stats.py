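"""The experiment's statistical battery on pipeline output tables.

Covers the tests applied to the kinematic measures and the bias statistic:

* split-plot ("mixed") ANOVA — one between-subjects factor (group) and one or
  two within-subjects factors (task, object size) — with Mauchly's sphericity
  test, Greenhouse-Geisser df correction when sphericity is violated, and
  partial eta-squared effect sizes;
* Bonferroni-corrected one-sample t tests (is the illusory bias > 0?);
* a nonparametric branch for non-normal measures: Friedman across object
  sizes, Mann-Whitney U between groups, pairwise Wilcoxon signed-rank tests
  (exact small-sample p-values where n <= 12 and there are no ties);
* Pearson / Kendall correlation screens with per-point Cook's distance from
  the underlying simple regression.

The ANOVA is computed stratum by stratum via orthonormal within-subject
contrast scores: for each within effect the subject-level scores are
regressed on the (sum-coded) group factor, giving the classic univariate
repeated-measures F tests with their correct error terms, for balanced
within-subject data and (possibly) unequal group sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

import statsmodels.api as sm

__all__ = ["StatResult", "mixed_anova", "bonferroni_one_sample_t",
           "nonparametric_battery", "correlation_screen",
           "run_statistical_battery", "results_to_frame"]


@dataclass
class StatResult:
    """One test outcome: statistic, (possibly corrected) df, p and effect size."""

    name: str
    test: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    correction: str = "none"       # none | greenhouse_geisser | bonferroni
    degenerate: bool = False
    primary: bool = True
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"name": self.name, "test": self.test, "statistic": self.statistic,
             "df": self.df, "p_value": self.p_value,
             "effect_size": self.effect_size,
             "effect_size_name": self.effect_size_name,
             "correction": self.correction, "degenerate": self.degenerate,
             "primary": self.primary}
        d.update(self.extra)
        return d


def results_to_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# split-plot mixed ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    return helmert(k, full=False)


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of orthonormal scores."""
    d = cov.shape[0]
    if d <= 1:
        return 1.0
    tr = float(np.trace(cov))
    tr2 = float(np.trace(cov @ cov))
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / (d * tr2), 1.0 / d, 1.0))


def _mauchly(cov: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value (sphericity test)."""
    d = cov.shape[0]
    if d <= 1:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(np.mean(eig))))
    df = d * (d + 1) // 2 - 1
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * n_error)
    chi2 = -f_corr * n_error * math.log(max(w, 1e-300))
    p = float(sps.chi2.sf(chi2, df))
    return w, p


def _type3_column_ss(z: np.ndarray, codes: np.ndarray
                     ) -> tuple[float, float, float]:
    """(SS_intercept, SS_group, RSS) for one score column regressed on
    an intercept plus sum-coded group."""
    x = np.column_stack([np.ones_like(codes), codes])
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ z
    resid = z - x @ beta
    rss = float(resid @ resid)
    ss_int = float(beta[0] ** 2 / xtx_inv[0, 0])
    ss_grp = float(beta[1] ** 2 / xtx_inv[1, 1])
    return ss_int, ss_grp, rss


def _f_result(name: str, ss_eff: float, df1: float, ss_err: float, df2: float,
              epsilon: float = 1.0, sphericity_p: float = 1.0,
              alpha: float = 0.05) -> StatResult:
    """Assemble an F test, applying GG correction when sphericity fails."""
    if ss_err <= 1e-12 and ss_eff <= 1e-12:
        return StatResult(name=name, test="mixed_anova_f", statistic=0.0,
                          df=(df1, df2), p_value=1.0, effect_size=0.0,
                          effect_size_name="partial_eta_sq", degenerate=True)
    correction = "none"
    adj1, adj2 = df1, df2
    if sphericity_p < alpha and epsilon < 1.0:
        correction = "greenhouse_geisser"
        adj1, adj2 = epsilon * df1, epsilon * df2
    if ss_err <= 0:
        f_val, p = float("inf"), 0.0
    else:
        f_val = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(f_val, adj1, adj2))
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return StatResult(name=name, test="mixed_anova_f", statistic=float(f_val),
                      df=(float(adj1), float(adj2)), p_value=p,
                      effect_size=float(eta), effect_size_name="partial_eta_sq",
                      correction=correction,
                      extra={"uncorrected_df": (float(df1), float(df2)),
                             "gg_epsilon": float(epsilon),
                             "mauchly_p": float(sphericity_p)})


def mixed_anova(table: pd.DataFrame, dv: str, subject: str, between: str,
                within: Sequence[str], alpha: float = 0.05) -> list[StatResult]:
    """Split-plot ANOVA: main effects and all interactions.

    ``table`` is long-format with exactly one value per subject x within-cell
    (aggregate to cell means first).  Requires >= 2 levels per factor, exactly
    two between-subject groups, and complete within-subject data.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within-subject factors are supported")
    groups = sorted(table[between].astype(str).unique())
    if len(groups) != 2:
        raise ValueError("exactly two between-subject groups are required")
    levels = {w: sorted(table[w].unique()) for w in within}
    for w in within:
        if len(levels[w]) < 2:
            raise ValueError(f"factor {w} needs >= 2 levels")

    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean", observed=True)
    cols = list(itertools.product(*(levels[w] for w in within))) \
        if len(within) > 1 else [(lv,) for lv in levels[within[0]]]
    wide = wide[[c if len(within) > 1 else c[0] for c in cols]]
    if wide.isna().any().any():
        raise ValueError("within-subject data must be complete for every subject")
    subj_group = table.groupby(subject, observed=True)[between].first()
    codes = np.where(subj_group.loc[wide.index].astype(str) == groups[0], 1.0, -1.0)
    y = wide.to_numpy(float)                      # subjects x cells
    n_subj = y.shape[0]
    if n_subj <= 2:
        raise ValueError("need more than two subjects")
    n_error = n_subj - 2                          # subjects - groups

    shape = tuple(len(levels[w]) for w in within)
    m = y.reshape((n_subj,) + shape)              # subject x w1 (x w2)

    results: list[StatResult] = []

    # between stratum: subject means
    subj_means = y.mean(axis=1)
    cells = y.shape[1]
    grand = subj_means.mean()
    ss_g = 0.0
    for gname, code in zip(groups, (1.0, -1.0)):
        sel = subj_means[codes == code]
        ss_g += len(sel) * (sel.mean() - grand) ** 2
    ss_subj_err = sum(((subj_means[codes == code]
                        - subj_means[codes == code].mean()) ** 2).sum()
                      for code in (1.0, -1.0))
    results.append(_f_result(between, cells * ss_g, 1.0,
                             cells * ss_subj_err, float(n_error), alpha=alpha))

    # within strata via orthonormal contrast scores
    contrasts = {w: _orthonormal_contrasts(len(levels[w])) for w in within}

    def stratum(name: str, scores: np.ndarray, df1: int):
        pooled = np.zeros((scores.shape[1], scores.shape[1]))
        for code in (1.0, -1.0):
            zc = scores[codes == code]
            zc = zc - zc.mean(axis=0)
            pooled += zc.T @ zc
        pooled /= n_error
        eps = _gg_epsilon(pooled)
        _, sph_p = _mauchly(pooled, n_error)
        ss_eff = ss_int = rss = 0.0
        for col in range(scores.shape[1]):
            a, b, r = _type3_column_ss(scores[:, col], codes)
            ss_eff += a
            ss_int += b
            rss += r
        df2 = float(df1 * n_error)
        results.append(_f_result(name, ss_eff, float(df1), rss, df2,
                                 eps, sph_p, alpha))
        results.append(_f_result(f"{name} * {between}", ss_int, float(df1),
                                 rss, df2, eps, sph_p, alpha))

    if len(within) == 1:
        w = within[0]
        stratum(w, m @ contrasts[w].T, len(levels[w]) - 1)
    else:
        w1, w2 = within
        k1, k2 = len(levels[w1]), len(levels[w2])
        stratum(w1, m.mean(axis=2) @ contrasts[w1].T, k1 - 1)
        stratum(w2, m.mean(axis=1) @ contrasts[w2].T, k2 - 1)
        q_int = np.kron(contrasts[w1], contrasts[w2])
        stratum(f"{w1} * {w2}", m.reshape(n_subj, k1 * k2) @ q_int.T,
                (k1 - 1) * (k2 - 1))
    return results


# ---------------------------------------------------------------------------
# one-sample t battery


def bonferroni_one_sample_t(values: np.ndarray, mu: float = 0.0, m: int = 1,
                            name: str = "one_sample_t",
                            alternative: str = "two-sided") -> StatResult:
    """One-sample t test with Bonferroni adjustment over ``m`` comparisons."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two observations")
    if np.std(values, ddof=1) == 0:
        equal = float(values[0]) == mu
        return StatResult(name=name, test="one_sample_t",
                          statistic=0.0 if equal else float("inf"),
                          df=float(n - 1), p_value=1.0 if equal else 0.0,
                          correction="bonferroni", degenerate=True,
                          extra={"m": m, "p_uncorrected": 1.0 if equal else 0.0})
    t_stat, p_raw = sps.ttest_1samp(values, popmean=mu, alternative=alternative)
    p_adj = min(1.0, m * float(p_raw))
    return StatResult(name=name, test="one_sample_t", statistic=float(t_stat),
                      df=float(n - 1), p_value=p_adj, correction="bonferroni",
                      extra={"m": m, "p_uncorrected": float(p_raw),
                             "mean": float(values.mean()),
                             "sd": float(values.std(ddof=1))})


# ---------------------------------------------------------------------------
# nonparametric battery


EXACT_N_MAX = 12  # exact p-values at or below this sample size, else asymptotic


def _friedman(data: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with mid-ranks and tie correction.

    Unlike :func:`scipy.stats.friedmanchisquare`, this also handles the
    two-condition case (equivalent to a two-sided sign test on the ranks).
    """
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction (mid-ranks)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n * k * (k ** 2 - 1))
    if denom > 0:
        chi2 /= denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return float(chi2), p


def _wilcoxon(name: str, x: np.ndarray, y: np.ndarray) -> StatResult:
    d = np.asarray(x, float) - np.asarray(y, float)
    nz = d[d != 0]
    if len(nz) == 0:
        return StatResult(name=name, test="wilcoxon_signed_rank",
                          statistic=float("nan"), df=None, p_value=float("nan"),
                          degenerate=True,
                          extra={"note": "no nonzero differences"})
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(x, y, method=method)
    return StatResult(name=name, test="wilcoxon_signed_rank",
                      statistic=float(res.statistic), df=None,
                      p_value=float(res.pvalue),
                      extra={"method": method, "n_nonzero": int(len(nz))})


def nonparametric_battery(wide: pd.DataFrame, group: pd.Series,
                          measure: str = "measure") -> list[StatResult]:
    """Friedman across the columns, Mann-Whitney between groups on row means,
    and pairwise Wilcoxon signed-rank tests.

    ``wide`` is subjects x conditions (e.g., the three object sizes); ``group``
    maps each subject to its group label.  Ties are handled with mid-ranks.
    """
    cols = list(wide.columns)
    results: list[StatResult] = []

    arrays = [wide[c].to_numpy(float) for c in cols]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        results.append(StatResult(name=f"{measure}: friedman", test="friedman",
                                  statistic=0.0, df=float(len(cols) - 1),
                                  p_value=1.0, degenerate=True))
    else:
        chi2, p = _friedman(np.column_stack(arrays))
        results.append(StatResult(name=f"{measure}: friedman", test="friedman",
                                  statistic=float(chi2), df=float(len(cols) - 1),
                                  p_value=float(p)))

    labels = sorted(group.astype(str).unique())
    if len(labels) == 2:
        means = wide.mean(axis=1)
        g1 = means[group.astype(str) == labels[0]].to_numpy(float)
        g2 = means[group.astype(str) == labels[1]].to_numpy(float)
        pooled = np.concatenate([g1, g2])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(g1), len(g2)) <= EXACT_N_MAX
                             and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(g1, g2, method=method)
        u = float(res.statistic)
        n1, n2 = len(g1), len(g2)
        mu_u = n1 * n2 / 2.0
        sd_u = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (u - mu_u) / sd_u if sd_u > 0 else float("nan")
        results.append(StatResult(
            name=f"{measure}: mann_whitney {labels[0]} vs {labels[1]}",
            test="mann_whitney_u", statistic=u, df=None,
            p_value=float(res.pvalue),
            extra={"z": z, "method": method, "n": (n1, n2)}))

    for a, b in itertools.combinations(cols, 2):
        results.append(_wilcoxon(f"{measure}: wilcoxon {a} vs {b}",
                                 wide[a].to_numpy(float), wide[b].to_numpy(float)))
    return results


# ---------------------------------------------------------------------------
# correlation + influence screen


def correlation_screen(x: np.ndarray, y: np.ndarray, method: str = "pearson",
                       name: str = "correlation"
                       ) -> tuple[StatResult, np.ndarray]:
    """Correlation between x and y plus per-point Cook's distance.

    Cook's distances come from the simple linear regression of y on x
    regardless of the correlation method, mirroring the use of the regression
    fit to screen for influential observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (StatResult(name=name, test=method, statistic=float("nan"),
                           df=None, p_value=float("nan"), degenerate=True,
                           extra={"note": "zero variance"}),
                np.full(len(x), np.nan))
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        eff, eff_name = float(r) ** 2, "r_squared"
    elif method == "kendall":
        r, p = sps.kendalltau(x, y)
        eff, eff_name = None, None
    else:
        raise ValueError(f"unknown method {method!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = model.get_influence().cooks_distance[0]
    return (StatResult(name=name, test=method, statistic=float(r), df=None,
                       p_value=float(p), effect_size=eff,
                       effect_size_name=eff_name,
                       extra={"n": len(x), "max_cooks_d": float(np.max(cooks))}),
            cooks)


# ---------------------------------------------------------------------------
# the full battery on pipeline tables


def _cell_normality(cell_table: pd.DataFrame, dv: str,
                    by: Sequence[str], alpha: float = 0.05) -> bool:
    """True when every cell passes Shapiro-Wilk at alpha."""
    for _, sub in cell_table.groupby(list(by), observed=True):
        vals = sub[dv].to_numpy(float)
        if len(vals) >= 3 and np.std(vals) > 0:
            if sps.shapiro(vals).pvalue < alpha:
                return False
    return True


def run_statistical_battery(kinematics: pd.DataFrame,
                            participant_bias: pd.DataFrame,
                            alpha: float = 0.05) -> list[StatResult]:
    """The full test battery on the trial-level kinematics and bias tables.

    For MA, MT and PV: participant x task x size cell means (plain bars only)
    go into a 2 (group) x 2 (task) x 3 (size) split-plot ANOVA, and into the
    nonparametric branch; whichever branch the per-cell Shapiro-Wilk check
    selects is flagged primary, but both are always computed and reported.
    For the corrected bias: a 2 x 2 group-by-task ANOVA plus four
    Bonferroni-corrected one-sample t tests against zero.
    """
    valid = kinematics[kinematics["valid"].astype(bool)]
    plain = valid[valid["fins"] == "none"]
    cell = (plain.groupby(["participant_id", "group", "task", "object_length_mm"],
                          observed=True)
            .agg(ma_mm=("ma_mm", "mean"), mt_s=("mt_s", "mean"),
                 pv_mm_s=("pv_mm_s", "mean"))
            .reset_index())

    # listwise completeness: drop participants missing any of the 6 cells
    counts = cell.groupby("participant_id", observed=True).size()
    complete = counts[counts == 6].index
    cell = cell[cell["participant_id"].isin(complete)]

    results: list[StatResult] = []
    for dv in ("ma_mm", "mt_s", "pv_mm_s"):
        normal = _cell_normality(cell, dv,
                                 ("group", "task", "object_length_mm"), alpha)
        anova = mixed_anova(cell, dv=dv, subject="participant_id",
                            between="group", within=["task", "object_length_mm"],
                            alpha=alpha)
        for r in anova:
            r.name = f"{dv}: {r.name}"
            r.primary = normal
        results.extend(anova)

        size_wide = cell.pivot_table(index="participant_id",
                                     columns="object_length_mm", values=dv,
                                     aggfunc="mean", observed=True)
        group = cell.groupby("participant_id", observed=True)["group"].first()
        task_wide = cell.pivot_table(index="participant_id", columns="task",
                                     values=dv, aggfunc="mean", observed=True)
        nonpar = nonparametric_battery(size_wide, group.loc[size_wide.index],
                                       measure=f"{dv} by size")
        nonpar += nonparametric_battery(task_wide, group.loc[task_wide.index],
                                        measure=f"{dv} by task")
        for r in nonpar:
            r.primary = not normal
        results.extend(nonpar)

    # corrected bias: 2 x 2 ANOVA + one-sample t battery
    pb = participant_bias[participant_bias["slope_valid"]]
    counts = pb.groupby("participant_id", observed=True).size()
    pb2 = pb[pb["participant_id"].isin(counts[counts == 2].index)]
    if pb2["participant_id"].nunique() > 2 and pb2["group"].nunique() == 2:
        anova = mixed_anova(pb2, dv="bias_corrected", subject="participant_id",
                            between="group", within=["task"], alpha=alpha)
        for r in anova:
            r.name = f"bias_corrected: {r.name}"
        results.extend(anova)
    cells = [(g, t) for g in sorted(pb["group"].unique())
             for t in sorted(pb["task"].unique())]
    m = len(cells)
    for g, t in cells:
        vals = pb[(pb["group"] == g) & (pb["task"] == t)]["bias_corrected"]
        if len(vals) >= 2:
            # directional hypothesis: the bias genuinely exceeds zero
            results.append(bonferroni_one_sample_t(
                vals.to_numpy(float), mu=0.0, m=m, alternative="greater",
                name=f"bias_corrected > 0: {g}/{t}"))
    return results
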