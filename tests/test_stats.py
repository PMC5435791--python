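"""Statistical battery: split-plot ANOVA against a brute-force sums-of-squares
oracle, influence diagnostics against a leave-one-out refit, nonparametric
branch behaviour, and error calibration under the null."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from graspkin.stats import (StatResult, _friedman, bonferroni_one_sample_t,
                            correlation_screen, mixed_anova,
                            nonparametric_battery)

rng = np.random.default_rng  # convenience


def long_table(y, groups):
    """y: subjects x tasks x sizes array -> long DataFrame."""
    n, b, c = y.shape
    rows = []
    for i, g in enumerate(groups):
        for j, t in enumerate(["t1", "t2"][:b]):
            for k, s in enumerate([60, 80, 100][:c]):
                rows.append({"participant_id": f"S{i}", "group": g,
                             "task": t, "size": s, "y": y[i, j, k]})
    return pd.DataFrame(rows)


def brute_force_split_plot(y, groups):
    """Classical sums of squares for a balanced two-group split-plot design,
    computed by direct summation over cells (independent oracle)."""
    n, b, c = y.shape
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    g_mean = {g: y[groups == g].mean() for g in labels}
    n_g = {g: np.sum(groups == g) for g in labels}

    ss = {}
    ss["subj"] = b * c * np.sum((subj - grand) ** 2)
    ss["group"] = b * c * sum(n_g[g] * (g_mean[g] - grand) ** 2 for g in labels)
    ss["subj(group)"] = ss["subj"] - ss["group"]

    t_mean = y.mean(axis=(0, 2))
    gt = {g: y[groups == g].mean(axis=(0, 2)) for g in labels}
    ss["task"] = n * c * np.sum((t_mean - grand) ** 2)
    ss["task*group"] = c * sum(
        n_g[g] * np.sum((gt[g] - g_mean[g] - t_mean + grand) ** 2)
        for g in labels)
    # task x subject within group (error term for task effects)
    e = 0.0
    for g in labels:
        sub = y[groups == g]
        for i in range(sub.shape[0]):
            for j in range(b):
                e += c * (sub[i, j].mean() - sub[i].mean()
                          - gt[g][j] + g_mean[g]) ** 2
    ss["task*subj"] = e

    s_mean = y.mean(axis=(0, 1))
    gs = {g: y[groups == g].mean(axis=(0, 1)) for g in labels}
    ss["size"] = n * b * np.sum((s_mean - grand) ** 2)
    ss["size*group"] = b * sum(
        n_g[g] * np.sum((gs[g] - g_mean[g] - s_mean + grand) ** 2)
        for g in labels)
    e = 0.0
    for g in labels:
        sub = y[groups == g]
        for i in range(sub.shape[0]):
            for k in range(c):
                e += b * (sub[i, :, k].mean() - sub[i].mean()
                          - gs[g][k] + g_mean[g]) ** 2
    ss["size*subj"] = e

    ts_mean = y.mean(axis=0)
    gts = {g: y[groups == g].mean(axis=0) for g in labels}
    ss["task*size"] = n * np.sum(
        (ts_mean - t_mean[:, None] - s_mean[None, :] + grand) ** 2)
    ss["task*size*group"] = sum(
        n_g[g] * np.sum((gts[g] - gt[g][:, None] - gs[g][None, :]
                         - ts_mean + t_mean[:, None] + s_mean[None, :]
                         + g_mean[g] - grand) ** 2)
        for g in labels)
    total = np.sum((y - grand) ** 2)
    ss["task*size*subj"] = (total - ss["subj"] - ss["task"] - ss["task*group"]
                            - ss["task*subj"] - ss["size"] - ss["size*group"]
                            - ss["size*subj"] - ss["task*size"]
                            - ss["task*size*group"])
    return ss


class TestMixedAnova:
    def test_partial_eta_sq_matches_brute_force_oracle(self):
        """Partial eta-squared equals SS_effect / (SS_effect + SS_error) from
        the direct-summation oracle on a 4-participant toy table (balanced
        groups, so weighted and unweighted solutions coincide)."""
        y = rng(7).normal(size=(4, 2, 3))
        groups = ["a", "a", "b", "b"]
        ss = brute_force_split_plot(y, groups)
        res = {r.name: r for r in mixed_anova(long_table(y, groups), "y",
                                              "participant_id", "group",
                                              ["task", "size"])}
        pairs = {
            "group": ("group", "subj(group)"),
            "task": ("task", "task*subj"),
            "task * group": ("task*group", "task*subj"),
            "size": ("size", "size*subj"),
            "size * group": ("size*group", "size*subj"),
            "task * size": ("task*size", "task*size*subj"),
            "task * size * group": ("task*size*group", "task*size*subj"),
        }
        for name, (eff, err) in pairs.items():
            expected = ss[eff] / (ss[eff] + ss[err])
            assert res[name].effect_size == pytest.approx(expected, rel=1e-8), name

    def test_f_statistics_match_oracle(self):
        y = rng(19).normal(size=(6, 2, 3)) + \
            np.arange(3)[None, None, :] * 0.5          # a size effect
        groups = ["a"] * 3 + ["b"] * 3
        ss = brute_force_split_plot(y, groups)
        res = {r.name: r for r in mixed_anova(long_table(y, groups), "y",
                                              "participant_id", "group",
                                              ["task", "size"])}
        n = 6
        f_size = (ss["size"] / 2) / (ss["size*subj"] / (2 * (n - 2)))
        assert res["size"].statistic == pytest.approx(f_size, rel=1e-8)
        f_group = (ss["group"] / 1) / (ss["subj(group)"] / (n - 2))
        assert res["group"].statistic == pytest.approx(f_group, rel=1e-8)

    def test_constant_measure_gives_zero_f(self):
        y = np.full((4, 2, 3), 7.0)
        res = mixed_anova(long_table(y, ["a", "a", "b", "b"]), "y",
                          "participant_id", "group", ["task", "size"])
        for r in res:
            assert r.statistic == 0.0 and r.p_value == 1.0 and r.degenerate

    def test_two_level_factor_never_corrected(self):
        y = rng(3).normal(size=(8, 2, 3))
        res = {r.name: r for r in mixed_anova(
            long_table(y, ["a"] * 4 + ["b"] * 4), "y", "participant_id",
            "group", ["task", "size"])}
        # sphericity holds trivially at 2 levels: df must stay (1, n-2)
        assert res["task"].correction == "none"
        assert res["task"].df == (1.0, 6.0)

    def test_gg_epsilon_matches_pingouin(self):
        """Greenhouse-Geisser epsilon for the 3-level factor agrees with an
        independent implementation (pingouin) on one-group data."""
        pg = pytest.importorskip("pingouin")
        y = rng(11).normal(size=(10, 1, 3))
        y[:, :, 2] += y[:, :, 1] * 0.9            # break sphericity
        df = long_table(np.repeat(y, 2, axis=1), ["a"] * 5 + ["b"] * 5)
        res = {r.name: r for r in mixed_anova(df, "y", "participant_id",
                                              "group", ["task", "size"])}
        wide = df[df["task"] == "t1"].pivot(index="participant_id",
                                            columns="size", values="y")
        eps_pg = pg.epsilon(wide, correction="gg")
        # pooled-within-group epsilon vs pingouin's single-group epsilon:
        # same statistic up to the group-mean centring; loose comparison
        assert res["size"].extra["gg_epsilon"] == pytest.approx(
            float(eps_pg), abs=0.1)

    def test_requires_two_groups_and_levels(self):
        y = rng(0).normal(size=(4, 2, 3))
        with pytest.raises(ValueError):
            mixed_anova(long_table(y, ["a"] * 4), "y", "participant_id",
                        "group", ["task", "size"])

    def test_power_for_planted_task_effect(self):
        """A task effect of one within-subject SD is detected in nearly every
        replicate at n = 24 (power-style check of the F machinery)."""
        hits = 0
        for seed in range(20):
            y = rng(100 + seed).normal(size=(24, 2, 3))
            y[:, 1, :] += 1.0
            res = {r.name: r for r in mixed_anova(
                long_table(y, ["a"] * 13 + ["b"] * 11), "y",
                "participant_id", "group", ["task", "size"])}
            hits += res["task"].p_value < 0.05
        assert hits >= 18


class TestOneSampleT:
    def test_all_zero_values_degenerate(self):
        r = bonferroni_one_sample_t(np.zeros(10), m=4)
        assert r.degenerate and r.statistic == 0.0 and r.p_value == 1.0

    def test_adjustment_monotone_and_capped(self):
        x = rng(5).normal(0.5, 1.0, size=12)
        ps = [bonferroni_one_sample_t(x, m=m).p_value for m in (1, 2, 4, 50)]
        assert ps == sorted(ps)
        assert ps[-1] <= 1.0
        assert ps[1] == pytest.approx(min(1.0, 2 * ps[0]))

    def test_null_p_values_uniform(self):
        """Under the null the (unadjusted) p-values are U(0, 1)."""
        g = rng(42)
        ps = [bonferroni_one_sample_t(g.normal(size=13), m=1).extra[
            "p_uncorrected"] for _ in range(500)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_familywise_error_near_nominal_alpha(self):
        """Bonferroni over four null cells: FWER ~ 1-(1-a/4)^4 ~ a."""
        g = rng(7)
        fwer = 0
        reps = 200
        for _ in range(reps):
            any_sig = any(
                bonferroni_one_sample_t(g.normal(size=13), m=4).p_value < 0.05
                for _ in range(4))
            fwer += any_sig
        rate = fwer / reps
        assert 0.005 <= rate <= 0.105      # nominal 0.049, binomial slack


class TestNonparametric:
    def wide(self, y):
        return pd.DataFrame(y, columns=[60, 80, 100],
                            index=[f"S{i}" for i in range(len(y))])

    def group_series(self, n):
        return pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2),
                         index=[f"S{i}" for i in range(n)])

    def test_friedman_matches_scipy_three_columns(self):
        y = rng(1).normal(size=(15, 3))
        chi2, p = _friedman(y)
        chi2_sp, p_sp = sps.friedmanchisquare(y[:, 0], y[:, 1], y[:, 2])
        assert chi2 == pytest.approx(chi2_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-10)

    def test_identical_columns_chi2_zero(self):
        y = np.tile(rng(2).normal(size=(10, 1)), (1, 3))
        res = nonparametric_battery(self.wide(y), self.group_series(10))
        fr = [r for r in res if r.test == "friedman"][0]
        assert fr.statistic == 0.0 and fr.degenerate

    def test_identical_pairs_wilcoxon_flagged(self):
        y = np.tile(rng(3).normal(size=(10, 1)), (1, 3))
        res = nonparametric_battery(self.wide(y), self.group_series(10))
        for r in res:
            if r.test == "wilcoxon_signed_rank":
                assert r.degenerate and np.isnan(r.p_value)

    def test_mann_whitney_alpha_under_label_permutation(self):
        """With group labels assigned at random, the U test rejects at ~ alpha."""
        g = rng(23)
        base = g.normal(size=(24, 3))
        hits = 0
        reps = 300
        for _ in range(reps):
            labels = np.array(["a"] * 12 + ["b"] * 12)
            g.shuffle(labels)
            res = nonparametric_battery(
                self.wide(base), pd.Series(labels,
                                           index=[f"S{i}" for i in range(24)]))
            mw = [r for r in res if r.test == "mann_whitney_u"][0]
            hits += mw.p_value < 0.05
        assert 0.01 <= hits / reps <= 0.105

    def test_exact_method_used_for_small_samples(self):
        y = rng(4).normal(size=(8, 3))
        res = nonparametric_battery(self.wide(y), self.group_series(8))
        for r in res:
            if r.test == "wilcoxon_signed_rank":
                assert r.extra["method"] == "exact"


class TestCorrelationScreen:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res, cooks = correlation_screen(x, x, method="pearson")
        assert res.statistic == pytest.approx(1.0)
        assert len(cooks) == 10

    def test_null_correlation_centred_on_zero(self):
        g = rng(8)
        rs = []
        for _ in range(500):
            res, _ = correlation_screen(g.normal(size=11), g.normal(size=11))
            rs.append(res.statistic)
        assert abs(np.mean(rs)) < 0.1

    def test_cooks_distance_matches_leave_one_out_oracle(self):
        """Cook's D from the fitted regression equals the brute-force
        leave-one-out refit definition, and a planted outlier dominates."""
        g = rng(9)
        x = np.linspace(0, 10, 12)
        y = 2.0 + 0.5 * x + g.normal(0, 0.3, size=12)
        y[7] += 6.0                                    # planted outlier
        res, cooks = correlation_screen(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        fitted = X @ beta
        s2 = np.sum((y - fitted) ** 2) / (len(x) - 2)
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            d_oracle = np.sum((fitted - X @ beta_i) ** 2) / (2 * s2)
            assert cooks[i] == pytest.approx(d_oracle, rel=1e-8)
        assert np.argmax(cooks) == 7
        assert cooks[7] > 4 / len(x)

    def test_kendall_method(self):
        x = np.arange(12.0)
        res, _ = correlation_screen(x, -x, method="kendall")
        assert res.statistic == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        res, cooks = correlation_screen(np.ones(5), np.arange(5.0))
        assert res.degenerate and np.all(np.isnan(cooks))
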