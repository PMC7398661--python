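"""Repeated-measures ANOVA, Holm-Sidak, t-tests and regression oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from fiberphot.stats import (
    holm_sidak,
    linregress,
    pairwise_contrasts,
    paired_t,
    rm_anova_one_way,
    rm_anova_two_way,
    unpaired_t,
)


def long_format(Y, groups=None, timepoints=None):
    """Wide subjects-by-levels array -> long cohort frame."""
    n, t = Y.shape
    timepoints = timepoints or [f"t{j}" for j in range(t)]
    rows = []
    for i in range(n):
        g = groups[i] if groups is not None else "g0"
        for j in range(t):
            rows.append((f"s{i:02d}", g, timepoints[j], Y[i, j]))
    return pd.DataFrame(rows, columns=["mouse_id", "group", "timepoint", "value"])


class TestOneWayRM:
    def test_constant_data_gives_f0_p1(self):
        df = long_format(np.full((4, 3), 2.5))
        res = rm_anova_one_way(df)
        assert res["timepoint"].F == 0.0
        assert res["timepoint"].p == 1.0

    def test_two_levels_reproduce_paired_t(self, rng):
        Y = rng.normal(0, 1, (8, 2)) + [0.0, 0.6]
        res = rm_anova_one_way(long_format(Y))
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        assert res["timepoint"].F == pytest.approx(t**2, rel=1e-9)
        assert res["timepoint"].p == pytest.approx(p, rel=1e-9)

    def test_degrees_of_freedom_counting(self, rng):
        Y = rng.normal(0, 1, (6, 4))
        res = rm_anova_one_way(long_format(Y))
        assert res["timepoint"].df == 3
        assert res["error"].df == 5 * 3
        assert res["subject"].df == 5

    def test_ss_conservation(self, rng):
        Y = rng.normal(0, 2, (7, 3))
        res = rm_anova_one_way(long_format(Y))
        assert sum(e.ss for e in res.effects) == pytest.approx(
            res.ss_total, rel=1e-12
        )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(-20, 5, (9, 3))
        df = long_format(Y)
        res = rm_anova_one_way(df)
        ref = pg.rm_anova(
            df, dv="value", within="timepoint", subject="mouse_id", detailed=True
        )
        assert res["timepoint"].F == pytest.approx(ref["F"].iloc[0], rel=1e-9)
        assert res["timepoint"].p == pytest.approx(ref["p_unc"].iloc[0], rel=1e-9)

    def test_missing_cell_rejected_by_name(self, rng):
        df = long_format(rng.normal(0, 1, (4, 3)))
        df = df[~((df.mouse_id == "s02") & (df.timepoint == "t1"))]
        with pytest.raises(ValueError, match="s02"):
            rm_anova_one_way(df)

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_one_way(long_format(np.ones((1, 3))))


def brute_force_mixed_ss(df):
    """Sums of squares for a balanced 2x2 mixed design from first principles:
    explicit cell/marginal means, no matrix shortcuts."""
    grand = df.value.mean()
    groups = sorted(df.group.unique())
    tps = sorted(df.timepoint.unique())
    n = df[df.group == groups[0]].mouse_id.nunique()
    t = len(tps)
    subj_mean = df.groupby("mouse_id").value.mean()
    group_of = df.groupby("mouse_id").group.first()
    group_mean = df.groupby("group").value.mean()
    time_mean = df.groupby("timepoint").value.mean()
    cell_mean = df.groupby(["group", "timepoint"]).value.mean()

    ss_group = sum(n * t * (group_mean[g] - grand) ** 2 for g in groups)
    ss_subj_w = sum(
        t * (subj_mean[s] - group_mean[group_of[s]]) ** 2 for s in subj_mean.index
    )
    ss_time = sum(len(groups) * n * (time_mean[tp] - grand) ** 2 for tp in tps)
    ss_inter = sum(
        n
        * (cell_mean[(g, tp)] - group_mean[g] - time_mean[tp] + grand) ** 2
        for g in groups
        for tp in tps
    )
    ss_total = ((df.value - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_w - ss_time - ss_inter
    return dict(
        group=ss_group,
        subject_within_group=ss_subj_w,
        timepoint=ss_time,
        interaction=ss_inter,
        error=ss_err,
        total=ss_total,
    )


class TestTwoWayMixed:
    def test_symmetric_data_gives_zero_group_and_interaction_f(self):
        # the two groups carry identical values -> no group or interaction effect
        base = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [0.0, 1.0, 2.0]])
        Y = np.vstack([base, base])
        groups = ["lean"] * 3 + ["DIO"] * 3
        res = rm_anova_two_way(long_format(Y, groups=groups))
        assert res["group"].F == 0.0
        assert res["group:timepoint"].F == 0.0
        assert res["timepoint"].F > 0

    def test_ss_decomposition_matches_first_principles(self, rng):
        Y = rng.normal(0, 1, (6, 2)) + np.array([[0.5, -0.5]] * 3 + [[0.0, 0.0]] * 3)
        groups = ["lean"] * 3 + ["DIO"] * 3
        df = long_format(Y, groups=groups)
        res = rm_anova_two_way(df)
        ref = brute_force_mixed_ss(df)
        assert res["group"].ss == pytest.approx(ref["group"], rel=1e-9)
        assert res["subject_within_group"].ss == pytest.approx(
            ref["subject_within_group"], rel=1e-9
        )
        assert res["timepoint"].ss == pytest.approx(ref["timepoint"], rel=1e-9)
        assert res["group:timepoint"].ss == pytest.approx(
            ref["interaction"], rel=1e-9
        )
        assert res["error"].ss == pytest.approx(ref["error"], rel=1e-9)

    def test_total_ss_is_sum_of_components(self, rng):
        Y = rng.normal(0, 3, (10, 3))
        groups = ["lean"] * 5 + ["DIO"] * 5
        res = rm_anova_two_way(long_format(Y, groups=groups))
        assert sum(e.ss for e in res.effects) == pytest.approx(
            res.ss_total, rel=1e-9
        )

    def test_matches_pingouin_including_unbalanced_groups(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(-15, 4, (11, 3))
        groups = ["lean"] * 6 + ["DIO"] * 5
        df = long_format(Y, groups=groups)
        res = rm_anova_two_way(df)
        ref = pg.mixed_anova(
            df, dv="value", within="timepoint", subject="mouse_id", between="group"
        ).set_index("Source")
        for mine, theirs in [
            ("group", "group"),
            ("timepoint", "timepoint"),
            ("group:timepoint", "Interaction"),
        ]:
            assert res[mine].F == pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
            assert res[mine].p == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-9)

    def test_single_group_redirects_to_one_way(self, rng):
        df = long_format(rng.normal(0, 1, (4, 3)), groups=["lean"] * 4)
        with pytest.raises(ValueError, match="one"):
            rm_anova_two_way(df)

    def test_missing_cell_rejected(self, rng):
        df = long_format(rng.normal(0, 1, (6, 3)), groups=["lean"] * 3 + ["DIO"] * 3)
        df = df[~((df.mouse_id == "s04") & (df.timepoint == "t2"))]
        with pytest.raises(ValueError, match="s04"):
            rm_anova_two_way(df)


class TestHolmSidak:
    def test_worked_fixture(self):
        res = holm_sidak([0.01, 0.02, 0.04])
        np.testing.assert_allclose(res.p_adjusted, [0.029701, 0.0396, 0.04])

    def test_single_p_identity(self):
        assert holm_sidak([0.03]).p_adjusted[0] == pytest.approx(0.03)

    def test_endpoints_fixed(self):
        np.testing.assert_allclose(holm_sidak([0.0, 1.0]).p_adjusted, [0.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])

    def test_matches_statsmodels(self, rng):
        smm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 1, 12)
        mine = holm_sidak(p)
        ref = smm.multipletests(p, method="holm-sidak")[1]
        np.testing.assert_allclose(mine.p_adjusted, ref, rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_stepdown_invariants(self, pvals):
        res = holm_sidak(pvals)
        assert np.all(res.p_adjusted >= res.p_raw - 1e-15)
        order = np.argsort(res.p_raw, kind="stable")
        assert np.all(np.diff(res.p_adjusted[order]) >= -1e-15)
        # Holm-Sidak is never more conservative than Bonferroni on the
        # smallest raw p
        i = order[0]
        m = len(pvals)
        assert res.p_adjusted[i] <= min(1.0, m * res.p_raw[i]) + 1e-12


class TestTTests:
    def test_identical_samples(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.df == 4

    def test_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 6)
        res = unpaired_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_agrees_with_exhaustive_permutation(self, rng):
        # exhaustive relabelling on a small sample: the permutation p-value
        # and the pooled t p-value must broadly agree and rank effects alike
        def perm_p(x, y):
            pooled = np.concatenate([x, y])
            nx = len(x)
            obs = abs(np.mean(x) - np.mean(y))
            count = total = 0
            for idx in itertools.combinations(range(len(pooled)), nx):
                sel = np.zeros(len(pooled), dtype=bool)
                sel[list(idx)] = True
                d = abs(pooled[sel].mean() - pooled[~sel].mean())
                count += d >= obs - 1e-12
                total += 1
            return count / total

        x = rng.normal(0, 1, 5)
        results = []
        for shift in (0.2, 1.0, 2.5):
            y = rng.normal(shift, 1, 5)
            res = unpaired_t(x, y)
            results.append((res.p, perm_p(x, y)))
        for p_t, p_perm in results:
            assert abs(p_t - p_perm) < 0.12
        # identical ranking of effect strength
        assert [r[0] for r in results] == sorted(
            [r[0] for r in results], reverse=True
        ) or np.argsort([r[0] for r in results]).tolist() == np.argsort(
            [r[1] for r in results]
        ).tolist()

    def test_paired_zero_difference(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])


class TestRegression:
    def test_exact_line(self):
        res = linregress([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        res = linregress([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert res.slope == 0.0
        assert res.r2 == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linregress([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_slope_ci_coverage_near_nominal(self):
        # 1000 seeded simulations under a known slope: the 95% CI for the
        # slope must cover the truth at close to the nominal rate
        rng = np.random.default_rng(7)
        n, slope_true = 12, 1.5
        x = np.linspace(0, 1, n)
        covered = 0
        n_sim = 1000
        tcrit = sps.t.ppf(0.975, n - 2)
        for _ in range(n_sim):
            y = 0.3 + slope_true * x + rng.normal(0, 0.5, n)
            res = sps.linregress(x, y)
            lo = res.slope - tcrit * res.stderr
            hi = res.slope + tcrit * res.stderr
            covered += lo <= slope_true <= hi
        assert 0.935 <= covered / n_sim <= 0.965


class TestContrastFamilies:
    def test_family_sizes(self, rng):
        Y = rng.normal(0, 1, (6, 3))
        df = long_format(
            Y, groups=["lean"] * 3 + ["DIO"] * 3,
            timepoints=["baseline", "wk6", "wk10"],
        )
        within = pairwise_contrasts(df, family="within")
        between = pairwise_contrasts(df, family="between")
        both = pairwise_contrasts(df, family="all")
        assert len(within.labels) == 2 * 3  # 2 groups x C(3,2) timepoint pairs
        assert len(between.labels) == 3  # one group pair per timepoint
        assert len(both.labels) == 9
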