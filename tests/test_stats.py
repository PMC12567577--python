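"""Repeated-measures ANOVA, effect sizes, pairwise contrasts, normality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from tremorband.stats import (
    CELL_LABELS,
    MeasureTable,
    bonferroni_pairwise,
    cohen_label,
    gg_epsilon,
    normality_screen,
    partial_eta_squared,
    partial_eta_squared_from_f,
    rm_anova_2x2,
    shapiro_wilk,
)


def _table(values, measure="L", band="low"):
    values = np.asarray(values, float)
    return MeasureTable(
        values=values,
        participants=[f"P{i}" for i in range(len(values))],
        measure=measure,
        band=band,
    )


def _random_table(rng, n=None):
    n = n or int(rng.integers(3, 13))
    return _table(rng.normal(0, 1, (n, 2, 2)) + rng.normal(0, 1, (n, 1, 1)))


def brute_force_ss(y):
    """Textbook two-way within-subject SS decomposition via explicit loops."""
    n, a, b = y.shape
    gm = y.mean()
    ss = {"time": 0.0, "limb": 0.0, "tl": 0.0, "ts": 0.0, "ls": 0.0, "tls": 0.0}
    t_mean = [y[:, i, :].mean() for i in range(a)]
    l_mean = [y[:, :, j].mean() for j in range(b)]
    s_mean = [y[s].mean() for s in range(n)]
    for i in range(a):
        ss["time"] += n * b * (t_mean[i] - gm) ** 2
    for j in range(b):
        ss["limb"] += n * a * (l_mean[j] - gm) ** 2
    for i in range(a):
        for j in range(b):
            cell = y[:, i, j].mean()
            ss["tl"] += n * (cell - t_mean[i] - l_mean[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            m = y[s, i, :].mean()
            ss["ts"] += b * (m - s_mean[s] - t_mean[i] + gm) ** 2
        for j in range(b):
            m = y[s, :, j].mean()
            ss["ls"] += a * (m - s_mean[s] - l_mean[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ts = y[s, i, :].mean()
                ls = y[s, :, j].mean()
                cell = y[:, i, j].mean()
                resid = (
                    y[s, i, j]
                    - cell
                    - ts
                    - ls
                    + t_mean[i]
                    + l_mean[j]
                    + s_mean[s]
                    - gm
                )
                ss["tls"] += resid**2
    return ss


class TestRmAnova:
    def test_ss_decomposition_matches_brute_force(self, rng):
        for _ in range(50):
            table = _random_table(rng)
            res = rm_anova_2x2(table)
            ss = brute_force_ss(table.values)
            scale = max(abs(v) for v in ss.values()) or 1.0
            assert res["time"].ss_effect == pytest.approx(ss["time"], rel=1e-10, abs=1e-10 * scale)
            assert res["limb"].ss_effect == pytest.approx(ss["limb"], rel=1e-10, abs=1e-10 * scale)
            assert res["time x limb"].ss_effect == pytest.approx(ss["tl"], rel=1e-10, abs=1e-10 * scale)
            assert res["time"].ss_error == pytest.approx(ss["ts"], rel=1e-10, abs=1e-10 * scale)
            assert res["limb"].ss_error == pytest.approx(ss["ls"], rel=1e-10, abs=1e-10 * scale)
            assert res["time x limb"].ss_error == pytest.approx(ss["tls"], rel=1e-10, abs=1e-10 * scale)

    def test_three_participant_toy_table(self):
        y = np.arange(1.0, 13.0).reshape(3, 2, 2)
        res = rm_anova_2x2(_table(y))
        ss = brute_force_ss(y)
        assert res["time"].ss_effect == pytest.approx(ss["time"], abs=1e-10)
        assert res["limb"].ss_effect == pytest.approx(ss["limb"], abs=1e-10)
        assert res["time x limb"].ss_effect == pytest.approx(ss["tl"], abs=1e-10)

    def test_time_f_equals_squared_paired_t(self, rng):
        """F(time) equals the squared paired t on limb-averaged scores."""
        for _ in range(10):
            table = _random_table(rng)
            res = rm_anova_2x2(table)
            pre = table.values[:, 0, :].mean(axis=1)
            post = table.values[:, 1, :].mean(axis=1)
            t = sst.ttest_rel(post, pre)
            assert res["time"].F == pytest.approx(t.statistic**2, rel=1e-10)
            assert res["time"].p == pytest.approx(t.pvalue, rel=1e-8)

    def test_null_time_effect(self, rng):
        y = rng.normal(0, 1, (8, 1, 2))
        y = np.concatenate([y, y], axis=1)  # POST identical to PRE
        with pytest.warns(UserWarning, match="zero error"):
            res = rm_anova_2x2(_table(y))
        assert res["time"].F == 0.0

    def test_identical_limb_columns_give_zero_limb_and_interaction(self, rng):
        y = rng.normal(0, 1, (8, 2, 1))
        y = np.concatenate([y, y], axis=2)
        with pytest.warns(UserWarning, match="zero error"):
            res = rm_anova_2x2(_table(y))
        assert res["limb"].F == 0.0
        assert res["time x limb"].F == 0.0

    def test_degrees_of_freedom(self, rng):
        res = rm_anova_2x2(_random_table(rng, n=50))
        for eff in res.effects.values():
            assert (eff.df_num, eff.df_den) == (1, 49)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        table = _random_table(rng, n=12)
        res = rm_anova_2x2(table)
        rows = []
        for s, pid in enumerate(table.participants):
            for i, cond in enumerate(("PRE", "POST")):
                for j, limb in enumerate(("dominant", "nondominant")):
                    rows.append(
                        {"subject": pid, "time": cond, "limb": limb,
                         "y": table.values[s, i, j]}
                    )
        sm = (
            AnovaRM(pd.DataFrame(rows), "y", "subject", within=["time", "limb"])
            .fit()
            .anova_table
        )
        assert res["time"].F == pytest.approx(sm.loc["time", "F Value"], rel=1e-8)
        assert res["limb"].F == pytest.approx(sm.loc["limb", "F Value"], rel=1e-8)
        assert res["time x limb"].F == pytest.approx(
            sm.loc["time:limb", "F Value"], rel=1e-8
        )
        assert res["time"].p == pytest.approx(sm.loc["time", "Pr > F"], abs=1e-10)

    def test_cross_check_against_pingouin(self, rng):
        import pingouin as pg

        table = _random_table(rng, n=15)
        res = rm_anova_2x2(table)
        rows = []
        for s, pid in enumerate(table.participants):
            for i, cond in enumerate(("PRE", "POST")):
                for j, limb in enumerate(("dominant", "nondominant")):
                    rows.append(
                        {"subject": pid, "time": cond, "limb": limb,
                         "y": table.values[s, i, j]}
                    )
        pg_res = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["time", "limb"],
            subject="subject", detailed=True,
        ).set_index("Source")
        assert res["time"].F == pytest.approx(pg_res.loc["time", "F"], rel=1e-8)
        assert res["limb"].F == pytest.approx(pg_res.loc["limb", "F"], rel=1e-8)
        assert res["time x limb"].F == pytest.approx(
            pg_res.loc["time * limb", "F"], rel=1e-8
        )
        assert res["time"].p == pytest.approx(
            pg_res.loc["time", "p_unc"], abs=1e-10
        )

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="2 complete"):
            _table(rng.normal(0, 1, (1, 2, 2)))


class TestGreenhouseGeisser:
    def test_two_levels_identically_one(self, rng):
        assert gg_epsilon(rng.normal(0, 1, (20, 2))) == 1.0

    def test_matches_pingouin_epsilon(self, rng):
        import pingouin as pg

        data = rng.normal(0, 1, (30, 4)) + rng.normal(0, 1, (30, 1))
        assert gg_epsilon(data) == pytest.approx(
            pg.epsilon(pd.DataFrame(data), correction="gg"), abs=1e-10
        )

    def test_compound_symmetry_near_one(self):
        """Under compound symmetry the population epsilon is 1; the sample
        estimate is consistent (slight small-sample downward bias)."""
        values = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            subj = rng.normal(0, 1.5, (300, 1))
            data = subj + rng.normal(0, 1, (300, 3))
            values.append(gg_epsilon(data))
        assert 0.95 <= np.mean(values) <= 1.0

    def test_maximal_nonsphericity_near_lower_bound(self):
        """A rank-one difference structure drives epsilon to 1/(k-1)."""
        values = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            z = rng.normal(0, 3, 200)
            data = np.column_stack([z, -z, rng.normal(0, 1e-3, 200)])
            values.append(gg_epsilon(data))
        assert np.mean(values) == pytest.approx(0.5, abs=0.05)

    def test_bounded(self, rng):
        for _ in range(20):
            eps = gg_epsilon(rng.normal(0, 1, (10, 4)))
            assert 1.0 / 3.0 <= eps <= 1.0


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(86.56, 1, 49, 0.639), (3.91, 1, 49, 0.074)],
    )
    def test_back_computation_from_reported_f(self, F, df1, df2, expected):
        assert partial_eta_squared_from_f(F, df1, df2) == pytest.approx(
            expected, abs=5e-4
        )

    def test_boundaries(self):
        assert partial_eta_squared(0.0, 1.0) == 0.0
        assert partial_eta_squared(1.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            partial_eta_squared(0.0, 0.0)

    def test_cohen_labels(self):
        assert cohen_label(0.005) == "negligible"
        assert cohen_label(0.01) == "small"
        assert cohen_label(0.06) == "medium"
        assert cohen_label(0.14) == "large"
        assert cohen_label(0.983) == "large"


class TestPairwise:
    def test_six_contrasts_with_bonferroni_cap(self, rng):
        table = _random_table(rng, n=10)
        results = bonferroni_pairwise(table)
        assert len(results) == 6
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))
            assert r.p_adjusted >= r.p_raw
        # a null table must show capping somewhere
        assert any(r.p_adjusted == 1.0 for r in results)

    def test_m_configurable(self, rng):
        table = _random_table(rng, n=10)
        results = bonferroni_pairwise(table, m=4)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 4 * r.p_raw))

    def test_significance_flag_uses_working_threshold(self, rng):
        n = 30
        base = rng.normal(0, 0.2, (n, 1, 2))
        y = np.concatenate([base, base + 3.0], axis=1)  # huge time effect
        y += rng.normal(0, 0.2, y.shape)
        results = {r.contrast: r for r in bonferroni_pairwise(_table(y))}
        assert results["PRE-dominant vs POST-dominant"].significant
        assert results["PRE-nondominant vs POST-nondominant"].significant
        assert not results["PRE-dominant vs PRE-nondominant"].significant

    def test_zero_variance_contrast_reported_degenerate(self, rng):
        y = rng.integers(0, 10, (6, 2, 1)).astype(float)
        y = np.concatenate([y, y + 1.0], axis=2)  # limb diff exactly 1.0
        results = {r.contrast: r for r in bonferroni_pairwise(_table(y))}
        degen = results["PRE-dominant vs PRE-nondominant"]
        assert degen.degenerate
        assert degen.t == -np.inf and degen.p_raw == 0.0


class TestShapiroWilk:
    def test_theoretical_normal_quantiles_near_perfect(self):
        q = sst.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, p = shapiro_wilk(q)
        assert w > 0.99

    def test_extreme_outlier_detected(self, rng):
        sample = np.concatenate([rng.normal(0, 1, 49), [50.0]])
        _, p = shapiro_wilk(sample)
        assert p < 0.01

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            shapiro_wilk(np.full(10, 3.3))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            shapiro_wilk(np.array([1.0, 2.0]))

    def test_screen_reports_all_cells_and_degenerates(self, rng):
        table = _random_table(rng, n=10)
        screen = normality_screen(table)
        assert len(screen) == 4
        assert not screen.degenerate.any()
        diff_screen = normality_screen(table, mode="differences")
        assert len(diff_screen) == 6


class TestMeasureTable:
    def test_from_long_drops_incomplete_listwise(self, small_indices):
        df = small_indices.copy()
        df = df[
            ~(
                (df.participant == "P001")
                & (df.condition == "POST")
                & (df.limb == "dominant")
            )
        ]
        table = MeasureTable.from_long(df, "low", "L")
        assert table.dropped == ["P001"]
        assert table.n == 5

    def test_cell_labels_cover_design(self, small_indices):
        table = MeasureTable.from_long(small_indices, "low", "F")
        labels = [lab for row in CELL_LABELS for lab in row]
        assert len(labels) == 4
        for lab in labels:
            assert table.cell(lab).shape == (table.n,)
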