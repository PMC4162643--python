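"""Factorial statistics: injected effects, guards, post-hoc, replication."""

import numpy as np
import pandas as pd
import pytest

import physync as ps
from physync.group_stats import (
    bonferroni_posthoc,
    one_way_f,
    records_to_table,
)

from conftest import make_balanced_table


class TestConditionGroupModel:
    def test_injected_group_effect_detected(self):
        rng = np.random.default_rng(0)
        table = make_balanced_table(
            rng, group_shift={"collective": {"VHF": 0.2}}, noise_sd=0.05
        )
        eff = ps.fit_condition_group_model(table, "accel")
        sel = eff.univariate[(eff.univariate.band == "VHF")
                             & (eff.univariate.effect == "group_setting")]
        assert sel.p.iloc[0] < 1e-6
        # multivariate tests see it too
        mv = eff.multivariate[eff.multivariate.effect == "group_setting"]
        assert (mv.p < 1e-6).all()

    def test_noise_free_effect_flags_infinite_f(self):
        rng = np.random.default_rng(1)
        table = make_balanced_table(
            rng, group_shift={"collective": {"VHF": 0.2, "HF": 0.2, "LF": 0.2}},
            noise_sd=0.0,
        )
        eff = ps.fit_condition_group_model(table, "accel", bands=("VHF",),
                                           multivariate=False, posthoc=False)
        assert np.isinf(eff.univariate_f("VHF", "group_setting"))

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(2)
        table = make_balanced_table(rng)
        table = table[~((table.condition == "baseline2")
                        & (table.group_setting == "individual"))]
        with pytest.raises(ValueError, match="empty design cells"):
            ps.fit_condition_group_model(table, "accel")

    def test_matches_hand_coded_sums_of_squares(self):
        # small balanced 2x2 table: type-III F equals the classic decomposition
        rng = np.random.default_rng(3)
        rows = []
        for cond in ("baseline1", "metronome"):
            for grp in ("collective", "individual"):
                for i in range(8):
                    rows.append(dict(signal="accel", condition=cond,
                                     group_setting=grp, experiment_index=1,
                                     day=1, condition_order=1,
                                     LF=rng.normal(), HF=rng.normal(),
                                     VHF=rng.normal()))
        table = pd.DataFrame(rows)
        eff = ps.fit_condition_group_model(table, "accel", bands=("LF",),
                                           multivariate=False, posthoc=False)
        # hand-coded balanced two-way ANOVA
        y = table.pivot_table(index="condition", columns="group_setting",
                              values="LF", aggfunc=list)
        cells = {(c, g): np.array(y.loc[c, g]) for c in y.index for g in y.columns}
        n = 8
        grand = np.mean([v for arr in cells.values() for v in arr])
        mc = {c: np.mean([cells[(c, g)].mean() for g in y.columns]) for c in y.index}
        mg = {g: np.mean([cells[(c, g)].mean() for c in y.index]) for g in y.columns}
        ss_a = 2 * n * sum((m - grand) ** 2 for m in mc.values())
        ss_b = 2 * n * sum((m - grand) ** 2 for m in mg.values())
        ss_ab = n * sum(
            (cells[(c, g)].mean() - mc[c] - mg[g] + grand) ** 2
            for c in y.index for g in y.columns
        )
        ss_e = sum(((arr - arr.mean()) ** 2).sum() for arr in cells.values())
        df_e = 4 * (n - 1)
        f_a = (ss_a / 1) / (ss_e / df_e)
        f_b = (ss_b / 1) / (ss_e / df_e)
        f_ab = (ss_ab / 1) / (ss_e / df_e)
        assert eff.univariate_f("LF", "condition") == pytest.approx(f_a, abs=1e-9)
        assert eff.univariate_f("LF", "group_setting") == pytest.approx(f_b, abs=1e-9)
        assert eff.univariate_f("LF", "condition:group_setting") == pytest.approx(f_ab, abs=1e-9)

    def test_two_level_f_equals_squared_t(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            dict(group_setting=["collective"] * 20 + ["individual"] * 20,
                 VHF=rng.normal(size=40))
        )
        F, df1, df2, _p = one_way_f(table, "group_setting", "VHF")
        from scipy import stats as spstats

        a = table.VHF[:20].to_numpy()
        b = table.VHF[20:].to_numpy()
        t, _ = spstats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, abs=1e-9)


class TestConditionDayModel:
    def test_injected_day_effect_detected(self):
        rng = np.random.default_rng(5)
        table = make_balanced_table(rng, days=(1, 2), noise_sd=0.05)
        table.loc[(table.day == 2) & (table.group_setting == "collective"), "VHF"] += 0.1
        eff = ps.fit_condition_day_model(table, "accel")
        sel = eff.univariate[(eff.univariate.band == "VHF")
                             & (eff.univariate.effect == "day")]
        assert sel.p.iloc[0] < 1e-4

    def test_identical_days_give_null_f(self):
        rng = np.random.default_rng(6)
        table = make_balanced_table(rng, days=(1,), noise_sd=0.05)
        dup = table.copy()
        dup["day"] = 2
        both = pd.concat([table, dup], ignore_index=True)
        eff = ps.fit_condition_day_model(both, "accel", bands=("VHF",),
                                         multivariate=False, posthoc=False)
        assert eff.univariate_f("VHF", "day") < 1e-9

    def test_single_day_rejected(self):
        rng = np.random.default_rng(7)
        table = make_balanced_table(rng, days=(1,))
        with pytest.raises(ValueError):
            ps.fit_condition_day_model(table, "accel")


class TestBonferroni:
    def test_adjustment_arithmetic(self):
        # m*p capped at 1; single comparison unchanged
        rng = np.random.default_rng(8)
        two = pd.DataFrame(dict(cond=["a"] * 30 + ["b"] * 30,
                                v=rng.normal(size=60)))
        adj = bonferroni_posthoc(two, "cond", "v")
        from scipy import stats as spstats

        a, b = two.v[:30].to_numpy(), two.v[30:].to_numpy()
        t, p_raw = spstats.ttest_ind(a, b)
        assert adj.loc["a", "b"] == pytest.approx(p_raw, abs=1e-12)  # m=1

        five = pd.DataFrame(dict(cond=np.repeat(list("abcde"), 20),
                                 v=rng.normal(size=100)))
        adj5 = bonferroni_posthoc(five, "cond", "v")
        assert np.nanmax(adj5.to_numpy()) <= 1.0
        # recompute one pair by hand: raw p * 10 comparisons, capped
        ga, gb = five.v[five.cond == "a"], five.v[five.cond == "b"]
        ss = sum(((five.v[five.cond == c] - five.v[five.cond == c].mean()) ** 2).sum()
                 for c in "abcde")
        mse = ss / (100 - 5)
        se = np.sqrt(mse * (2 / 20))
        t = (ga.mean() - gb.mean()) / se
        p = 2 * spstats.t.sf(abs(t), 95)
        assert adj5.loc["a", "b"] == pytest.approx(min(1.0, 10 * p), abs=1e-12)

    def test_single_level_rejected(self):
        one = pd.DataFrame(dict(cond=["a"] * 5, v=np.arange(5.0)))
        with pytest.raises(ValueError):
            bonferroni_posthoc(one, "cond", "v")


class TestTypeICalibrationAndPower:
    def test_group_type_one_error_rate(self):
        # 2000 balanced null replicates; rejection rate at alpha=.05
        rng = np.random.default_rng(123)
        base = make_balanced_table(rng, n_pairs=10, noise_sd=0.0, bands=("LF",))
        n = len(base)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            tbl = base.copy()
            tbl["LF"] = rng.standard_normal(n)
            eff = ps.fit_condition_group_model(tbl, "accel", bands=("LF",),
                                               multivariate=False, posthoc=False)
            sel = eff.univariate[(eff.univariate.effect == "group_setting")]
            if sel.p.iloc[0] < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.04 <= rate <= 0.06

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(321)
        base = make_balanced_table(rng, n_pairs=6, noise_sd=0.0, bands=("LF",))
        n = len(base)
        rates = []
        for shift in (0.0, 0.05, 0.1, 0.2):
            rej = 0
            reps = 60
            for _ in range(reps):
                tbl = base.copy()
                tbl["LF"] = 0.05 * rng.standard_normal(n)
                tbl.loc[tbl.group_setting == "collective", "LF"] += shift
                eff = ps.fit_condition_group_model(tbl, "accel", bands=("LF",),
                                                   multivariate=False, posthoc=False)
                if eff.univariate[(eff.univariate.effect == "group_setting")].p.iloc[0] < 0.05:
                    rej += 1
            rates.append(rej / reps)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestReplication:
    def test_replication_report_on_schema_table(self):
        # synthetic table in the supplementary-database schema with a known
        # group effect injected on accel VHF, day 2
        rng = np.random.default_rng(9)
        table = make_balanced_table(rng, days=(1, 2), noise_sd=0.05)
        table.loc[(table.day == 2) & (table.group_setting == "collective"), "VHF"] += 0.15
        report = ps.replicate_database_s1_stats(table)
        assert {"group_day1", "group_day2", "group_pooled", "day_collective"} <= set(report.variant)
        day2 = report[(report.variant == "group_day2") & (report.band == "VHF")
                      & (report.effect == "group_setting")]
        day1 = report[(report.variant == "group_day1") & (report.band == "VHF")
                      & (report.effect == "group_setting")]
        assert day2.F.iloc[0] > day1.F.iloc[0]
        assert day2.p.iloc[0] < 1e-6
        # reference comparison flags exactly one closest variant per target
        flagged = report[report.closest_variant]
        assert len(flagged) == flagged[["signal", "band", "effect"]].drop_duplicates().shape[0]

    def test_records_round_trip_to_table(self):
        rng = np.random.default_rng(10)
        mats = {b.name: rng.uniform(0, 1, (4, 4)) for b in ps.DEFAULT_BANDS}
        recs = ps.build_pair_records(
            mats, list("abcd"), signal="accel", condition="music",
            group_setting="collective", experiment_index=1, day=1,
            condition_order=2,
        )
        table = records_to_table(recs)
        assert len(table) == 12
        assert {"LF", "HF", "VHF"} <= set(table.columns)
        row = table[(table.source == "a") & (table.target == "b")]
        assert row.LF.iloc[0] == pytest.approx(mats["LF"][1, 0])
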