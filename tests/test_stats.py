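"""Outcome-statistics tests: NDS scale, Welch t (summary and raw), Fisher
exact vs enumeration, Spearman, logistic regression, Kaplan–Meier/log-rank,
and the two-way ANOVA with hand-worked sums of squares."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qeeg.stats import (
    NDSRecord,
    SurvivalRecord,
    fisher_exact_2x2,
    km_logrank,
    logistic_single,
    nds_total,
    spearman,
    twoway_anova_posthoc,
    welch_t_raw,
    welch_t_summary,
)


def _nds(c, r, co, cr, au, mo, be, day=1):
    return NDSRecord(
        consciousness=c,
        respiration=r,
        cornea_reflex=co,
        cranial_gag_reflex=cr,
        auditory_reflex=au,
        motor_sensory=mo,
        behavior=be,
        day=day,
    )


class TestNDS:
    def test_scale_extremes(self):
        assert nds_total(_nds(0, 0, 0, 0, 0, 0, 0)) == 0
        assert nds_total(_nds(100, 100, 40, 30, 30, 100, 100)) == 500

    def test_intermediate_column_sum(self):
        assert nds_total(_nds(50, 0, 20, 0, 15, 50, 50)) == 185

    def test_out_of_set_value_rejected_naming_category(self):
        with pytest.raises(ValueError, match="cornea_reflex"):
            _nds(0, 0, 25, 0, 0, 0, 0)

    def test_invalid_day_rejected(self):
        with pytest.raises(ValueError):
            _nds(0, 0, 0, 0, 0, 0, 0, day=5)


class TestWelchT:
    def test_identical_summaries_give_p_one(self):
        res = welch_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_scipy_cross_check(self):
        ours = welch_t_summary(15.1, 1.9, 10, 21.5, 6.0, 10)
        t, p = sps.ttest_ind_from_stats(15.1, 1.9, 10, 21.5, 6.0, 10, equal_var=False)
        assert ours.statistic == pytest.approx(t)
        assert ours.p == pytest.approx(p)

    def test_zero_variance_group_uses_other_groups_df(self):
        res = welch_t_summary(204.0, 254.8, 10, 500.0, 0.0, 10)
        assert res.df == pytest.approx(9.0)

    def test_both_zero_sd_conventions(self):
        assert welch_t_summary(3.0, 0.0, 5, 3.0, 0.0, 5).p == 1.0
        with pytest.warns(UserWarning):
            assert welch_t_summary(3.0, 0.0, 5, 4.0, 0.0, 5).p == 0.0

    def test_raw_equals_summary_on_own_summaries(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 9)
        raw = welch_t_raw(x, y)
        summ = welch_t_summary(
            x.mean(), x.std(ddof=1), 12, y.mean(), y.std(ddof=1), 9
        )
        assert raw.statistic == summ.statistic and raw.p == summ.p

    def test_trivial_identical_samples(self):
        assert welch_t_raw([1, 2, 3], [1, 2, 3]).p == 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_raw([1.0], [1.0, 2.0])


def _fisher_enumeration(a, b, c, d):
    """Independent oracle: sum hypergeometric P of all tables with the
    observed margins whose probability is <= the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(aa):
        return (
            math.comb(r1, aa) * math.comb(r2, c1 - aa) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_survival_table(self):
        res = fisher_exact_2x2(6, 4, 0, 10)
        assert round(res.p, 3) == 0.011

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5).p == pytest.approx(1.0)

    def test_empty_margin_p_one(self):
        assert fisher_exact_2x2(0, 0, 3, 4).p == 1.0

    @pytest.mark.parametrize(
        "table", [(6, 4, 0, 10), (1, 9, 5, 5), (3, 2, 2, 3), (8, 1, 1, 8)]
    )
    def test_matches_enumeration(self, table):
        assert fisher_exact_2x2(*table).p == pytest.approx(
            _fisher_enumeration(*table), abs=1e-12
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_equal_pearson_on_midranks(self, rng):
        x = rng.integers(0, 4, 20).astype(float)
        y = rng.integers(0, 4, 20).astype(float)
        rho, _ = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_constant_input_missing(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestLogistic:
    def test_balanced_symmetric_intercept_near_zero(self, rng):
        # overlapping symmetric classes: E[intercept] = 0 with modest SE
        x = np.r_[rng.normal(-0.5, 1.0, 100), rng.normal(0.5, 1.0, 100)]
        y = np.r_[np.zeros(100), np.ones(100)]
        fit = logistic_single(x, y)
        assert fit.converged and not fit.separated
        assert abs(fit.intercept) < 0.5
        assert fit.slope > 0

    def test_predict_is_logistic_curve(self):
        from qeeg.stats import LogisticFit

        fit = LogisticFit(0.0, 1.0, 0.05, True, False)
        assert fit.predict(0.0) == pytest.approx(0.5)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_single([1.0, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])

    def test_complete_separation_flagged(self):
        x = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = logistic_single(x, y)
        assert fit.separated

    def test_positive_effect_recovered(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            x = r.normal(0, 1, 60)
            p = 1 / (1 + np.exp(-(0.2 + 1.5 * x)))
            y = (r.random(60) < p).astype(float)
            if y.min() == y.max():
                continue
            fit = logistic_single(x, y)
            hits += fit.slope > 0
        assert hits >= 19


class TestSurvival:
    def test_survival_record_validation(self):
        with pytest.raises(ValueError):
            SurvivalRecord(time_hr=48.0, event=0)  # censoring only at 96 h
        with pytest.raises(ValueError):
            SurvivalRecord(time_hr=0.0, event=1)

    def _arm(self, death_days, n=10):
        recs = [SurvivalRecord(24.0 * d, 1) for d in death_days]
        recs += [SurvivalRecord(96.0, 0) for _ in range(n - len(death_days))]
        return recs

    def test_table_counts_reproduce_survival_fractions(self):
        # treated: 10, 8, 6, 6 alive at 24/48/72/96 h → S(96) = 0.6
        treated = self._arm([2, 2, 3, 3])
        # control: 8, 2, 0 alive at 24/48/72 h → S(72) = 0
        control = self._arm([1, 1, 2, 2, 2, 2, 2, 2, 3, 3])
        res = km_logrank(treated, control, names=("treated", "control"))
        assert res.survival_at("treated", 96.0) == pytest.approx(0.6)
        assert res.survival_at("control", 72.0) == pytest.approx(0.0)
        assert res.p < 0.05

    def test_no_censoring_equals_empirical_survival(self):
        times = [24.0, 48.0, 48.0, 72.0]
        recs = [SurvivalRecord(t, 1) for t in times]
        res = km_logrank(recs, self._arm([1, 2]), names=("a", "b"))
        for t, expected in [(24.0, 0.75), (48.0, 0.25), (72.0, 0.0)]:
            assert res.survival_at("a", t) == pytest.approx(expected)

    def test_identical_groups_zero_statistic(self):
        arm = self._arm([1, 2, 3])
        res = km_logrank(arm, list(arm))
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_no_events_anywhere_undefined(self):
        arm = self._arm([])
        res = km_logrank(arm, self._arm([]))
        assert np.isnan(res.p)


class TestTwoWayAnova:
    def _frame(self, cells):
        rows = []
        for (g, t), values in cells.items():
            rows += [{"group": g, "time": t, "value": v} for v in values]
        return pd.DataFrame(rows)

    def test_identical_groups_null_result(self, rng):
        base = {1: rng.normal(0, 1, 6), 2: rng.normal(0, 1, 6)}
        cells = {(g, t): base[t] for g in ("a", "b") for t in (1, 2)}
        table, posthoc = twoway_anova_posthoc(self._frame(cells))
        assert table.loc["C(group)", "F"] == pytest.approx(0.0, abs=1e-9)
        assert all(r.p == pytest.approx(1.0) for r in posthoc.values())

    def test_hand_worked_sums_of_squares(self):
        # balanced 2×2, n=2 per cell — type-II SS equal textbook SS
        cells = {
            ("a", 1): [1.0, 2.0],
            ("a", 2): [3.0, 4.0],
            ("b", 1): [5.0, 6.0],
            ("b", 2): [7.0, 9.0],
        }
        table, _ = twoway_anova_posthoc(self._frame(cells))
        values = np.array([v for vs in cells.values() for v in vs])
        grand = values.mean()
        mean_g = {g: np.mean([cells[(g, t)] for t in (1, 2)]) for g in "ab"}
        mean_t = {t: np.mean([cells[(g, t)] for g in "ab"]) for t in (1, 2)}
        ss_group = 4 * sum((m - grand) ** 2 for m in mean_g.values())
        ss_time = 4 * sum((m - grand) ** 2 for m in mean_t.values())
        ss_inter = 2 * sum(
            (np.mean(cells[(g, t)]) - mean_g[g] - mean_t[t] + grand) ** 2
            for g in "ab"
            for t in (1, 2)
        )
        assert table.loc["C(group)", "sum_sq"] == pytest.approx(ss_group)
        assert table.loc["C(time)", "sum_sq"] == pytest.approx(ss_time)
        assert table.loc["C(group):C(time)", "sum_sq"] == pytest.approx(ss_inter)

    def test_group_effect_grows_with_effect_size(self, rng):
        fs = []
        noise = {t: rng.normal(0, 1, 8) for t in (1, 2, 3)}
        for effect in (0.5, 1.5, 3.0):
            cells = {}
            for t in (1, 2, 3):
                cells[("a", t)] = noise[t][:4]
                cells[("b", t)] = noise[t][4:] + effect
            table, _ = twoway_anova_posthoc(self._frame(cells))
            fs.append(table.loc["C(group)", "F"])
        assert fs[0] < fs[1] < fs[2]

    def test_empty_cell_time_excluded_with_warning(self):
        cells = {
            ("a", 1): [1.0, 2.0],
            ("b", 1): [2.0, 3.0],
            ("a", 2): [4.0, 5.0],
        }
        df = self._frame(cells)
        with pytest.warns(UserWarning, match="excluded"):
            _, posthoc = twoway_anova_posthoc(df)
        assert list(posthoc) == [1]
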