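"""Trial filtering, binding scores, and the behavioral statistics layer."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bindwave.behavior import (
    binding_score,
    chi2_2x2,
    filter_trials,
    mixed_anova_2x2x2,
    one_sample_t,
    one_sample_t_data,
    welch_t,
)
from bindwave.experiments import anova_oracle_check


def trial_table(rt2s, s1_correct=True, participant="p1"):
    n = len(rt2s)
    return pd.DataFrame(
        {
            "participant": [participant] * n,
            "group": ["HC"] * n,
            "condition": ["RRFR"] * n,
            "rt1": [300.0] * n,
            "rt2": rt2s,
            "s1_correct": [s1_correct] * n,
            "s2_correct": [True] * n,
        }
    )


class TestFilterTrials:
    def test_fast_rts_below_floor_excluded(self):
        out, _ = filter_trials(trial_table([150.0, 300.0, 310.0, 320.0, 330.0]))
        assert 150.0 not in out["rt2"].values

    def test_tukey_fence_by_linear_interpolation(self):
        # sorted RTs 300..360 step 10 plus 2000: Q1 = 317.5, Q3 = 352.5,
        # fence = 352.5 + 1.5*35 = 405 -> only 2000 excluded
        rts = [300.0, 310.0, 320.0, 330.0, 340.0, 350.0, 360.0, 2000.0]
        out, report = filter_trials(trial_table(rts))
        assert report.loc[0, "fence_ms"] == pytest.approx(405.0)
        assert set(out["rt2"]) == set(rts[:-1])

    def test_identical_rts_keep_everything(self):
        out, report = filter_trials(trial_table([400.0] * 6))
        assert len(out) == 6
        assert report.loc[0, "fence_ms"] == pytest.approx(400.0)

    def test_s1_incorrect_trials_dropped(self):
        t = pd.concat(
            [trial_table([300.0] * 5), trial_table([310.0] * 2, s1_correct=False)],
            ignore_index=True,
        )
        out, _ = filter_trials(t)
        assert (out["rt2"] == 300.0).all()

    def test_too_few_trials_flagged_and_fence_skipped(self):
        out, report = filter_trials(trial_table([300.0, 9000.0]))
        assert report.loc[0, "flagged"]
        assert np.isnan(report.loc[0, "fence_ms"])
        assert len(out) == 2  # fence not applied


class TestBindingScore:
    def test_equal_means_give_zero(self):
        assert binding_score({c: 500.0 for c in ("RRFA", "RRFR", "RAFR", "RAFA")}) == 0.0

    def test_arithmetic_example(self):
        means = {"RRFA": 500.0, "RRFR": 450.0, "RAFA": 460.0, "RAFR": 495.0}
        assert binding_score(means) == pytest.approx(85.0)

    def test_invariant_to_constant_shift(self, rng):
        means = dict(zip(("RRFA", "RRFR", "RAFR", "RAFA"), rng.uniform(400, 600, 4)))
        shifted = {k: v + 123.4 for k, v in means.items()}
        assert binding_score(shifted) == pytest.approx(binding_score(means))

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError, match="missing condition"):
            binding_score({"RRFA": 1.0, "RRFR": 1.0, "RAFR": 1.0})


class TestOneSampleT:
    @pytest.mark.parametrize(
        "mean,sd,n,t_want,dz_want",
        [
            (58.14, 92.31, 62, 4.96, 0.63),
            (70.93, 85.56, 54, 6.09, 0.83),
            (18.06, 17.36, 62, 8.19, 1.04),
            (21.48, 17.16, 54, 9.20, 1.25),
        ],
    )
    def test_group_binding_statistics(self, mean, sd, n, t_want, dz_want):
        t, df, dz = one_sample_t(mean, sd, n)
        assert round(t, 2) == t_want
        assert round(dz, 2) == dz_want
        assert df == n - 1

    def test_zero_mean_gives_zero_t(self):
        assert one_sample_t(0.0, 5.0, 30)[0] == 0.0

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            one_sample_t(1.0, 0.0, 10)

    def test_data_overload_matches_summary_overload(self, rng):
        x = rng.normal(10, 4, size=40)
        t1, df1, dz1, p = one_sample_t_data(x)
        t2, df2, dz2 = one_sample_t(x.mean(), x.std(ddof=1), 40)
        assert (t1, df1, dz1) == pytest.approx((t2, df2, dz2))
        ref = scipy.stats.ttest_1samp(x, 0.0)
        assert t1 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestWelchT:
    def test_identical_groups_give_zero(self):
        t, df, _ = welch_t(5.0, 2.0, 20, 5.0, 2.0, 20)
        assert t == 0.0

    def test_equal_variance_equal_n_matches_pooled(self):
        m1, m2, s, n = 10.0, 12.0, 3.0, 25
        t, df, _ = welch_t(m1, s, n, m2, s, n)
        pooled_t = (m1 - m2) / (s * np.sqrt(2 / n))
        assert t == pytest.approx(pooled_t)
        assert df == pytest.approx(2 * n - 2)

    def test_t_grows_without_bound_as_spread_vanishes(self):
        ts = [abs(welch_t(1.0, s, 10, 0.0, s, 10)[0]) for s in (1.0, 0.1, 0.01)]
        assert ts[0] < ts[1] < ts[2]

    def test_zero_variance_both_groups_raises(self):
        with pytest.raises(ValueError):
            welch_t(1.0, 0.0, 10, 0.0, 0.0, 10)


class TestChi2:
    @pytest.mark.parametrize(
        "table,want",
        [
            ((35, 19, 37, 25), 0.14),  # sex composition
            ((46, 7, 56, 6), 0.09),  # handedness
            ((15, 38, 2, 60), 12.34),  # comorbidity
        ],
    )
    def test_yates_corrected_cohort_tables(self, table, want):
        chi2, _ = chi2_2x2(*table, continuity=True)
        assert round(chi2, 2) == want

    def test_balanced_table_is_zero(self):
        assert chi2_2x2(10, 10, 10, 10, continuity=False)[0] == 0.0
        assert chi2_2x2(10, 10, 10, 10, continuity=True)[0] == 0.0

    def test_invariant_under_row_and_column_swap(self):
        a = chi2_2x2(15, 38, 2, 60)[0]
        b = chi2_2x2(60, 2, 38, 15)[0]  # both rows and columns swapped
        assert a == pytest.approx(b)

    def test_matches_scipy_contingency(self):
        got, p = chi2_2x2(35, 19, 37, 25, continuity=True)
        ref = scipy.stats.chi2_contingency([[35, 19], [37, 25]], correction=True)
        assert got == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)


def cell_table(y, groups):
    return pd.DataFrame(
        {
            "participant": [f"s{i}" for i in range(len(groups))],
            "group": groups,
            "RRFR": y[:, 0, 0],
            "RRFA": y[:, 0, 1],
            "RAFR": y[:, 1, 0],
            "RAFA": y[:, 1, 1],
        }
    )


class TestMixedAnova:
    def test_zero_condition_variance_gives_zero_within_f(self, rng):
        n = 10
        y = np.repeat(rng.normal(size=(n, 1, 1)), 2, axis=1).repeat(2, axis=2)
        res = mixed_anova_2x2x2(cell_table(y, ["A"] * 5 + ["B"] * 5))
        within = res[res["effect"].isin(["response", "feature", "response:feature"])]
        assert np.allclose(within["F"], 0.0)

    def test_sums_of_squares_match_bruteforce_oracle(self):
        assert anova_oracle_check(seed=3)["max_abs_ss_diff"] < 1e-8

    def test_planted_crossover_interaction_detected(self, rng):
        n = 16
        y = rng.normal(scale=0.3, size=(n, 2, 2))
        y[:, 0, 0] += 1.0  # RRFR up
        y[:, 1, 1] += 1.0  # RAFA up
        res = mixed_anova_2x2x2(cell_table(y, ["A"] * 8 + ["B"] * 8)).set_index("effect")
        assert res.loc["response:feature", "F"] > 30
        assert res.loc["response:feature", "p"] < 1e-4

    def test_threeway_null_calibrated(self):
        # no group difference planted: 3-way interaction F should follow its
        # null F(1, n-2) distribution -> ~5% rejections at alpha = .05
        rng = np.random.default_rng(99)
        n_rej = 0
        n_sim = 200
        for _ in range(n_sim):
            y = rng.normal(size=(12, 2, 2))
            res = mixed_anova_2x2x2(cell_table(y, ["A"] * 6 + ["B"] * 6)).set_index("effect")
            n_rej += res.loc["response:feature:group", "p"] < 0.05
        rate = n_rej / n_sim
        assert abs(rate - 0.05) < 0.05  # binomial 3*SE ~ 0.046

    def test_missing_cell_participant_excluded_with_warning(self):
        y = np.random.default_rng(0).normal(size=(6, 2, 2))
        t = cell_table(y, ["A"] * 3 + ["B"] * 3)
        t.loc[0, "RRFR"] = np.nan
        with pytest.warns(UserWarning, match="excluded 1"):
            res = mixed_anova_2x2x2(t)
        assert (res["df_error"] == 3).all()
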