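from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxswitch import post_switch_class_table, summarize_table1, temporal_trend, time_to_switch_summary
from rxswitch.descriptives import center_heterogeneity, chi_square_from_counts
from oracles import chi2_oracle, kruskal_oracle, ranksum_oracle


def pheno_frame(statuses, tts=None, post_class=None, index_ssri=None, years=None):
    n = len(statuses)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "status": statuses,
            "time_to_switch_days": tts if tts is not None else [np.nan] * n,
            "post_switch_class": post_class if post_class is not None else [None] * n,
            "index_ssri": index_ssri if index_ssri is not None else ["fluoxetine"] * n,
            "index_date": pd.to_datetime(
                [f"{y}-06-01" for y in (years if years is not None else [2000] * n)]
            ),
        }
    )


class TestChiSquare:
    def test_identical_groups_give_zero_statistic(self):
        stat, p, _ = chi_square_from_counts([[50, 50], [50, 50]])
        assert stat == 0.0 and p == 1.0

    def test_published_sex_counts_are_nonsignificant(self):
        # switcher/nonswitcher by sex: 67% female in both groups
        stat, p, _ = chi_square_from_counts([[22598, 3428], [11082, 1705]])
        assert 0.5 < p < 0.9

    def test_small_table_matches_formula_oracle(self):
        table = [[3, 1], [1, 3]]
        stat, p, _ = chi_square_from_counts(table)
        o_stat, o_p = chi2_oracle(table)
        assert stat == pytest.approx(o_stat, rel=1e-12)
        assert p == pytest.approx(o_p, rel=1e-12)


class TestTable1:
    def _data(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        status = np.where(rng.random(n) < 0.2, "SWITCHER", "NONSWITCHER")
        pheno = pheno_frame(status)
        cov = pd.DataFrame(
            {
                "participant_id": pheno["participant_id"],
                "sex": rng.choice(["FEMALE", "MALE"], n),
                "education": rng.choice(
                    ["NONE", "SECONDARY", "VOCATIONAL", "FURTHER", "DEGREE", "MISSING"], n
                ),
                "income": rng.choice(["LT18K", "18_31K", "31_52K", "52_100K", "GT100K"], n),
                "family_history": rng.choice(["NO", "YES"], n),
                "tdi": rng.normal(size=n),
                "bmi": rng.normal(27, 4, n),
            }
        )
        return pheno, cov

    def test_tests_match_independent_formulas(self):
        pheno, cov = self._data()
        out = summarize_table1(pheno, cov)
        df = pheno.merge(cov, on="participant_id")
        sw = df["status"] == "SWITCHER"
        # binary: chi-square
        sex_p = out.loc[out["variable"] == "sex", "p_value"].iloc[0]
        tab = pd.crosstab(df["sex"], sw).to_numpy()
        assert sex_p == pytest.approx(chi2_oracle(tab)[1], rel=1e-9)
        # continuous: rank-sum
        tdi_p = out.loc[out["variable"] == "tdi", "p_value"].iloc[0]
        assert tdi_p == pytest.approx(
            ranksum_oracle(df.loc[sw, "tdi"], df.loc[~sw, "tdi"])[1], rel=1e-9
        )
        # ordered categorical: Kruskal-Wallis on display-order scores
        edu_p = out.loc[out["variable"] == "education", "p_value"].iloc[0]
        order = {l: i for i, l in enumerate(["NONE", "SECONDARY", "VOCATIONAL", "FURTHER", "DEGREE"])}
        obs = df[df["education"] != "MISSING"]
        scores = obs["education"].map(order).to_numpy(float)
        osw = (obs["status"] == "SWITCHER").to_numpy()
        assert edu_p == pytest.approx(kruskal_oracle(scores[osw], scores[~osw])[1], rel=1e-9)

    def test_missing_reported_separately_and_excluded_from_test(self):
        pheno, cov = self._data()
        out = summarize_table1(pheno, cov)
        edu = out[out["variable"] == "education"]
        assert "Unknown" in set(edu["level"])
        assert "MISSING" not in set(edu["level"])

    def test_single_level_variable_skipped_with_warning(self):
        pheno, cov = self._data()
        cov["sex"] = "FEMALE"
        with pytest.warns(UserWarning, match="single observed level"):
            out = summarize_table1(pheno, cov)
        assert out.loc[out["variable"] == "sex", "p_value"].isna().all()

    def test_rank_tests_invariant_to_monotone_transform(self):
        pheno, cov = self._data()
        out1 = summarize_table1(pheno, cov)
        cov2 = cov.assign(tdi=np.exp(cov["tdi"]), bmi=cov["bmi"] ** 3)
        out2 = summarize_table1(pheno, cov2)
        for var in ("tdi", "bmi"):
            p1 = out1.loc[out1["variable"] == var, "p_value"].iloc[0]
            p2 = out2.loc[out2["variable"] == var, "p_value"].iloc[0]
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestTimeToSwitch:
    def test_single_value(self):
        pheno = pheno_frame(["SWITCHER"], tts=[28])
        row = time_to_switch_summary(pheno).iloc[0]
        assert (row["median"], row["q25"], row["q75"]) == (28, 28, 28)

    def test_odd_count_median(self):
        pheno = pheno_frame(["SWITCHER"] * 5, tts=[10, 20, 30, 40, 50])
        assert time_to_switch_summary(pheno).iloc[0]["median"] == 30

    def test_no_switchers_raises(self):
        with pytest.raises(ValueError):
            time_to_switch_summary(pheno_frame(["NONSWITCHER"]))

    def test_grouped_by_index_ssri(self):
        pheno = pheno_frame(
            ["SWITCHER"] * 4, tts=[10, 20, 30, 40],
            index_ssri=["fluoxetine", "fluoxetine", "sertraline", "sertraline"],
        )
        out = time_to_switch_summary(pheno, by="index_ssri").set_index("group")
        assert out.loc["fluoxetine", "median"] == 15
        assert out.loc["sertraline", "median"] == 35


class TestPostSwitchClasses:
    def test_simple_percentages(self):
        pheno = pheno_frame(
            ["SWITCHER"] * 10,
            post_class=["SSRI"] * 5 + ["TCA"] * 3 + ["SNRI"] * 2,
        )
        out = post_switch_class_table(pheno).set_index("post_switch_class")
        assert out.loc["SSRI", "pct"] == 50.0

    def test_small_classes_lumped_below_threshold(self):
        pheno = pheno_frame(
            ["SWITCHER"] * 10,
            post_class=["SSRI"] * 8 + ["MAOI", "NRI"],
        )
        out = post_switch_class_table(pheno, label_threshold=2).set_index("post_switch_class")
        assert out.loc["other", "n"] == 2

    def test_invariant_to_row_order(self):
        pheno = pheno_frame(
            ["SWITCHER"] * 6, post_class=["SSRI", "TCA", "SSRI", "SNRI", "TCA", "SSRI"]
        )
        a = post_switch_class_table(pheno)
        b = post_switch_class_table(pheno.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(a, b)


class TestCenterHeterogeneity:
    def _with_centers(self, props, n_per=100, seed=0):
        rng = np.random.default_rng(seed)
        rows, centers = [], []
        for ci, p in enumerate(props):
            sw = rng.random(n_per) < p
            rows.extend(np.where(sw, "SWITCHER", "NONSWITCHER"))
            centers.extend([f"C{ci}"] * n_per)
        pheno = pheno_frame(rows)
        cov = pd.DataFrame({"participant_id": pheno["participant_id"], "center": centers})
        return pheno, cov

    def test_identical_centers_not_significant(self):
        pheno, cov = self._with_centers([0.5, 0.5])
        # deterministic identical proportions
        pheno["status"] = ["SWITCHER", "NONSWITCHER"] * 100
        out = center_heterogeneity(pheno, cov)
        assert out["p_value"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        pheno, cov = self._with_centers([0.1, 0.9], seed=2)
        out = center_heterogeneity(pheno, cov)
        df = pheno.merge(cov, on="participant_id")
        tab = pd.crosstab(df["center"], df["status"] == "SWITCHER").to_numpy()
        assert out["p_value"] == pytest.approx(chi2_oracle(tab)[1], rel=1e-9)

    def test_center_effects_detected_in_seeded_replicates(self):
        """±0.05 prevalence offsets across centres should be detectable."""
        detected = 0
        for seed in range(100):
            pheno, cov = self._with_centers([0.08, 0.13, 0.18] * 4, n_per=150, seed=seed)
            out = center_heterogeneity(pheno, cov)
            detected += out["p_value"] < 0.05
        assert detected >= 95


class TestTemporalTrend:
    def test_constant_rate_reports_zero_correlation(self):
        statuses, years = [], []
        for y in range(2000, 2006):
            statuses += ["SWITCHER"] * 10 + ["NONSWITCHER"] * 90
            years += [y] * 100
        pheno = pheno_frame(statuses, tts=[28] * len(statuses), years=years)
        out = temporal_trend(pheno)
        assert out.rate_r == 0.0 and out.rate_p == 1.0

    def test_linear_rate_gives_perfect_correlation(self):
        statuses, years = [], []
        for i, y in enumerate(range(2000, 2006)):
            n_sw = 10 + 5 * i
            statuses += ["SWITCHER"] * n_sw + ["NONSWITCHER"] * (100 - n_sw)
            years += [y] * 100
        pheno = pheno_frame(statuses, tts=[28] * len(statuses), years=years)
        assert temporal_trend(pheno).rate_r == pytest.approx(1.0)

    def test_small_bins_dropped(self):
        statuses = ["SWITCHER", "NONSWITCHER"] * 50 + ["SWITCHER"]
        years = [2000] * 50 + [2001] * 50 + [2002]
        pheno = pheno_frame(statuses, tts=[28] * 101, years=years)
        with pytest.raises(ValueError):
            temporal_trend(pheno, min_bin_n=20)  # only 2 bins survive

    def test_positive_year_effect_recovers_sign(self):
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(20):
            statuses, years = [], []
            for i, y in enumerate(range(2000, 2010)):
                p = 0.08 + 0.01 * i
                sw = rng.random(200) < p
                statuses += list(np.where(sw, "SWITCHER", "NONSWITCHER"))
                years += [y] * 200
            pheno = pheno_frame(statuses, tts=[28] * len(statuses), years=years)
            hits += temporal_trend(pheno).rate_r > 0
        assert hits >= 19
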