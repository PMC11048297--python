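"""Hyper/hypo classification, Kaplan-Meier estimation, log-rank testing, and
the per-site survival scan."""

import numpy as np
import pandas as pd
import pytest

from editscape.repeats import ALU, NON_ALU_REPEAT, NON_REPETITIVE, RepeatInterval, annotate_repeat_class
from editscape.simulate import SurvSimConfig, gen_survival
from editscape.survival import (
    HYPER,
    HYPO,
    classify_hyper_hypo,
    km_estimate,
    logrank_test,
    pfs_quartile_filter,
    site_survival_scan,
)

from conftest import brute_force_km, brute_force_logrank


class TestClassify:
    def test_mean_split(self):
        labels = classify_hyper_hypo(pd.Series([0.1, 0.3], index=["p1", "p2"]))
        assert labels.tolist() == [HYPO, HYPER]

    def test_value_at_mean_is_hypo(self):
        # mean of (0.1, 0.2, 0.3) is 0.2: strictly "over" the mean is required
        labels = classify_hyper_hypo(pd.Series([0.1, 0.2, 0.3]))
        assert labels.tolist() == [HYPO, HYPO, HYPER]

    def test_missing_stays_missing(self):
        labels = classify_hyper_hypo(pd.Series([0.1, np.nan, 0.5]))
        assert labels.isna().tolist() == [False, True, False]

    def test_matches_brute_force_mean_comparison(self):
        rng = np.random.default_rng(8)
        lev = pd.Series(rng.random(10))
        labels = classify_hyper_hypo(lev)
        expected = [HYPER if v > lev.mean() else HYPO for v in lev]
        assert labels.tolist() == expected

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        lev = pd.Series(rng.random(12) * 0.5)
        assert classify_hyper_hypo(lev).tolist() == classify_hyper_hypo(lev + 0.3).tolist()

    def test_constant_levels_warn_all_hypo(self, caplog):
        with caplog.at_level("WARNING"):
            labels = classify_hyper_hypo(pd.Series([0.2, 0.2, 0.2]))
        assert (labels == HYPO).all()
        assert "degenerate" in caplog.text


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([3.0, 5.0, 9.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()
        assert km["events"].sum() == 0

    def test_closed_form_no_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km["at_risk"].tolist() == [3, 2, 1]

    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(10, 25).round(1) + 0.1
        events = rng.integers(0, 2, 25)
        km = km_estimate(times, events)
        oracle = dict(brute_force_km(times, events))
        for t, s in oracle.items():
            got = km.loc[km["time"] == t, "survival"].iloc[0]
            assert got == pytest.approx(s, abs=1e-12)

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(5, 40)
        events = rng.integers(0, 2, 40)
        km = km_estimate(times, events)
        s = km["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_uncensored_tail_equals_empirical_fraction(self):
        times = [1.0, 2.0, 2.0, 4.0, 7.0]
        km = km_estimate(times, [1] * 5)
        # at the third distinct event time (t=4), 1/5 remain
        assert km.loc[km["time"] == 4.0, "survival"].iloc[0] == pytest.approx(0.2)


class TestLogrank:
    def test_micro_example_hand_computation(self):
        # g1 events at 1,2; g2 events at 3,4 -> chi2 = (7/6)^2 / (17/36) = 49/17
        labels = ["a", "a", "b", "b"]
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        chi2, p = logrank_test(labels, times, events)
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)
        assert brute_force_logrank(labels, times, events) == pytest.approx(49 / 17, abs=1e-12)

    def test_identical_groups_give_zero(self):
        times = [2.0, 5.0, 7.0, 2.0, 5.0, 7.0]
        events = [1, 1, 0, 1, 1, 0]
        chi2, p = logrank_test(["a"] * 3 + ["b"] * 3, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            n = 30
            labels = np.where(rng.random(n) < 0.5, "x", "y")
            if len(set(labels)) < 2:
                continue
            times = rng.exponential(12, n).round(1) + 0.1
            events = rng.integers(0, 2, n)
            chi2, _ = logrank_test(labels, times, events)
            assert chi2 == pytest.approx(
                brute_force_logrank(labels, times, events), abs=1e-8
            )

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(31)
        labels = ["a"] * 10 + ["b"] * 10
        times = rng.exponential(10, 20)
        events = rng.integers(0, 2, 20)
        c1, p1 = logrank_test(labels, times, events)
        c2, p2 = logrank_test(["b" if l == "a" else "a" for l in labels], times, events)
        assert c1 == pytest.approx(c2, abs=1e-10) and p1 == pytest.approx(p2, abs=1e-12)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestScan:
    def _cohort(self, seed=0, n=60, beta=4.0):
        rng = np.random.default_rng(seed)
        levels = pd.DataFrame(
            {
                "driver": rng.beta(0.5, 0.5, n),
                "null_site": rng.beta(0.5, 0.5, n),
            },
            index=pd.Index([f"p{i:03d}" for i in range(1, n + 1)], name="patient_id"),
        )
        surv = gen_survival(
            levels["driver"],
            SurvSimConfig(n_patients=n, effect_beta=beta, censor_rate=0.2, seed=seed + 1),
        )
        return levels, surv

    def test_planted_effect_detected_null_site_bookkeeping(self):
        levels, surv = self._cohort()
        summary, details = site_survival_scan(levels, surv)
        row = summary.set_index("site_id").loc["driver"]
        assert row["significant"]
        assert row["n_hyper"] + row["n_hypo"] == 60
        km = details["driver"].km_hyper
        assert np.all(np.diff(km["survival"]) <= 1e-12)

    def test_missing_patients_excluded_per_site(self):
        levels, surv = self._cohort(seed=5)
        levels.loc[levels.index[:20], "null_site"] = np.nan
        summary, _ = site_survival_scan(levels, surv)
        row = summary.set_index("site_id").loc["null_site"]
        assert row["n_hyper"] + row["n_hypo"] == 40

    def test_site_without_patients_skipped(self):
        levels, surv = self._cohort(seed=6)
        levels["empty"] = np.nan
        summary, _ = site_survival_scan(levels, surv)
        assert "empty" not in set(summary["site_id"])

    def test_bh_adjusted_column_present(self):
        levels, surv = self._cohort(seed=7)
        summary, _ = site_survival_scan(levels, surv)
        assert (summary["pvalue_bh"] >= summary["pvalue"] - 1e-12).all()


class TestPfsQuartileFilter:
    def test_keeps_extreme_quartiles_only(self):
        surv = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(8)],
                "pfs_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                "event": [1] * 8,
            }
        )
        kept = pfs_quartile_filter(surv)
        assert set(kept["pfs_months"]) == {1.0, 2.0, 7.0, 8.0}


class TestRepeatClass:
    REPEATS = [
        RepeatInterval("chr1", 99, 200, ALU),
        RepeatInterval("chr1", 150, 400, NON_ALU_REPEAT),
    ]

    def _classify(self, pos):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]})
        return annotate_repeat_class(sites, self.REPEATS).iloc[0]

    def test_interval_boundaries(self):
        assert self._classify(100) == ALU       # start <= pos-1 (99) < end
        assert self._classify(200) == ALU       # pos-1 = 199, last covered base
        assert self._classify(99) == NON_REPETITIVE  # pos-1 = 98 < start
        assert self._classify(201) == NON_ALU_REPEAT

    def test_alu_precedence_on_overlap(self):
        assert self._classify(180) == ALU  # covered by both interval classes

    def test_uncovered_chromosome(self):
        sites = pd.DataFrame({"chrom": ["chrX"], "pos": [100]})
        assert annotate_repeat_class(sites, self.REPEATS).iloc[0] == NON_REPETITIVE
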