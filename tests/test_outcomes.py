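"""Survival and group-comparison statistics against hand-computed
risk-set oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physiotype.outcomes import (
    bonferroni_adjust,
    cox_fit,
    group_compare,
    km_estimate,
    km_survival_at,
    logrank_test,
    reverse_km_followup,
    sofa_band,
)


class TestKmEstimate:
    def test_two_deaths_no_censoring(self):
        curve = km_estimate([1, 2], [1, 1])
        assert km_survival_at(curve, 1) == 0.5
        assert km_survival_at(curve, 2) == 0.0

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([5, 7, 9], [0, 0, 0])
        assert np.all(curve["survival"] == 1.0)

    def test_matches_hand_product_limit(self):
        """Mixed 6-subject toy: S(t) equals the hand-computed product
        over risk sets."""
        time = [1, 2, 2, 3, 4, 5]
        event = [1, 0, 1, 1, 0, 1]
        curve = km_estimate(time, event)
        # risk sets: t=1 (n=6,d=1); t=2 (n=5,d=1,c=1); t=3 (n=3,d=1);
        # t=4 (n=2,c=1); t=5 (n=1,d=1)
        s1 = 1 - 1 / 6
        s2 = s1 * (1 - 1 / 5)
        s3 = s2 * (1 - 1 / 3)
        s5 = s3 * (1 - 1 / 1)
        assert km_survival_at(curve, 1) == pytest.approx(s1)
        assert km_survival_at(curve, 2) == pytest.approx(s2)
        assert km_survival_at(curve, 3.5) == pytest.approx(s3)
        assert km_survival_at(curve, 5) == pytest.approx(s5, abs=1e-12)

    @given(
        times=st.lists(st.floats(0.1, 100), min_size=1, max_size=30),
        events=st.lists(st.integers(0, 1), min_size=30, max_size=30),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_nonincreasing_from_one(self, times, events):
        curve = km_estimate(times, events[: len(times)])
        surv = curve["survival"].to_numpy()
        assert np.all(np.diff(surv) <= 1e-12)
        assert km_survival_at(curve, 0) == 1.0

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0, 1], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4] * 2
        event = [1, 1, 0, 1] * 2
        group = [0] * 4 + [1] * 4
        chi2, df, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0, abs=1e-9)
        assert df == 1

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(1, 40)
        event = rng.integers(0, 2, 40)
        group = np.repeat([0, 1], 20)
        c1, _, _ = logrank_test(time, event, group)
        c2, _, _ = logrank_test(time, event, 1 - group)
        assert c1 == pytest.approx(c2)

    def test_matches_risk_set_enumeration(self):
        """8-subject two-group toy: chi-square equals the O-E statistic
        from direct enumeration of risk sets at pooled event times."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 4.5, 5.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(time[event == 1]):
            at_risk = time >= t
            d = ((time == t) & (event == 1)).sum()
            n = at_risk.sum()
            n1 = (at_risk & (group == 1)).sum()
            d1 = ((time == t) & (event == 1) & (group == 1)).sum()
            e1 = d * n1 / n
            o_minus_e += d1 - e1
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, df, _ = logrank_test(time, event, group)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_no_events_convention(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, df, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (chi2, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestReverseKm:
    def test_all_censored_single_time(self):
        assert reverse_km_followup([100] * 5, [0] * 5) == 100

    def test_all_events_open_ended(self):
        with pytest.warns(UserWarning, match="open-ended"):
            assert reverse_km_followup([10, 20, 30], [1, 1, 1]) == np.inf

    def test_split_censoring_right_continuous(self):
        """50/50 censoring at 100/200 days: the curve sits exactly at
        0.5 on [100, 200), so the median is 200."""
        time = [100] * 5 + [200] * 5
        assert reverse_km_followup(time, [0] * 10) == 200


class TestCoxFit:
    @staticmethod
    def _simulate(n, hrs, seed, censor_at=1570.0):
        rng = np.random.default_rng(seed)
        labels = rng.choice(list("ABCD"), n, p=[0.31, 0.23, 0.31, 0.15])
        lam0 = -np.log(1 - 0.16) / 1095
        lam = lam0 * np.array([hrs[l] for l in labels])
        t = rng.exponential(1 / lam)
        event = (t <= censor_at).astype(int)
        return pd.DataFrame(
            {
                "time_days": np.minimum(t, censor_at),
                "event": event,
                "physiotype": labels,
            }
        )

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "time_days": rng.exponential(500, 500),
                "event": np.ones(500, int),
                "physiotype": rng.choice(["C", "X"], 500),
            }
        )
        table = cox_fit(df)
        hr = table.loc[table["covariate"] == "physiotype_X", "hr"].iloc[0]
        assert abs(np.log(hr)) < 0.25

    def test_reference_row_and_ci_contains_hr(self):
        df = self._simulate(800, {"A": 1.1, "B": 1.8, "C": 1.0, "D": 1.4}, 2)
        table = cox_fit(df)
        ref = table[table["reference"]]
        assert list(ref["covariate"]) == ["physiotype=C"]
        est = table[~table["reference"]]
        assert np.all(est["ci_low"] < est["hr"]) and np.all(est["hr"] < est["ci_high"])

    def test_reference_swap_inverts_hr(self):
        df = self._simulate(600, {"A": 1.0, "B": 2.0, "C": 1.0, "D": 1.0}, 3)
        df = df[df["physiotype"].isin(["B", "C"])]
        t1 = cox_fit(df, reference="C")
        t2 = cox_fit(df, reference="B")
        hr_b = t1.loc[t1["covariate"] == "physiotype_B", "hr"].iloc[0]
        hr_c = t2.loc[t2["covariate"] == "physiotype_C", "hr"].iloc[0]
        assert hr_b == pytest.approx(1 / hr_c, rel=1e-6)

    def test_few_events_warns(self):
        df = self._simulate(400, {"A": 1, "B": 1, "C": 1, "D": 1}, 4,
                            censor_at=365.0)
        with pytest.warns(UserWarning, match="events"):
            cox_fit(df)

    def test_adjustment_covariates_pass_through(self):
        df = self._simulate(400, {"A": 1.1, "B": 1.8, "C": 1.0, "D": 1.4}, 5)
        df["age_ge65"] = np.random.default_rng(0).integers(0, 2, len(df))
        table = cox_fit(df, covariates=("age_ge65",))
        assert "age_ge65" in set(table["covariate"])


class TestSofaBand:
    def test_banding(self):
        bands = sofa_band([0, 1, 2, 4, 5, 12])
        assert list(bands) == ["0-1", "0-1", "2-4", "2-4", ">=5", ">=5"]


class TestGroupCompare:
    def test_identical_categorical_distributions(self):
        values = np.array(["x", "y"] * 10)
        labels = np.repeat(["A", "B"], 10)
        chi2, p = group_compare(values, labels, "categorical")
        assert chi2 == pytest.approx(0)

    def test_disjoint_2x2_chi2_is_20(self):
        """2x2 table (10,0 / 0,10): chi-square = sum (O-E)^2/E = 20
        without continuity correction."""
        values = np.array(["x"] * 10 + ["y"] * 10)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        chi2, _ = group_compare(values, labels, "categorical")
        assert chi2 == pytest.approx(20.0)

    def test_kruskal_identical_groups(self):
        values = np.array([1.0, 2.0, 3.0] * 2)
        labels = np.repeat(["A", "B"], 3)
        h, _ = group_compare(values, labels, "continuous-rank")
        assert h == pytest.approx(0)

    def test_anova_matches_scipy_directly(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 60)
        labels = np.repeat(["A", "B", "C"], 20)
        f, p = group_compare(values, labels, "continuous-normal")
        from scipy.stats import f_oneway

        expected = f_oneway(values[:20], values[20:40], values[40:])
        assert f == pytest.approx(expected.statistic)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2], ["A", "B"], "bayes")


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 3, 0.03), (0.5, 3, 1.0), (0.2, 1, 0.2)],
    )
    def test_examples(self, p, m, expected):
        assert bonferroni_adjust([p], m) == [pytest.approx(expected)]

    @given(
        ps=st.lists(st.floats(0, 1), min_size=1, max_size=6),
        extra=st.integers(0, 5),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_never_decreases_never_exceeds_one(self, ps, extra):
        adj = bonferroni_adjust(ps, len(ps) + extra)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1 for a in adj)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)
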