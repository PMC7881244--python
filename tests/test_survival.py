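import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmesig.survival import (
    chi_squared_association,
    cox_ph,
    high_risk_binary,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
    oncotype_dx,
)

from conftest import make_matrix


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert len(curve.event_times) == 0
        assert curve.survival_at(99.0) == 1.0

    def test_three_events_closed_form(self):
        curve = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_six_subject_hand_worked_example(self):
        # times (1, 2, 2, 3+, 4, 5); product-limit by hand:
        # S(1)=5/6, S(2)=5/6*3/5=1/2, S(4)=1/2*1/2=1/4, S(5)=0
        curve = kaplan_meier([1, 2, 2, 3, 4, 5], [1, 1, 1, 0, 1, 1])
        np.testing.assert_array_equal(curve.event_times, [1, 2, 4, 5])
        np.testing.assert_allclose(curve.survival, [5 / 6, 0.5, 0.25, 0.0], atol=1e-12)
        np.testing.assert_array_equal(curve.at_risk, [6, 5, 2, 1])
        # Greenwood at t=1: S * sqrt(d/(n(n-d))) = 5/6 * sqrt(1/30)
        assert curve.greenwood_se[0] == pytest.approx(5 / 6 * np.sqrt(1 / 30), abs=1e-12)

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        curve = kaplan_meier(t, np.ones(40))
        for x in (np.quantile(t, 0.3), np.quantile(t, 0.7)):
            assert curve.survival_at(x) == pytest.approx(np.mean(t > x), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        chi2, df, p = logrank_test(t + t, e + e, ["a"] * 5 + ["b"] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        g = rng.choice(["a", "b", "c"], 60)
        chi2a, _, _ = logrank_test(t, e, g)
        relabel = {"a": "z", "b": "y", "c": "x"}
        chi2b, _, _ = logrank_test(t, e, [relabel[x] for x in g])
        assert chi2a == pytest.approx(chi2b, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_power_at_hazard_ratio_three(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, 100)
            t2 = rng.exponential(1.0 / 3.0, 100)
            t = np.r_[t1, t2]
            e = np.ones(200)
            _, _, p = logrank_test(t, e, ["a"] * 100 + ["b"] * 100)
            rejections += p < 0.05
        assert rejections >= 18  # power >= 0.9 at HR = 3


class TestCox:
    def test_sign_flips_when_binary_covariate_recoded(self):
        rng = np.random.default_rng(3)
        x = np.r_[np.zeros(60), np.ones(60)]
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        fit = cox_ph(t, np.ones(120), pd.DataFrame({"x": x}))
        flipped = cox_ph(t, np.ones(120), pd.DataFrame({"x": 1 - x}))
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            -flipped.summary.loc["x", "coef"], abs=1e-6
        )
        lo, hi = fit.summary.loc["x", ["ci_lower", "ci_upper"]]
        assert lo <= fit.summary.loc["x", "hr"] <= hi

    def test_null_covariate_mean_hr_near_one(self):
        rng = np.random.default_rng(4)
        hrs = []
        for _ in range(50):
            t = rng.exponential(1.0, 100)
            x = rng.standard_normal(100)
            fit = cox_ph(t, np.ones(100), pd.DataFrame({"x": x}))
            hrs.append(fit.summary.loc["x", "hr"])
        assert abs(np.mean(hrs) - 1.0) < 0.1

    def test_efron_matches_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        x = rng.standard_normal(80)
        t = np.round(rng.exponential(1.0 / np.exp(0.5 * x)), 1) + 0.1  # ties
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        fit = cox_ph(t, e, pd.DataFrame({"x": x}), ties="efron")
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            cph.params_["x"], abs=1e-4
        )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestOncotype:
    CONFIG = {
        "reference_genes": ["ref1", "ref2"],
        "groups": {
            "proliferation": {"genes": ["p1", "p2"], "weight": 10.0},
            "stromal": {"genes": ["s1"], "weight": -5.0},
        },
        "intercept": 30.0,
        "slope": 1.0,
    }

    def _matrix(self, prolif, stromal, ref=7.0):
        genes = ["ref1", "ref2", "p1", "p2", "s1"]
        vals = np.array([[ref], [ref], [prolif], [prolif], [stromal]])
        return make_matrix(vals, genes, ["s"])

    def test_affine_score_and_categories(self):
        # rs = 30 + 10*(prolif-ref) - 5*(stromal-ref)
        low = oncotype_dx(self._matrix(6.99, 7.0), self.CONFIG)
        assert low["rs"].iloc[0] == pytest.approx(29.9)
        assert low["category"].iloc[0] == "low"
        high = oncotype_dx(self._matrix(8.1, 7.0), self.CONFIG)
        assert high["rs"].iloc[0] == pytest.approx(41.0)
        assert high["category"].iloc[0] == "high"

    def test_boundaries_partition_the_line(self):
        for rs, cat in [(29.999, "low"), (30.0, "intermediate"),
                        (40.0, "intermediate"), (40.001, "high")]:
            prolif = 7.0 + (rs - 30.0) / 10.0
            out = oncotype_dx(self._matrix(prolif, 7.0), self.CONFIG)
            assert out["rs"].iloc[0] == pytest.approx(rs)
            assert out["category"].iloc[0] == cat, rs

    def test_zero_weights_give_intercept(self):
        cfg = {
            "reference_genes": ["ref1"],
            "groups": {"g": {"genes": ["p1"], "weight": 0.0}},
            "intercept": 31.5,
            "slope": 1.0,
        }
        mx = make_matrix([[7.0], [9.0]], ["ref1", "p1"], ["s"])
        out = oncotype_dx(mx, cfg)
        assert out["rs"].iloc[0] == pytest.approx(31.5)

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="p2"):
            oncotype_dx(make_matrix([[7.0]], ["ref1"], ["s"]), self.CONFIG)


class TestCategoricalTests:
    def test_balanced_table_zero_statistic(self):
        chi2, p, method = chi_squared_association([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert method == "chi2"

    def test_pooled_response_table_matches_hand_computation(self):
        # responders/nonresponders x pooled subtypes; Pearson sum by hand
        table = np.array([[8, 0], [1, 12]], float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        p_hand = stats.chi2.sf(chi2_hand, 1)
        chi2, p, _ = chi_squared_association(table)
        assert chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_fisher_fallback_matches_tail_enumeration(self):
        table = np.array([[2, 7], [8, 2]])
        stat, p, method = chi_squared_association(table, fallback_fisher=True)
        assert method == "fisher"
        # enumerate all tables with the same margins; two-sided Fisher sums
        # probabilities of tables no more likely than the observed one
        r1, c1, n = table[0].sum(), table[:, 0].sum(), table.sum()
        probs = {
            a: stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        }
        p_obs = probs[table[0, 0]]
        p_enum = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(p_enum, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_association([[0, 0], [3, 4]])

    def test_kruskal_two_groups_equals_squared_ranksum_z(self):
        values = np.array([3.1, 1.2, 5.5, 2.2, 4.4, 6.6, 0.5, 7.7, 8.1, 2.9])
        labels = ["a"] * 5 + ["b"] * 5
        h, _ = kruskal_wallis(values, labels)
        z = stats.ranksums(values[:5], values[5:]).statistic
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_kruskal_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestHighRiskBinary:
    def test_merges_selected_labels(self):
        out = high_risk_binary([1, 5, 6, 2], {5, 6})
        assert list(out) == ["other", "high", "high", "other"]
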