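import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from brmtls.stats import (
    bh_adjust,
    binomial_enrichment,
    concordance,
    cox_fit,
    cox_log_partial_likelihood,
    encode_covariates,
    group_compare,
    km_logrank,
    pearson_r,
)


class TestGroupCompare:
    def test_identical_two_group_distributions_sit_at_null_center(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        grp = ["a"] * 3 + ["b"] * 3
        res = group_compare(vals, grp)
        assert res.method == "mann-whitney-u"
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2
        assert res.pvalue > 0.9

    def test_complete_separation_exact_p(self):
        vals = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        grp = ["a"] * 5 + ["b"] * 5
        res = group_compare(vals, grp)
        # exact enumeration: 2 of C(10,5)=252 orderings are as extreme
        assert res.pvalue == pytest.approx(2 / 252, abs=1e-12)

    def test_three_identical_groups_give_zero_kw_statistic(self):
        vals = [1.0, 2.0, 3.0] * 3
        grp = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = group_compare(vals, grp)
        assert res.method == "kruskal-wallis"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_and_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_compare([1, 2], ["a", "a"])


class TestBHAdjust:
    def test_hand_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_bruteforce_definition_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 40))
            adj = bh_adjust(p)
            order = np.argsort(p)
            m = len(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expected[i] = running
            assert adj == pytest.approx(expected, abs=1e-12)

    def test_never_decreases_and_preserves_ranking(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # order-preserving: sorting by raw p sorts the adjusted values too
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=(2, 50))
        r = pearson_r(x, y).statistic
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(expected, rel=1e-10)

    def test_constant_vector_and_tiny_n_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_r([1, 2], [1, 2])


class TestConcordance:
    def test_identical_and_fully_discordant(self):
        idx = [f"s{i}" for i in range(4)]
        rna = pd.Series(["TLS3", "TLS3", "TLS1", "TLS2"], index=idx)
        mif_same = pd.Series(["positive", "positive", "negative", "negative"], index=idx)
        assert concordance(rna, mif_same).fraction == 1.0
        mif_flip = mif_same.map({"positive": "negative", "negative": "positive"})
        assert concordance(rna, mif_flip).fraction == 0.0

    def test_11_of_20_agreeing_is_55_percent(self):
        idx = [f"s{i}" for i in range(20)]
        rna = pd.Series(["TLS3"] * 10 + ["TLS1"] * 10, index=idx)
        mif = pd.Series(
            ["positive"] * 6 + ["negative"] * 4 + ["positive"] * 5 + ["negative"] * 5,
            index=idx,
        )  # 6 + 5 agree
        assert concordance(rna, mif).fraction == pytest.approx(0.55)

    def test_alternative_mapping_and_sample_mismatch(self):
        idx = ["a", "b"]
        rna = pd.Series(["TLS2", "TLS1"], index=idx)
        mif = pd.Series(["positive", "negative"], index=idx)
        assert concordance(rna, mif, positive_classes=("TLS2", "TLS3")).fraction == 1.0
        with pytest.raises(ValueError, match="different samples"):
            concordance(rna, mif.rename({"a": "zz"}))


def toy_survival():
    # two groups of three, distinct event times, one censored observation
    return pd.DataFrame(
        {
            "time_months": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
            "event": [1, 1, 1, 1, 0, 1],
            "group": ["a", "a", "a", "b", "b", "b"],
        }
    )


def bruteforce_logrank(df):
    """Hand tabulation of the two-group log-rank chi-square (O-E form)."""
    times = sorted(df.loc[df.event == 1, "time_months"].unique())
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        at_risk = df[df.time_months >= t]
        n = len(at_risk)
        n1 = (at_risk.group == "a").sum()
        d = ((df.time_months == t) & (df.event == 1)).sum()
        d1 = ((df.time_months == t) & (df.event == 1) & (df.group == "a")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def test_product_limit_closed_form_without_censoring(self):
        n = 8
        df = pd.DataFrame(
            {"time_months": np.arange(1.0, n + 1), "event": 1, "group": "a"}
        )
        res = km_logrank(df, "group")
        surv = res.fitters["a"].survival_function_["a"]
        for i in range(1, n + 1):
            assert surv.loc[float(i)] == pytest.approx((n - i) / n)

    def test_identical_groups_give_zero_statistic(self):
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "event": [1] * 6,
                "group": ["a"] * 3 + ["b"] * 3,
            }
        )
        assert km_logrank(df, "group").statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_risk_table(self):
        df = toy_survival()
        res = km_logrank(df, "group")
        assert res.statistic == pytest.approx(bruteforce_logrank(df), rel=1e-10)

    def test_zero_events_rejected(self):
        df = toy_survival().assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            km_logrank(df, "group")


class TestCoxFit:
    def test_identical_group_survival_gives_null_coefficient(self):
        # exactly tied event times across groups: Breslow gradient vanishes at 0
        times = np.linspace(1, 20, 12)
        df = pd.DataFrame(
            {
                "time_months": np.r_[times, times],
                "event": 1,
                "x": np.r_[np.zeros(12), np.ones(12)],
            }
        )
        fit = cox_fit(df, ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(0.0, abs=1e-8)

    def test_two_covariate_fit_matches_lifelines_partial_likelihood(self, rng):
        n = 120
        df = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.4, n).astype(float)}
        )
        h = 0.05 * np.exp(0.5 * df.x1 - 0.6 * df.x2)
        df["time_months"] = rng.exponential(1 / h)  # continuous: no ties
        df["event"] = rng.binomial(1, 0.85, n)
        mine = cox_fit(df, ["x1", "x2"])
        cph = CoxPHFitter().fit(df, "time_months", "event")
        assert abs(mine.log_likelihood - cph.log_likelihood_) < 1e-6
        assert mine.summary["coef"].to_numpy() == pytest.approx(
            cph.params_.to_numpy(), abs=1e-5
        )
        # the reported optimum maximises the in-package partial likelihood
        X = df[["x1", "x2"]].to_numpy()
        ll_opt = cox_log_partial_likelihood(
            mine.summary["coef"].to_numpy(), X, df.time_months.to_numpy(),
            df.event.to_numpy(),
        )
        assert ll_opt == pytest.approx(mine.log_likelihood, abs=1e-8)

    def test_score_test_equivalence_with_logrank_on_untied_data(self, rng):
        from brmtls.stats import _breslow_ll_grad_hess

        n = 40
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(10, n),
                "event": 1,
                "x": rng.binomial(1, 0.5, n).astype(float),
            }
        )
        df["group"] = np.where(df.x > 0, "b", "a")
        _, grad, hess = _breslow_ll_grad_hess(
            np.zeros(1), df[["x"]].to_numpy(), df.time_months.to_numpy(),
            df.event.to_numpy(),
        )
        score_stat = float(grad[0] ** 2 / -hess[0, 0])
        logrank = km_logrank(df, "group").statistic
        assert score_stat == pytest.approx(logrank, abs=1e-3)

    def test_underdetermined_and_constant_covariate_rejected(self):
        df = toy_survival().assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df.assign(event=1), ["x"])
        with pytest.raises(ValueError, match="events"):
            cox_fit(toy_survival().assign(event=0, x=[1, 0, 1, 0, 1, 0]), ["x"])

    def test_forest_table_lists_covariates(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(10, n),
                "event": 1,
                "x1": rng.normal(size=n),
            }
        )
        fit = cox_fit(df, ["x1"])
        txt = fit.forest_table()
        assert "x1" in txt and "HR" in txt

    def test_encode_covariates_dummies_categories(self):
        df = pd.DataFrame({"age": [60.0, 70.0], "sex": ["F", "M"]})
        enc = encode_covariates(df, ["age", "sex"])
        assert "age" in enc.columns and enc.shape[1] == 2
        assert set(enc.dtypes) == {np.dtype(float)}


class TestBinomialEnrichment:
    @staticmethod
    def _expand(a, b, c, d):
        # 2x2 (outcome x predictor) laid out as (TT, TF, FT, FF) counts
        outcome = [True] * (a + b) + [False] * (c + d)
        predictor = [True] * a + [False] * b + [True] * c + [False] * d
        return outcome, predictor

    def test_closed_form_log_odds_identity(self):
        outcome, predictor = self._expand(10, 5, 2, 8)
        res = binomial_enrichment(outcome, predictor)
        assert res.coef == pytest.approx(np.log(8.0), abs=1e-6)
        assert not res.haldane

    def test_balanced_independent_table_has_zero_coefficient(self):
        outcome, predictor = self._expand(5, 5, 5, 5)
        assert binomial_enrichment(outcome, predictor).coef == pytest.approx(0.0, abs=1e-8)

    def test_swapping_outcome_labels_negates_coefficient(self):
        outcome, predictor = self._expand(10, 5, 2, 8)
        res = binomial_enrichment(outcome, predictor)
        flipped = binomial_enrichment([not o for o in outcome], predictor)
        assert flipped.coef == pytest.approx(-res.coef, abs=1e-6)

    def test_zero_cell_uses_haldane_correction_with_warning(self):
        outcome, predictor = self._expand(10, 5, 0, 8)
        with pytest.warns(UserWarning, match="Haldane"):
            res = binomial_enrichment(outcome, predictor)
        assert res.haldane
        assert res.coef == pytest.approx(np.log(10.5 * 8.5 / (5.5 * 0.5)))

    def test_single_level_variable_rejected(self):
        with pytest.raises(ValueError, match="both levels"):
            binomial_enrichment([True, True], [True, False])
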