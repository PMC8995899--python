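"""Cox fitting (vs lifelines and brute force), risk score, KM/ROC plumbing."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

from crdcnet import (crdc_score, fit_risk_model, fit_univariate_cox,
                     km_logrank, multivariate_cox, roc_auc)
from crdcnet._cox import CoxData, cox_fit
from crdcnet.matrix import ExpressionMatrix
from crdcnet.survival import RiskModel


def simulate_cox(rng, n, beta, censor_scale=2.0):
    X = rng.standard_normal((n, len(np.atleast_1d(beta))))
    t = rng.exponential(1.0, n) / np.exp(X @ np.atleast_1d(beta))
    c = rng.exponential(censor_scale, n)
    return X, np.minimum(t, c), t <= c


class TestCoxSolver:
    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_lifelines(self, tied):
        rng = np.random.default_rng(4)
        X, time, event = simulate_cox(rng, 300, [0.7, -0.5, 0.0])
        if tied:
            time = np.ceil(time * 8)  # force heavy ties -> Efron correction
        fit = cox_fit(X, time, event)
        df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        df["T"], df["E"] = time, event
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, ref.params_.values, atol=2e-4)
        assert np.allclose(fit.se, ref.standard_errors_.values, atol=2e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_matches_partial_likelihood_grid_search(self):
        """5+5 two-sample toy, no ties: brute-force maximizer to 1e-4."""
        time = np.array([1., 2., 3., 4., 5., 1.5, 2.5, 3.5, 4.5, 5.5])
        event = np.ones(10, bool)
        x = np.r_[np.ones(5), np.zeros(5)]

        def neg_pl(beta):
            order = np.argsort(time)
            xs = x[order]
            ll = 0.0
            for i in range(10):
                ll += beta * xs[i] - np.log(np.exp(beta * xs[i:]).sum())
            return -ll

        grid = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                        options={"xatol": 1e-10})
        fit = cox_fit(x, time, event)
        assert fit.beta[0] == pytest.approx(grid.x, abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones(20), np.arange(1, 21.0), np.ones(20, bool))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            CoxData(np.arange(1, 11.0), np.zeros(10, bool))


class TestCoxRecovery:
    def test_null_beta_small(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            X, t, e = simulate_cox(rng, 500, [0.0])
            hits += abs(cox_fit(X, t, e).beta[0]) < 0.2
        assert hits >= 48

    def test_planted_beta_recovered(self):
        rng = np.random.default_rng(7)
        est = [cox_fit(*simulate_cox(rng, 500, [0.7])).beta[0] for _ in range(30)]
        assert np.mean(est) == pytest.approx(0.7, abs=0.05)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(8)
        for beta in (-1.0, 0.0, 1.0):
            X, t, e = simulate_cox(rng, 2000, [beta])
            assert cox_fit(X, t, e).beta[0] == pytest.approx(beta, abs=0.1)


@pytest.fixture(scope="module")
def toy_model():
    # expression [1, 2] with HR [2, 0.5]: score = ln2 - 2 ln2 = -ln2
    table = pd.DataFrame({"beta": [np.log(2.0), np.log(0.5)],
                          "hr": [2.0, 0.5], "p": [0.01, 0.01],
                          "ci_low": [1.0, 0.2], "ci_high": [4.0, 1.0]},
                         index=["gA", "gB"])
    return RiskModel(table)


class TestCrdcScore:
    def matrix(self, values, genes):
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=["s1"]), "log2TPM")

    def test_weighted_sum_arithmetic(self, toy_model):
        sv = crdc_score(self.matrix([[1.0], [2.0]], ["gA", "gB"]), toy_model)
        assert sv.scores["s1"] == pytest.approx(-np.log(2.0))

    def test_unit_hazard_ratios_give_zero(self):
        table = pd.DataFrame({"beta": [0.0, 0.0], "hr": [1.0, 1.0],
                              "p": [0.5, 0.5], "ci_low": [1, 1],
                              "ci_high": [1, 1]}, index=["gA", "gB"])
        sv = crdc_score(self.matrix([[3.0], [9.0]], ["gA", "gB"]), RiskModel(table))
        assert sv.scores["s1"] == 0.0

    def test_linearity_in_expression(self, toy_model):
        a = crdc_score(self.matrix([[1.0], [2.0]], ["gA", "gB"]), toy_model)
        b = crdc_score(self.matrix([[3.0], [6.0]], ["gA", "gB"]), toy_model)
        assert b.scores["s1"] == pytest.approx(3 * a.scores["s1"])

    def test_missing_model_gene_is_error(self, toy_model):
        with pytest.raises(KeyError, match="gB"):
            crdc_score(self.matrix([[1.0]], ["gA"]), toy_model)


class TestKmLogrank:
    def test_maximal_separation_is_significant(self):
        surv = pd.DataFrame(
            {"time": [1.0] * 20 + [2.0] * 20,
             "event": [True] * 20 + [False] * 20},
            index=[f"s{i}" for i in range(40)])
        labels = pd.Series(["High"] * 20 + ["Low"] * 20, index=surv.index)
        _, p, curves = km_logrank(labels, surv)
        assert p < 1e-3
        assert set(curves) == {"High", "Low"}

    def test_label_swap_preserves_statistic(self, survival_300):
        rng = np.random.default_rng(1)
        labels = pd.Series(rng.choice(["High", "Low"], 300), index=survival_300.index)
        chi2_a, _, _ = km_logrank(labels, survival_300)
        swapped = labels.map({"High": "Low", "Low": "High"})
        chi2_b, _, _ = km_logrank(swapped, survival_300)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)

    def test_null_rejection_rate_nominal(self, survival_300):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            labels = pd.Series(rng.choice(["High", "Low"], 300),
                               index=survival_300.index)
            _, p, _ = km_logrank(labels, survival_300)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_single_group_is_error(self, survival_300):
        labels = pd.Series("High", index=survival_300.index)
        with pytest.raises(ValueError):
            km_logrank(labels, survival_300)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series([1, 2, 3, 4], index=list("abcd"))
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        assert roc_auc(scores, labels) == 1.0

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(1000)]
        scores = pd.Series(rng.normal(size=1000), index=idx)
        labels = pd.Series(rng.integers(0, 2, 1000), index=idx)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(200)]
        scores = pd.Series(rng.normal(size=200), index=idx)
        labels = pd.Series(rng.integers(0, 2, 200), index=idx)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(scores * 3), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc(pd.Series([1.0, 2.0], index=["a", "b"]),
                    pd.Series([1, 1], index=["a", "b"]))


class TestMultivariateCox:
    def test_single_covariate_reduces_to_univariate(self, survival_300):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=300), index=survival_300.index, name="x")
        uni = fit_univariate_cox(x, survival_300)
        multi = multivariate_cox(x.to_frame(), survival_300)
        assert multi.loc["x", "beta"] == pytest.approx(uni.beta[0], rel=1e-8)
        assert multi.loc["x", "p"] == pytest.approx(uni.p[0], rel=1e-6)

    def test_independent_effects_recovered(self):
        rng = np.random.default_rng(6)
        X, t, e = simulate_cox(rng, 800, [0.5, -0.5])
        idx = [f"s{i}" for i in range(800)]
        surv = pd.DataFrame({"time": t, "event": e}, index=idx)
        cov = pd.DataFrame(X, columns=["a", "b"], index=idx)
        res = multivariate_cox(cov, surv)
        assert res.loc["a", "beta"] == pytest.approx(0.5, abs=0.15)
        assert res.loc["b", "beta"] == pytest.approx(-0.5, abs=0.15)

    def test_duplicated_covariate_is_collinearity_error(self, survival_300):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        cov = pd.DataFrame({"a": x, "dup": x}, index=survival_300.index)
        with pytest.raises(ValueError, match="collinear"):
            multivariate_cox(cov, survival_300)


class TestRiskModelEndToEnd:
    def test_planted_signature_splits_survival(self, default_cohort):
        """High/Low split of the risk score separates survival strongly."""
        from crdcnet import stepminer_split

        cohort = default_cohort
        log2 = ExpressionMatrix(
            np.log2(cohort.expression.values + 1.0), "log2TPM",
            cohort.expression.gene_meta, cohort.expression.sample_meta)
        genes = list(cohort.truth.planted_prognostic)
        model = fit_risk_model(log2, genes, cohort.survival)
        assert set(model.genes) == set(genes)
        sv = crdc_score(log2, model)
        split = stepminer_split(sv.scores.loc[cohort.survival.index])
        _, p, _ = km_logrank(split.labels, cohort.survival)
        assert p < 0.01
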