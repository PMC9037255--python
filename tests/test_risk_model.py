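import numpy as np
import pandas as pd
import pytest

from epmkit.data_io import ClinicalTable
from epmkit.risk_model import (
    DAYS_PER_YEAR,
    RiskModel,
    breslow_loglik,
    km_logrank,
    lasso_cox_select,
    logrank_statistic,
    optimal_cutpoint,
    risk_score,
    time_dependent_auc,
    univariate_cox,
)
from tests.conftest import make_clinical


class TestUnivariateCox:
    def test_matches_grid_search_oracle(self):
        # interleaved groups: the partial likelihood has an interior maximum
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = univariate_cox(x, clin)
        grid = np.linspace(-5, 5, 20001)
        lls = [breslow_loglik(b * x, clin.time, clin.event) for b in grid]
        beta_oracle = grid[int(np.argmax(lls))]
        assert res.beta == pytest.approx(beta_oracle, abs=1e-3)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(100 * np.exp(-0.4 * x))
        e = (rng.uniform(size=n) < 0.75).astype(int)
        clin = make_clinical(t, e)
        res = univariate_cox(x, clin)
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E")
        assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert res.p == pytest.approx(float(cph.summary.loc["x", "p"]), rel=1e-4)

    def test_independent_covariate_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(100, size=n)
            e = (rng.uniform(size=n) < 0.7).astype(int)
            res = univariate_cox(x, make_clinical(t, e))
            hits += res.p > 0.01
        assert hits >= 9

    def test_score_test_equals_logrank_for_binary_covariate(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        n = 80
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(100 * np.exp(-0.5 * x))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        res = univariate_cox(x, make_clinical(t, e))
        lr = logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
        assert res.score_chi2 == pytest.approx(float(lr.test_statistic), abs=1e-9)

    def test_constant_covariate_rejected(self):
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(4), clin)

    def test_perfect_separation_capped(self):
        clin = make_clinical([1, 2, 3, 100, 110, 120], [1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1, 1, 0, 0, 0])
        res = univariate_cox(x, clin)
        assert abs(res.beta) <= 10.0 + 1e-9


class TestLassoCox:
    def _data(self, seed=0, n=120, p=30, strong=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        lp = 1.0 * X[:, :strong].sum(axis=1)
        t = rng.exponential(100 * np.exp(-lp))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        genes = [f"g{i}" for i in range(p)]
        expr = pd.DataFrame(X.T, index=genes, columns=[f"s{i}" for i in range(n)])
        return expr, make_clinical(t, e)

    def test_huge_penalty_empty_model_error(self):
        expr, clin = self._data()
        with pytest.raises(ValueError, match="zero"):
            lasso_cox_select(expr, clin, n_folds=3, seed=0, alphas=[1e6])

    def test_strong_gene_dominates_at_tiny_penalty(self):
        expr, clin = self._data(seed=3, strong=1)
        model = lasso_cox_select(expr, clin, n_folds=3, seed=0, alphas=[1e-4])
        coefs = dict(zip(model.genes, model.coef))
        assert max(coefs, key=lambda g: abs(coefs[g])) == "g0"

    def test_recovers_strong_signals_by_cv(self):
        expr, clin = self._data(seed=5, strong=3)
        model = lasso_cox_select(expr, clin, n_folds=5, seed=1)
        assert {"g0", "g1", "g2"} <= set(model.genes)
        for g in ("g0", "g1", "g2"):
            assert model.coef[model.genes.index(g)] > 0  # higher expr -> higher hazard


class TestRiskScore:
    def test_hand_example(self):
        model = RiskModel(genes=["g1", "g2"], coef=np.array([0.5, -1.0]), lambda_=0.1)
        expr = pd.DataFrame({"s1": [2.0, 1.0]}, index=["g1", "g2"])
        assert risk_score(model, expr)["s1"] == 0.0

    def test_zero_coefficients_zero_score(self):
        model = RiskModel(genes=["g1"], coef=np.array([0.0]), lambda_=0.1)
        expr = pd.DataFrame({"s1": [9.0], "s2": [1.0]}, index=["g1"])
        assert risk_score(model, expr).tolist() == [0.0, 0.0]

    def test_linearity_and_zero_gene_irrelevance(self):
        rng = np.random.default_rng(0)
        model = RiskModel(genes=["a", "b"], coef=np.array([0.3, -0.7]), lambda_=0.1)
        expr = pd.DataFrame(rng.uniform(1, 5, size=(2, 6)), index=["a", "b"])
        s = risk_score(model, expr)
        np.testing.assert_allclose(risk_score(model, 2 * expr), 2 * s, atol=1e-12)
        model2 = RiskModel(genes=["a", "b", "c"], coef=np.array([0.3, -0.7, 0.0]), lambda_=0.1)
        expr2 = pd.concat([expr, pd.DataFrame(rng.uniform(size=(1, 6)), index=["c"])])
        np.testing.assert_allclose(risk_score(model2, expr2), s, atol=1e-12)

    def test_missing_gene_error(self):
        model = RiskModel(genes=["zz"], coef=np.array([1.0]), lambda_=0.1)
        expr = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(KeyError, match="zz"):
            risk_score(model, expr)


class TestOptimalCutpoint:
    def test_exhaustive_scan_example(self):
        scores = np.arange(1.0, 11.0)
        time = np.where(scores >= 6, 1.0, 10.0)
        event = (scores >= 6).astype(int)
        res = optimal_cutpoint(scores, make_clinical(time, event), minprop=0.1)
        assert res.cutpoint == 5.0
        assert res.high.sum() == 5

    def test_exchangeable_tie_returns_smallest_candidate(self):
        scores = np.arange(1.0, 11.0)
        clin = make_clinical([5.0] * 10, [1] * 10)
        res = optimal_cutpoint(scores, clin, minprop=0.1)
        assert res.cutpoint == 1.0

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        t = rng.exponential(100 * np.exp(scores))
        e = (rng.uniform(size=60) < 0.8).astype(int)
        clin = make_clinical(t, e)
        a = optimal_cutpoint(scores, clin)
        b = optimal_cutpoint(np.exp(scores), clin)
        np.testing.assert_array_equal(a.high, b.high)
        assert b.cutpoint == pytest.approx(np.exp(a.cutpoint))

    def test_step_hazard_threshold_recovery(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.uniform(-1, 1, size=n)
            lam = 0.002 * np.exp(1.1 * (x > 0))
            t_ev = rng.exponential(1 / lam)
            c = rng.uniform(0, 1500, size=n)
            clin = make_clinical(np.minimum(t_ev, c), (t_ev <= c).astype(int))
            res = optimal_cutpoint(x, clin)
            ok += abs(res.cutpoint) <= 0.1
        assert ok >= 8

    def test_minprop_violation_error(self):
        scores = np.array([1.0, 2.0])
        clin = make_clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            optimal_cutpoint(scores, clin, minprop=0.6)


class TestKMLogrank:
    def test_logrank_matches_hand_oracle(self):
        time = np.array([1.0, 2.0, 10.0, 20.0])
        event = np.array([1, 1, 1, 1])
        group = np.array([True, True, False, False])
        ome, var = logrank_statistic(time, event, group)
        # hand computation over the 4 risk tables (event times 1, 2, 10, 20):
        # O1-E1 = (1-2/4) + (1-1/3) + 0 + 0 = 7/6
        assert ome == pytest.approx(7 / 6, abs=1e-12)
        # V = 2/4*2/4 + (1/3)*(2/3) = 1/4 + 2/9
        assert var == pytest.approx(1 / 4 + 2 / 9, abs=1e-12)
        clin = make_clinical(time, event)
        ev = km_logrank(np.where(group, "A", "B"), clin)
        assert ev.logrank_chi2 == pytest.approx(ome**2 / var, abs=1e-9)

    def test_identical_groups_chi2_zero(self):
        time = np.array([1.0, 2.0, 1.0, 2.0])
        clin = make_clinical(time, [1, 1, 1, 1])
        ev = km_logrank(np.array(["A", "A", "B", "B"]), clin)
        assert ev.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert ev.logrank_p == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.exponential(10, size=30)).round(3)
        clin = make_clinical(np.concatenate([t, [99.0, 99.0]]), [1] * 30 + [1, 1])
        groups = np.array(["A"] * 30 + ["B"] * 2)
        ev = km_logrank(groups, clin)
        km = ev.km_curves["A"]
        for time_pt, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx(np.mean(t > time_pt), abs=1e-12)


class TestTimeDependentAUC:
    def test_perfect_and_anti_ordering(self):
        clin = make_clinical(np.array([4, 3, 2, 1.0]) * DAYS_PER_YEAR, [1, 1, 1, 1])
        assert time_dependent_auc(np.array([1, 2, 3, 4.0]), clin, [2.5])[2.5] == 1.0
        clin2 = make_clinical(np.array([1, 2, 3, 4.0]) * DAYS_PER_YEAR, [1, 1, 1, 1])
        assert time_dependent_auc(np.array([1, 2, 3, 4.0]), clin2, [2.5])[2.5] == 0.0

    def test_equals_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(0)
        n = 300
        scores = rng.normal(size=n)
        t = rng.exponential(500, size=n)
        clin = make_clinical(t, np.ones(n, int))
        horizon = 1.0
        auc = time_dependent_auc(scores, clin, [horizon])[horizon]
        cases = t <= horizon * DAYS_PER_YEAR
        mw = np.mean(
            [(si > sj) + 0.5 * (si == sj) for si in scores[cases] for sj in scores[~cases]]
        )
        assert auc == pytest.approx(mw, abs=1e-9)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        n = 500
        scores = rng.normal(size=n)
        t = rng.exponential(700, size=n)
        c = rng.uniform(0, 2500, size=n)
        clin = make_clinical(np.minimum(t, c), (t <= c).astype(int))
        auc = time_dependent_auc(scores, clin, [1.0])[1.0]
        assert auc == pytest.approx(0.5, abs=0.06)

    def test_horizon_without_controls_is_missing(self):
        clin = make_clinical([10.0, 20.0, 30.0, 40.0], [1, 1, 1, 1])
        out = time_dependent_auc(np.array([1, 2, 3, 4.0]), clin, [5.0])
        assert np.isnan(out[5.0])
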