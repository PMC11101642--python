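"""Correlation screen, thresholding, preranked enrichment, elastic net."""

import numpy as np
import pandas as pd
import pytest

from elastomics.screen import (
    InsufficientDataError,
    correlate_genes,
    elastic_net_regulators,
    enrichment_score,
    preranked_enrichment,
    threshold_genes,
)


def naive_pearson(x, y):
    """Two-pass covariance oracle."""
    xm, ym = x - x.mean(), y - y.mean()
    return np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))


class TestCorrelate:
    def test_self_correlation(self, rng):
        y = rng.normal(size=50)
        res = correlate_genes(y[None, :], ["g"], y)
        assert res.loc["g", "pearson_r"] == pytest.approx(1.0)
        assert res.loc["g", "p_value"] < 1e-30

    def test_constant_gene_degenerate(self, rng):
        expr = np.vstack([np.full(30, 2.0), rng.normal(size=30)])
        res = correlate_genes(expr, ["const", "noisy"], rng.normal(size=30))
        assert res.loc["const", "pearson_r"] == 0.0
        assert res.loc["const", "p_value"] == 1.0
        assert bool(res.loc["const", "degenerate"])
        assert not bool(res.loc["noisy", "degenerate"])

    def test_matches_naive_two_pass_oracle(self, rng):
        expr = rng.normal(size=(10, 40))
        y = rng.normal(size=40)
        res = correlate_genes(expr, [f"g{i}" for i in range(10)], y)
        for i in range(10):
            assert res.iloc[i]["pearson_r"] == pytest.approx(
                naive_pearson(expr[i], y), rel=1e-10
            )

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(size=60)
        y = 0.3 * x + rng.normal(size=60)
        res = correlate_genes(x[None, :], ["g"], y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.loc["g", "pearson_r"] == pytest.approx(r_ref, rel=1e-10)
        assert res.loc["g", "p_value"] == pytest.approx(p_ref, rel=1e-6)

    def test_min_clr_cell_filter(self, rng):
        y = np.concatenate([np.full(10, -2.0), rng.normal(2.0, 1.0, 40)])
        expr = rng.normal(size=(3, 50))
        res = correlate_genes(expr, list("abc"), y, min_dtd_clr=1.0)
        assert (res["n_cells"] == np.sum(y >= 1.0)).all()

    def test_too_few_cells(self):
        with pytest.raises(InsufficientDataError):
            correlate_genes(np.ones((1, 2)), ["g"], np.array([0.0, 1.0]))

    def test_bh_adjustment_order_invariant(self, rng):
        expr = rng.normal(size=(20, 30))
        y = rng.normal(size=30)
        genes = [f"g{i}" for i in range(20)]
        res1 = correlate_genes(expr, genes, y)
        perm = rng.permutation(20)
        res2 = correlate_genes(expr[perm], [genes[i] for i in perm], y)
        for g in genes:
            assert res2.loc[g, "p_adjusted"] == pytest.approx(res1.loc[g, "p_adjusted"], rel=1e-12)

    def test_adjusted_not_below_raw(self, rng):
        res = correlate_genes(rng.normal(size=(15, 25)), [f"g{i}" for i in range(15)],
                              rng.normal(size=25))
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()


class TestThreshold:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "pearson_r": [0.3, -0.3, 0.1, 0.25, 0.0],
                "p_value": [1e-12, 1e-12, 1e-12, 1e-3, 1.0],
                "p_adjusted": [1e-11, 1e-11, 1e-11, 1e-2, 1.0],
                "degenerate": [False, False, False, False, True],
            },
            index=list("abcde"),
        )

    def test_matches_brute_force_scan(self):
        res = self.table()
        got = threshold_genes(res, r_min=0.15, p_max=1e-10, mode="greater", use_adjusted=False)
        expect = [
            g
            for g in res.index
            if res.loc[g, "pearson_r"] > 0.15
            and res.loc[g, "p_value"] < 1e-10
            and not res.loc[g, "degenerate"]
        ]
        assert got == expect == ["a"]

    def test_two_sided_mode(self):
        got = threshold_genes(self.table(), 0.15, 1e-10, mode="two-sided", use_adjusted=False)
        assert got == ["a", "b"]

    def test_trivial_thresholds_keep_all_non_degenerate(self):
        got = threshold_genes(self.table(), r_min=-1.0, p_max=1.1, mode="two-sided")
        assert got == list("abcd")

    def test_empty_input(self):
        assert threshold_genes(pd.DataFrame(), 0.1, 0.05) == []


def oracle_running_sum(order, metric, gene_set, weight=1.0):
    """Exhaustive hand computation of the weighted KS running sum."""
    n = len(order)
    hits = [g in gene_set for g in order]
    nr = sum(abs(m) ** weight for g, m in zip(order, metric) if g in gene_set)
    n_miss = n - sum(hits)
    running, total = [], 0.0
    for g, m in zip(order, metric):
        if g in gene_set:
            total += abs(m) ** weight / nr
        else:
            total -= 1.0 / n_miss
        running.append(total)
    es = max(running, key=abs)
    return es, running


class TestEnrichment:
    UNIVERSE = [f"g{i}" for i in range(10)]
    METRIC = np.array([0.9, 0.8, 0.5, 0.4, 0.3, 0.1, -0.2, -0.4, -0.6, -0.9])

    def test_es_matches_hand_computation(self):
        gene_set = {"g0", "g3", "g7"}
        es, running = enrichment_score(self.UNIVERSE, self.METRIC, gene_set, weight=1.0)
        es_oracle, running_oracle = oracle_running_sum(self.UNIVERSE, self.METRIC, gene_set)
        np.testing.assert_allclose(running, running_oracle, rtol=1e-12)
        assert es == pytest.approx(es_oracle, rel=1e-12)

    def test_running_sum_ends_at_zero(self):
        _, running = enrichment_score(self.UNIVERSE, self.METRIC, {"g1", "g4"}, weight=0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_top_k_set_is_maximally_enriched(self, rng):
        ranked = pd.Series(self.METRIC, index=self.UNIVERSE)
        top = set(self.UNIVERSE[:3])
        es_top, _ = enrichment_score(self.UNIVERSE, self.METRIC, top)
        assert es_top > 0
        for _ in range(50):
            random_set = set(rng.choice(self.UNIVERSE, size=3, replace=False))
            es_rand, _ = enrichment_score(self.UNIVERSE, self.METRIC, random_set)
            assert es_top >= es_rand

    def test_preranked_table(self):
        ranked = pd.Series(self.METRIC, index=self.UNIVERSE)
        out = preranked_enrichment(
            ranked, {"top": self.UNIVERSE[:3], "bottom": self.UNIVERSE[-3:]}, n_perm=200, seed=1
        )
        assert out.loc["top", "enrichment_score"] > 0
        assert out.loc["bottom", "enrichment_score"] < 0
        assert ((out["p_value"] > 0) & (out["p_value"] <= 1)).all()

    def test_small_set_skipped_with_warning(self):
        ranked = pd.Series(self.METRIC, index=self.UNIVERSE)
        with pytest.warns(UserWarning):
            out = preranked_enrichment(ranked, {"tiny": ["g0"]}, n_perm=10, seed=0)
        assert out.empty

    def test_deterministic_given_seed(self):
        ranked = pd.Series(self.METRIC, index=self.UNIVERSE)
        a = preranked_enrichment(ranked, {"s": self.UNIVERSE[:4]}, n_perm=100, seed=7)
        b = preranked_enrichment(ranked, {"s": self.UNIVERSE[:4]}, n_perm=100, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestElasticNet:
    def test_oracle_predictor_dominates(self, rng):
        n, p = 300, 20
        x = rng.normal(size=(p, n))
        y = x[3] + 0.05 * rng.normal(size=n)
        fit = elastic_net_regulators(x, [f"g{i}" for i in range(p)], y, seed=0)
        assert fit.coefficients["abs_s"].idxmax() == "g3"
        others = fit.coefficients.drop("g3")["abs_s"]
        assert (others < 0.1 * fit.coefficients.loc["g3", "abs_s"]).all()

    def test_lasso_produces_exact_zeros_ridge_does_not(self, rng):
        n, p = 200, 30
        x = rng.normal(size=(p, n))
        y = x[0] + rng.normal(size=n)
        lasso = elastic_net_regulators(x, [f"g{i}" for i in range(p)], y, mixing=1.0, seed=0)
        ridge = elastic_net_regulators(x, [f"g{i}" for i in range(p)], y, mixing=0.0, seed=0)
        assert (lasso.coefficients["s"] == 0).sum() > 0
        assert (ridge.coefficients["s"] == 0).sum() < (lasso.coefficients["s"] == 0).sum()

    def test_weak_penalty_approaches_ols(self, rng):
        from sklearn.linear_model import ElasticNet, LinearRegression

        n, p = 500, 4
        x = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 0.25, 0.0])
        y = x @ beta + 0.1 * rng.normal(size=n)
        ols = LinearRegression().fit(x, y)
        weak = ElasticNet(alpha=1e-8, l1_ratio=0.5, max_iter=100_000).fit(x, y)
        np.testing.assert_allclose(weak.coef_, ols.coef_, rtol=1e-3, atol=1e-5)

    def test_fold_count_validated(self, rng):
        x = rng.normal(size=(3, 5))
        with pytest.raises(ValueError):
            elastic_net_regulators(x, list("abc"), rng.normal(size=5), n_folds=10)

    def test_cv_curve_reported(self, rng):
        x = rng.normal(size=(5, 100))
        y = x[0] + rng.normal(size=100)
        fit = elastic_net_regulators(x, list("abcde"), y, seed=0)
        assert {"alpha", "mean_cv_mse"} <= set(fit.cv_curve.columns)
        assert len(fit.cv_curve) > 10
        assert fit.alpha in fit.cv_curve["alpha"].to_numpy()
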