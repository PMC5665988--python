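"""Spike-and-slab selection, stepwise AICc, OLS and variance partitioning."""

import numpy as np
import pytest
from scipy import stats

from ncplink import selection
from ncplink.selection import (
    SSVSRegressor,
    SsvsConfig,
    aicc,
    fit_mlr,
    forward_stepwise_aicc,
    inclusion_probabilities,
    select_by_sharp_drop,
    simple_r2_scan,
    ssvs_fit,
    standardize_predictors,
    variance_partition,
)


class TestStandardize:
    def test_mean_zero_unit_sd(self):
        z = standardize_predictors(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        z = standardize_predictors(X)
        np.testing.assert_allclose(standardize_predictors(z), z, atol=1e-12)

    def test_constant_column_named(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="OTU_7"):
            standardize_predictors(X, ids=["OTU_7", "OTU_8"])


def _planted_design(seed, n=21, p=20, beta=5.0, noise=0.5):
    rng = np.random.default_rng(seed)
    X = standardize_predictors(rng.normal(size=(n, p)))
    y = beta * X[:, 0] + rng.normal(0, noise, size=n)
    return X, y


class TestSsvs:
    def test_planted_signal_dominates_inclusion(self):
        cfg = SsvsConfig(iterations=2000, burn_in=1000)
        hits, probs = 0, []
        for s in range(20):
            X, y = _planted_design(s)
            cfg.seed = s
            res = ssvs_fit(X, y, cfg)
            probs.append(res.inclusion_probs[0])
            if res.ranking[0] == "x0":
                hits += 1
        assert np.median(probs) >= 0.95
        assert hits >= 18

    def test_pure_noise_keeps_inclusion_low(self):
        cfg = SsvsConfig(iterations=2000, burn_in=1000)
        all_probs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            X = standardize_predictors(rng.normal(size=(21, 20)))
            y = rng.normal(size=21)
            cfg.seed = s
            all_probs.append(ssvs_fit(X, y, cfg).inclusion_probs)
        all_probs = np.array(all_probs)
        assert all_probs.mean() <= 0.5
        assert np.median(all_probs, axis=0).max() < 0.9

    def test_seeded_rerun_bit_identical(self):
        X, y = _planted_design(7)
        cfg = SsvsConfig(iterations=500, burn_in=200, seed=3)
        a = ssvs_fit(X, y, cfg)
        b = ssvs_fit(X, y, cfg)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.sigma2_draws, b.sigma2_draws)

    def test_reported_probs_match_recomputation_from_draws(self):
        X, y = _planted_design(8)
        res = ssvs_fit(X, y, SsvsConfig(iterations=800, burn_in=400, seed=1))
        np.testing.assert_array_equal(
            res.inclusion_probs, inclusion_probabilities(res.beta_draws))

    def test_more_noise_weakens_inclusion(self):
        cfg = SsvsConfig(iterations=2000, burn_in=1000, seed=2)
        meds = []
        for noise in (0.5, 5.0):
            probs = []
            for s in range(8):
                X, y = _planted_design(200 + s, beta=3.0, noise=noise)
                cfg.seed = s
                probs.append(ssvs_fit(X, y, cfg).inclusion_probs[0])
            meds.append(np.median(probs))
        assert meds[1] < meds[0]

    def test_nonfinite_input_rejected(self):
        X, y = _planted_design(9)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            ssvs_fit(X, y, SsvsConfig(iterations=100, burn_in=50))

    def test_sklearn_estimator_interface(self):
        X, y = _planted_design(10)
        est = SSVSRegressor(iterations=500, burn_in=200, random_state=0)
        assert est.get_params()["iterations"] == 500
        est.fit(X, y)
        assert est.inclusion_probs_.shape == (20,)
        pred = est.predict(X)
        assert pred.shape == y.shape
        # the planted direction dominates the posterior-mean prediction
        assert np.corrcoef(pred, y)[0, 1] > 0.9


class TestInclusionProbabilities:
    def test_hand_fraction(self):
        draws = np.zeros((5000, 2))
        draws[:4600, 0] = 1.5
        draws[:, 1] = 0.7
        probs = inclusion_probabilities(draws)
        assert probs[0] == pytest.approx(0.92)
        assert probs[1] == 1.0

    def test_all_zero_column(self):
        assert inclusion_probabilities(np.zeros((10, 1)))[0] == 0.0

    def test_no_draws_rejected(self):
        with pytest.raises(ValueError):
            inclusion_probabilities(np.zeros((0, 3)))


class TestSharpDrop:
    def test_drop_after_three(self):
        probs = [0.98, 0.95, 0.90, 0.15, 0.12, 0.10, 0.02]
        res = select_by_sharp_drop(probs)
        assert res.selected == ["x0", "x1", "x2"]
        assert not res.no_sharp_drop

    def test_drop_after_one(self):
        res = select_by_sharp_drop([0.99, 0.20, 0.18, 0.1])
        assert res.selected == ["x0"]

    def test_uniform_probs_flagged_empty(self):
        res = select_by_sharp_drop([0.5] * 6)
        assert res.selected == []
        assert res.no_sharp_drop

    def test_max_k_guard(self):
        # the largest drop is beyond max_k; the cut stays within the guard
        probs = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.01]
        res = select_by_sharp_drop(probs, max_k=3)
        assert len(res.selected) <= 3


def _normal_equations(X, y):
    design = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(design.T @ design, design.T @ y)


class TestFitMlr:
    def test_noiseless_r2_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        fit = fit_mlr(X, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_response_r2_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        # project out the fitted part to construct a residual-orthogonal y
        fit = fit_mlr(X, y)
        resid = y - fit.predict(X)
        fit2 = fit_mlr(X, resid)
        assert fit2.r2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(8, 25)
            p = rng.integers(1, 4)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_mlr(X, y)
            np.testing.assert_allclose(fit.coefficients,
                                       _normal_equations(X, y), atol=1e-10)

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_mlr(X, np.arange(10.0))


class TestAicc:
    def test_correction_term_hand_value(self):
        # n=21, k=4 (3 coefficients + variance): 2*4*5/16 = 2.5
        rss, n = 10.0, 21
        aic = n * np.log(rss / n) + 2 * 4
        assert aicc(rss, n, 3) == pytest.approx(aic + 2.5)

    def test_exceeds_plain_aic(self):
        rss, n, n_params = 5.0, 30, 2
        k = n_params + 1
        aic = n * np.log(rss / n) + 2 * k
        assert aicc(rss, n, n_params) > aic

    def test_converges_to_aic_at_large_n(self):
        rss_per_n, k = 1.3, 3
        diffs = [aicc(rss_per_n * n, n, k - 1) - (n * np.log(rss_per_n) + 2 * k)
                 for n in (50, 5000)]
        assert abs(diffs[1]) < abs(diffs[0])
        assert diffs[1] < 0.01

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)


class TestStepwise:
    def test_dominant_predictor_enters_first(self):
        rng = np.random.default_rng(4)
        X = standardize_predictors(rng.normal(size=(21, 10)))
        y = 5.0 * X[:, 3] + rng.normal(0, 0.5, size=21)
        res = forward_stepwise_aicc(X, y)
        assert res.trace[0][0] == "x3"

    def test_pure_noise_selects_little(self):
        rng = np.random.default_rng(5)
        X = standardize_predictors(rng.normal(size=(21, 10)))
        y = rng.normal(size=21)
        res = forward_stepwise_aicc(X, y)
        if res.final_model is not None:
            assert res.final_model.aicc < res.null_aicc
        assert len(res.selected) <= 3


class TestVariancePartition:
    def test_orthogonal_sets_share_nothing(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a, b = a - a.mean(), b - b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        y = a + b
        X = np.column_stack([a, b])
        vp = variance_partition(X, y, {"A": ["a"], "B": ["b"]}, ["a", "b"])
        shared = vp.fractions[frozenset({"A", "B"})]
        assert shared == pytest.approx(0.0, abs=0.02)
        assert vp.fractions[frozenset({"A"})] > 0.3

    def test_overlapping_sets_rejected(self):
        X = np.random.default_rng(7).normal(size=(20, 2))
        with pytest.raises(ValueError, match="disjoint"):
            variance_partition(X, X[:, 0], {"A": ["a"], "B": ["a"]}, ["a", "b"])

    def test_fractions_recompose_total(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=25)
        ids = ["a", "b", "c"]
        vp = variance_partition(X, y, {"A": ["a"], "B": ["b"], "C": ["c"]}, ids)
        assert sum(vp.fractions.values()) == pytest.approx(
            vp.total_adjusted_r2, abs=1e-9)


class TestR2Scan:
    def test_exact_fit(self):
        x = np.arange(10.0)
        df = simple_r2_scan(x[:, None], x)
        assert df["r2"].iloc[0] == pytest.approx(1.0)

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(21, 4))
        y = rng.normal(size=21)
        df = simple_r2_scan(X, y)
        for j in range(4):
            r = np.corrcoef(X[:, j], y)[0, 1]
            assert df["r2"].iloc[j] == pytest.approx(r ** 2, abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        pvals = [simple_r2_scan(rng.normal(size=(21, 1)),
                                rng.normal(size=21))["p_value"].iloc[0]
                 for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_column_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        df = simple_r2_scan(X, np.arange(10.0))
        assert bool(df["constant"].iloc[0])
        assert np.isnan(df["r2"].iloc[0])
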