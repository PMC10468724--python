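import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fertgwas import (
    accuracy_from_ability,
    compute_grm,
    cross_validate,
    fit_gblup,
    gower_scale,
    prediction_metrics,
    simulate_genotypes,
    simulate_study,
)
from fertgwas.gblup import GBLUP, predict_fold
from fertgwas.varcomp import design_matrix, emma_reml

from oracles import metric_suite_direct, snp_blup_gebv


class TestFitGblup:
    def test_equals_snp_blup_on_raw_grm(self):
        gm = simulate_genotypes(30, 60, seed=13)
        rng = np.random.default_rng(13)
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        grm = compute_grm(gm)  # raw VanRaden so that G = M M'
        fit = fit_gblup(y, X, grm, gm, ridge=0.0)
        oracle = snp_blup_gebv(y, X, gm.dosages, delta=fit.vc.delta)
        np.testing.assert_allclose(fit.gebv, oracle, atol=1e-6)

    def test_gebv_reproduced_by_marker_effects(self, small_study):
        fit = fit_gblup(small_study["y"], small_study["X"], small_study["grm"],
                        small_study["gm"])
        from fertgwas.gblup import normalized_genotypes

        M, _, _ = normalized_genotypes(small_study["gm"])
        rel = np.linalg.norm(M @ fit.ase - fit.gebv) / np.linalg.norm(fit.gebv)
        assert rel < 1e-6

    def test_translation_invariance(self, small_study):
        y, X, grm, gm = (small_study[k] for k in ("y", "X", "grm", "gm"))
        vc = emma_reml(y, X, grm)
        a = fit_gblup(y, X, grm, gm, vc=vc)
        b = fit_gblup(y + 3.0, X, grm, gm, vc=vc)
        assert b.fixed_effects[0] - a.fixed_effects[0] == pytest.approx(3.0, abs=1e-8)
        np.testing.assert_allclose(a.gebv, b.gebv, atol=1e-10)

    def test_no_signal_shrinks_gebv(self):
        maxima = []
        for seed in range(5):
            gm = simulate_genotypes(300, 400, seed=seed + 40)
            y = np.random.default_rng(seed + 40).normal(size=300)
            grm = gower_scale(compute_grm(gm))
            fit = fit_gblup(y, np.ones((300, 1)), grm, gm)
            maxima.append(np.abs(fit.gebv).max() / y.std())
        assert np.median(maxima) <= 0.01


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.3, 0.9])
        ms = prediction_metrics(y, y)
        assert ms.pearson_r == pytest.approx(1.0)
        assert ms.rss == 0.0 and ms.rmse == 0.0 and ms.mae == 0.0
        assert ms.r_squared == pytest.approx(1.0)

    def test_mean_predictor(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=25)
        with pytest.warns(UserWarning, match="constant prediction"):
            ms = prediction_metrics(y, np.full(25, y.mean()))
        assert np.isnan(ms.pearson_r)
        assert ms.r_squared == pytest.approx(0.0, abs=1e-12)
        assert ms.rmse == pytest.approx(np.std(y))  # population sd

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        yhat = 0.6 * y + rng.normal(0, 0.5, size=40)
        ms = prediction_metrics(y, yhat)
        oracle = metric_suite_direct(y, yhat)
        for k, v in oracle.items():
            assert getattr(ms, k) == pytest.approx(v, abs=1e-12)
        assert ms.r_squared == pytest.approx(1 - ms.rss / ms.tss, abs=1e-12)
        assert ms.rmse == pytest.approx(np.sqrt(ms.rss / 40), abs=1e-12)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant y_true"):
            prediction_metrics(np.ones(5), np.arange(5.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(float, 12, elements=st.floats(-5, 5, allow_nan=False)),
        arrays(float, 12, elements=st.floats(-5, 5, allow_nan=False)),
    )
    def test_metric_identities_property(self, y, yhat):
        if np.std(y) == 0:
            return
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ms = prediction_metrics(y, yhat)
        oracle = metric_suite_direct(y, yhat)
        for key in ("rss", "tss", "rmse", "mae"):
            assert getattr(ms, key) == pytest.approx(oracle[key], abs=1e-9)
        assert ms.r_squared == pytest.approx(1 - ms.rss / ms.tss, abs=1e-12)


class TestAccuracyFromAbility:
    def test_reported_values_identity(self):
        # 0.2301 / sqrt(0.2550) must reproduce the published 0.4557
        assert round(accuracy_from_ability(0.2301, 0.2550), 4) == 0.4557

    def test_trivial_cases(self):
        assert accuracy_from_ability(0.0, 0.3) == 0.0
        assert accuracy_from_ability(0.42, 1.0) == pytest.approx(0.42)

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            accuracy_from_ability(0.2, 0.0)
        with pytest.raises(ValueError):
            accuracy_from_ability(0.2, 1.2)


class TestCrossValidate:
    def test_fold_partition_bookkeeping(self, small_study):
        cv = cross_validate(small_study["y"], small_study["X"], small_study["grm"],
                            small_study["gm"], k=3, iterations=2, seed=7)
        n = len(small_study["y"])
        per_iter = cv.folds.groupby("iteration")["n_validation"].sum()
        assert (per_iter == n).all()
        sizes = cv.folds["n_validation"]
        assert sizes.max() - sizes.min() <= 1
        assert len(cv.folds) == 6

    def test_masked_phenotypes_cannot_leak(self, small_study):
        y, X, grm = (small_study[k] for k in ("y", "X", "grm"))
        n = len(y)
        rng = np.random.default_rng(0)
        v_idx = np.sort(rng.choice(n, size=n // 3, replace=False))
        t_idx = np.setdiff1d(np.arange(n), v_idx)
        yhat1, u1, _ = predict_fold(y, X, grm, t_idx, v_idx)
        y_perturbed = y.copy()
        y_perturbed[v_idx] = rng.normal(size=len(v_idx))  # garbage in the masked slots
        yhat2, u2, _ = predict_fold(y_perturbed, X, grm, t_idx, v_idx)
        np.testing.assert_array_equal(yhat1, yhat2)
        np.testing.assert_array_equal(u1, u2)

    def test_seeded_determinism(self, small_study):
        a = cross_validate(small_study["y"], small_study["X"], small_study["grm"],
                           k=3, iterations=2, seed=3)
        b = cross_validate(small_study["y"], small_study["X"], small_study["grm"],
                           k=3, iterations=2, seed=3)
        assert a.folds.equals(b.folds)
        assert a.predictive_ability_mean == b.predictive_ability_mean

    def test_accuracy_uses_whole_data_h2(self, small_study):
        cv = cross_validate(small_study["y"], small_study["X"], small_study["grm"],
                            k=3, iterations=2, seed=5)
        assert cv.prediction_accuracy_mean == pytest.approx(
            cv.predictive_ability_mean / np.sqrt(cv.h2_whole_data), rel=1e-12
        )

    def test_ability_positive_and_stable_across_seeds(self):
        gm = simulate_genotypes(600, 1500, seed=77)
        phen, _ = simulate_study(gm, n_qtl=0, h2_target=0.25, seed=77)
        grm = gower_scale(compute_grm(gm))
        y = phen["ri"].to_numpy()
        X = np.ones((600, 1))
        a = cross_validate(y, X, grm, k=3, iterations=3, seed=1)
        b = cross_validate(y, X, grm, k=3, iterations=3, seed=2)
        assert a.predictive_ability_mean > 0
        # two independent CV estimates of the same quantity agree
        assert abs(a.predictive_ability_mean - b.predictive_ability_mean) < 0.08
        # ability cannot exceed the square root of heritability by much
        assert a.predictive_ability_mean < np.sqrt(a.h2_whole_data) + 0.08

    def test_covariates_lift_phenotype_prediction(self):
        gm = simulate_genotypes(360, 600, seed=55)
        phen, _ = simulate_study(gm, n_qtl=0, h2_target=0.3, n_farms=4, n_seasons=2,
                                 covariate_sd=1.0, seed=55)
        grm = gower_scale(compute_grm(gm))
        y = phen["ri"].to_numpy()
        X0 = np.ones((360, 1))
        X1 = design_matrix(phen)
        plain = cross_validate(y, X0, grm, k=3, iterations=2, seed=9)
        adjusted = cross_validate(y, X1, grm, k=3, iterations=2, seed=9)
        assert adjusted.means["pearson_r"] > plain.means["pearson_r"]

    def test_small_fold_and_k_guards(self, small_study):
        with pytest.raises(ValueError):
            cross_validate(small_study["y"][:5], small_study["X"][:5],
                           small_study["grm"].subset(range(5)), k=1)
        with pytest.raises(ValueError):
            cross_validate(small_study["y"][:6], small_study["X"][:6],
                           small_study["grm"].subset(range(6)), k=4)


def test_sklearn_gblup_estimator(small_study):
    from sklearn.base import clone

    est = GBLUP(grm_scaling="gower")
    est = clone(est).fit(small_study["gm"].dosages, small_study["y"])
    assert est.gebv_.shape == (250,)
    assert est.ase_.shape == (500,)
    assert 0 <= est.h2_ <= 1
    # in-sample prediction = intercept + M ase ~ intercept + gebv
    pred = est.predict(small_study["gm"].dosages)
    np.testing.assert_allclose(pred, est.beta_[0] + est.gebv_, atol=1e-5)
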