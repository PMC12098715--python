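"""Elastic-net fitting, alpha tuning, nested CV schemes and prediction."""

import numpy as np
import pandas as pd
import pytest

from frogclock.clock import (
    ClockModel,
    alpha_grid,
    fit_elastic_net,
    loo_cv,
    loto_cv,
    medae,
    pearson_r,
    predict,
    shuffled_loto_cv,
    train_final,
    tune_alpha,
)
from frogclock.io_formats import MethylationMatrix


def _matrix(rows: np.ndarray, site_ids=None) -> MethylationMatrix:
    n_sites, n_samples = rows.shape
    beta = pd.DataFrame(
        np.clip(rows, 0, 1),
        index=pd.Index(
            site_ids if site_ids is not None else [f"s{i}" for i in range(n_sites)],
            name="site_id",
        ),
        columns=[f"F{i}" for i in range(n_samples)],
    )
    return MethylationMatrix(
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(n_sites),
        beta=beta,
    )


def _samples(ages, tanks=None):
    n = len(ages)
    return pd.DataFrame(
        {
            "sample_id": [f"F{i}" for i in range(n)],
            "age_years": ages,
            "strain": "S00",
            "tank_id": tanks if tanks is not None else [f"T{i}" for i in range(n)],
            "life_stage": "adult",
        }
    )


def _signal_cohort(rng, n=40, p=60, n_informative=10, tanks_of=4):
    ages = np.repeat(rng.uniform(1, 10, n // tanks_of), tanks_of)
    X = rng.uniform(0.2, 0.8, size=(p, n))
    X[:n_informative] = np.clip(
        0.3 + 0.05 * ages + rng.normal(0, 0.02, size=(n_informative, n)), 0, 1
    )
    tanks = [f"T{i // tanks_of}" for i in range(n)]
    return _matrix(X), _samples(ages, tanks)


class TestFitElasticNet:
    def test_huge_alpha_gives_null_model(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(30, 10))
        y = rng.uniform(1, 10, 30)
        coef, intercept = fit_elastic_net(X, y, alpha=1e6)
        assert np.all(coef == 0)
        assert intercept == pytest.approx(y.mean())

    def test_tiny_alpha_recovers_ols(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=50)
        y = 2 * x + 1
        coef, intercept = fit_elastic_net(x[:, None], y, alpha=1e-8)
        assert coef[0] == pytest.approx(2.0, abs=1e-2)
        assert intercept == pytest.approx(1.0, abs=1e-2)

    def test_duplicate_columns_share_weight(self):
        # grouping effect of the quadratic penalty: identical columns take
        # identical weight at the optimum (rho < 1)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=60)
        X = np.column_stack([x, x])
        y = 3 * x + rng.normal(0, 0.01, 60)
        coef, _ = fit_elastic_net(X, y, alpha=0.01, l1_ratio=0.5, tol=1e-12,
                                  max_iter=100_000)
        assert abs(coef[0] - coef[1]) < 1e-6

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.array([1.0, 2.0]), alpha=0.1)


class TestTuneAlpha:
    def test_one_point_grid_returned(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(20, 5))
        y = rng.uniform(size=20)
        folds = [(np.arange(10), np.arange(10, 20))]
        assert tune_alpha(X, y, folds, alphas=[0.37]) == 0.37

    def test_empty_training_fold_rejected(self):
        X = np.zeros((4, 2))
        y = np.zeros(4)
        with pytest.raises(ValueError):
            tune_alpha(X, y, [(np.array([], dtype=int), np.arange(4))])

    def test_noise_selects_strong_penalty(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(40, 50))
            y = rng.normal(size=40)
            grid = alpha_grid(X, y)
            folds = [
                (np.setdiff1d(np.arange(40), te), te)
                for te in np.array_split(np.arange(40), 5)
            ]
            a = tune_alpha(X, y, folds, alphas=grid)
            if a >= grid[len(grid) // 10]:  # grid is descending: large decile
                hits += 1
        assert hits >= 4

    def test_strong_signal_selects_weak_penalty(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 5))
            y = X @ np.array([3.0, -2.0, 1.0, 0.5, 2.0]) + rng.normal(0, 0.01, 200)
            grid = alpha_grid(X, y)
            folds = [
                (np.setdiff1d(np.arange(200), te), te)
                for te in np.array_split(np.arange(200), 5)
            ]
            a = tune_alpha(X, y, folds, alphas=grid)
            if a <= grid[-len(grid) // 10]:  # smallest decile
                hits += 1
        assert hits >= 4


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert medae(y, y) == 0.0
        assert pearson_r(y, y) == pytest.approx(1.0)

    def test_medae_order_statistics(self):
        actual = np.zeros(3)
        pred = np.array([-1.0, 0.5, 2.0])
        assert medae(pred, actual) == 1.0

    def test_medae_even_n_midpoint(self):
        assert medae(np.array([0.0, 0.0]), np.array([1.0, 2.0])) == 1.5

    def test_anticorrelated(self):
        assert pearson_r(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == pytest.approx(-1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            medae(np.zeros(2), np.zeros(3))


class TestNestedCV:
    def test_loo_emits_one_prediction_per_sample(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.uniform(size=(5, 3)))
        s = _samples([1.0, 2.0, 3.0])
        res = loo_cv(m, s, seed=0)
        assert len(res.predictions) == 3
        assert res.predictions.index.is_unique

    def test_constant_target_predicted_exactly(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.uniform(size=(8, 6)))
        s = _samples([4.0] * 6)
        res = loo_cv(m, s, seed=0)
        assert res.medae == pytest.approx(0.0, abs=1e-8)

    def test_loo_recovers_planted_signal(self):
        rng = np.random.default_rng(6)
        m, s = _signal_cohort(rng)
        res = loo_cv(m, s, seed=0)
        assert res.pearson_r > 0.9

    def test_single_tank_loto_rejected(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.uniform(size=(5, 4)))
        s = _samples([1, 2, 3, 4], tanks=["T0"] * 4)
        with pytest.raises(ValueError, match="tank"):
            loto_cv(m, s)

    def test_two_tank_boundary_runs(self):
        rng = np.random.default_rng(8)
        m, s = _signal_cohort(rng, n=12, p=20, tanks_of=6)
        res = loto_cv(m, s, seed=0)
        assert len(res.predictions) == 12
        assert set(res.predictions["fold_id"]) == {"0", "1"}

    def test_singleton_tanks_reduce_to_loo_structure(self):
        rng = np.random.default_rng(9)
        m, s = _signal_cohort(rng, n=8, p=10, tanks_of=1)
        res = loto_cv(m, s, seed=0)
        assert len(res.predictions) == 8
        assert res.predictions["fold_id"].nunique() == 8

    def test_shuffled_returns_requested_repeats_deterministically(self):
        rng = np.random.default_rng(10)
        m, s = _signal_cohort(rng, n=16, p=20, tanks_of=4)
        r1 = shuffled_loto_cv(m, s, n_repeats=3, seed=5)
        r2 = shuffled_loto_cv(m, s, n_repeats=3, seed=5)
        assert len(r1) == 3
        for a, b in zip(r1, r2):
            pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_fit_and_predict_invariant_to_site_order(self):
        rng = np.random.default_rng(11)
        m, s = _signal_cohort(rng, n=12, p=15, tanks_of=3)
        y = s["age_years"].to_numpy()
        coef, b = fit_elastic_net(
            m.beta.to_numpy().T, y, alpha=0.01, tol=1e-12, max_iter=100_000
        )
        perm = rng.permutation(m.n_sites)
        m2 = m.subset_sites(perm)
        coef2, b2 = fit_elastic_net(
            m2.beta.to_numpy().T, y, alpha=0.01, tol=1e-12, max_iter=100_000
        )
        np.testing.assert_allclose(coef[perm], coef2, atol=1e-8)
        assert b == pytest.approx(b2, abs=1e-8)
        model = ClockModel(
            site_ids=list(m.site_ids), coefficients=coef, intercept=b, alpha=0.01
        )
        # predict() looks sites up by id, so site order in the matrix is moot
        np.testing.assert_allclose(predict(model, m), predict(model, m2), atol=0)

    def test_constant_feature_never_changes_predictions(self):
        rng = np.random.default_rng(12)
        m, s = _signal_cohort(rng, n=12, p=15, tanks_of=3)
        rows = np.vstack([m.beta.to_numpy(), np.full((1, 12), 0.5)])
        m2 = _matrix(rows)
        res = loo_cv(m, s, seed=0)
        res2 = loo_cv(m2, s, seed=0)
        np.testing.assert_allclose(
            res.predictions["predicted_age"], res2.predictions["predicted_age"],
            atol=1e-8,
        )

    def test_log_clock_backtransforms_to_years(self):
        rng = np.random.default_rng(13)
        m, s = _signal_cohort(rng)
        res = loo_cv(m, s, log_age=True, seed=0)
        assert res.log_age
        # predictions are on the year scale (positive, in a sane range)
        assert (res.predictions["predicted_age"] > 0).all()
        assert res.pearson_r > 0.8


class TestFinalModelAndPredict:
    def test_strong_single_feature_retained_with_sign(self):
        rng = np.random.default_rng(14)
        ages = np.repeat(rng.uniform(1, 10, 10), 2)
        X = rng.uniform(0.4, 0.6, size=(10, 20))
        X[0] = np.clip(0.05 * ages + rng.normal(0, 0.005, 20), 0, 1)
        m = _matrix(X)
        s = _samples(ages, tanks=[f"T{i // 2}" for i in range(20)])
        model = train_final(m, s, seed=0)
        assert "s0" in model.site_ids
        assert model.coefficients[model.site_ids.index("s0")] > 0

    def test_null_model_predicts_intercept(self):
        model = ClockModel(
            site_ids=[], coefficients=np.array([]), intercept=5.0, alpha=1.0
        )
        rng = np.random.default_rng(15)
        m = _matrix(rng.uniform(size=(3, 4)))
        np.testing.assert_allclose(predict(model, m), 5.0)

    def test_missing_model_sites_error(self):
        model = ClockModel(
            site_ids=["absent"], coefficients=np.array([1.0]), intercept=0.0, alpha=1.0
        )
        rng = np.random.default_rng(16)
        m = _matrix(rng.uniform(size=(3, 4)))
        with pytest.raises(ValueError, match="absent"):
            predict(model, m)

    def test_near_interpolating_fit_predicts_training(self):
        rng = np.random.default_rng(17)
        ages = rng.uniform(1, 10, 30)
        X = np.clip(0.05 * ages + rng.normal(0, 0.002, (5, 30)), 0, 1)
        m = _matrix(X)
        coef, intercept = fit_elastic_net(m.beta.to_numpy().T, ages, alpha=1e-8)
        model = ClockModel(
            site_ids=[f"s{i}" for i in np.flatnonzero(coef)],
            coefficients=coef[coef != 0],
            intercept=intercept,
            alpha=1e-8,
        )
        pred = predict(model, m)
        assert medae(pred.to_numpy(), ages) < 0.2

    def test_model_json_round_trip(self, tmp_path):
        model = ClockModel(
            site_ids=["a", "b"], coefficients=np.array([1.5, -2.0]),
            intercept=0.3, alpha=0.01, log_age=True,
            training_site_universe=["a", "b", "c"],
        )
        p = tmp_path / "clock.json"
        model.to_json(p)
        back = ClockModel.from_json(p)
        assert back.site_ids == model.site_ids
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.log_age and back.intercept == 0.3
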