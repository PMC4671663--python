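"""PLS2, cross-validated R², and the three-model mediation comparison."""

import numpy as np
import pandas as pd
import pytest

from soundhue.pls import (PLS2, ModelSpec, adjusted_r2, compare_models,
                          cv_r2, default_model_specs, fit_pls2, noise_floor,
                          _cv_once)
from soundhue.simulate import (DIMENSIONAL_SCALES, DISCRETE_SCALES,
                               FEATURE_NAMES)


def rank2_problem(rng, n=30, p=10, q=4, noise=0.0):
    # X carries exactly two latent directions; Y lives on the same pair,
    # so a two-component projection can represent it exactly
    T = rng.normal(size=(n, 2))
    P = rng.normal(size=(2, p))
    Q = rng.normal(size=(2, q))
    X = T @ P + noise * rng.normal(size=(n, p))
    Y = T @ Q + noise * rng.normal(size=(n, q))
    return X, Y


class TestPLS2Fit:
    def test_noiseless_rank2_train_r2_is_one(self, rng):
        X, Y = rank2_problem(rng)
        model = fit_pls2(X, Y)
        assert np.all(model.score_r2(X, Y) > 1 - 1e-8)

    def test_row_permutation_invariance(self, rng):
        X, Y = rank2_problem(rng, noise=0.5)
        perm = rng.permutation(len(X))
        a = fit_pls2(X, Y)
        b = fit_pls2(X[perm], Y[perm])
        assert np.allclose(a.coef_, b.coef_, atol=1e-10)

    def test_two_orthonormal_predictors_match_ols(self, rng):
        # with p = n_components = 2 the PLS span equals the full X space
        X = np.linalg.qr(rng.normal(size=(40, 2)))[0]
        Y = rng.normal(size=(40, 3))
        model = fit_pls2(X, Y)
        ones = np.ones((len(X), 1))
        beta, *_ = np.linalg.lstsq(np.hstack([ones, X]), Y, rcond=None)
        yhat_ols = np.hstack([ones, X]) @ beta
        assert np.allclose(model.predict(X), yhat_ols, atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(3):
            X = rng.normal(size=(27, 10))
            Y = rng.normal(size=(27, 4))
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
            ref = skpls.PLSRegression(2, scale=False, tol=1e-10,
                                      max_iter=5000).fit(Xs, Ys)
            mine = fit_pls2(X, Y)
            # the reference NIPALS is a power iteration converging only
            # linearly to the SVD fixed point used here
            assert np.allclose(mine.predict(X),
                               ref.predict(Xs) * Y.std(0, ddof=1) + Y.mean(0),
                               atol=2e-3)

    def test_constant_column_dropped_with_warning(self, rng):
        X, Y = rank2_problem(rng)
        X[:, 3] = 7.0
        with pytest.warns(UserWarning):
            model = fit_pls2(X, Y)
        assert np.isfinite(model.predict(X)).all()

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls2(rng.normal(size=(2, 5)), rng.normal(size=(2, 4)))


class TestCvR2:
    def test_noiseless_representable_is_one(self, rng):
        X, Y = rank2_problem(rng, n=27)
        med, _ = cv_r2(X, Y, n_reps=20, seed=0)
        assert np.all(med > 1 - 1e-6)

    def test_matches_naive_fold_loop(self, rng):
        # independent leave-three-out loop over a fixed fold assignment
        X, Y = rank2_problem(rng, n=27, noise=1.0)
        perm = rng.permutation(27)
        got = _cv_once(X, Y, 2, 9, rng, perm=perm)
        Yhat = np.empty_like(Y)
        for f in range(9):
            test = perm[f * 3:(f + 1) * 3]
            train = np.array([i for i in perm if i not in test])
            m = PLS2(2).fit(X[train], Y[train])
            Yhat[test] = m.predict(X[test])
        expect = 1 - ((Y - Yhat) ** 2).sum(0) / ((Y - Y.mean(0)) ** 2).sum(0)
        assert np.abs(got - expect).max() < 1e-10

    def test_chance_level_is_low(self, rng):
        # independent X and Y: chance-level predictive R^2 across datasets
        meds = []
        for seed in range(8):
            X = rng.normal(size=(27, 19))
            Y = rng.normal(size=(27, 4))
            med, _ = cv_r2(X, Y, n_reps=50, seed=seed)
            meds.append(med)
        meds = np.array(meds)
        assert np.median(meds) <= 0.1   # typical chance level
        assert meds.max() <= 0.35       # no dataset looks predictable

    def test_deterministic_and_stable_in_reps(self, rng):
        X, Y = rank2_problem(rng, n=27, noise=2.0)
        m1, _ = cv_r2(X, Y, n_reps=150, seed=9)
        m2, _ = cv_r2(X, Y, n_reps=150, seed=9)
        assert np.array_equal(m1, m2)
        m3, _ = cv_r2(X, Y, n_reps=300, seed=9)
        assert np.abs(m1 - m3).max() < 0.05  # Monte-Carlo stability


class TestAdjustedR2:
    def test_examples(self):
        assert adjusted_r2(1.0, 27, 2) == 1.0
        assert adjusted_r2(0.0, 27, 2) == pytest.approx(-2 / 24)
        assert adjusted_r2(0.5, 27, 2) < 0.5

    def test_df_validation(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 10, 9)


def synthetic_study(mediation, seed, n_reps=60, n_sim=40, grid=None):
    from soundhue.colour import build_hybrid_grid
    from soundhue.processing import aggregate_by_stimulus, process_envelopes
    from soundhue.simulate import GeneratorConfig, generate_dataset

    grid = grid or build_hybrid_grid(10.0)
    cfg = GeneratorConfig(n_stimuli=27, n_participants=22,
                          mediation_strength=mediation, seed=seed)
    data = generate_dataset(cfg)
    patches = process_envelopes(data["envelopes"], grid)
    pm = aggregate_by_stimulus(patches)
    return compare_models(data["stimuli"], pm, grid, n_reps=n_reps,
                          n_boot=400, n_sim=n_sim, seed=seed)


class TestCompareModels:
    def test_nesting_on_representable_data(self, rng):
        # responses generated from the audio features alone: every pool
        # that contains them reaches training R^2 = 1
        n = 27
        cols = list(FEATURE_NAMES) + list(DIMENSIONAL_SCALES) + list(DISCRETE_SCALES)
        T = rng.normal(size=(n, 2))
        st = pd.DataFrame(T @ rng.normal(size=(2, len(cols))), columns=cols)
        Y = T @ rng.normal(size=(2, 4))
        r2s = []
        for spec in default_model_specs():
            X = st[list(spec.predictors)].to_numpy()
            r2s.append(fit_pls2(X, Y).score_r2(X, Y).min())
        assert r2s[1] >= r2s[0] - 1e-9 and r2s[2] >= r2s[0] - 1e-9

    def test_table_shape_and_verdicts(self, coarse_grid):
        cmp_ = synthetic_study(mediation=0.9, seed=4, grid=coarse_grid)
        assert len(cmp_.table) == 12
        assert set(cmp_.table["model"]) == {"Model1", "Model2", "Model3"}
        assert len(cmp_.noise) == 4
        assert (cmp_.table["ci_lo"] <= cmp_.table["adj_r2cv"]).all()
        assert (cmp_.table["adj_r2cv"] <= cmp_.table["ci_hi"]).all()

    def test_missing_rating_columns_named(self, coarse_grid, rng):
        st = pd.DataFrame(rng.normal(size=(27, 19)), columns=list(FEATURE_NAMES))
        st.insert(0, "id", [f"S{i:03d}" for i in range(27)])
        pm = pd.DataFrame({"stimulus": st["id"],
                           "size": rng.uniform(0, 1, 27), "L": rng.uniform(0, 100, 27),
                           "a": rng.normal(size=27), "b": rng.normal(size=27)})
        with pytest.raises(ValueError, match="Valence"):
            compare_models(st, pm, coarse_grid, n_reps=5, n_sim=3, n_boot=10)


class TestNoiseFloor:
    def test_shape_and_relabelling_invariance(self, coarse_grid, rng):
        X = rng.normal(size=(27, 10))
        a = noise_floor(X, coarse_grid, n_sim=30, seed=11, n_boot=200)
        b = noise_floor(X[:, ::-1], coarse_grid, n_sim=30, seed=11, n_boot=200)
        assert np.allclose(a["r2_median"], b["r2_median"])
        assert (a["ci_lo"] <= a["r2_median"]).all()
        assert (a["r2_median"] <= a["ci_hi"]).all()

    def test_ci_narrows_with_more_simulations(self, coarse_grid, rng):
        X = rng.normal(size=(27, 10))
        small = noise_floor(X, coarse_grid, n_sim=30, seed=2, n_boot=300)
        big = noise_floor(X, coarse_grid, n_sim=240, seed=2, n_boot=300)
        assert (big["ci_hi"] - big["ci_lo"]).mean() < \
            (small["ci_hi"] - small["ci_lo"]).mean()
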