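"""Cross-validated prediction, dropout importance, CCA and PCA."""

import numpy as np
import pandas as pd
import pytest

from epimorph import (SquaredExponentialRegressor, cca_predict,
                      dropout_importance, pca_biplot_data, predict)
from epimorph.multivar import DAPI_EXCLUDED_PREDICTORS, resolve_predictors


def _frame(seed=0, n=500, n_noise=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "f1": rng.normal(size=n),
        "f2": rng.normal(size=n),
        "f3": rng.normal(size=n),
    })
    for i in range(n_noise):
        df[f"noise{i}"] = rng.normal(size=n)
    return df, rng


class TestPredict:
    def test_noiseless_linear_target_recovered_exactly(self):
        df, _ = _frame(seed=1)
        df["y"] = 3 * df.f1 - df.f2
        res = predict(df, "y", ["f1", "f2", "f3"], model_kind="linear")
        assert res.prediction_r >= 0.999

    def test_single_predictor_matches_direct_pearson(self):
        """Linear CV prediction from one feature reproduces the plain
        correlation between the feature and the target."""
        rng = np.random.default_rng(2)
        cell = rng.lognormal(5.5, 0.3, 800)
        nuc = 0.3 * cell * np.exp(rng.normal(0, 0.2, 800))
        df = pd.DataFrame({"cell_area": cell, "nucleus_area": nuc})
        res = predict(df, "nucleus_area", ["cell_area"])
        direct = np.corrcoef(cell, nuc)[0, 1]
        assert res.prediction_r == pytest.approx(direct, abs=0.05)

    def test_kernel_model_beats_linear_on_nonlinear_signal(self):
        df, rng = _frame(seed=3, n=500)
        df["y"] = np.sin(2 * np.pi * df.f1) + 0.1 * rng.normal(size=500)
        lin = predict(df, "y", ["f1"], model_kind="linear", seed=0)
        ker = predict(df, "y", ["f1"], model_kind="se_kernel", seed=0)
        assert ker.prediction_r - lin.prediction_r >= 0.2

    def test_out_of_fold_predictions_and_seeded_determinism(self):
        df, rng = _frame(seed=4)
        df["y"] = df.f1 + rng.normal(size=len(df))
        a = predict(df, "y", ["f1", "f2"], seed=5)
        b = predict(df, "y", ["f1", "f2"], seed=5)
        assert np.array_equal(a.y_pred, b.y_pred)
        assert a.prediction_r == b.prediction_r

    def test_noise_predictors_do_not_inflate_cv_accuracy(self):
        df, rng = _frame(seed=6, n=600, n_noise=6)
        df["y"] = df.f1 + 0.5 * rng.normal(size=600)
        base = predict(df, "y", ["f1"])
        noisy = predict(df, "y", ["f1"] + [f"noise{i}" for i in range(6)])
        assert abs(noisy.prediction_r - base.prediction_r) < 0.05

    def test_dapi_predictors_excluded_for_histone_targets(self):
        df, rng = _frame(seed=7, n=200)
        for c in DAPI_EXCLUDED_PREDICTORS:
            df[c] = rng.normal(size=200)
        df["H3K27me3_norm"] = df.f1 + 0.2 * rng.normal(size=200)
        preds = ["f1", "f2", *DAPI_EXCLUDED_PREDICTORS]
        kept = resolve_predictors(df, "H3K27me3_norm", preds)
        assert set(kept) == {"f1", "f2"}
        res = predict(df, "H3K27me3_norm", preds)
        assert set(res.predictors) == {"f1", "f2"}

    def test_constant_target_and_small_n_rejected(self):
        df, _ = _frame(seed=8, n=100)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            predict(df, "y", ["f1"])
        df2, _ = _frame(seed=9, n=20)
        df2["y"] = df2.f1
        with pytest.raises(ValueError):
            predict(df2, "y", ["f1"])


class TestDropoutImportance:
    def test_informative_predictor_ranks_first_across_seeds(self):
        """One real predictor among noise: dropout puts it at rank 1 in at
        least 95% of seeded repeats."""
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame({"signal": rng.normal(size=200)})
            for i in range(5):
                df[f"noise{i}"] = rng.normal(size=200)
            df["y"] = df.signal + 0.5 * rng.normal(size=200)
            imp = dropout_importance(df, "y",
                                     ["signal"] + [f"noise{i}" for i in range(5)],
                                     seed=seed)
            if imp.table.feature.iloc[0] == "signal":
                wins += 1
        assert wins / n_rep >= 0.95

    def test_duplicated_predictor_has_no_dropout_cost(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=400)})
        df["b"] = df.a.to_numpy().copy()
        df["c"] = rng.normal(size=400)
        df["y"] = df.a + 0.3 * rng.normal(size=400)
        imp = dropout_importance(df, "y", ["a", "b", "c"], seed=0)
        tab = imp.table.set_index("feature")
        assert abs(tab.loc["a", "delta_r"]) < 0.05
        assert abs(tab.loc["b", "delta_r"]) < 0.05

    def test_all_noise_predictors_have_null_importance(self):
        rng = np.random.default_rng(12)
        n = 2000  # large n keeps CV sampling noise well under the 0.05 band
        df = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(4)})
        df["y"] = rng.normal(size=n)
        imp = dropout_importance(df, "y", [f"n{i}" for i in range(4)], seed=0)
        assert np.all(np.abs(imp.table.delta_r) < 0.05)
        # ranks are a permutation of 1..n
        assert sorted(imp.table["rank"]) == [1, 2, 3, 4]


class TestCCA:
    def test_identical_blocks_have_unit_first_correlation(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        res = cca_predict(X, X.copy())
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(1000, 3)))
        Y = pd.DataFrame(rng.normal(size=(1000, 3)))
        res = cca_predict(X, Y)
        assert res.correlations[0] < 0.15

    def test_shared_latent_factor_recovered(self):
        """One latent factor with loadings a, b on the two blocks: the first
        canonical correlation approaches corr(u'X, v'Y) of the generative
        model, computed in closed form."""
        rng = np.random.default_rng(15)
        n = 4000
        z = rng.normal(size=n)
        sx, sy = 0.6, 0.8
        X = np.column_stack([z + sx * rng.normal(size=n) for _ in range(3)])
        Y = np.column_stack([z + sy * rng.normal(size=n) for _ in range(3)])
        res = cca_predict(pd.DataFrame(X), pd.DataFrame(Y))
        # best linear combos are the block means; their correlation:
        def block_r(s, p=3):
            return np.sqrt(1.0 / (1.0 + s ** 2 / p))
        expected = block_r(sx) * block_r(sy)
        assert res.correlations[0] == pytest.approx(expected, abs=0.05)

    def test_agrees_with_sklearn_cca(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(16)
        z = rng.normal(size=600)
        X = np.column_stack([z, rng.normal(size=600), rng.normal(size=600)])
        Y = np.column_stack([0.7 * z, rng.normal(size=600),
                             rng.normal(size=600)])
        res = cca_predict(pd.DataFrame(X), pd.DataFrame(Y))
        sk = SkCCA(n_components=1).fit(X, Y)
        u, v = sk.transform(X, Y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert res.correlations[0] == pytest.approx(r_sk, abs=0.01)

    def test_shape_errors(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            cca_predict(X, pd.DataFrame(rng.normal(size=(10, 12))))


class TestPCA:
    def test_perfectly_correlated_features_load_on_one_component(self):
        rng = np.random.default_rng(18)
        a = rng.normal(size=300)
        df = pd.DataFrame({"a": a, "b": 2 * a + 5})
        res = pca_biplot_data(df)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        res = pca_biplot_data(df)
        assert np.allclose(res.variance_fractions, 1 / 3, atol=0.03)

    def test_variance_fractions_sum_to_one_and_constant_dropped(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({"a": rng.normal(size=200),
                           "b": rng.normal(size=200),
                           "c": np.ones(200)})
        with pytest.warns(UserWarning):
            res = pca_biplot_data(df)
        assert res.dropped == ["c"]
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)


class TestEstimatorContract:
    def test_se_kernel_regressor_is_sklearn_compatible(self):
        from sklearn.base import clone
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(21)
        X = rng.normal(size=(200, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=200)
        est = SquaredExponentialRegressor()
        assert clone(est).get_params()["inner_folds"] == 3
        scores = cross_val_score(est, X, y, cv=3)
        assert scores.mean() > 0.5
        est.fit(X, y)
        assert hasattr(est, "length_scale_") and hasattr(est, "alpha_")
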