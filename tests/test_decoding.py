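"""TR-wise decoders: OLS, Elastic Net, lagged designs, the combined model."""

import numpy as np
import pytest

from paindyn import (
    BoldSpec,
    FitConfig,
    SplitSpec,
    build_lagged_design,
    evaluate_decoders,
    fit_combined,
    fit_en,
    fit_ols,
    make_decoding_dataset,
)
from paindyn.decoding import EmptyDesignError, lagged_columns, predict
from paindyn.fitting import pearson_r


@pytest.fixture(scope="module")
def small_dataset():
    return make_decoding_dataset(seed=1, bold_spec=BoldSpec(n_voxels=60, seed=3))


class TestOls:
    def test_identity_design_returns_targets(self):
        y = np.array([3.0, -1.0, 2.0, 0.5])
        dec = fit_ols(np.eye(4), y)
        np.testing.assert_allclose(dec.coef, y)

    def test_exact_linear_model_has_zero_residual(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        dec = fit_ols(X, X @ beta)
        np.testing.assert_allclose(dec.predict(X), X @ beta, atol=1e-10)

    def test_duplicated_column_gets_minimum_norm_split(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        X = np.column_stack([x, x])
        dec = fit_ols(X, 2.0 * x)
        # pseudo-inverse oracle: weight splits equally
        oracle = np.linalg.pinv(X) @ (2.0 * x)
        np.testing.assert_allclose(dec.coef, oracle, atol=1e-10)
        assert dec.coef[0] == pytest.approx(dec.coef[1])

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            fit_ols(np.zeros((0, 0)), np.zeros(0))


class TestElasticNet:
    def test_unregularized_full_limit_matches_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 6))
        X -= X.mean(axis=0)
        y = X @ np.array([1.0, 0.5, -1.0, 2.0, 0.0, -0.5]) + 0.01 * rng.normal(size=80)
        y -= y.mean()
        en = fit_en(X, y, lambda2=0.0, n_select=6)
        ols = fit_ols(X, y)
        np.testing.assert_allclose(en.coef, ols.coef, atol=1e-6)

    def test_selects_strong_predictor_first(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=100)
        strong = z + 0.05 * rng.normal(size=100)
        weak = 0.3 * z + rng.normal(size=100)
        X = np.column_stack([weak, strong])
        en = fit_en(X, z, lambda2=1.0, n_select=1)
        assert en.coef[1] != 0.0 and en.coef[0] == 0.0

    def test_grouping_effect_on_identical_columns(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=120)
        X = np.column_stack([z, z, rng.normal(size=120)])
        en = fit_en(X, z + 0.1 * rng.normal(size=120), lambda2=50.0, n_select=3)
        w1, w2 = en.coef[0], en.coef[1]
        assert abs(w1 - w2) / abs(w1 + w2) < 0.1

    def test_active_set_never_exceeds_n_select(self, small_dataset):
        ds = small_dataset
        for n_sel in (1, 5, 20):
            en = fit_en(ds.X[:120], ds.y_pain[:120], lambda2=1.0, n_select=n_sel)
            assert np.count_nonzero(en.coef) <= n_sel

    def test_training_sse_non_increasing_in_n_select(self, small_dataset):
        ds = small_dataset
        X, y = ds.X[:120], ds.y_pain[:120]
        sses = []
        for n_sel in (2, 5, 10, 25, 50):
            en = fit_en(X, y, lambda2=1.0, n_select=n_sel)
            sses.append(np.sum((en.predict(X) - y) ** 2))
        assert np.all(np.diff(sses) <= 1e-6)

    def test_invalid_arguments_rejected(self, small_dataset):
        X, y = small_dataset.X[:50], small_dataset.y_pain[:50]
        with pytest.raises(ValueError):
            fit_en(X, y, n_select=0)
        with pytest.raises(ValueError):
            fit_en(X, y, n_select=X.shape[1] + 1)


class TestLaggedDesign:
    def test_keep_all_cardinality(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10))
        D, lag_map = build_lagged_design(X, rng.normal(size=60), max_lag=7,
                                         screen_r=-1.0)
        assert D.shape == (53, 80)
        assert len(lag_map) == 80

    def test_shifted_target_found_at_its_lag(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        y = np.roll(X[:, 2], 3)  # y(t) = voxel2(t-3)
        D, lag_map = build_lagged_design(X, y, max_lag=7, screen_r=0.95)
        assert (2, 3) in lag_map
        j = lag_map.index((2, 3))
        assert abs(np.corrcoef(D[:, j], y[7:])[0, 1]) == pytest.approx(1.0)

    def test_impossible_screen_threshold_errors(self):
        rng = np.random.default_rng(7)
        with pytest.raises(EmptyDesignError):
            build_lagged_design(rng.normal(size=(40, 5)), rng.normal(size=40),
                                screen_r=1.0)

    def test_lagged_columns_align_with_design(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        D, lag_map = build_lagged_design(X, rng.normal(size=30), screen_r=-1.0,
                                         max_lag=2)
        np.testing.assert_array_equal(lagged_columns(X, lag_map, 2), D)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds = small_dataset
    return ds, fit_combined(ds.X[:120], ds.y_pain[:120], ds.y_temp[:120],
                            en_cfg={"lambda2": 1.0, "n_select": 10},
                            fit_cfg=FitConfig(n_draws=1000, seed=0))


class TestCombined:
    def test_en_only_mix_reproduces_direct_pathway(self, fitted):
        ds, comb = fitted
        comb_mix = comb.mix.copy()
        comb.mix = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(comb.predict(ds.X[120:]),
                                   comb.en_pain.predict(ds.X[120:]))
        comb.mix = comb_mix

    def test_ls_mix_training_sse_bounded_by_pathways(self, small_dataset):
        ds = small_dataset
        comb = fit_combined(ds.X[:120], ds.y_pain[:120], ds.y_temp[:120],
                            en_cfg={"lambda2": 1.0, "n_select": 10},
                            fit_cfg=FitConfig(n_draws=500, seed=0),
                            validate_mix=False)
        p_en, p_an = comb.pathway_predictions(ds.X[:120])
        y = ds.y_pain[:120]
        sse_mix = np.sum((comb.predict(ds.X[:120]) - y) ** 2)
        assert sse_mix <= np.sum((p_en - y) ** 2) + 1e-6
        assert sse_mix <= np.sum((p_an - y) ** 2) + 1e-6

    def test_prediction_is_deterministic(self, fitted):
        ds, comb = fitted
        a = comb.predict(ds.X[120:])
        b = comb.predict(ds.X[120:])
        np.testing.assert_array_equal(a, b)


class TestEvaluationProtocol:
    def test_default_split_is_120_120(self):
        ds = make_decoding_dataset(seed=2, bold_spec=BoldSpec(n_voxels=40, seed=1))
        assert ds.n_tr == 240
        table = evaluate_decoders(
            ds, cfgs={"en": {"n_select": 10},
                      "combined": {"fit_cfg": FitConfig(n_draws=500, seed=0)}})
        assert list(table.index) == ["ols", "en", "enlags", "combined"]
        assert np.all(np.abs(table["test_r"]) <= 1.0)

    def test_noise_free_informative_voxel_recovered_by_all_models(self):
        base = make_decoding_dataset(seed=3, bold_spec=BoldSpec(n_voxels=10, seed=2))
        from paindyn import DecodingDataset
        rng = np.random.default_rng(0)
        X = np.column_stack([0.5 * base.y_pain,
                             rng.normal(size=(base.n_tr, 2)) * 1e-3])
        ds = DecodingDataset(X=X, y_pain=base.y_pain, y_temp=base.y_temp)
        table = evaluate_decoders(
            ds, cfgs={"en": {"n_select": 1},
                      "combined": {"fit_cfg": FitConfig(n_draws=300, seed=0)}})
        for model in ("ols", "en", "enlags", "combined"):
            assert table.loc[model, "test_r"] >= 0.99

    def test_no_test_rows_rejected(self):
        ds = make_decoding_dataset(seed=4, bold_spec=BoldSpec(n_voxels=20, seed=0))
        with pytest.raises(ValueError):
            evaluate_decoders(ds, SplitSpec(n_train_tr=ds.n_tr))


class TestLeakageControl:
    def test_shuffled_training_targets_destroy_test_accuracy(self):
        ds = make_decoding_dataset(seed=1)  # full-size fixture: chance level
        n = 120                             # is set by the 240-TR time series
        max_lag, screen = 7, 0.2
        rs = []
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = ds.y_pain.copy()
            y[:n] = rng.permutation(y[:n])
            try:
                D, lag_map = build_lagged_design(ds.X, y, max_lag=max_lag,
                                                 screen_r=screen, n_train=n)
            except EmptyDesignError:
                rs.append(0.0)
                continue
            y_trim = y[max_lag:]
            cut = n - max_lag
            en = fit_en(D[:cut], y_trim[:cut], lambda2=1.0,
                        n_select=min(25, D.shape[1]))
            pred = en.predict(D[cut:])
            rs.append(0.0 if np.ptp(pred) == 0
                      else pearson_r(pred, ds.y_pain[n:]))
        assert np.mean(np.abs(rs)) < 0.1
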