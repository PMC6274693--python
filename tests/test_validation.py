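"""Validation statistics: analytic identities, brute-force hat-matrix
oracles, permutation baselines, and the grouped cross-validation layout."""

import numpy as np
import pandas as pd
import pytest

from mixtox import dataset_io
from mixtox.errors import UndefinedStatisticError, ValidationError
from mixtox.mlr import OLSRegressor, REFERENCE_MODELS, fit_ols
from mixtox.validation import (
    golbraikh_tropsha,
    leverage,
    lmo_crossvalidation,
    loo_q2,
    mean_effect,
    r_squared,
    rms,
    vif,
    williams_ad,
    y_randomization,
)


@pytest.fixture(scope="module")
def structured():
    return dataset_io.generate_synthetic(60, "linear", noise_sd=0.3, seed=17)


class TestRSquaredAndRms:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2, 3, 4])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert rms(y, y) == 0.0

    def test_symmetric_in_arguments(self, structured):
        fit = OLSRegressor().fit(structured.X, structured.y)
        pred = fit.predict(structured.X)
        assert r_squared(structured.y, pred) == pytest.approx(
            r_squared(pred, structured.y), abs=1e-12
        )

    def test_rms_translation_covariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert rms(a + 5, b + 5) == pytest.approx(rms(a, b), abs=1e-12)

    def test_constant_residual(self):
        y = np.arange(10.0)
        assert rms(y, y - 0.7) == pytest.approx(0.7)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared(np.ones(5), np.arange(5.0))

    def test_df_corrected_form(self):
        y = np.arange(10.0)
        pred = y - 1.0
        assert rms(y, pred, ddof=4) == pytest.approx(np.sqrt(10 / 6))
        with pytest.raises(ValidationError):
            rms(y, pred, ddof=10)


class TestLooQ2:
    def test_noise_free_linear_is_one(self):
        ds = dataset_io.generate_synthetic(20, "linear", noise_sd=0.0, seed=1)
        assert loo_q2(fit_ols, ds.X, ds.y) == pytest.approx(1.0, abs=1e-9)

    def test_permuted_response_scores_poorly(self, structured):
        rng = np.random.default_rng(99)
        assert loo_q2(fit_ols, structured.X, rng.permutation(structured.y)) < 0.3

    def test_q2_rarely_exceeds_r2(self):
        wins = 0
        for seed in range(100):
            ds = dataset_io.generate_synthetic(25, "linear", noise_sd=0.5, seed=seed)
            r2 = OLSRegressor().fit(ds.X, ds.y).r2_
            if loo_q2(fit_ols, ds.X, ds.y) <= r2:
                wins += 1
        assert wins >= 95


class TestGolbraikhTropsha:
    def test_identity_passes_everything(self):
        y = np.linspace(1, 5, 10)
        rep = golbraikh_tropsha(y, y, q2=0.9)
        assert rep.k == pytest.approx(1.0) and rep.k_prime == pytest.approx(1.0)
        assert rep.r0_sq == pytest.approx(rep.r2, abs=1e-12)
        assert all(rep.gt_pass.values())

    def test_scaling_law(self):
        # y_pred = a*y_obs makes the through-origin slope exactly 1/a
        y = np.linspace(1, 5, 12)
        rep = golbraikh_tropsha(y, 2.0 * y)
        assert rep.k == pytest.approx(0.5, abs=1e-12)
        assert rep.k_prime == pytest.approx(2.0, abs=1e-12)

    def test_zero_denominator_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            golbraikh_tropsha(np.ones(5) - 1, np.arange(5.0))


class TestVif:
    @pytest.mark.parametrize(
        "r,expected", [(0.0, 1.0), (0.740, 2.210), (-0.314, 1.109), (0.013, 1.000)]
    )
    def test_values(self, r, expected):
        assert vif(r) == pytest.approx(expected, abs=5e-4)

    def test_perfect_correlation_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            vif(1.0)


class TestMeanEffect:
    def test_single_descriptor_is_one(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        fit = OLSRegressor().fit(X, np.array([2.0, 4, 6, 8, 10.5]))
        assert mean_effect(fit, X)["a"] == pytest.approx(1.0)

    def test_sums_to_one_for_random_models(self):
        for seed in range(5):
            ds = dataset_io.generate_synthetic(30, "linear", noise_sd=0.5, seed=seed)
            fit = OLSRegressor().fit(ds.X, ds.y)
            assert sum(mean_effect(fit, ds.X).values()) == pytest.approx(1.0, abs=1e-12)

    def test_printed_reference_identity(self):
        # the published per-descriptor contributions close to a full budget
        assert -0.051 + 0.401 + 0.650 == pytest.approx(1.000, abs=1e-9)


class TestYRandomization:
    def test_scrambling_destroys_signal(self, structured):
        results, averages = y_randomization(
            fit_ols, structured.X, structured.y, n_repeats=10, seed=3
        )
        assert len(results) == 10 and averages["n_failed"] == 0
        assert averages["r2"] < 0.2

    def test_single_repeat_reproducible(self, structured):
        _, a = y_randomization(fit_ols, structured.X, structured.y, n_repeats=1, seed=5)
        _, b = y_randomization(fit_ols, structured.X, structured.y, n_repeats=1, seed=5)
        assert a == b

    def test_degenerate_response_recorded_not_fatal(self, structured):
        results, averages = y_randomization(
            fit_ols, structured.X, np.ones(len(structured.y)), n_repeats=2, seed=0
        )
        assert averages["n_failed"] == 2
        assert all(r["error"] is not None for r in results)


class TestLmoCrossValidation:
    def test_fixture_labels_give_expected_fold_sizes(self, mixtures, descriptor_table):
        from mixtox.mixture_descriptors import build_mixture_matrix

        mat = build_mixture_matrix(mixtures, descriptor_table)
        X = mat[["ntb_mix", "acic2_mix", "qmaxc_mix"]]
        y = mixtures.neg_log_ec50mix_exp.to_numpy()
        folds, averages = lmo_crossvalidation(fit_ols, X, y, mixtures.subset)
        assert [f["held_out"] for f in folds] == ["A", "B", "C", "D", "T"]
        assert sorted(f["n_test"] for f in folds) == [19, 20, 20, 20, 20]
        assert averages["r2_train"] == pytest.approx(
            np.mean([f["r2_train"] for f in folds]), abs=1e-12
        )

    def test_noise_free_linear_data_scores_one_everywhere(self):
        ds = dataset_io.generate_synthetic(50, "linear", noise_sd=0.0, seed=8)
        labels = np.repeat(list("ABCDE"), 10)
        folds, _ = lmo_crossvalidation(fit_ols, ds.X, ds.y, labels)
        assert all(f["r2_test"] == pytest.approx(1.0, abs=1e-9) for f in folds)

    def test_empty_group_is_partition_error(self):
        ds = dataset_io.generate_synthetic(10, "linear", noise_sd=0.1, seed=0)
        with pytest.raises(ValidationError):
            lmo_crossvalidation(fit_ols, ds.X, ds.y, ["A"] * 10)


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 3))
    return np.column_stack([np.ones(10), X]), X


class TestLeverageAndWilliams:
    def test_matches_brute_force_hat_matrix(self, design):
        D, _ = design
        hat = D @ np.linalg.inv(D.T @ D) @ D.T
        np.testing.assert_allclose(leverage(D, D), np.diag(hat), atol=1e-10)

    def test_training_leverages_sum_to_parameter_count(self, design):
        D, _ = design
        assert leverage(D, D).sum() == pytest.approx(D.shape[1], abs=1e-9)
        assert np.all((leverage(D, D) > 0) & (leverage(D, D) <= 1))

    def test_centroid_attains_minimum_leverage(self, design):
        D, X = design
        centroid = np.concatenate([[1.0], X.mean(axis=0)])
        assert leverage(D, centroid) == pytest.approx(1 / len(X), abs=1e-12)

    def test_williams_flags_far_query_as_x_outlier(self):
        ds = dataset_io.generate_synthetic(40, "linear", noise_sd=0.2, seed=12)
        fit = OLSRegressor().fit(ds.X, ds.y)
        far = ds.X.mean() + 10 * ds.X.std()
        report = williams_ad(fit, ds.X, ds.y, X_query=pd.DataFrame([far]))
        query = report.table[report.table.set == "query"]
        assert bool(query.x_outlier.iloc[0])
        centroid = williams_ad(fit, ds.X, ds.y,
                               X_query=pd.DataFrame([ds.X.mean()]))
        assert not bool(
            centroid.table[centroid.table.set == "query"].x_outlier.iloc[0]
        )

    def test_no_y_outliers_when_residuals_tiny(self):
        ds = dataset_io.generate_synthetic(30, "linear", noise_sd=0.0, seed=2)
        # perturb minimally so the studentized-residual scale is defined
        y = ds.y + np.random.default_rng(0).normal(scale=1e-6, size=30)
        fit = OLSRegressor().fit(ds.X, y)
        report = williams_ad(fit, ds.X, y)
        assert report.y_outliers == []

    def test_h_star_formulas(self):
        ds = dataset_io.generate_synthetic(30, "linear", noise_sd=0.2, seed=3)
        fit = OLSRegressor().fit(ds.X, ds.y)
        narrow = williams_ad(fit, ds.X, ds.y)
        standard = williams_ad(fit, ds.X, ds.y, h_star_formula="standard")
        assert narrow.h_star == pytest.approx(3 * 3 / 30)
        assert standard.h_star == pytest.approx(3 * 4 / 30)

    def test_reference_model_accepted(self, mixtures, descriptor_table):
        from mixtox.mixture_descriptors import build_mixture_matrix

        mat = build_mixture_matrix(mixtures, descriptor_table).rename(columns={
            "ntb_mix": "ntb", "acic2_mix": "acic2", "qmaxc_mix": "qmaxc"
        })
        train = mat[mixtures.subset.to_numpy() != "T"]
        y = mixtures.loc[mixtures.subset != "T", "neg_log_ec50mix_exp"].to_numpy()
        report = williams_ad(REFERENCE_MODELS["mixture_training"], train, y)
        assert report.n_train == 79
        assert report.table.leverage.iloc[:79].sum() == pytest.approx(4.0, abs=1e-9)
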