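"""Prediction framework: scaling, CV schemes, metrics, permutation test."""

import numpy as np
import pingouin as pg
import pytest

from memconn import rvr
from memconn.connectome import DegenerateInputError
from memconn.prediction import (
    CVResult,
    apply_scaling,
    composite_memory,
    composite_memory_two,
    fit_scaling,
    format_p,
    loocv_predict,
    partial_correlation,
    permutation_test,
    repeated_kfold_predict,
)


def _easy_cohort(n=16, m=6, noise=0.0, seed=0):
    """Features directly linear in the score: trivially predictable."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, m))
    w = np.array([1.5, -1.0, 0.5] + [0.0] * (m - 3))
    y = X @ w + 1.0 + noise * rng.standard_normal(n)
    return X, y


class TestCompositeMemory:
    def test_table_means_baseline_and_followup(self):
        assert round(composite_memory(2.78, 3.34, 13.47), 2) == 6.53
        assert round(composite_memory(2.46, 2.60, 14.14), 2) == 6.40

    def test_equal_values_identity(self):
        assert composite_memory(4.2, 4.2, 4.2) == pytest.approx(4.2)

    def test_vectorized_over_subjects(self):
        out = composite_memory([1.0, 2.0], [2.0, 4.0], [3.0, 6.0])
        assert np.allclose(out, [2.0, 4.0])

    def test_missing_value_names_subject(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            composite_memory([1.0, np.nan], [2.0, 2.0], [3.0, 3.0])

    def test_two_test_variant(self):
        assert composite_memory_two(3.0, 5.0) == pytest.approx(4.0)


class TestScaling:
    def test_basic_formula(self):
        params = fit_scaling(np.array([[0.0], [10.0]]))
        assert apply_scaling(params, np.array([[5.0]]))[0, 0] == 0.5

    def test_test_values_not_clipped(self):
        params = fit_scaling(np.array([[0.0], [10.0]]))
        assert apply_scaling(params, np.array([[12.0]]))[0, 0] == pytest.approx(1.2)
        assert apply_scaling(params, np.array([[-2.0]]))[0, 0] == pytest.approx(-0.2)

    def test_constant_column_maps_to_zero_everywhere(self):
        params = fit_scaling(np.array([[3.0, 1.0], [3.0, 2.0]]))
        out = apply_scaling(params, np.array([[3.0, 1.5], [99.0, 2.0]]))
        assert np.all(out[:, 0] == 0.0)
        assert out[0, 1] == 0.5

    def test_training_rows_land_in_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 7))
        out = apply_scaling(fit_scaling(X), X)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestLOOCV:
    def test_fold_accounting(self):
        X, y = _easy_cohort(n=5)
        with pytest.warns(RuntimeWarning, match="unstable"):
            cv = loocv_predict(X, y)
        assert cv.scheme == "loocv"
        assert len(cv.predictions) == 5
        assert np.array_equal(cv.fold_assignment, np.arange(5))
        assert len(cv.models) == 5

    def test_noiseless_signal_near_perfect(self):
        X, y = _easy_cohort(n=16, noise=0.0)
        cv = loocv_predict(X, y)
        assert cv.r > 0.99

    def test_matches_explicit_loop_oracle(self):
        X, y = _easy_cohort(n=12, noise=0.2, seed=3)
        cv = loocv_predict(X, y)
        preds = np.empty(12)
        for i in range(12):
            tr = np.delete(np.arange(12), i)
            params = fit_scaling(X[tr])
            model = rvr.fit(apply_scaling(params, X[tr]), y[tr])
            preds[i] = rvr.predict(model, apply_scaling(params, X[[i]]))[0]
        assert np.array_equal(cv.predictions, preds)

    def test_subject_order_equivariance(self):
        X, y = _easy_cohort(n=14, noise=0.3, seed=4)
        cv = loocv_predict(X, y, return_models=False)
        perm = np.random.default_rng(5).permutation(14)
        cv_p = loocv_predict(X[perm], y[perm], return_models=False)
        assert np.abs(cv_p.predictions - cv.predictions[perm]).max() < 1e-8

    def test_held_out_subject_never_shapes_its_own_fold(self):
        """Corrupting a held-out subject's features leaves that fold's
        scaling and fitted model untouched (train-only derivation)."""
        X, y = _easy_cohort(n=12, noise=0.2, seed=6)
        cv = loocv_predict(X, y)
        X2 = X.copy()
        X2[4] = 1e3  # wreck subject 4's features
        cv2 = loocv_predict(X2, y)
        assert np.array_equal(cv.scalings[4].minimum, cv2.scalings[4].minimum)
        assert np.array_equal(cv.scalings[4].maximum, cv2.scalings[4].maximum)
        assert np.array_equal(cv.models[4].mu_full, cv2.models[4].mu_full)
        assert np.array_equal(cv.models[4].relevance_set, cv2.models[4].relevance_set)


class TestRepeatedKFold:
    def test_k_equal_n_matches_loocv(self):
        X, y = _easy_cohort(n=12, noise=0.2, seed=7)
        cv_loo = loocv_predict(X, y, return_models=False)
        cv_k = repeated_kfold_predict(X, y, k=12, repeats=1, seed=9)
        assert np.allclose(cv_k.predictions, cv_loo.predictions)
        assert cv_k.r == pytest.approx(cv_loo.r)
        assert cv_k.mae == pytest.approx(cv_loo.mae)

    def test_seed_reproducibility(self):
        X, y = _easy_cohort(n=15, noise=0.3, seed=8)
        a = repeated_kfold_predict(X, y, k=5, repeats=3, seed=42)
        b = repeated_kfold_predict(X, y, k=5, repeats=3, seed=42)
        assert a.r == b.r and a.mae == b.mae
        assert np.array_equal(a.predictions, b.predictions)

    def test_every_subject_predicted_each_repeat(self):
        X, y = _easy_cohort(n=13, noise=0.3, seed=9)
        cv = repeated_kfold_predict(X, y, k=4, repeats=2, seed=1)
        assert cv.fold_assignment.shape == (2, 13)
        for rep in range(2):
            sizes = np.bincount(cv.fold_assignment[rep])
            assert sizes.max() - sizes.min() <= 1

    def test_averaging_reduces_between_repeat_noise(self):
        X, y = _easy_cohort(n=20, m=8, noise=1.0, seed=10)
        cv = repeated_kfold_predict(X, y, k=5, repeats=20, seed=3)
        rs = cv.per_repeat_r
        group_means = rs.reshape(4, 5).mean(axis=1)
        assert group_means.std() < rs.std()

    def test_k_validation(self):
        X, y = _easy_cohort(n=8)
        with pytest.raises(ValueError, match="exceeds"):
            repeated_kfold_predict(X, y, k=9, repeats=1, seed=0)
        with pytest.raises(ValueError, match="seed"):
            repeated_kfold_predict(X, y, k=4, repeats=1)


class TestPartialCorrelation:
    def test_empty_covariates_equals_pearson(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal((2, 30))
        assert partial_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_predicted_equal_to_covariate_vanishes(self):
        rng = np.random.default_rng(12)
        c = rng.standard_normal(40)
        x = 0.5 * c + 0.1 * rng.standard_normal(40)
        assert abs(partial_correlation(x, c, c[:, None])) < 1e-10

    def test_matches_textbook_recursion_single_covariate(self):
        rng = np.random.default_rng(13)
        x, y, z = rng.standard_normal((3, 10))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expect = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_correlation(x, y, z[:, None]) == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin_two_covariates(self):
        import pandas as pd

        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("xyab"))
        expect = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])["r"].iloc[0]
        got = partial_correlation(df["x"], df["y"], df[["a", "b"]].to_numpy())
        assert got == pytest.approx(expect, abs=1e-10)

    def test_orthogonal_covariates_equal_pearson(self):
        rng = np.random.default_rng(15)
        x, y = rng.standard_normal((2, 40))
        c = rng.standard_normal((40, 2))
        # make covariates exactly orthogonal to x, y and the intercept
        basis = np.column_stack([np.ones(40), x, y])
        c = c - basis @ np.linalg.lstsq(basis, c, rcond=None)[0]
        assert partial_correlation(x, y, c) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-10
        )

    def test_collinear_covariates_warn(self):
        rng = np.random.default_rng(16)
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.warns(RuntimeWarning, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestPermutationTest:
    def test_constant_targets_rejected_before_permuting(self):
        X, _ = _easy_cohort(n=10)
        with pytest.raises(DegenerateInputError, match="constant"):
            permutation_test(X, np.ones(10), n_perm=9, seed=0)

    def test_strong_signal_reported_below_resolution(self):
        X, y = _easy_cohort(n=16, noise=0.05, seed=17)
        res = permutation_test(X, y, n_perm=19, seed=2)
        assert res.p_r == 0.0
        assert res.p_r_label == f"< {1/19:g}"
        assert len(res.null_r) == 19

    def test_observed_metric_matches_loocv_path(self):
        X, y = _easy_cohort(n=14, noise=0.3, seed=18)
        cv = loocv_predict(X, y, return_models=False)
        res = permutation_test(X, y, n_perm=5, seed=3)
        assert res.observed_r == pytest.approx(cv.r, abs=1e-6)
        assert res.observed_mae == pytest.approx(cv.mae, abs=1e-6)

    def test_seeded_determinism(self):
        X, y = _easy_cohort(n=12, noise=0.5, seed=19)
        a = permutation_test(X, y, n_perm=11, seed=7)
        b = permutation_test(X, y, n_perm=11, seed=7)
        assert np.array_equal(a.null_r, b.null_r)
        assert a.p_r == b.p_r

    def test_strict_vs_nonstrict_counting(self):
        X, y = _easy_cohort(n=12, noise=2.0, seed=20)
        loose = permutation_test(X, y, n_perm=19, seed=4, strict=False)
        strict = permutation_test(X, y, n_perm=19, seed=4, strict=True)
        assert strict.p_r <= loose.p_r

    def test_kfold_scheme_runs(self):
        X, y = _easy_cohort(n=12, noise=0.3, seed=21)
        res = permutation_test(X, y, scheme="kfold", k=4, repeats=2, n_perm=5, seed=5)
        assert res.scheme == "kfold"
        assert len(res.null_r) == 5

    def test_cofold_subjects_do_not_interact(self):
        """Within one train/test split, corrupting one test subject leaves
        the other test subjects' predictions unchanged."""
        from memconn.prediction import _run_cv

        X, y = _easy_cohort(n=12, noise=0.3, seed=22)
        folds = [(np.arange(4, 12), np.arange(0, 4))]
        preds, *_ = _run_cv(X, y, folds, rvr.RVRFitConfig(), False)
        X2 = X.copy()
        X2[0] = -50.0
        preds2, *_ = _run_cv(X2, y, folds, rvr.RVRFitConfig(), False)
        assert np.array_equal(preds[1:4], preds2[1:4])


def test_format_p():
    assert format_p(0.0, 1000) == "< 0.001"
    assert format_p(0.034, 1000) == "0.034"


def test_cv_result_serializable():
    X, y = _easy_cohort(n=12, noise=0.2, seed=23)
    cv = loocv_predict(X, y, covariates=np.random.default_rng(0).standard_normal((12, 2)))
    d = cv.to_dict()
    assert set(d) >= {"scheme", "r", "mae", "partial_r", "predictions", "actual"}
    import json

    json.dumps(d)
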