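"""Polynomial gaze model: basis evaluation, fitting, progressive updates."""

import json
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from gazekit.model import (
    MODEL_SPECS,
    BinocularGazeEstimator,
    CalibrationSample,
    GazeRegressor,
    ModelSpec,
    NotEnoughSamplesError,
    combine_eyes,
    get_spec,
    median_fixation_features,
    n_coefficients,
)


def random_features(rng, m):
    """Feature vectors with realistic scales: pupil +-60 px, corner ~400."""
    x = rng.uniform(-60, 60, size=m)
    y = rng.uniform(-50, 50, size=m)
    mm = rng.uniform(380, 440, size=m)
    nn = rng.uniform(240, 280, size=m)
    return np.column_stack([x, y, mm, nn])


class TestBasis:
    def test_adopted_basis_row_is_the_documented_monomial_order(self):
        row = get_spec("quadratic_pupil_linear_corner").basis_row([2, 3, 10, 20])
        assert row.tolist() == [2, 3, 6, 4, 9, 10, 20, 1]

    def test_zero_features_leave_only_the_constant(self):
        row = get_spec("quadratic_pupil_linear_corner").basis_row([0, 0, 0, 0])
        assert row.tolist() == [0, 0, 0, 0, 0, 0, 0, 1]

    def test_full_quadratic_on_all_ones_gives_all_ones(self):
        row = get_spec("full_quadratic").basis_row([1, 1, 1, 1])
        assert row.tolist() == [1.0] * 15

    @pytest.mark.parametrize(
        "name, n",
        [
            ("quadratic_pupil", 6),
            ("quadratic_pupil_linear_corner", 8),
            ("cubic_pupil_linear_corner", 12),
            ("full_quadratic", 15),
        ],
    )
    def test_coefficient_counts(self, name, n):
        assert n_coefficients(name) == n
        assert get_spec(name).n_terms == n

    def test_full_quadratic_enumerates_every_degree_le_2_monomial(self):
        # independent enumeration: all exponent tuples with total degree <= 2
        expected = {
            (i, j, k, l)
            for i in range(3)
            for j in range(3)
            for k in range(3)
            for l in range(3)
            if i + j + k + l <= 2
        }
        assert set(get_spec("full_quadratic").terms) == expected

    def test_basis_must_contain_constant_term(self):
        with pytest.raises(ValueError, match="constant"):
            ModelSpec("bad", ((1, 0, 0, 0),))

    @given(
        e=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=4
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_basis_row_matches_naive_monomial_product(self, e):
        spec = get_spec("full_quadratic")
        row = spec.basis_row(e)
        naive = [
            np.prod([float(v) ** p for v, p in zip(e, t)]) for t in spec.terms
        ]
        assert np.allclose(row, naive, rtol=1e-12, atol=1e-9)


class TestFit:
    @pytest.mark.parametrize("name", sorted(MODEL_SPECS))
    def test_exact_recovery_of_coefficients_from_family_data(self, name, rng):
        spec = get_spec(name)
        c0 = rng.normal(size=(spec.n_terms, 2)) * 0.01
        X = random_features(rng, spec.n_terms + 10)
        G = spec.basis_matrix(X) @ c0
        est = GazeRegressor(spec=name).fit(X, G)
        assert np.linalg.norm(est.coef_ - c0) <= 1e-8 * np.linalg.norm(c0)
        assert np.allclose(est.predict(X), G, atol=1e-9)

    def test_square_system_interpolates_with_zero_residual(self, rng):
        X = random_features(rng, 8)
        G = rng.uniform(0, 1, size=(8, 2))
        est = GazeRegressor().fit(X, G)
        assert np.allclose(est.predict(X), G, atol=1e-7)

    def test_duplicating_all_rows_leaves_coefficients_unchanged(self, rng):
        X = random_features(rng, 12)
        G = rng.uniform(0, 1, size=(12, 2))
        a = GazeRegressor().fit(X, G)
        b = GazeRegressor().fit(np.vstack([X, X]), np.vstack([G, G]))
        assert np.allclose(a.coef_, b.coef_, atol=1e-10)

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(NotEnoughSamplesError):
            GazeRegressor().fit(random_features(rng, 7), np.zeros((7, 2)))

    def test_rank_deficient_fit_warns_and_returns_min_norm(self, rng):
        X = random_features(rng, 20)
        X[:, 2] = 400.0  # constant corner column, collinear with the 1 term
        X[:, 3] = 260.0
        G = rng.uniform(0, 1, size=(20, 2))
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            est = GazeRegressor().fit(X, G)
        assert est.rank_ < 8
        assert np.all(np.isfinite(est.coef_))

    def test_refit_is_idempotent(self, rng):
        X = random_features(rng, 15)
        G = rng.uniform(0, 1, size=(15, 2))
        est = GazeRegressor().fit(X, G)
        c1 = est.coef_.copy()
        est.fit(X, G)
        assert np.array_equal(c1, est.coef_)

    def test_screen_affine_equivariance_of_percent_width_errors(self, rng):
        # rescaling all targets rescales predictions identically, so errors
        # expressed as fractions of the screen width are unchanged
        X = random_features(rng, 30)
        G = rng.uniform(0, 1, size=(30, 2))
        Xt = random_features(rng, 5)
        a = GazeRegressor().fit(X, G)
        s = 3.7
        b = GazeRegressor().fit(X, s * G)
        assert np.allclose(s * a.predict(Xt), b.predict(Xt), rtol=1e-8)

    def test_unfitted_predict_raises(self):
        with pytest.raises(Exception):
            GazeRegressor().predict(np.zeros((1, 4)))

    def test_constant_only_coefficients_map_everything_to_that_point(self, rng):
        est = GazeRegressor()
        est.spec_ = get_spec("quadratic_pupil_linear_corner")
        est.coef_ = np.zeros((8, 2))
        est.coef_[7] = [0.5, 0.5]
        out = est.predict(random_features(rng, 6))
        assert np.allclose(out, 0.5)


class TestProgressive:
    def test_append_sample_bookkeeping(self, rng):
        X = random_features(rng, 9)
        G = rng.uniform(0, 1, size=(9, 2))
        est = GazeRegressor().fit(X, G)
        est.augment(random_features(rng, 1), rng.uniform(0, 1, size=(1, 2)))
        assert est.n_samples_ == 10

    def test_append_then_fit_equals_batch_fit(self, rng):
        X = random_features(rng, 20)
        G = rng.uniform(0, 1, size=(20, 2))
        batch = GazeRegressor().fit(X, G)
        inc = GazeRegressor().fit(X[:10], G[:10])
        for i in range(10, 20):
            inc.augment(X[[i]], G[[i]])
        assert np.allclose(batch.coef_, inc.coef_, atol=1e-10)

    def test_appending_a_model_consistent_sample_barely_moves_coefficients(
        self, rng
    ):
        spec = get_spec("quadratic_pupil_linear_corner")
        c0 = rng.normal(size=(8, 2)) * 0.01
        X = random_features(rng, 20)
        est = GazeRegressor().fit(X, spec.basis_matrix(X) @ c0)
        c_before = est.coef_.copy()
        Xn = random_features(rng, 1)
        est.augment(Xn, spec.basis_matrix(Xn) @ c0)
        assert np.linalg.norm(est.coef_ - c_before) < 1e-6

    def test_binocular_append_grows_both_eyes(self, rng):
        est = BinocularGazeEstimator()
        est.fit(random_features(rng, 9), random_features(rng, 9),
                rng.uniform(0, 1, size=(9, 2)))
        sample = CalibrationSample(
            t=1.0, g=(0.25, 0.4),
            e_left=tuple(random_features(rng, 1)[0]),
            e_right=tuple(random_features(rng, 1)[0]),
        )
        est.append_sample(sample)
        assert est.n_samples_ == (10, 10)

    def test_serialization_roundtrip(self, rng):
        X = random_features(rng, 12)
        G = rng.uniform(0, 1, size=(12, 2))
        est = GazeRegressor().fit(X, G)
        other = GazeRegressor.from_json(est.to_json())
        assert np.allclose(other.coef_, est.coef_)
        assert np.allclose(other.predict(X), est.predict(X))
        json.loads(est.to_json())  # valid JSON document

    def test_sklearn_clone_and_params(self):
        est = GazeRegressor(spec="quadratic_pupil", rcond=1e-8)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


class TestCombination:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((0.4, 0.5), (0.6, 0.5), (0.5, 0.5)),
            ((0.3, 0.3), (0.3, 0.3), (0.3, 0.3)),
            (None, (0.3, 0.3), (0.3, 0.3)),
            ((np.nan, 0.2), (0.3, 0.3), (0.3, 0.3)),
        ],
    )
    def test_combine_eyes(self, left, right, expected):
        assert np.allclose(combine_eyes(left, right), expected)

    def test_combine_eyes_both_missing_returns_none(self):
        assert combine_eyes(None, (np.nan, np.nan)) is None

    def test_median_of_constant_buffer_is_that_constant(self):
        buf = np.tile([10.0, 10.0, 100.0, 100.0], (9, 1))
        assert np.allclose(median_fixation_features(buf), [10, 10, 100, 100])

    def test_median_rejects_microsaccade_outlier(self):
        buf = np.tile([10.0, 10.0, 100.0, 100.0], (9, 1))
        buf = np.vstack([buf, [30.0, 30.0, 100.0, 100.0]])
        assert np.allclose(median_fixation_features(buf), [10, 10, 100, 100])

    def test_median_of_symmetric_tremor_recovers_center(self):
        jitter = np.array([[1, -1, 0, 0], [-1, 1, 0, 0]] * 5, dtype=float)
        buf = np.array([10.0, 10.0, 100.0, 100.0]) + jitter
        assert np.allclose(median_fixation_features(buf), [10, 10, 100, 100])

    def test_median_requires_half_the_frames_valid(self):
        buf = np.tile([10.0, 10.0, 100.0, 100.0], (10, 1))
        valid = np.array([True] * 4 + [False] * 6)
        assert median_fixation_features(buf, valid) is None
        assert median_fixation_features(np.empty((0, 4))) is None
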