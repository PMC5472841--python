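"""Probability core: utilities, softmax link, transforms, identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnrm.model import (
    IdentificationPattern,
    ModelParameters,
    ResponseMatrix,
    category_probabilities,
    count_free_parameters,
    echelon_pattern,
    expand_scoring,
    log_likelihood,
    n_response_patterns,
    re_reference,
    to_deviation,
    to_scoring,
    utilities,
)
from mnrm.simulate import table2_parameters


def random_simple_params(rng, J=3, K=4, D=2):
    c = rng.normal(0, 1.5, (J, K))
    a = rng.normal(0, 1.0, (J, K, D))
    c[:, K - 1] = 0.0
    a[:, K - 1, :] = 0.0
    return ModelParameters(c, a, "simple", reference_category=K)


class TestResponseMatrix:
    def test_valid_matrix_infers_k(self):
        X = ResponseMatrix(np.array([[1, 2], [2, 1]]))
        assert (X.N, X.J, X.K) == (2, 2, 2)

    @pytest.mark.parametrize(
        "values, msg",
        [
            ([[0, 1]], "code < 1"),
            ([[1, 5]], "code > K"),
            ([[1.5, 1.0]], "non-integer"),
        ],
    )
    def test_invalid_entries_rejected(self, values, msg):
        with pytest.raises(ValueError, match=msg):
            ResponseMatrix(np.array(values), K=4)

    def test_too_few_categories(self):
        with pytest.raises(ValueError, match="at least 2"):
            ResponseMatrix(np.array([[1, 1]]), K=1)


class TestUtilities:
    def test_zero_parameters_give_zero_utilities(self):
        p = ModelParameters(np.zeros((2, 3)), np.zeros((2, 3, 2)), "simple",
                            reference_category=3)
        z = utilities(p, np.array([0.7, -1.2]))
        assert np.array_equal(z, np.zeros((2, 3)))

    def test_generating_item_at_origin(self):
        # item 1 of the built-in generator evaluated at theta = 0
        z = utilities(table2_parameters(1), np.zeros(1))
        np.testing.assert_array_equal(z[0], [-1.0, 0.0, 1.0, 0.0])

    def test_linear_in_theta(self):
        z = utilities(table2_parameters(1), np.array([2.0]))
        np.testing.assert_allclose(z[0], [1.0, 1.0, -1.0, 0.0])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            utilities(table2_parameters(2), np.zeros(3))


class TestCategoryProbabilities:
    def test_equal_utilities_give_uniform(self):
        p = ModelParameters(np.zeros((1, 5)), np.zeros((1, 5, 1)), "simple")
        np.testing.assert_allclose(category_probabilities(p, np.zeros(1)), 0.2)

    def test_softmax_of_generating_item(self):
        P = category_probabilities(table2_parameters(1), np.zeros(1))
        np.testing.assert_allclose(
            P[0], [0.0723, 0.1966, 0.5344, 0.1966], atol=5e-5
        )

    def test_shift_invariance(self):
        # adding a constant to every utility of an item leaves P unchanged
        rng = np.random.default_rng(7)
        p = random_simple_params(rng)
        theta = rng.normal(size=2)
        P = category_probabilities(p, theta)
        from scipy.special import softmax

        for T in rng.uniform(-50, 50, 10):
            z = utilities(p, theta) + T
            np.testing.assert_allclose(softmax(z, axis=-1), P, atol=1e-12)

    def test_normalization_over_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = random_simple_params(rng, J=2, K=3, D=1)
            P = category_probabilities(p, rng.normal(size=1))
            np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-12)
            assert np.all(P > 0)

    def test_extreme_utilities_stable(self):
        p = ModelParameters(
            np.array([[690.0, -690.0, 0.0]]), np.zeros((1, 3, 1)), "simple"
        )
        P = category_probabilities(p, np.zeros(1))
        assert np.all(np.isfinite(P))
        np.testing.assert_allclose(P.sum(), 1.0, atol=1e-12)


class TestLogLikelihood:
    def test_uniform_model_gives_log_inverse_k(self):
        p = ModelParameters(np.zeros((1, 4)), np.zeros((1, 4, 1)), "simple")
        X = ResponseMatrix(np.array([[3]]), K=4)
        out = log_likelihood(p, np.zeros((1, 1)), X)
        assert out["total"] == pytest.approx(np.log(0.25))

    def test_additivity_over_identical_persons(self):
        p = table2_parameters(1)
        X = ResponseMatrix(np.array([[1, 2, 3, 4], [1, 2, 3, 4]]), K=4)
        out = log_likelihood(p, np.zeros((2, 1)), X)
        assert out["total"] == pytest.approx(2 * out["pointwise"][0])

    def test_single_item_value(self):
        p = table2_parameters(1)
        one_item = ModelParameters(
            p.intercepts[:1], p.slopes[:1], "simple", reference_category=4
        )
        X = ResponseMatrix(np.array([[3]]), K=4)
        out = log_likelihood(one_item, np.zeros((1, 1)), X)
        assert out["total"] == pytest.approx(-0.6266, abs=1e-4)


class TestDeviationTransform:
    def test_worked_intercept_example(self):
        p = ModelParameters(
            np.array([[5.0, 4.0, 0.0]]), np.zeros((1, 3, 1)), "simple",
            reference_category=3,
        )
        np.testing.assert_allclose(to_deviation(p).intercepts, [[2.0, 1.0, -3.0]])

    def test_idempotent_on_centered_input(self):
        p = ModelParameters(
            np.array([[2.0, 1.0, -3.0]]),
            np.array([[[1.0], [-0.5], [-0.5]]]),
            "deviation",
        )
        out = to_deviation(p)
        np.testing.assert_allclose(out.intercepts, p.intercepts)
        np.testing.assert_allclose(out.slopes, p.slopes)

    def test_published_slope_column(self):
        p = ModelParameters(
            np.zeros((1, 4)),
            np.array([0.0, 1.0, 0.52, 0.0]).reshape(1, 4, 1),
            "simple",
            reference_category=4,
        )
        np.testing.assert_allclose(
            to_deviation(p).slopes[0, :, 0], [-0.38, 0.62, 0.14, -0.38]
        )

    def test_probabilities_preserved(self):
        rng = np.random.default_rng(3)
        p = random_simple_params(rng)
        q = to_deviation(p)
        for _ in range(100):
            theta = rng.normal(size=2)
            np.testing.assert_allclose(
                category_probabilities(p, theta),
                category_probabilities(q, theta),
                atol=1e-10,
            )


class TestScoringTransform:
    def test_equally_spaced_slopes_give_integer_scores(self):
        p = ModelParameters(
            np.zeros((1, 4)),
            np.array([0.0, 0.5, 1.0, 1.5]).reshape(1, 4, 1),
            "simple",
            reference_category=1,
        )
        out = to_scoring(p)
        assert out.item_slopes[0, 0] == pytest.approx(0.5)
        np.testing.assert_allclose(out.scores[0, :, 0], [0, 1, 2, 3])

    @pytest.mark.parametrize("a", [0.3, -1.7])
    def test_proportional_slopes(self, a):
        p = ModelParameters(
            np.zeros((1, 4)),
            (a * np.arange(4.0)).reshape(1, 4, 1),
            "simple",
            reference_category=1,
        )
        np.testing.assert_allclose(to_scoring(p).scores[0, :, 0], [0, 1, 2, 3])

    def test_round_trip_and_probability_preservation(self):
        rng = np.random.default_rng(5)
        p = random_simple_params(rng, J=2, K=4, D=2)
        sc = to_scoring(p)
        back = expand_scoring(sc)
        # reconstruction reproduces the re-referenced slopes exactly
        p1 = re_reference(p, 1)
        np.testing.assert_allclose(back.slopes, p1.slopes, atol=1e-10)
        for _ in range(20):
            theta = rng.normal(size=2)
            np.testing.assert_allclose(
                category_probabilities(p, theta),
                category_probabilities(sc, theta),
                atol=1e-10,
            )

    def test_degenerate_anchor_raises(self):
        a = np.zeros((1, 4, 1))
        a[0, 1, 0] = 0.5  # last category slope stays 0 after re-reference
        p = ModelParameters(np.zeros((1, 4)), a, "simple", reference_category=1)
        with pytest.raises(ValueError, match="item 1, dimension 1"):
            to_scoring(p)

    def test_intercepts_carry_over(self):
        c = np.array([[0.0, 1.0, -0.5, 2.0]])
        a = np.array([0.0, 0.5, 1.0, 1.5]).reshape(1, 4, 1)
        p = ModelParameters(c, a, "simple", reference_category=1)
        np.testing.assert_allclose(to_scoring(p).intercepts, c)


class TestEchelonPattern:
    def test_three_item_three_dim_mask(self):
        pat = echelon_pattern(3, 3, 3)
        A_one = pat.fixed_one.reshape(3, 3, 3)[:, :2].reshape(6, 3)
        A_zero = pat.fixed_zero.reshape(3, 3, 3)[:, :2].reshape(6, 3)
        expected_one = np.zeros((6, 3), dtype=bool)
        expected_one[0, 0] = expected_one[1, 1] = expected_one[2, 2] = True
        expected_zero = np.zeros((6, 3), dtype=bool)
        expected_zero[0, 1:] = True
        expected_zero[1, 2] = True
        assert np.array_equal(A_one, expected_one)
        assert np.array_equal(A_zero, expected_zero)

    def test_one_dimension_single_anchor(self):
        pat = echelon_pattern(4, 4, 1)
        assert pat.fixed_one.sum() == 1
        assert pat.fixed_one[0, 0, 0]
        # only structural zeros (reference category)
        assert pat.fixed_zero.sum() == 4

    def test_counts_match_formula(self):
        pat = echelon_pattern(4, 4, 2)
        assert pat.free_count == {"free_slopes": 21, "free_intercepts": 12}

    def test_infeasible_pattern_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            echelon_pattern(1, 2, 2)

    def test_masks_disjoint_invariant(self):
        with pytest.raises(ValueError, match="disjoint"):
            IdentificationPattern(
                np.ones((1, 2, 1), bool), np.ones((1, 2, 1), bool), 2
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=1, max_value=4),
    )
    def test_free_entries_agree_with_counting(self, J, K, D):
        if J * (K - 1) < D:
            return
        pat = echelon_pattern(J, K, D)
        expected = count_free_parameters(J, K, D, "echelon_with_sigma")
        assert pat.free_count["free_slopes"] == expected["free_slopes"]
        assert pat.free_count["free_intercepts"] == expected["free_intercepts"]


class TestCounting:
    def test_per_item_formula(self):
        out = count_free_parameters(1, 3, 2, "per_item_formula")
        assert out == {"free_intercepts": 2, "free_slopes": 4, "sigmas": 0}

    @pytest.mark.parametrize("D, slopes", [(1, 11), (2, 21), (3, 30), (4, 38)])
    def test_echelon_counts_four_item_design(self, D, slopes):
        out = count_free_parameters(4, 4, D, "echelon_with_sigma")
        assert out["free_slopes"] == slopes
        assert out["free_intercepts"] == 12
        assert out["sigmas"] == D

    def test_pattern_space_size(self):
        assert n_response_patterns(4, 4) == 256
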