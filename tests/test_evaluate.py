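"""SGDDM, posterior predictive p-values, and information criteria."""

import numpy as np
import pytest
from scipy.special import logsumexp

from mnrm.evaluate import (
    indicator_coding,
    loo,
    ppp,
    sgddm_pair,
    sgddm_pair_matrix,
    sgddm_total,
    waic,
)
from mnrm.model import ResponseMatrix, category_probabilities
from mnrm.simulate import generate_theta, simulate_responses, table2_parameters


class TestIndicatorCoding:
    def test_last_category_is_all_zero(self):
        X = ResponseMatrix(np.array([[1, 4], [4, 2]]), K=4)
        ind = indicator_coding(X)
        assert ind.shape == (2, 2, 3)
        np.testing.assert_array_equal(ind[0, 0], [1, 0, 0])
        np.testing.assert_array_equal(ind[0, 1], [0, 0, 0])
        np.testing.assert_array_equal(ind[1, 1], [0, 1, 0])
        assert np.all(ind.sum(axis=2) <= 1)


class TestSgddmPair:
    def test_hand_computed_two_person_example(self):
        X = np.array([[1], [2]])  # two persons, two pseudo-items via K=2...
        # build directly: two items, K=2 -> one pseudo-item each
        Xm = ResponseMatrix(np.array([[1, 2], [2, 1]]), K=2)
        ind = indicator_coding(Xm)  # [[1,0],[0,1]] over (N, J, 1)
        P = np.full((2, 2, 1), 0.5)
        assert sgddm_pair(ind, P, 0, 1) == pytest.approx(1.0)

    def test_zero_variance_pair_raises(self):
        Xm = ResponseMatrix(np.array([[1, 1], [1, 1]]), K=2)
        ind = indicator_coding(Xm)
        P = ind.astype(float).copy()  # P == X -> zero residuals
        with pytest.raises(ZeroDivisionError, match="undefined"):
            sgddm_pair(ind, P, 0, 1)

    def test_null_pairs_are_small_at_large_n(self):
        # data from the true model with its own theta: residual cross-moments
        # between items vanish as N grows
        p = table2_parameters(1)
        lat = generate_theta(5000, 1, 1.0, seed=0)
        X = simulate_responses(p, lat, seed=1)
        P = category_probabilities(p, lat.theta)[:, :, :3]
        values, defined = sgddm_pair_matrix(indicator_coding(X), P)
        item = np.repeat(np.arange(4), 3)
        cross = item[:, None] != item[None, :]
        assert values[cross & defined].max() < 0.1

    def test_bounded_by_one(self):
        rng = np.random.default_rng(2)
        X = ResponseMatrix(rng.integers(1, 5, size=(50, 4)), K=4)
        P = rng.dirichlet(np.ones(4), size=(50, 4))[:, :, :3]
        values, defined = sgddm_pair_matrix(indicator_coding(X), P)
        assert np.all(values[defined] <= 1.0 + 1e-12)
        assert np.all(values[defined] >= 0.0)


class TestSgddmTotal:
    def test_two_binary_items_reduce_to_single_pair(self):
        Xm = ResponseMatrix(np.array([[1, 2], [2, 1], [1, 1]]), K=2)
        ind = indicator_coding(Xm)
        P = np.full((3, 2, 1), 0.4)
        pair = sgddm_pair(ind, P, 0, 1)
        assert sgddm_total(ind, P) == pytest.approx(pair)

    def test_printed_constant_and_term_count(self):
        # J=4, K=4: 54 cross-item terms, constant 2/(12*11) = 1/66
        rng = np.random.default_rng(3)
        X = ResponseMatrix(rng.integers(1, 5, size=(200, 4)), K=4)
        ind = indicator_coding(X)
        P = np.full((200, 4, 3), 0.25)
        values, _ = sgddm_pair_matrix(ind, P)
        item = np.repeat(np.arange(4), 3)
        iu = np.triu_indices(12, k=1)
        cross = item[iu[0]] != item[iu[1]]
        assert cross.sum() == 54
        manual = values[iu][cross].sum() / 66.0
        assert sgddm_total(ind, P) == pytest.approx(manual)
        pair_mean = values[iu][cross].mean()
        assert sgddm_total(ind, P, pair_mean=True) == pytest.approx(pair_mean)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="J >= 2"):
            sgddm_total(np.zeros((5, 1, 3)), np.full((5, 1, 3), 0.25))


class TestPpp:
    def test_predicted_always_larger_gives_one(self):
        assert ppp(np.zeros(10), np.ones(10)) == 1.0

    def test_ties_count_as_exceedance(self):
        v = np.full(7, 0.3)
        assert ppp(v, v.copy()) == 1.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = rng.normal(size=50)
            p = rng.normal(size=50)
            brute = sum(1 for a, b in zip(r, p) if b >= a) / 50
            assert ppp(r, p) == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ppp(np.array([]), np.array([]))


class TestWaic:
    def test_constant_draws_have_zero_penalty(self):
        ll = np.tile(np.log([0.2, 0.5, 0.7]), (4, 1))
        out = waic(ll)
        assert out["p_waic"] == pytest.approx(0.0)
        assert out["waic"] == pytest.approx(-2 * ll[0].sum())

    def test_two_draw_hand_computation(self):
        ll = np.log([[0.5], [0.25]])
        out = waic(ll)
        assert out["lppd"] == pytest.approx(np.log(0.375))
        assert out["p_waic"] == pytest.approx(np.var(ll[:, 0], ddof=1))
        assert out["waic"] == pytest.approx(-2 * (np.log(0.375) - out["p_waic"]))

    def test_deviance_scale_identity(self):
        rng = np.random.default_rng(5)
        ll = rng.normal(-1.0, 0.2, size=(100, 17))
        out = waic(ll)
        assert out["waic"] + 2 * out["elpd_waic"] == pytest.approx(0.0, abs=1e-8)
        assert out["p_waic"] >= 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            waic(np.array([[0.0, -np.inf]]))

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(6)
        ll = rng.normal(-1.0, 0.3, size=(400, 25))
        idata = az.from_dict(
            posterior={"mu": rng.normal(size=(4, 100))},
            log_likelihood={"y": ll.reshape(4, 100, 25)},
        )
        ref = az.waic(idata)
        out = waic(ll)
        # arviz penalizes with the population variance; we follow the sample
        # (n-1) convention, so agreement is to the ddof correction
        correction = (ll.var(axis=0, ddof=1) - ll.var(axis=0, ddof=0)).sum()
        assert out["elpd_waic"] == pytest.approx(float(ref.elpd_waic) - correction, abs=1e-8)
        assert out["p_waic"] == pytest.approx(float(ref.p_waic) + correction, abs=1e-8)


class TestLoo:
    def test_constant_draws(self):
        ll = np.tile(np.log([0.2, 0.5]), (6, 1))
        out = loo(ll)
        assert out["elpd_loo"] == pytest.approx(ll[0].sum())
        assert out["p_loo"] == pytest.approx(0.0, abs=1e-9)

    def test_two_draw_importance_formula(self):
        # with two draws the smoothed weights reduce to the raw ones
        ll = np.log(np.array([[0.5, 0.2], [0.25, 0.4]]))
        out = loo(ll)
        lw = -ll - logsumexp(-ll, axis=0)
        expected = logsumexp(lw + ll, axis=0).sum()
        assert out["elpd_loo"] == pytest.approx(expected)

    def test_lppd_upper_bounds_elpd_loo(self):
        rng = np.random.default_rng(7)
        ll = rng.normal(-2.0, 0.5, size=(300, 40))
        out = loo(ll)
        lppd = (logsumexp(ll, axis=0) - np.log(300)).sum()
        assert out["elpd_loo"] <= lppd
        assert out["loo"] == pytest.approx(-2 * out["elpd_loo"])

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(8)
        ll = rng.normal(-1.0, 0.3, size=(400, 25))
        idata = az.from_dict(
            posterior={"mu": rng.normal(size=(4, 100))},
            log_likelihood={"y": ll.reshape(4, 100, 25)},
        )
        ref = az.loo(idata)
        out = loo(ll)
        # reff differs slightly (arviz uses ESS); agreement to ~0.5%
        assert out["elpd_loo"] == pytest.approx(float(ref.elpd_loo), rel=5e-3)
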