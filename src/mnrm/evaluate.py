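"""Model evaluation: nominal SGDDM, posterior predictive checks, DIC/WAIC/LOO.

The standardized generalized dimensionality discrepancy measure (SGDDM)
treats each (item, category) pair with k < K as a binary pseudo-item
X_ijk = 1{x_ij = k} and measures, for two pseudo-items from different
items, the absolute standardized cross-moment of the model residuals
X - P.  If the model's dimensionality is adequate, residuals of different
items are close to uncorrelated given theta, so realized and
model-predicted SGDDM values overlap; an under-dimensioned model leaves
structure in the residuals and the realized SGDDM exceeds the predicted
one.

The aggregate statistic averages the pairwise values over item pairs
j < j' and all category pairs, scaled by 2 / [J(K-1)(J(K-1)-1)].  Note the
constant counts all pseudo-item pairs while the sum omits within-item
pairs; the printed formula is the default, `pair_mean=True` divides by the
number of summed pairs instead.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import ModelParameters, ResponseMatrix, category_probabilities
from .simulate import LatentState, simulate_responses

__all__ = [
    "indicator_coding",
    "sgddm_pair",
    "sgddm_pair_matrix",
    "sgddm_total",
    "posterior_predictive_sgddm",
    "ppp",
    "waic",
    "loo",
    "dic",
]

_VAR_TOL = 1e-12


def indicator_coding(X: ResponseMatrix) -> np.ndarray:
    """Binary (N, J, K-1) coding; category K maps to an all-zero row."""
    N, J, K = X.N, X.J, X.K
    out = np.zeros((N, J, K - 1))
    idx = X.zero_based
    mask = idx < K - 1
    n_i, j_i = np.nonzero(mask)
    out[n_i, j_i, idx[mask]] = 1.0
    return out


def _as_pseudo(X_ind: np.ndarray) -> np.ndarray:
    """Flatten (N, J, K-1) indicators to (N, J(K-1)) pseudo-items."""
    return X_ind.reshape(X_ind.shape[0], -1)


def _pair_stats(X_ind: np.ndarray, P: np.ndarray):
    """Residual cross-moment and RMS matrices over pseudo-items.

    Returns (values, defined) where ``values[p, q]`` is the pairwise SGDDM
    of pseudo-items p and q and ``defined`` marks pairs whose residual
    variances are both positive.
    """
    Xp, Pp = _as_pseudo(np.asarray(X_ind, float)), _as_pseudo(np.asarray(P, float))
    if Xp.shape != Pp.shape:
        raise ValueError(f"indicator shape {Xp.shape} != probability shape {Pp.shape}")
    N = Xp.shape[0]
    R = Xp - Pp
    cross = np.abs(R.T @ R) / N
    rms = np.sqrt((R**2).mean(axis=0))
    defined = rms > _VAR_TOL
    denom = np.outer(rms, rms)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = cross / denom
    return values, np.outer(defined, defined)


def sgddm_pair(X_ind: np.ndarray, P: np.ndarray, jk: int, j2k2: int) -> float:
    """Pairwise SGDDM of pseudo-items ``jk`` and ``j2k2`` (0-based indices).

    The value is the absolute population-moment correlation of the two
    residual series, hence bounded by 1.  A zero residual variance makes
    the pair undefined and raises rather than silently returning 0.
    """
    values, defined = _pair_stats(X_ind, P)
    if not defined[jk, j2k2]:
        raise ZeroDivisionError(
            f"undefined SGDDM pair ({jk}, {j2k2}): zero residual variance"
        )
    return float(values[jk, j2k2])


def sgddm_pair_matrix(X_ind: np.ndarray, P: np.ndarray):
    """All pairwise SGDDM values and their defined-mask, as matrices."""
    return _pair_stats(X_ind, P)


def _cross_item_pairs(J: int, Km1: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (p, q) with p in item j, q in item j' > j."""
    n = J * Km1
    item = np.repeat(np.arange(J), Km1)
    p, q = np.triu_indices(n, k=1)
    keep = item[p] != item[q]
    return p[keep], q[keep]


def sgddm_total(X_ind: np.ndarray, P: np.ndarray, pair_mean: bool = False) -> float:
    """Aggregate SGDDM over cross-item pseudo-item pairs.

    Default scaling is the printed constant 2/[J(K-1)(J(K-1)-1)];
    ``pair_mean=True`` divides by the number of (defined) summed pairs.
    Undefined pairs are dropped from the sum and reported via a warning
    when present; if every pair is undefined an error is raised.
    """
    X_ind = np.asarray(X_ind, float)
    if X_ind.ndim != 3 or X_ind.shape[1] < 2:
        raise ValueError("need an (N, J, K-1) indicator array with J >= 2 items")
    J, Km1 = X_ind.shape[1], X_ind.shape[2]
    values, defined = _pair_stats(X_ind, P)
    p, q = _cross_item_pairs(J, Km1)
    ok = defined[p, q]
    if not ok.any():
        raise ZeroDivisionError("all SGDDM pairs undefined (zero residual variances)")
    n_undefined = int((~ok).sum())
    if n_undefined:
        warnings.warn(
            f"{n_undefined} of {ok.size} SGDDM pairs undefined; excluded from the sum",
            RuntimeWarning,
            stacklevel=2,
        )
    total = values[p, q][ok].sum()
    if pair_mean:
        return float(total / ok.sum())
    n_pseudo = J * Km1
    return float(2.0 * total / (n_pseudo * (n_pseudo - 1)))


# ---------------------------------------------------------------------------
# posterior predictive check


def posterior_predictive_sgddm(
    draws,
    X: ResponseMatrix,
    thin: int = 500,
    seed: int = 0,
    redraw_theta: bool = False,
    pair_mean: bool = False,
) -> dict:
    """Realized and predicted aggregate SGDDM per (thinned) posterior draw.

    For each retained draw: probabilities come from that draw's (c, a,
    theta); predicted responses are simulated conditional on the draw —
    by default with the same persons' theta (``redraw_theta=True`` instead
    redraws theta from N(0, sigma)).  ``thin`` caps the number of draws
    used, taken evenly spaced over the retained sequence.
    """
    L = draws.L
    n_use = min(thin, L) if thin else L
    idx = np.unique(np.linspace(0, L - 1, n_use).astype(int))
    X_ind = indicator_coding(X)
    ss = np.random.SeedSequence(seed)
    realized = np.empty(idx.size)
    predicted = np.empty(idx.size)
    for out_i, (l, child) in enumerate(zip(idx, ss.spawn(idx.size))):
        params = draws.parameters_at(int(l))
        rng_children = child.spawn(2)
        if redraw_theta:
            rng = np.random.default_rng(rng_children[0])
            theta = rng.standard_normal((X.N, draws.D)) * draws.sigma[l]
        else:
            theta = draws.theta[l]
        P = category_probabilities(params, theta)[:, :, : X.K - 1]
        X_pred = simulate_responses(
            params, LatentState(theta, draws.sigma[l]), seed=rng_children[1]
        )
        realized[out_i] = sgddm_total(X_ind, P, pair_mean=pair_mean)
        predicted[out_i] = sgddm_total(indicator_coding(X_pred), P, pair_mean=pair_mean)
    return {"realized": realized, "predicted": predicted, "draw_index": idx}


def ppp(realized: np.ndarray, predicted: np.ndarray) -> float:
    """Posterior predictive p-value: share of draws with predicted >= realized.

    Ties count as exceedance.
    """
    realized = np.asarray(realized, float)
    predicted = np.asarray(predicted, float)
    if realized.shape != predicted.shape or realized.size == 0:
        raise ValueError("realized and predicted must be equal-length, non-empty")
    return float(np.mean(predicted >= realized))


# ---------------------------------------------------------------------------
# information criteria


def _check_loglik(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (L, N)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    return ll


def waic(pointwise_loglik: np.ndarray) -> dict:
    """Widely applicable information criterion on the deviance scale.

    lppd_i = log mean_l exp(ll_li); the effective-parameter penalty is the
    posterior variance of ll_li per unit; waic = -2 (lppd - p_waic).
    """
    from scipy.special import logsumexp

    ll = _check_loglik(pointwise_loglik)
    L = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(L)
    p_i = ll.var(axis=0, ddof=1) if L > 1 else np.zeros(ll.shape[1])
    elpd = float((lppd_i - p_i).sum())
    return {"elpd_waic": elpd, "p_waic": float(p_i.sum()), "waic": -2.0 * elpd,
            "lppd": float(lppd_i.sum())}


def loo(pointwise_loglik: np.ndarray, reff: float = 1.0) -> dict:
    """PSIS leave-one-out cross-validation on the deviance scale.

    Importance weights 1/p(y_i | theta_l) are Pareto-smoothed per unit
    (arviz's psislw); units with shape diagnostic k-hat > 0.7 are reported,
    not fatal.
    """
    from scipy.special import logsumexp

    import arviz as az

    ll = _check_loglik(pointwise_loglik)
    lppd_i = logsumexp(ll, axis=0) - np.log(ll.shape[0])
    if ll.shape[0] > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw, khat = az.psislw(-ll.T, reff=reff)
        lw = np.asarray(lw)
        khat = np.asarray(khat)
        elpd_i = logsumexp(lw + ll.T, axis=1)
    else:
        elpd_i = ll[0]
        khat = np.zeros(ll.shape[1])
    elpd = float(elpd_i.sum())
    return {
        "elpd_loo": elpd,
        "p_loo": float(lppd_i.sum() - elpd),
        "loo": -2.0 * elpd,
        "pareto_k": khat,
        "n_high_k": int((khat > 0.7).sum()),
    }


def dic(draws, X: ResponseMatrix) -> dict:
    """Deviance information criterion with the conditional (theta-inclusive)
    deviance and plug-in at posterior means of (c, a, theta)."""
    from .model import log_likelihood

    if draws.L < 2:
        raise ValueError("DIC needs at least two draws")
    ll = _results_total_loglik(draws, X)
    mean_dev = float(np.mean(-2.0 * ll))
    point = ModelParameters(
        draws.intercepts.mean(axis=0),
        draws.slopes.mean(axis=0),
        "simple",
        reference_category=draws.pattern.reference_category,
    )
    dev_hat = -2.0 * log_likelihood(point, draws.theta.mean(axis=0), X)["total"]
    p_d = mean_dev - dev_hat
    return {"dic": mean_dev + p_d, "p_d": p_d, "mean_deviance": mean_dev}


def _results_total_loglik(draws, X: ResponseMatrix, chunk: int = 64) -> np.ndarray:
    """(L,) total log-likelihood per draw, conditional on the draw's theta."""
    L, N, J, K = draws.L, X.N, X.J, X.K
    flat = np.arange(N * J) * K + X.zero_based.ravel()
    out = np.empty(L)
    for lo in range(0, L, chunk):
        hi = min(lo + chunk, L)
        z = (
            np.einsum("lnd,ljkd->lnjk", draws.theta[lo:hi], draws.slopes[lo:hi])
            + draws.intercepts[lo:hi, None, :, :]
        )
        m = z.max(axis=3)
        lse = m + np.log(np.exp(z - m[..., None]).sum(axis=3))
        z_obs = z.reshape(hi - lo, -1)[:, flat].reshape(hi - lo, N, J)
        out[lo:hi] = (z_obs - lse).sum(axis=(1, 2))
    return out
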