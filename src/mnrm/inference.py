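"""Bayesian estimation of the MNRM: model class, posterior, results.

``NominalResponseModel`` holds a response matrix, a dimensionality and a
prior specification; ``fit`` samples the joint posterior of the intercepts,
the free slopes, the trait standard deviations and the person traits with
Hamiltonian Monte Carlo, under the echelon identification pattern (fixed
unit slope per dimension, fixed zeros above the diagonal of the stacked
slope matrix, reference category K).  The fixed unit slopes set the
orientation and scale of each trait; the trait SDs sigma_d are free to
compensate, so the parameter count is unchanged relative to fixing
sigma_d = 1.

The resulting ``NominalResponseResults`` object carries the retained draws
and exposes EAP summaries, split-chain R-hat, pointwise log-likelihoods and
the model-evaluation statistics (SGDDM posterior predictive check, DIC,
WAIC, PSIS-LOO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmc import HMCDiagnostics, nuts_sample
from .model import (
    IdentificationPattern,
    ModelParameters,
    ResponseMatrix,
    echelon_pattern,
)
from .priors import PriorSpec

__all__ = [
    "PosteriorDraws",
    "NominalResponseModel",
    "NominalResponseResults",
    "eap_estimates",
    "rhat",
]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of (c, a, sigma, theta) with chain labels.

    Fixed pattern entries (zeros, unit slopes, reference category) are
    constant across draws.  ``L`` equals chains x (iterations - warmup).
    """

    intercepts: np.ndarray  # (L, J, K)
    slopes: np.ndarray  # (L, J, K, D)
    sigma: np.ndarray  # (L, D)
    theta: np.ndarray  # (L, N, D)
    chain: np.ndarray  # (L,) int labels
    pattern: IdentificationPattern
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.intercepts.shape[0]

    @property
    def J(self) -> int:
        return self.intercepts.shape[1]

    @property
    def K(self) -> int:
        return self.intercepts.shape[2]

    @property
    def D(self) -> int:
        return self.slopes.shape[3]

    @property
    def N(self) -> int:
        return self.theta.shape[1]

    def n_chains(self) -> int:
        return int(len(np.unique(self.chain)))

    def parameters_at(self, l: int) -> ModelParameters:
        """Structured parameters of a single draw (simple constraints)."""
        return ModelParameters(
            self.intercepts[l],
            self.slopes[l],
            "simple",
            reference_category=self.pattern.reference_category,
        )

    def free_parameter_frame(self, include_theta: bool = False) -> pd.DataFrame:
        """(L x P) frame of free parameters with 1-based names like a[1,2,1]."""
        cols: dict[str, np.ndarray] = {}
        fc = self.pattern.free_intercepts
        for j, k in np.argwhere(fc):
            cols[f"c[{j + 1},{k + 1}]"] = self.intercepts[:, j, k]
        fa = self.pattern.free_slopes
        for j, k, d in np.argwhere(fa):
            cols[f"a[{j + 1},{k + 1},{d + 1}]"] = self.slopes[:, j, k, d]
        for d in range(self.D):
            cols[f"sigma[{d + 1}]"] = self.sigma[:, d]
        if include_theta:
            for i in range(self.N):
                for d in range(self.D):
                    cols[f"theta[{i + 1},{d + 1}]"] = self.theta[:, i, d]
        return pd.DataFrame(cols)


class _Posterior:
    """Flat-vector view of the unconstrained posterior with analytic gradient.

    Layout of the unconstrained vector: free intercepts (on the prior's
    unconstrained axis), free slopes, log sigma, eta (row-major).  Traits
    are non-centered, theta_id = sigma_d * eta_id with eta_id ~ N(0, 1):
    each person contributes only J responses, so theta_i is weakly informed
    and the centered prior geometry (Neal's funnel) mixes poorly, biasing
    sigma low along the sigma-versus-slope-scale ridge that only the fixed
    unit slope pins down.
    """

    def __init__(self, X: ResponseMatrix, D: int, priors: PriorSpec,
                 pattern: IdentificationPattern):
        self.X = X
        self.D = D
        self.priors = priors
        self.pattern = pattern
        self.N, self.J, self.K = X.N, X.J, X.K
        self.free_c = pattern.free_intercepts  # (J, K)
        self.free_a = pattern.free_slopes  # (J, K, D)
        self.fixed_a = pattern.fixed_values()  # (J, K, D) of 0/1
        self.n_c = int(self.free_c.sum())
        self.n_a = int(self.free_a.sum())
        self.dim = self.n_c + self.n_a + D + self.N * D
        self._cj, self._ck = np.nonzero(self.free_c)
        self._aj, self._ak, self._ad = np.nonzero(self.free_a)
        self._x0 = X.zero_based  # (N, J)
        self._flat_obs = (
            np.arange(self.N * self.J) * self.K + self._x0.ravel()
            if self.N
            else np.empty(0, dtype=int)
        )

    # -- packing ---------------------------------------------------------
    def split(self, w: np.ndarray):
        n_c, n_a, D, N = self.n_c, self.n_a, self.D, self.N
        return (
            w[:n_c],
            w[n_c : n_c + n_a],
            w[n_c + n_a : n_c + n_a + D],
            w[n_c + n_a + D :].reshape(N, D),
        )

    def constrain(self, w: np.ndarray):
        """Map an unconstrained vector to (c, a, sigma, theta)."""
        cu, au, s, eta = self.split(w)
        c = np.zeros((self.J, self.K))
        c[self._cj, self._ck] = self.priors.intercept.transform(cu)
        a = self.fixed_a.copy()
        a[self._aj, self._ak, self._ad] = self.priors.slope.transform(au)
        sigma = np.exp(s)
        return c, a, sigma, eta * sigma[None, :]

    # -- target ----------------------------------------------------------
    def logp_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        cu, au, s, eta = self.split(w)
        c = np.zeros((self.J, self.K))
        c[self._cj, self._ck] = pr.intercept.transform(cu)
        a = self.fixed_a.copy()
        a[self._aj, self._ak, self._ad] = pr.slope.transform(au)
        sigma = np.exp(s)
        theta = eta * sigma[None, :]

        grad = np.empty_like(w)
        g_cu, g_au, g_s, g_eta = self.split(grad)

        if self.N:
            A2 = a.reshape(self.J * self.K, self.D)
            z = theta @ A2.T + c.ravel()[None, :]  # (N, J*K)
            z3 = z.reshape(self.N, self.J, self.K)
            m = z3.max(axis=2)
            e = np.exp(z3 - m[:, :, None])
            tot = e.sum(axis=2)
            # log-likelihood of the observed categories
            z_obs = z.ravel()[self._flat_obs].reshape(self.N, self.J)
            loglik = float((z_obs - m - np.log(tot)).sum())
            # residuals X - P drive every likelihood gradient
            R = -(e / tot[:, :, None])
            R2 = R.reshape(self.N * self.J, self.K)
            R2[np.arange(self.N * self.J), self._x0.ravel()] += 1.0
            Rf = R2.reshape(self.N, self.J * self.K)
            g_c_full = Rf.sum(axis=0).reshape(self.J, self.K)
            g_a_full = (Rf.T @ theta).reshape(self.J, self.K, self.D)
            g_theta_lik = Rf @ A2  # dloglik/dtheta, (N, D)
        else:
            loglik = 0.0
            g_c_full = np.zeros((self.J, self.K))
            g_a_full = np.zeros((self.J, self.K, self.D))
            g_theta_lik = np.zeros((0, self.D))

        # priors on item parameters (chain rule through the transform)
        g_cu[:] = g_c_full[self._cj, self._ck] * pr.intercept.dtransform(cu)
        g_cu += pr.intercept.dlogp_u(cu)
        g_au[:] = g_a_full[self._aj, self._ak, self._ad] * pr.slope.dtransform(au)
        g_au += pr.slope.dlogp_u(au)

        # non-centered traits: theta = sigma * eta, eta ~ N(0, 1)
        g_eta[:] = g_theta_lik * sigma[None, :] - eta
        g_s[:] = (g_theta_lik * theta).sum(axis=0)  # dtheta/ds = theta
        g_s -= (s - pr.sigma_mu) / pr.sigma_tau**2

        logp = (
            loglik
            + float(pr.intercept.logp_u(cu).sum())
            + float(pr.slope.logp_u(au).sum())
            - 0.5 * float((((s - pr.sigma_mu) / pr.sigma_tau) ** 2).sum())
            - 0.5 * float((eta**2).sum())
        )
        return logp, grad

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        w = np.empty(self.dim)
        cu, au, s, eta = self.split(w)
        cu[:] = rng.normal(0.0, jitter, self.n_c)
        au[:] = rng.normal(0.0, jitter, self.n_a)
        s[:] = rng.normal(0.0, 0.2, self.D)
        eta[:] = rng.normal(0.0, jitter, (self.N, self.D))
        return w

    # -- orientation-basin comparison --------------------------------------
    def _quad_grid(self):
        if not hasattr(self, "_grid_cache"):
            nodes, weights = np.polynomial.hermite_e.hermegauss(
                31 if self.D == 1 else 13
            )
            weights = weights / weights.sum()
            if self.D == 1:
                grid, logw = nodes[:, None], np.log(weights)
            else:
                g1, g2 = np.meshgrid(nodes, nodes, indexing="ij")
                grid = np.column_stack([g1.ravel(), g2.ravel()])
                logw = np.log(np.outer(weights, weights).ravel())
            onehot = np.zeros((self.N, self.J, self.K))
            n_i, j_i = np.meshgrid(np.arange(self.N), np.arange(self.J), indexing="ij")
            onehot[n_i.ravel(), j_i.ravel(), self._x0.ravel()] = 1.0
            self._grid_cache = (grid, logw, onehot)
        return self._grid_cache

    def _marginal_objective(self, v: np.ndarray):
        """Negative theta-marginalized log posterior of (c, a, log sigma),
        with its analytic gradient (Gauss-Hermite quadrature, D <= 2).

        The gradient of the marginal likelihood is the node-posterior-
        weighted softmax residual, accumulated per parameter.
        """
        from scipy.special import logsumexp

        pr = self.priors
        grid, logw, onehot = self._quad_grid()
        c = np.zeros((self.J, self.K))
        c[self._cj, self._ck] = v[: self.n_c]
        a = self.fixed_a.copy()
        a[self._aj, self._ak, self._ad] = v[self.n_c : self.n_c + self.n_a]
        s = v[self.n_c + self.n_a :]
        sigma = np.exp(s)

        A2 = a.reshape(self.J * self.K, self.D)
        th = grid * sigma  # (Q, D)
        z3 = (th @ A2.T + c.ravel()[None, :]).reshape(-1, self.J, self.K)
        lse = logsumexp(z3, axis=2)
        logp = z3 - lse[:, :, None]
        lp_qn = logp[:, np.arange(self.J)[None, :], self._x0].sum(axis=2)  # (Q, N)
        Li = logsumexp(lp_qn + logw[:, None], axis=0)  # (N,)
        W = np.exp(lp_qn + logw[:, None] - Li[None, :])  # (Q, N) node posteriors
        P = np.exp(logp)
        # E[q, j, k] = sum_n W[q, n] (1{x_nj = k} - P[q, j, k])
        E = np.einsum("qn,njk->qjk", W, onehot) - W.sum(axis=1)[:, None, None] * P
        grad_c = E.sum(axis=0)
        grad_a = np.einsum("qjk,qd->jkd", E, th)
        grad_s = np.einsum("qjk,jkd,qd->d", E, a, th)

        logpost = (
            float(Li.sum())
            + float(pr.intercept.logpdf(c[self._cj, self._ck]).sum())
            + float(pr.slope.logpdf(a[self._aj, self._ak, self._ad]).sum())
            - 0.5 * float((((s - pr.sigma_mu) / pr.sigma_tau) ** 2).sum())
        )
        grad = np.empty_like(v)
        grad[: self.n_c] = grad_c[self._cj, self._ck] + pr.intercept.dlogpdf(
            c[self._cj, self._ck]
        )
        grad[self.n_c : self.n_c + self.n_a] = grad_a[
            self._aj, self._ak, self._ad
        ] + pr.slope.dlogpdf(a[self._aj, self._ak, self._ad])
        grad[self.n_c + self.n_a :] = grad_s - (s - pr.sigma_mu) / pr.sigma_tau**2
        return -logpost, -grad

    def basin_score(self, w: np.ndarray) -> float:
        """Marginal-posterior height of a mode's orientation basin.

        The joint density at a mode ignores the theta-integration volume and
        can rank reflected-orientation basins incorrectly, so basins are
        compared on the theta-marginalized posterior, maximized over
        (c, a, sigma) within the basin.  Exact quadrature for D <= 2; a
        Laplace plug-in profiled along the scale ridge for higher D.
        """
        if self.N == 0:
            return 0.0
        c, a, sigma, _ = self.constrain(w)
        if self.D <= 2:
            from scipy.optimize import minimize

            v0 = np.concatenate(
                [c[self._cj, self._ck], a[self._aj, self._ak, self._ad], np.log(sigma)]
            )
            lo, hi = self.priors.slope.bounds
            bounds = (
                [self.priors.intercept.bounds] * self.n_c
                + [(lo, hi)] * self.n_a
                + [(None, None)] * self.D
            )
            if all(b == (None, None) for b in bounds):
                bounds = None
            res = minimize(
                self._marginal_objective, v0, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 2000},
            )
            return float(-res.fun)
        best = -np.inf
        for lam in np.geomspace(0.45, 1.6, 9):
            a_s = a.copy()
            a_s[self.free_a] = a[self.free_a] / lam
            sig_s = sigma * lam
            score = (
                self._laplace_marginal_loglik(c, a_s, sig_s)
                + float(self.priors.intercept.logpdf(c[self.free_c]).sum())
                + float(self.priors.slope.logpdf(a_s[self.free_a]).sum())
                - 0.5
                * float(
                    (((np.log(sig_s) - self.priors.sigma_mu) / self.priors.sigma_tau) ** 2).sum()
                )
            )
            best = max(best, score)
        return best

    def _laplace_marginal_loglik(self, c: np.ndarray, a: np.ndarray,
                                 sigma: np.ndarray) -> float:
        """log p(X | c, a, sigma) by per-person Laplace approximation.

        The person-level problem is concave, so batched Newton steps find
        each conditional mode; used for D > 2 where tensor quadrature is
        too coarse or too costly.
        """
        if self.N == 0:
            return 0.0
        A2 = a.reshape(self.J * self.K, self.D)
        eye = np.eye(self.D)
        theta = self._conditional_theta_mode(c, a, sigma)
        z = theta @ A2.T + c.ravel()[None, :]
        z3 = z.reshape(self.N, self.J, self.K)
        m = z3.max(axis=2)
        lse = m + np.log(np.exp(z3 - m[:, :, None]).sum(axis=2))
        z_obs = z.ravel()[self._flat_obs].reshape(self.N, self.J)
        loglik_i = (z_obs - lse).sum(axis=1)
        P = np.exp(z3 - lse[:, :, None])
        m1 = np.einsum("njk,jkd,jke->nde", P, a, a)
        mv = np.einsum("njk,jkd->njd", P, a)
        H = m1 - np.einsum("njd,nje->nde", mv, mv) + eye / sigma**2
        _, logdet = np.linalg.slogdet(H)
        return float(
            (
                loglik_i
                - float(np.log(sigma).sum())
                - 0.5 * (theta**2 / sigma**2).sum(axis=1)
                - 0.5 * logdet
            ).sum()
        )

    def _conditional_theta_mode(self, c: np.ndarray, a: np.ndarray,
                                sigma: np.ndarray) -> np.ndarray:
        """Per-person conditional posterior mode of theta given (c, a, sigma).

        The person-level objective is concave; batched Newton steps converge
        in a handful of iterations.
        """
        A2 = a.reshape(self.J * self.K, self.D)
        eye = np.eye(self.D)
        theta = np.zeros((self.N, self.D))
        for _ in range(50):
            z = theta @ A2.T + c.ravel()[None, :]
            z3 = z.reshape(self.N, self.J, self.K)
            z3 = z3 - z3.max(axis=2, keepdims=True)
            P = np.exp(z3)
            P /= P.sum(axis=2, keepdims=True)
            R = -P.reshape(self.N * self.J, self.K)
            R[np.arange(self.N * self.J), self._x0.ravel()] += 1.0
            grad = R.reshape(self.N, self.J * self.K) @ A2 - theta / sigma**2
            m1 = np.einsum("njk,jkd,jke->nde", P, a, a)
            mv = np.einsum("njk,jkd->njd", P, a)
            H = m1 - np.einsum("njd,nje->nde", mv, mv) + eye / sigma**2
            step = np.linalg.solve(H, grad[..., None])[..., 0]
            theta = theta + step
            if np.abs(step).max() < 1e-8:
                break
        return theta

    def orientation_signature(self, w: np.ndarray, reference: np.ndarray) -> np.ndarray:
        """Per-dimension sign of the free-slope alignment with a reference."""
        _, au, _, _ = self.split(w)
        _, au_ref, _, _ = self.split(reference)
        out = np.empty(self.D)
        for d in range(self.D):
            sel = self._ad == d
            out[d] = np.sign(float(au[sel] @ au_ref[sel])) or 1.0
        return out

    def map_point(self, rng: np.random.Generator, restarts: int = 2) -> np.ndarray:
        """Mode of the fixed-scale joint posterior, oriented by marginal mass.

        The posterior is multimodal: reversing a trait's orientation (and
        the signs of its slopes) leaves everything but the fixed unit slope
        intact, so a minor reflected mode exists next to the dominant one.
        For D <= 2 the mode of the theta-marginalized posterior is found by
        L-BFGS with a per-dimension reflection hill-climb (the marginal is
        free of the joint-mode degeneracies in which eta overfits every
        response), and eta is set to each person's conditional mode.  For
        D > 2 the joint mode is found with log sigma tethered to 0 and
        basins are ranked by a Laplace-marginal score.
        """
        return self.map_candidates(rng, restarts, top=1)[0][0]

    def map_candidates(self, rng: np.random.Generator, restarts: int = 2,
                       top: int = 2) -> list[tuple[np.ndarray, float]]:
        """Top orientation-basin modes as (joint vector, score) pairs.

        For D <= 2 the score is the basin's theta-marginalized log posterior
        maximum, so score gaps are interpretable as posterior odds between
        basins; for D > 2 a single candidate is returned.
        """
        from scipy.optimize import minimize

        if self.D <= 2 and self.N > 0:
            return self._marginal_map_point(rng, restarts, top=top)

        n0 = self.n_c + self.n_a

        def objective(w):
            lp, g = self.logp_grad(w)
            s = w[n0 : n0 + self.D]
            lp -= 1e4 * float(s @ s)
            g[n0 : n0 + self.D] -= 2e4 * s
            return -lp, -g

        def optimize(w0):
            res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                           options={"maxiter": 3000, "maxfun": 6000})
            return np.asarray(res.x), float(-res.fun)

        best, best_lp = None, -np.inf
        for _ in range(max(1, restarts)):
            x, lp = optimize(self.initial_point(rng, jitter=0.3))
            if lp > best_lp:
                best, best_lp = x, lp

        # hill-climb over per-dimension reflections, ranking basins by their
        # theta-marginalized posterior height
        best_marg = self.basin_score(best)
        improved = True
        while improved:
            improved = False
            for d in range(self.D):
                cand = best.copy()
                cu, au, s, eta = self.split(cand)
                au[self._ad == d] *= -1.0
                eta[:, d] *= -1.0
                x, _ = optimize(cand)
                marg = self.basin_score(x)
                if marg > best_marg + 1e-6:
                    best, best_marg = x, marg
                    improved = True
        return [(best, best_marg)]

    def _marginal_map_point(self, rng: np.random.Generator, restarts: int,
                            top: int = 1) -> list[tuple[np.ndarray, float]]:
        """Modes of the theta-marginalized posterior, reflection-aware (D <= 2).

        Returns up to ``top`` distinct local modes as (joint vector, marginal
        log-posterior) pairs, best first.  Distinctness is judged by the sign
        pattern of the free slopes, which is what separates the reflected and
        partially reflected basins.
        """
        from scipy.optimize import minimize

        lo_c, hi_c = self.priors.intercept.bounds
        lo_a, hi_a = self.priors.slope.bounds
        bounds = (
            [(lo_c, hi_c)] * self.n_c
            + [(lo_a, hi_a)] * self.n_a
            + [(None, None)] * self.D
        )
        if all(b == (None, None) for b in bounds):
            bounds = None

        found: dict[tuple, tuple[np.ndarray, float]] = {}

        def signature(v):
            au = v[self.n_c : self.n_c + self.n_a]
            return tuple(np.where(np.abs(au) < 0.02, 0, np.sign(au)).astype(int))

        def optimize(v0):
            res = minimize(self._marginal_objective, v0, jac=True,
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 2000})
            x, lp = np.asarray(res.x), float(-res.fun)
            sig = signature(x)
            if sig not in found or lp > found[sig][1]:
                found[sig] = (x, lp)
            return x, lp

        best, best_lp = None, -np.inf
        for _ in range(max(1, restarts)):
            v0 = np.concatenate([
                rng.normal(0.0, 0.3, self.n_c),
                rng.normal(0.0, 0.3, self.n_a),
                rng.normal(0.0, 0.1, self.D),
            ])
            x, lp = optimize(v0)
            if lp > best_lp:
                best, best_lp = x, lp

        # hill-climb over sign-flip moves: whole-dimension reflections plus
        # per-item flips — partial-flip local modes (one item's slopes
        # oriented against the rest) are not reachable by full reflections
        moves = [self._ad == d for d in range(self.D)]
        moves += [
            (self._ad == d) & (self._aj == j)
            for d in range(self.D)
            for j in range(self.J)
        ]
        improved = True
        while improved:
            improved = False
            for mask in moves:
                if not mask.any():
                    continue
                cand = best.copy()
                au = cand[self.n_c : self.n_c + self.n_a]
                au[mask] *= -1.0
                x, lp = optimize(cand)
                if lp > best_lp + 1e-6:
                    best, best_lp = x, lp
                    improved = True

        ranked = sorted(found.values(), key=lambda t: -t[1])[:top]
        return [(self._assemble_joint(v), lp) for v, lp in ranked]

    def _assemble_joint(self, v: np.ndarray) -> np.ndarray:
        """Joint vector from a marginal-MAP point, eta at conditional modes."""
        c = np.zeros((self.J, self.K))
        c[self._cj, self._ck] = v[: self.n_c]
        a = self.fixed_a.copy()
        a[self._aj, self._ak, self._ad] = v[self.n_c : self.n_c + self.n_a]
        s = v[self.n_c + self.n_a :]
        sigma = np.exp(s)
        theta = self._conditional_theta_mode(c, a, sigma)
        w = np.empty(self.dim)
        cu, au, sw, eta = self.split(w)
        cu[:] = self.priors.intercept.inverse(v[: self.n_c])
        au[:] = self.priors.slope.inverse(v[self.n_c : self.n_c + self.n_a])
        sw[:] = s
        eta[:] = theta / sigma[None, :]
        return w


class NominalResponseModel:
    """Multidimensional nominal response model for unordered categories.

    Parameters
    ----------
    responses : ResponseMatrix or integer array (N, J), categories 1..K
    n_dims : int
        Number of latent dimensions D; requires J(K-1) >= D.
    priors : PriorSpec, optional
        Defaults to the informative preset (normal(0, 3) item parameters,
        lognormal(0, 0.5) trait SDs).
    pattern : IdentificationPattern, optional
        Defaults to the echelon pattern with reference category K.
    """

    def __init__(
        self,
        responses: ResponseMatrix | np.ndarray,
        n_dims: int,
        priors: PriorSpec | None = None,
        pattern: IdentificationPattern | None = None,
    ):
        if not isinstance(responses, ResponseMatrix):
            responses = ResponseMatrix(np.asarray(responses))
        if responses.K < 2:
            raise ValueError("need at least two categories")
        if n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if responses.J * (responses.K - 1) < n_dims:
            raise ValueError(
                f"J(K-1) = {responses.J * (responses.K - 1)} rows cannot carry "
                f"D = {n_dims} dimensions"
            )
        self.data = responses
        self.n_dims = int(n_dims)
        self.priors = priors if priors is not None else PriorSpec.informative()
        self.pattern = (
            pattern
            if pattern is not None
            else echelon_pattern(responses.J, responses.K, n_dims)
        )
        self._posterior = _Posterior(self.data, self.n_dims, self.priors, self.pattern)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, n_dims: int, priors: PriorSpec | None = None
    ) -> "NominalResponseModel":
        X = ResponseMatrix(frame.to_numpy(), item_names=list(map(str, frame.columns)))
        return cls(X, n_dims, priors=priors)

    def fit(
        self,
        chains: int = 4,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int = 0,
        target_accept: float = 0.8,
        max_tree_depth: int = 9,
    ) -> "NominalResponseResults":
        """Sample the posterior; retains the post-warmup halves of all chains."""
        if warmup >= iterations:
            raise ValueError("warmup must be smaller than iterations")
        if chains < 1:
            raise ValueError("need at least one chain")
        post = self._posterior
        ss = np.random.SeedSequence(seed)
        kept_per_chain = iterations - warmup
        draws = np.empty((chains * kept_per_chain, post.dim))
        chain_labels = np.repeat(np.arange(chains), kept_per_chain)
        diags: list[HMCDiagnostics] = []
        mode_rng = np.random.default_rng(ss.spawn(1)[0])
        candidates = post.map_candidates(mode_rng, top=2)
        # when two orientation basins have nearly equal marginal mass the
        # honest posterior is their mixture: split the chains between them;
        # an equal split approximates the mixture well only near 1:1 odds,
        # hence the tight gap threshold (0.5 nats is about 1.6:1)
        modes = [candidates[0][0]]
        if (
            chains > 1
            and len(candidates) > 1
            and candidates[0][1] - candidates[1][1] < 0.5
        ):
            modes.append(candidates[1][0])
        orientation_retries = 0
        for ch, child in enumerate(ss.spawn(chains)):
            x_mode = modes[ch % len(modes)]
            # a chain can slip out of its assigned basin while the warmup
            # adaptation walks down the trait-scale ridge, even though that
            # basin carries most of the marginal mass; resample such chains
            # from a fresh jitter (bounded retries, last attempt kept)
            for attempt_ss in child.spawn(3):
                rng = np.random.default_rng(attempt_ss)
                x0 = x_mode + rng.normal(0.0, 0.1, post.dim)
                kept, diag = nuts_sample(
                    post.logp_grad,
                    x0,
                    iterations,
                    warmup,
                    rng,
                    target_accept=target_accept,
                    max_tree_depth=max_tree_depth,
                )
                signature = post.orientation_signature(kept.mean(axis=0), x_mode)
                if np.all(signature > 0):
                    break
                orientation_retries += 1
            draws[ch * kept_per_chain : (ch + 1) * kept_per_chain] = kept
            diags.append(diag)
        mean_accept = float(np.mean([d.accept_rate for d in diags]))
        if mean_accept < 0.1:
            raise RuntimeError(
                f"sampler failed: mean acceptance {mean_accept:.3f}; "
                f"diagnostics per chain: {diags}"
            )

        L = draws.shape[0]
        cu = draws[:, : post.n_c]
        au = draws[:, post.n_c : post.n_c + post.n_a]
        s = draws[:, post.n_c + post.n_a : post.n_c + post.n_a + post.D]
        eta = draws[:, post.n_c + post.n_a + post.D :].reshape(L, post.N, post.D)
        theta = eta * np.exp(s)[:, None, :]
        intercepts = np.zeros((L, post.J, post.K))
        intercepts[:, post._cj, post._ck] = self.priors.intercept.transform(cu)
        slopes = np.broadcast_to(
            post.fixed_a, (L, post.J, post.K, post.D)
        ).copy()
        slopes[:, post._aj, post._ak, post._ad] = self.priors.slope.transform(au)
        pd_draws = PosteriorDraws(
            intercepts=intercepts,
            slopes=slopes,
            sigma=np.exp(s),
            theta=theta,
            chain=chain_labels,
            pattern=self.pattern,
            meta={
                "chains": chains,
                "iterations": iterations,
                "warmup": warmup,
                "seed": seed,
                "priors": self.priors.name,
                "accept_rate": mean_accept,
                "step_sizes": [d.step_size for d in diags],
                "divergences": int(sum(d.divergences for d in diags)),
                "orientation_retries": orientation_retries,
                "basins_used": len(modes),
                "basin_gap": (
                    float(candidates[0][1] - candidates[1][1])
                    if len(candidates) > 1
                    else None
                ),
            },
        )
        return NominalResponseResults(self, pd_draws)


# ---------------------------------------------------------------------------
# posterior summaries


def eap_estimates(draws: PosteriorDraws) -> dict:
    """Expected a-posteriori (posterior mean) estimates and posterior SDs.

    SDs use the sample (n-1) convention; fixed pattern entries therefore
    report SD exactly 0.  Returns structured point estimates under simple
    constraints plus matching SD tables and trait summaries.
    """
    if draws.L < 2:
        raise ValueError("need at least two draws for posterior summaries")
    point = ModelParameters(
        draws.intercepts.mean(axis=0),
        draws.slopes.mean(axis=0),
        "simple",
        reference_category=draws.pattern.reference_category,
    )
    return {
        "point": point,
        "posterior_sd": {
            "intercepts": draws.intercepts.std(axis=0, ddof=1),
            "slopes": draws.slopes.std(axis=0, ddof=1),
            "sigma": draws.sigma.std(axis=0, ddof=1),
            "theta": draws.theta.std(axis=0, ddof=1),
        },
        "sigma": draws.sigma.mean(axis=0),
        "theta": draws.theta.mean(axis=0),
    }


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``x`` has shape (chains, n); each chain is halved before computing the
    classic between/within variance ratio.
    """
    m, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B_over_n <= 0 else float("inf")
    var_plus = (half - 1) / half * W + B_over_n
    return float(np.sqrt(var_plus / W))


def rhat(draws: PosteriorDraws, include_theta: bool = False,
         threshold: float = 1.05) -> pd.Series:
    """Split-chain R-hat per free parameter (requires >= 2 chains).

    Values near 1 indicate the chains agree; parameters exceeding
    ``threshold`` are flagged in the returned Series' attrs.
    """
    n_chains = draws.n_chains()
    if n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    frame = draws.free_parameter_frame(include_theta=include_theta)
    per_chain_n = draws.L // n_chains
    out = {}
    for name, col in frame.items():
        x = col.to_numpy().reshape(n_chains, per_chain_n)
        out[name] = _split_rhat(x)
    series = pd.Series(out, name="rhat")
    series.attrs["flagged"] = list(series.index[series > threshold])
    return series


class NominalResponseResults:
    """Posterior draws plus summaries and model-evaluation statistics."""

    def __init__(self, model: NominalResponseModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- summaries --------------------------------------------------------
    def eap(self) -> dict:
        return eap_estimates(self.draws)

    def rhat(self, include_theta: bool = False) -> pd.Series:
        return rhat(self.draws, include_theta=include_theta)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and R-hat for every free parameter."""
        frame = self.draws.free_parameter_frame()
        table = pd.DataFrame(
            {"mean": frame.mean(), "sd": frame.std(ddof=1)}
        )
        try:
            table["rhat"] = self.rhat()
        except ValueError:
            table["rhat"] = np.nan
        return table

    # -- pointwise likelihood (feeds WAIC / LOO) --------------------------
    def pointwise_loglik(self, chunk: int = 64) -> np.ndarray:
        """(L, N) per-person log-likelihoods, conditional on each draw's theta."""
        d = self.draws
        X0 = self.model.data.zero_based
        L, N, J, K = d.L, d.N, d.J, d.K
        out = np.empty((L, N))
        flat = np.arange(N * J) * K + X0.ravel()
        for lo in range(0, L, chunk):
            hi = min(lo + chunk, L)
            z = (
                np.einsum("lnd,ljkd->lnjk", d.theta[lo:hi], d.slopes[lo:hi])
                + d.intercepts[lo:hi, None, :, :]
            )
            m = z.max(axis=3)
            lse = m + np.log(np.exp(z - m[..., None]).sum(axis=3))
            z_obs = z.reshape(hi - lo, -1)[:, flat].reshape(hi - lo, N, J)
            out[lo:hi] = (z_obs - lse).sum(axis=2)
        return out

    # -- evaluation statistics --------------------------------------------
    def waic(self) -> dict:
        from .evaluate import waic

        return waic(self.pointwise_loglik())

    def loo(self) -> dict:
        from .evaluate import loo

        return loo(self.pointwise_loglik())

    def dic(self) -> dict:
        from .evaluate import dic

        return dic(self.draws, self.model.data)

    def sgddm_ppc(self, thin: int = 500, seed: int = 0) -> dict:
        """Realized/predicted aggregate SGDDM over thinned draws plus p_post."""
        from .evaluate import posterior_predictive_sgddm, ppp

        rp = posterior_predictive_sgddm(self.draws, self.model.data, thin=thin, seed=seed)
        return {
            "realized": rp["realized"],
            "predicted": rp["predicted"],
            "p_post": ppp(rp["realized"], rp["predicted"]),
        }

    def evaluation_report(self, thin: int = 500, seed: int = 0) -> dict:
        """All evaluation statistics in one dictionary (plot-ready vectors)."""
        report = self.sgddm_ppc(thin=thin, seed=seed)
        report.update(self.waic())
        report.update(self.loo())
        report.update(self.dic())
        report["rhat_max"] = float(self.rhat().max()) if self.draws.n_chains() > 1 else np.nan
        return report
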