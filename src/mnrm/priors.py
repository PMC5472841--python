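"""Prior specifications for Bayesian MNRM estimation.

Two presets are provided:

* informative — c_jk ~ N(0, 3), a_jkd ~ N(0, 3), sigma_d ~ lognormal(0, 0.5)
  (scale parameters are standard deviations; the lognormal has median 1,
  mean e^{1/8} ≈ 1.13 and SD ≈ 0.60, a mildly regularizing choice that
  keeps the trait scale near 1),
* uniform — c_jk, a_jkd ~ U(-10, 10) with the same lognormal on sigma_d,
  essentially bounded maximum likelihood.

Traits are modelled as random effects, theta_id ~ N(0, sigma_d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["MarginalPrior", "NormalPrior", "UniformPrior", "PriorSpec", "lognormal_moments"]


def lognormal_moments(mu: float, tau: float) -> dict[str, float]:
    """Median, mean and SD of a lognormal with log-scale mean mu and SD tau."""
    mean = float(np.exp(mu + tau**2 / 2))
    sd = float(np.sqrt((np.exp(tau**2) - 1.0) * np.exp(2 * mu + tau**2)))
    return {"median": float(np.exp(mu)), "mean": mean, "sd": sd}


class MarginalPrior:
    """A univariate prior sampled on an unconstrained axis ``u``.

    Subclasses define the constraining transform x(u), its derivative, and
    the log prior density on the u scale (Jacobian included), plus gradients
    — everything HMC needs.
    """

    def transform(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dtransform(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def logp_u(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dlogp_u(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        raise NotImplementedError

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log density on the constrained (x) axis, up to a constant."""
        raise NotImplementedError

    def dlogpdf(self, x: np.ndarray) -> np.ndarray:
        """Gradient of :meth:`logpdf` on the constrained axis."""
        raise NotImplementedError

    @property
    def bounds(self) -> tuple:
        """Support bounds on the constrained axis (None = unbounded)."""
        return (None, None)


@dataclass
class NormalPrior(MarginalPrior):
    """x ~ N(mean, sd); the unconstrained axis is x itself."""

    mean: float = 0.0
    sd: float = 1.0

    def transform(self, u):
        return u

    def inverse(self, x):
        return np.asarray(x, dtype=float)

    def dtransform(self, u):
        return np.ones_like(u)

    def logp_u(self, u):
        return -0.5 * ((u - self.mean) / self.sd) ** 2

    def dlogp_u(self, u):
        return -(u - self.mean) / self.sd**2

    def sample(self, rng, size):
        return rng.normal(self.mean, self.sd, size)

    def logpdf(self, x):
        return -0.5 * ((np.asarray(x) - self.mean) / self.sd) ** 2

    def dlogpdf(self, x):
        return -(np.asarray(x) - self.mean) / self.sd**2

    @property
    def bounds(self):
        return (None, None)


@dataclass
class UniformPrior(MarginalPrior):
    """x ~ U(low, high) via the logistic transform x = low + (high-low)·expit(u).

    The flat density on x contributes only the transform's log-Jacobian on
    the u axis, which keeps HMC inside the support without rejections.
    """

    low: float = -10.0
    high: float = 10.0

    def transform(self, u):
        return self.low + (self.high - self.low) * expit(u)

    def inverse(self, x):
        p = (np.asarray(x, dtype=float) - self.low) / (self.high - self.low)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def dtransform(self, u):
        p = expit(u)
        return (self.high - self.low) * p * (1.0 - p)

    def logp_u(self, u):
        # log |dx/du|; constant -log(high-low) of the flat density dropped
        p = expit(u)
        return np.log(self.high - self.low) + np.log(p) + np.log1p(-p)

    def dlogp_u(self, u):
        return 1.0 - 2.0 * expit(u)

    def sample(self, rng, size):
        x = rng.uniform(self.low, self.high, size)
        # return on the unconstrained axis
        p = (x - self.low) / (self.high - self.low)
        return np.log(p) - np.log1p(-p)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x > self.low) & (x < self.high), 0.0, -np.inf)

    def dlogpdf(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    @property
    def bounds(self):
        return (self.low + 1e-6, self.high - 1e-6)


@dataclass
class PriorSpec:
    """Priors for intercepts, slopes and trait SDs.

    ``sigma_mu`` / ``sigma_tau`` are the log-scale mean and SD of the
    lognormal prior on sigma_d; sampling is done on log sigma, where the
    prior is simply N(sigma_mu, sigma_tau).
    """

    intercept: MarginalPrior
    slope: MarginalPrior
    sigma_mu: float = 0.0
    sigma_tau: float = 0.5
    name: str = "custom"

    @classmethod
    def informative(cls, scale: float = 3.0) -> "PriorSpec":
        return cls(
            intercept=NormalPrior(0.0, scale),
            slope=NormalPrior(0.0, scale),
            name="informative",
        )

    @classmethod
    def uniform(cls, bound: float = 10.0) -> "PriorSpec":
        return cls(
            intercept=UniformPrior(-bound, bound),
            slope=UniformPrior(-bound, bound),
            name="uniform",
        )

    @classmethod
    def preset(cls, name: str) -> "PriorSpec":
        if name == "informative":
            return cls.informative()
        if name == "uniform":
            return cls.uniform()
        raise ValueError(f"unknown prior preset {name!r}")

    def sigma_prior_moments(self) -> dict[str, float]:
        """Closed-form median/mean/SD of the lognormal prior on sigma_d."""
        return lognormal_moments(self.sigma_mu, self.sigma_tau)
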