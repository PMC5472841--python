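"""Simulation of latent traits and categorical responses from an MNRM.

Traits are independent normals, theta_id ~ N(0, sigma_d), with dimensions
uncorrelated; responses are drawn categorically from the softmax
probabilities.  The module also ships the 4-item, 4-category generating
parameters used throughout the package's simulation study (simple
constraints, category 4 as the zero reference, slopes conforming to the
echelon identification pattern so fitted and true values are directly
comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, ResponseMatrix, category_probabilities

__all__ = [
    "LatentState",
    "generate_theta",
    "simulate_responses",
    "table2_parameters",
]

# Generating item parameters: columns are item, category, c, a1, a2, a3.
# Category 4 of every item is the zero reference; item 1's leading slopes
# carry the echelon fixed ones/zeros (1,0,0 / 0.5,1,0 / -1,0.5,1).
_GENERATOR_TABLE = np.array(
    [
        [1, 1, -1, 1.0, 0.0, 0.0],
        [1, 2, 0, 0.5, 1.0, 0.0],
        [1, 3, 1, -1.0, 0.5, 1.0],
        [1, 4, 0, 0.0, 0.0, 0.0],
        [2, 1, -1, 1.0, -0.5, -1.0],
        [2, 2, 0, 0.5, 1.0, -0.5],
        [2, 3, 1, -1.0, 0.5, 0.5],
        [2, 4, 0, 0.0, 0.0, 0.0],
        [3, 1, -1, 1.0, 0.5, 0.5],
        [3, 2, 0, 0.5, -0.5, -1.0],
        [3, 3, 1, -1.0, 1.0, -0.5],
        [3, 4, 0, 0.0, 0.0, 0.0],
        [4, 1, -1, 1.0, 1.0, -0.5],
        [4, 2, 0, 0.5, 0.5, 0.5],
        [4, 3, 1, -1.0, -0.5, -1.0],
        [4, 4, 0, 0.0, 0.0, 0.0],
    ]
)


@dataclass
class LatentState:
    """Latent trait draws theta (N x D) with their generating SDs sigma (D,)."""

    theta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 1 or self.sigma.shape[0] != self.theta.shape[1]:
            raise ValueError("sigma must be a D-vector matching theta's columns")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")

    @property
    def N(self) -> int:
        return self.theta.shape[0]

    @property
    def D(self) -> int:
        return self.theta.shape[1]


def generate_theta(
    N: int, D: int, sigma: np.ndarray | float = 1.0, seed: int | np.random.SeedSequence = 0
) -> LatentState:
    """Draw theta_id ~ N(0, sigma_d), independent across persons and dimensions."""
    if N < 0 or D < 1:
        raise ValueError("need N >= 0 and D >= 1")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (D,)).copy()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal((N, D)) * sigma
    return LatentState(theta.reshape(N, D), sigma)


def simulate_responses(
    params: ModelParameters,
    latent: LatentState,
    seed: int | np.random.SeedSequence = 0,
) -> ResponseMatrix:
    """Draw one categorical response per person-item from the model.

    Each response x_ij is drawn with probabilities P_j(theta_i); the draw is
    fully determined by ``seed``.
    """
    if latent.D != params.D:
        raise ValueError(
            f"latent state has D={latent.D}, parameters have D={params.D}"
        )
    rng = np.random.default_rng(seed)
    N, J, K = latent.N, params.J, params.K
    if N == 0:
        return ResponseMatrix(np.zeros((0, J), dtype=int), K=K)
    P = category_probabilities(params, latent.theta)  # (N, J, K)
    cum = np.cumsum(P, axis=-1)
    cum[..., -1] = 1.0  # guard against round-off
    u = rng.random((N, J, 1))
    codes = (u > cum).sum(axis=-1) + 1  # 1-based categories
    return ResponseMatrix(codes.astype(int), K=K)


def table2_parameters(D: int) -> ModelParameters:
    """Generating parameters of the built-in 4-item, 4-category design.

    For ``D`` in {1, 2, 3} the leading ``D`` slope columns are used; the
    returned parameters satisfy simple constraints with reference category 4
    and conform to the echelon identification pattern.
    """
    if D not in (1, 2, 3):
        raise ValueError(f"generator dimensionality must be 1, 2 or 3, got {D}")
    c = _GENERATOR_TABLE[:, 2].reshape(4, 4)
    a = _GENERATOR_TABLE[:, 3 : 3 + D].reshape(4, 4, D)
    return ModelParameters(c.copy(), a.copy(), "simple", reference_category=4)
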