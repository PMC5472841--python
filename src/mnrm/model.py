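"""Probability core of the multidimensional nominal response model (MNRM).

The MNRM assigns each response category ``k`` of item ``j`` a linear
*utility* in the latent traits,

    z_jk(theta) = c_jk + sum_d a_jkd * theta_d,

and links utilities to category probabilities through a softmax,

    P_jk(theta) = exp(z_jk) / sum_k' exp(z_jk').

Adding a constant to all utilities of an item leaves the probabilities
unchanged, so identification constraints are required.  This module
implements the three standard parameterizations (simple / reference
category, deviation / sum-to-zero, and item-slope-plus-scoring), the
echelon identification pattern that removes rotational and scale
indeterminacy during estimation, and parameter-counting bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "ResponseMatrix",
    "ModelParameters",
    "IdentificationPattern",
    "utilities",
    "category_probabilities",
    "log_likelihood",
    "to_deviation",
    "to_scoring",
    "expand_scoring",
    "re_reference",
    "echelon_pattern",
    "count_free_parameters",
    "n_response_patterns",
]


@dataclass
class ResponseMatrix:
    """N x J matrix of observed categories, coded 1..K.

    Parameters
    ----------
    values : ndarray of int, shape (N, J)
        One row per person, one column per item.  Categories are 1-based
        (file convention); internally 0-based indices are derived on demand.
    K : int, optional
        Number of categories per item (constant across items).  Inferred as
        the maximum observed code when omitted.
    item_names : list of str, optional
    """

    values: np.ndarray
    K: int | None = None
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"response matrix must be 2-D, got shape {v.shape}")
        if v.size and not np.issubdtype(v.dtype, np.integer):
            f = np.asarray(v, dtype=float)
            if not np.all(f == np.round(f)):
                bad = np.argwhere(f != np.round(f))[0]
                raise ValueError(
                    f"non-integer response at row {bad[0] + 1}, column {bad[1] + 1}"
                )
            v = f.astype(int)
        self.values = np.asarray(v, dtype=int)
        if self.K is None:
            if self.values.size == 0:
                raise ValueError("K must be given for an empty response matrix")
            self.K = int(self.values.max())
        if self.K < 2:
            raise ValueError(f"need at least 2 categories, got K={self.K}")
        if self.values.size:
            if self.values.min() < 1:
                bad = np.argwhere(self.values < 1)[0]
                raise ValueError(
                    f"response code < 1 at row {bad[0] + 1}, column {bad[1] + 1}"
                )
            if self.values.max() > self.K:
                bad = np.argwhere(self.values > self.K)[0]
                raise ValueError(
                    f"response code > K={self.K} at row {bad[0] + 1}, "
                    f"column {bad[1] + 1}"
                )

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @property
    def zero_based(self) -> np.ndarray:
        """Responses as 0-based indices (internal array convention)."""
        return self.values - 1


@dataclass
class ModelParameters:
    """Intercepts and category slopes for a J-item, K-category, D-trait MNRM.

    ``intercepts[j, k]`` and ``slopes[j, k, d]`` follow the classical
    (Bock-style) parameterization; ``parameterization`` records which
    identification constraints the stored values satisfy.  The scoring
    factorization (item slope times category scores, anchored at
    s_1d = 0 and s_Kd = K-1) is carried in ``item_slopes`` / ``scores``
    and expanded back to category slopes via a_jkd = s_jkd * a_jd.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    parameterization: str = "simple"
    reference_category: int = 0  # 1-based; 0 means "last" (K)
    item_slopes: np.ndarray | None = None  # (J, D), scoring only
    scores: np.ndarray | None = None  # (J, K, D), scoring only

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.intercepts.ndim != 2:
            raise ValueError("intercepts must be (J, K)")
        if self.slopes.ndim != 3 or self.slopes.shape[:2] != self.intercepts.shape:
            raise ValueError(
                f"slopes shape {self.slopes.shape} inconsistent with "
                f"intercepts shape {self.intercepts.shape}"
            )
        if self.parameterization not in ("simple", "deviation", "scoring"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.reference_category == 0:
            self.reference_category = self.K
        self._validate_constraints()

    @property
    def J(self) -> int:
        return self.intercepts.shape[0]

    @property
    def K(self) -> int:
        return self.intercepts.shape[1]

    @property
    def D(self) -> int:
        return self.slopes.shape[2]

    def _validate_constraints(self, tol: float = 1e-10) -> None:
        if self.parameterization == "simple":
            r = self.reference_category - 1
            if np.any(self.intercepts[:, r] != 0) or np.any(self.slopes[:, r, :] != 0):
                raise ValueError(
                    "simple constraints require zero intercept and slopes for "
                    f"reference category {self.reference_category}"
                )
        elif self.parameterization == "deviation":
            if np.max(np.abs(self.intercepts.sum(axis=1))) > tol or np.max(
                np.abs(self.slopes.sum(axis=1))
            ) > tol:
                raise ValueError(
                    "deviation constraints require intercepts and slopes to "
                    "sum to zero across categories"
                )
        else:  # scoring
            if self.item_slopes is None or self.scores is None:
                raise ValueError("scoring parameterization requires item_slopes and scores")
            s = np.asarray(self.scores, dtype=float)
            if np.any(s[:, 0, :] != 0) or np.any(s[:, -1, :] != self.K - 1):
                raise ValueError(
                    f"scoring anchors must be s_1d = 0 and s_Kd = {self.K - 1}"
                )


@dataclass
class IdentificationPattern:
    """Fixed-zero / fixed-one masks over the (J, K, D) slope array.

    The reference category's slopes are structural zeros (they never enter
    the stacked slope matrix A); the echelon pattern additionally fixes, in
    the first D rows of A, the diagonal entry to 1 and the entries above it
    to 0, which removes rotational indeterminacy and — together with free
    trait standard deviations — the scale indeterminacy.
    """

    fixed_zero: np.ndarray
    fixed_one: np.ndarray
    reference_category: int  # 1-based

    def __post_init__(self) -> None:
        self.fixed_zero = np.asarray(self.fixed_zero, dtype=bool)
        self.fixed_one = np.asarray(self.fixed_one, dtype=bool)
        if self.fixed_zero.shape != self.fixed_one.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.fixed_zero & self.fixed_one):
            raise ValueError("fixed_zero and fixed_one must be disjoint")

    @property
    def J(self) -> int:
        return self.fixed_zero.shape[0]

    @property
    def K(self) -> int:
        return self.fixed_zero.shape[1]

    @property
    def D(self) -> int:
        return self.fixed_zero.shape[2]

    @property
    def free_slopes(self) -> np.ndarray:
        """Boolean mask of freely estimated slope entries."""
        return ~(self.fixed_zero | self.fixed_one)

    @property
    def free_intercepts(self) -> np.ndarray:
        """Boolean (J, K) mask of freely estimated intercepts."""
        m = np.ones((self.J, self.K), dtype=bool)
        m[:, self.reference_category - 1] = False
        return m

    @property
    def free_count(self) -> dict[str, int]:
        return {
            "free_slopes": int(self.free_slopes.sum()),
            "free_intercepts": int(self.free_intercepts.sum()),
        }

    def fixed_values(self) -> np.ndarray:
        """(J, K, D) array of the fixed slope entries (0/1), free entries 0."""
        return self.fixed_one.astype(float)


# ---------------------------------------------------------------------------
# probability core


def _check_theta(params: ModelParameters, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[None, :]
    if theta.ndim != 2 or theta.shape[1] != params.D:
        raise ValueError(
            f"theta has shape {theta.shape}, expected (..., {params.D}) to match "
            f"the model's {params.D} dimension(s)"
        )
    return theta


def _category_slopes(params: ModelParameters) -> np.ndarray:
    if params.parameterization == "scoring":
        return expand_scoring(params).slopes
    return params.slopes


def utilities(params: ModelParameters, theta: np.ndarray) -> np.ndarray:
    """Category utilities z_jk = c_jk + sum_d a_jkd theta_d.

    ``theta`` may be a single D-vector (returns (J, K)) or an (N, D) matrix
    (returns (N, J, K)).  A scoring parameterization is expanded to category
    slopes first.
    """
    single = np.asarray(theta).ndim == 1
    th = _check_theta(params, theta)
    a = _category_slopes(params)
    z = params.intercepts[None] + np.einsum("nd,jkd->njk", th, a)
    return z[0] if single else z


def category_probabilities(params: ModelParameters, theta: np.ndarray) -> np.ndarray:
    """Softmax category probabilities P_jk(theta), stable up to |z| ~ 700.

    Stability comes from max-subtraction before exponentiation, which is an
    exact utility shift and therefore leaves the probabilities unchanged.
    """
    z = utilities(params, theta)
    return softmax(z, axis=-1)


def log_likelihood(
    params: ModelParameters, theta_matrix: np.ndarray, X: ResponseMatrix
) -> dict[str, np.ndarray | float]:
    """Categorical log-likelihood of a response matrix.

    Returns ``{"total": float, "pointwise": (N,) array}`` where the
    pointwise unit is the person: pointwise_i = sum_j log P_{i, j, x_ij}.
    The per-person grain is what WAIC/LOO consume, because theta_i couples
    all of a person's responses.
    """
    th = _check_theta(params, theta_matrix)
    if th.shape[0] != X.N:
        raise ValueError(f"theta has {th.shape[0]} rows for {X.N} persons")
    if X.J != params.J:
        raise ValueError(f"data has {X.J} items, model has {params.J}")
    if X.K != params.K:
        raise ValueError(f"data has K={X.K}, model has K={params.K}")
    z = utilities(params, th)  # (N, J, K)
    logp = log_softmax(z, axis=-1)
    idx = X.zero_based
    pointwise = np.take_along_axis(logp, idx[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    return {"total": float(pointwise.sum()), "pointwise": pointwise}


# ---------------------------------------------------------------------------
# parameterization transforms


def re_reference(params: ModelParameters, new_reference: int) -> ModelParameters:
    """Shift utilities so ``new_reference`` (1-based) is the zero category.

    Subtracting one category's (c, a) from every category of the item is a
    pure utility shift and preserves all probabilities.
    """
    if params.parameterization != "simple":
        raise ValueError("re_reference expects simple constraints")
    r = new_reference - 1
    c = params.intercepts - params.intercepts[:, r][:, None]
    a = params.slopes - params.slopes[:, r, :][:, None, :]
    return ModelParameters(c, a, "simple", reference_category=new_reference)


def to_deviation(params: ModelParameters) -> ModelParameters:
    """Center intercepts and slopes to mean zero across categories.

    Centering is a utility shift per item, so category probabilities are
    unchanged at every theta.  Applying it twice is a no-op.
    """
    if params.parameterization == "scoring":
        params = expand_scoring(params)
    c = params.intercepts - params.intercepts.mean(axis=1, keepdims=True)
    a = params.slopes - params.slopes.mean(axis=1, keepdims=True)
    return ModelParameters(c, a, "deviation")


def to_scoring(params: ModelParameters, anchor_low: float = 0.0) -> ModelParameters:
    """Factor category slopes into item slopes a_jd and category scores s_jkd.

    The factorization presumes category 1 is the zero category, so the input
    (simple constraints with any reference) is first re-referenced to
    category 1 — a probability-preserving utility shift.  Then

        a_jd = a_jKd / (K - 1),      s_jkd = a_jkd / a_jd,

    with anchors s_j1d = 0 and s_jKd = K - 1.  Intercepts carry over
    unchanged (after the re-reference).
    """
    if params.parameterization != "simple":
        raise ValueError("to_scoring expects simple constraints")
    K = params.K
    p1 = re_reference(params, 1)
    a_K = p1.slopes[:, K - 1, :]  # (J, D)
    degenerate = np.abs(a_K) < 1e-12
    if np.any(degenerate):
        j, d = np.argwhere(degenerate)[0]
        raise ValueError(
            f"degenerate scoring anchor: slope of category K is ~0 for item "
            f"{j + 1}, dimension {d + 1}; scores a_jkd / a_jd are undefined"
        )
    item_slopes = a_K / (K - 1)
    scores = p1.slopes / item_slopes[:, None, :]
    scores[:, 0, :] = 0.0
    scores[:, K - 1, :] = K - 1
    return ModelParameters(
        p1.intercepts,
        p1.slopes,
        "scoring",
        reference_category=1,
        item_slopes=item_slopes,
        scores=scores,
    )


def expand_scoring(params: ModelParameters) -> ModelParameters:
    """Expand a scoring parameterization back to category slopes (Bock form)."""
    if params.parameterization != "scoring":
        raise ValueError("expand_scoring expects a scoring parameterization")
    a = params.scores * params.item_slopes[:, None, :]
    return ModelParameters(params.intercepts, a, "simple", reference_category=1)


# ---------------------------------------------------------------------------
# identification and counting


def echelon_pattern(J: int, K: int, D: int) -> IdentificationPattern:
    """Echelon identification pattern over the stacked slope matrix A.

    A has J(K-1) rows (reference category K excluded as structural zeros)
    ordered item-major.  Row t (t = 1..D) carries a fixed 1 at column t and
    fixed 0s at columns d > t; everything else is free.
    """
    if J < 1 or K < 2 or D < 1:
        raise ValueError("need J >= 1, K >= 2, D >= 1")
    if J * (K - 1) < D:
        raise ValueError(
            f"infeasible pattern: stacked slope matrix has J(K-1) = {J * (K - 1)} "
            f"rows, fewer than D = {D}"
        )
    fixed_zero = np.zeros((J, K, D), dtype=bool)
    fixed_one = np.zeros((J, K, D), dtype=bool)
    fixed_zero[:, K - 1, :] = True  # structural zeros of the reference category
    for t in range(D):  # 0-based row index into A
        j, k = divmod(t, K - 1)
        fixed_one[j, k, t] = True
        fixed_zero[j, k, t + 1 :] = True
    return IdentificationPattern(fixed_zero, fixed_one, reference_category=K)


def count_free_parameters(
    J: int, K: int, D: int, scheme: str = "echelon_with_sigma"
) -> dict[str, int]:
    """Free-parameter bookkeeping.

    ``per_item_formula``
        (K-1)(D+1) per item under simple or deviation constraints, split as
        K-1 intercepts and (K-1)D slopes; totals multiply by J; no sigmas.
    ``echelon_with_sigma``
        Echelon pattern with unit diagonal slopes and free trait SDs:
        free_slopes = J(K-1)D - D(D-1)/2 - D, free_intercepts = J(K-1),
        sigmas = D.
    """
    if J < 1 or K < 1 or D < 1:
        raise ValueError("J, K, D must be >= 1")
    if scheme == "per_item_formula":
        return {
            "free_intercepts": J * (K - 1),
            "free_slopes": J * (K - 1) * D,
            "sigmas": 0,
        }
    if scheme == "echelon_with_sigma":
        return {
            "free_intercepts": J * (K - 1),
            "free_slopes": J * (K - 1) * D - D * (D - 1) // 2 - D,
            "sigmas": D,
        }
    raise ValueError(f"unknown scheme {scheme!r}")


def n_response_patterns(J: int, K: int) -> int:
    """Number of distinct response patterns, K**J."""
    return K**J
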