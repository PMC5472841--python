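"""Post-estimation rotation of the slope matrix with trait counter-rotation.

Rotating the stacked slope matrix A by a nonsingular M (A* = AM) while
transforming traits by M^{-1} leaves every utility — hence the model —
unchanged; it only changes the coordinate system in which slopes are read.
Both simple- and deviation-constraint slopes remain valid after rotation
(column operations preserve per-item zero rows and zero column sums); a
scoring parameterization must be expanded to category slopes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RotationMatrix", "rotation_matrix_2d", "apply_rotation", "varimax"]


@dataclass
class RotationMatrix:
    M: np.ndarray
    kind: str = "custom"  # angle_orthogonal | varimax | custom

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("rotation matrix must be square")
        if abs(np.linalg.det(self.M)) < 1e-10:
            raise ValueError("rotation matrix is singular")
        if self.kind == "angle_orthogonal":
            if not np.allclose(self.M.T @ self.M, np.eye(self.D), atol=1e-10):
                raise ValueError("angle rotation must be orthogonal")

    @property
    def D(self) -> int:
        return self.M.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.M)


def rotation_matrix_2d(angle_degrees: float, direction: str = "clockwise") -> RotationMatrix:
    """2-D orthogonal rotation by a given angle.

    The clockwise convention is M = [[cos φ, sin φ], [-sin φ, cos φ]],
    applied to slope ROW vectors as A* = AM; counterclockwise is its
    transpose.
    """
    phi = np.deg2rad(angle_degrees)
    M = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
    if direction == "counterclockwise":
        M = M.T
    elif direction != "clockwise":
        raise ValueError(f"direction must be clockwise or counterclockwise, got {direction!r}")
    return RotationMatrix(M, kind="angle_orthogonal")


def apply_rotation(A: np.ndarray, M: RotationMatrix | np.ndarray) -> dict:
    """Rotate slopes: A* = AM, with the trait transform theta* = M^{-1} theta.

    ``A`` is any array whose last axis is the dimension axis (a stacked
    (rows, D) matrix or a (J, K, D) slope array).
    """
    if not isinstance(M, RotationMatrix):
        M = RotationMatrix(np.asarray(M))
    A = np.asarray(A, dtype=float)
    if A.shape[-1] != M.D:
        raise ValueError(f"slope array has {A.shape[-1]} columns, M is {M.D}x{M.D}")
    return {"A_star": A @ M.M, "theta_transform": M.inverse, "M": M.M}


def varimax(A: np.ndarray, normalize: bool = True, max_iter: int = 500,
            tol: float = 1e-8) -> RotationMatrix:
    """Orthogonal varimax rotation matrix for a stacked (rows, D) slope matrix.

    Standard Kaiser-normalized variant, iterated via the SVD updates until
    the criterion changes by less than ``tol``.  Non-convergence warns and
    returns the last iterate.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("varimax needs a 2-D matrix with at least 2 columns")
    p, D = A.shape
    if normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    M = np.eye(D)
    crit = 0.0
    for _ in range(max_iter):
        L = A @ M
        u, s, vt = np.linalg.svd(
            A.T @ (L**3 - L * (L**2).sum(axis=0) / p)
        )
        M = u @ vt
        new_crit = s.sum()
        if abs(new_crit - crit) < tol:
            return RotationMatrix(M, kind="varimax")
        crit = new_crit
    import warnings

    warnings.warn("varimax did not converge; returning last iterate", RuntimeWarning)
    return RotationMatrix(M, kind="varimax")


def varimax_criterion(A: np.ndarray) -> float:
    """Raw varimax criterion: sum over columns of the variance of squared loadings."""
    A = np.asarray(A, dtype=float)
    sq = A**2
    return float((sq.var(axis=0)).sum())
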