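"""Linear state-space model of neural activity and its stationary decomposition.

The continuous-time model is the multivariate Ornstein-Uhlenbeck process

    dx/dt = A x + w,      Cov(w) = sigma2 * I

with ``A`` the effective-connectivity (EC) matrix, assumed Hurwitz stable, and
isotropic white-noise fluctuations.  Its stationary covariance ``Sigma`` solves
the continuous Lyapunov equation ``A Sigma + Sigma A^T + sigma2 I = 0``, and the
drift decomposes exactly into a dissipative (gradient) part and a solenoidal
(circulating) part:

    A = (-(sigma2/2) I + S) Sigma^{-1}

where ``S = (A Sigma - Sigma A^T) / 2`` is the skew-symmetric steady-state
differential cross-covariance (dC-Cov), ``S_ij = E[dx_i/dt * x_j]`` at
stationarity.  ``S = 0`` is equivalent to detailed balance (time-reversible
dynamics, symmetric ``A``); a nonzero ``S`` sustains a curl probability flux
and makes the process irreversible.

The decomposition is a one-to-one map between (Sigma, S) and A for fixed noise
variance, which is why all downstream directionality analyses consume ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import (
    ConditioningError,
    ConsistencyError,
    SkewSymmetryError,
    StabilityError,
)

__all__ = [
    "LinearModel",
    "SteadyState",
    "StrengthDecomposition",
    "solve_stationary_covariance",
    "compute_dccov",
    "reconstruct_ec",
    "symmetric_ec",
    "steady_state",
    "strength_decomposition",
]

#: eigenvalues of A must have real part below this for a stationary regime
STABILITY_TOL = -1e-10

#: relative tolerance for rejecting a non-skew-symmetric S
SKEW_RTOL = 1e-8

#: tolerance on the decomposition residual A - (-(sigma2/2) I + S) Sigma^{-1}
CONSISTENCY_TOL = 1e-8


def _default_labels(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


def _check_square(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {M.shape}")
    return M


@dataclass
class LinearModel:
    """Stable linear stochastic model (A, sigma2) with labeled nodes.

    Parameters
    ----------
    A : (n, n) array
        Effective-connectivity matrix, units 1/s.  Must be Hurwitz stable.
    sigma2 : float
        Variance rate of the endogenous fluctuations (noise covariance is
        ``sigma2 * I``), units (state^2)/s.
    labels : list of str, optional
        Region names; autogenerated when omitted.
    """

    A: np.ndarray
    sigma2: float
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = _check_square(self.A, "A")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A contains non-finite entries")
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        eigs = np.linalg.eigvals(self.A)
        worst = float(np.max(eigs.real))
        if worst >= STABILITY_TOL:
            raise StabilityError(
                f"A is not stable: max Re(eig) = {worst:.3e} "
                f"(required < {STABILITY_TOL:.0e})"
            )
        if self.labels is None:
            self.labels = _default_labels(self.n)
        elif len(self.labels) != self.n:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n} nodes"
            )

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass
class SteadyState:
    """Stationary second-order statistics of a :class:`LinearModel`.

    Sigma is the stationary covariance (the model's functional connectivity up
    to normalization), Precision its inverse, and S the skew-symmetric
    steady-state differential cross-covariance.
    """

    Sigma: np.ndarray
    Precision: np.ndarray
    S: np.ndarray


@dataclass
class StrengthDecomposition:
    """Row/column strengths of A and of the matrices it decomposes into.

    ``Delta = S @ Precision`` is the gradient of the solenoidal flow; it equals
    ``A + (sigma2/2) Precision``, i.e. the deviation of the drift from the
    time-reversible (purely dissipative) drift sharing the same covariance.
    """

    row_sum_A: np.ndarray
    col_sum_A: np.ndarray
    row_sum_prec: np.ndarray
    col_sum_prec: np.ndarray
    row_sum_S: np.ndarray
    col_sum_S: np.ndarray
    Delta: np.ndarray
    delta_row_sum: np.ndarray
    delta_col_sum: np.ndarray


def solve_stationary_covariance(model: LinearModel) -> np.ndarray:
    """Solve ``A Sigma + Sigma A^T + sigma2 I = 0`` for the stationary covariance.

    Uses the Bartels-Stewart continuous-Lyapunov solver.  The result is
    symmetrized and checked for positive definiteness.

    Raises
    ------
    StabilityError
        If ``model.A`` is not stable (checked at model construction).
    ConditioningError
        If the solve produces a non-positive-definite Sigma, reporting the
        offending eigenvalue.
    """
    n = model.n
    Q = -model.sigma2 * np.eye(n)
    Sigma = linalg.solve_continuous_lyapunov(model.A, Q)
    Sigma = (Sigma + Sigma.T) / 2.0
    eig_min = float(np.min(np.linalg.eigvalsh(Sigma)))
    if eig_min <= 0:
        raise ConditioningError(
            f"stationary covariance not positive definite "
            f"(min eigenvalue {eig_min:.3e}); A is too close to marginal stability"
        )
    return Sigma


def compute_dccov(model: LinearModel, Sigma: np.ndarray) -> np.ndarray:
    """Steady-state differential cross-covariance ``S = (A Sigma - Sigma A^T)/2``.

    Exact skew-symmetry is enforced after construction (``S <- (S - S^T)/2``
    and zero diagonal) so downstream sign-based source/sink calls never see
    rounding asymmetry.
    """
    Sigma = _check_square(Sigma, "Sigma")
    if Sigma.shape[0] != model.n:
        raise ValueError(
            f"Sigma is {Sigma.shape[0]}x{Sigma.shape[0]} but model has {model.n} nodes"
        )
    M = model.A @ Sigma
    S = (M - M.T) / 2.0
    S = (S - S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return S


def _check_skew(S: np.ndarray, name: str = "S") -> np.ndarray:
    S = _check_square(S, name)
    scale = float(np.max(np.abs(S)))
    if scale > 0 and float(np.max(np.abs(S + S.T))) > SKEW_RTOL * scale:
        raise SkewSymmetryError(
            f"{name} is not skew-symmetric: max|{name}+{name}^T| = "
            f"{np.max(np.abs(S + S.T)):.3e} vs scale {scale:.3e}"
        )
    return (S - S.T) / 2.0


def reconstruct_ec(Sigma: np.ndarray, S: np.ndarray, sigma2: float) -> np.ndarray:
    """Rebuild the EC matrix from its decomposition: ``A = (-(sigma2/2) I + S) Sigma^{-1}``.

    This inverts :func:`solve_stationary_covariance` + :func:`compute_dccov`:
    the round trip reproduces ``A`` to numerical precision.
    """
    Sigma = _check_square(Sigma, "Sigma")
    S = _check_skew(S)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = Sigma.shape[0]
    B = -(sigma2 / 2.0) * np.eye(n) + S
    # A = B Sigma^{-1}  <=>  Sigma^T A^T = B^T
    return linalg.solve(Sigma, B.T, assume_a="pos").T


def symmetric_ec(Sigma: np.ndarray, sigma2: float) -> np.ndarray:
    """Time-reversible EC with the given stationary covariance: ``-(sigma2/2) Sigma^{-1}``.

    This is the unique symmetric drift consistent with Sigma; it has S = 0 and
    equal incoming/outgoing strengths per node.
    """
    Sigma = _check_square(Sigma, "Sigma")
    eig_min = float(np.min(np.linalg.eigvalsh((Sigma + Sigma.T) / 2)))
    if eig_min <= 0:
        raise ConditioningError(
            f"Sigma is singular or indefinite (min eigenvalue {eig_min:.3e})"
        )
    A_sym = -(sigma2 / 2.0) * linalg.inv(Sigma)
    return (A_sym + A_sym.T) / 2.0


def steady_state(model: LinearModel) -> SteadyState:
    """Convenience: solve for Sigma, Precision and S of a model in one call."""
    Sigma = solve_stationary_covariance(model)
    Precision = linalg.inv(Sigma)
    Precision = (Precision + Precision.T) / 2.0
    S = compute_dccov(model, Sigma)
    return SteadyState(Sigma=Sigma, Precision=Precision, S=S)


def strength_decomposition(
    model: LinearModel, ss: SteadyState
) -> StrengthDecomposition:
    """Decompose row (incoming) and column (outgoing) strengths of A.

    The exact identities realized here: the incoming strength of node i is a
    linear combination of precision row sums weighted by row i of S, minus the
    dissipative term; the outgoing strength of node i weights the column sums
    of S by column i of the precision matrix.  Only the outgoing strengths
    inherit the directional (solenoidal) information carried by S.

    Raises
    ------
    ConsistencyError
        If (A, Sigma, S, sigma2) do not satisfy the decomposition identity.
    """
    A, sigma2 = model.A, model.sigma2
    Sigma, Precision, S = ss.Sigma, ss.Precision, ss.S
    A_rebuilt = (-(sigma2 / 2.0) * np.eye(model.n) + S) @ Precision
    resid = float(np.max(np.abs(A - A_rebuilt)))
    scale = max(1.0, float(np.max(np.abs(A))))
    if resid > CONSISTENCY_TOL * scale:
        raise ConsistencyError(
            f"(A, Sigma, S, sigma2) inconsistent: decomposition residual "
            f"{resid:.3e} exceeds tolerance {CONSISTENCY_TOL * scale:.3e}"
        )
    Delta = S @ Precision
    return StrengthDecomposition(
        row_sum_A=A.sum(axis=1),
        col_sum_A=A.sum(axis=0),
        row_sum_prec=Precision.sum(axis=1),
        col_sum_prec=Precision.sum(axis=0),
        row_sum_S=S.sum(axis=1),
        col_sum_S=S.sum(axis=0),
        Delta=Delta,
        delta_row_sum=Delta.sum(axis=1),
        delta_col_sum=Delta.sum(axis=0),
    )
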