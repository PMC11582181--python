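"""Latent VAR(1) dynamics and the unit-variance identification constraint.

The latent states follow ``x_{t+1} = A x_t + eps_t`` with ``eps_t ~ N(0, Sigma)``
and ``Sigma`` diagonal.  Because the location and scale of latent states are
arbitrary, the model is identified by constraining the *stationary marginal*
variance of every state to 1.  The stationary covariance ``Gamma`` solves the
discrete Lyapunov relation

    Gamma = A Gamma A' + Sigma,   equivalently
    vec(Gamma) = (I - A kron A)^{-1} vec(Sigma),

so fixing ``diag(Gamma) = 1`` determines the off-diagonal marginal
correlations of ``Gamma`` — and then the diagonal of ``Sigma`` — purely as a
function of ``A``.  The off-diagonal solve uses selection matrices: with
``M = I - A kron A``, ``S`` selecting the off-diagonal positions of
``vec(Gamma)`` and ``c`` marking its diagonal positions,

    vec(Gamma)* = -(S M S')^{-1} S M c.

Not every stationary ``A`` is compatible with the constraint: the back-solved
``Sigma`` may have a non-positive diagonal.  Such matrices are rejected with
:class:`~ordssm.errors.InfeasibleDynamicsError`, which the MIF2 estimator
treats as a zero-weight proposal rather than a hard failure.

``vec`` is column-major throughout (Fortran order), and ``S``/``c`` are
constructed against that convention; any consistent stacking satisfies the
Lyapunov identity, and the round trip is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InfeasibleDynamicsError, StationarityError

__all__ = [
    "StateDynamics",
    "IdentifiedCovariances",
    "SelectionStructure",
    "is_stationary",
    "spectral_radius",
    "stationary_covariance",
    "selection_structure",
    "identify_innovations",
]

#: diagonal entries of the implied innovation covariance below this are
#: treated as infeasible (the boundary of the permissible set for A)
SIGMA_FLOOR = 1e-8


def _as_square(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"transition matrix must be square, got shape {A.shape}")
    if A.shape[0] < 1:
        raise DimensionError("transition matrix must be at least 1x1")
    return A


@dataclass(frozen=True)
class StateDynamics:
    """Transition matrix of the latent VAR(1) process.

    Parameters
    ----------
    A : (p, p) array
        Transition coefficients. Stationarity (spectral radius < 1) is
        validated at construction.
    """

    A: np.ndarray

    def __post_init__(self):
        A = _as_square(self.A)
        object.__setattr__(self, "A", A)
        if not is_stationary(A):
            raise StationarityError(
                "transition matrix has spectral radius >= 1 (non-stationary)"
            )

    @property
    def p(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class IdentifiedCovariances:
    """The pair (Gamma, Sigma) implied by A under diag(Gamma) = 1.

    Gamma is the stationary marginal covariance (a correlation matrix under
    the identification constraint); Sigma is the diagonal innovation
    covariance.
    """

    Gamma: np.ndarray
    Sigma: np.ndarray

    @property
    def sigma_diag(self) -> np.ndarray:
        return np.diag(self.Sigma)


@dataclass(frozen=True)
class SelectionStructure:
    """Selection matrix S (off-diagonal positions of vec(Gamma), column-major)
    and indicator vector c (diagonal positions)."""

    S: np.ndarray
    c: np.ndarray


def spectral_radius(A) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(_as_square(A)))))


def is_stationary(A) -> bool:
    """True iff the VAR(1) process with transition matrix ``A`` is stationary,
    i.e. all eigenvalues of ``A`` lie strictly inside the unit circle."""
    return spectral_radius(A) < 1.0


def stationary_covariance(A, Sigma) -> np.ndarray:
    """Stationary marginal covariance of the VAR(1) process.

    Solves ``Gamma = A Gamma A' + Sigma`` through the p^2-dimensional linear
    system ``(I - A kron A) vec(Gamma) = vec(Sigma)`` (exact at the small p
    used here, p <= 4 in practice).

    Parameters
    ----------
    A : (p, p) array
        Stationary transition matrix.
    Sigma : (p, p) array or (p,) vector
        Innovation covariance (a vector is taken as the diagonal).

    Returns
    -------
    (p, p) ndarray, symmetric PSD.
    """
    A = _as_square(A)
    if not is_stationary(A):
        raise StationarityError("stationary covariance requires spectral radius < 1")
    p = A.shape[0]
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim == 1:
        Sigma = np.diag(Sigma)
    if Sigma.shape != (p, p):
        raise DimensionError(f"Sigma shape {Sigma.shape} incompatible with p={p}")
    M = np.eye(p * p) - np.kron(A, A)
    vec_gamma = np.linalg.solve(M, Sigma.flatten(order="F"))
    Gamma = vec_gamma.reshape((p, p), order="F")
    return 0.5 * (Gamma + Gamma.T)  # symmetrize away round-off


def selection_structure(p: int) -> SelectionStructure:
    """Build S and c for a p-state model against column-major vec()."""
    if p < 1:
        raise DimensionError("p must be >= 1")
    n = p * p
    eye = np.eye(n)
    # column-major: vec index of entry (i, j) is i + j*p
    off = [i + j * p for j in range(p) for i in range(p) if i != j]
    diag = [i + i * p for i in range(p)]
    S = eye[off, :]
    c = np.zeros(n)
    c[diag] = 1.0
    return SelectionStructure(S=S, c=c)


def identify_innovations(A) -> IdentifiedCovariances:
    """Solve the identification constraint for a stationary transition matrix.

    Given ``A``, fixes ``diag(Gamma) = 1``, solves for the off-diagonal
    entries of ``Gamma`` via the selection-matrix linear system, then
    back-solves the diagonal of ``Sigma`` from the Lyapunov identity.

    Returns
    -------
    IdentifiedCovariances
        With ``diag(Gamma) = 1`` exactly and ``Sigma`` diagonal positive.

    Raises
    ------
    StationarityError
        If ``A`` is not stationary.
    InfeasibleDynamicsError
        If the implied innovation variances are not strictly positive or the
        implied ``Gamma`` is not positive definite — ``A`` lies outside the
        permissible set for the unit-variance constraint.
    """
    A = _as_square(A)
    if not is_stationary(A):
        raise StationarityError("identification requires a stationary transition matrix")
    p = A.shape[0]
    M = np.eye(p * p) - np.kron(A, A)
    sel = selection_structure(p)
    vec_gamma = sel.c.copy()  # unit diagonal
    if p > 1:
        SMS = sel.S @ M @ sel.S.T
        rhs = sel.S @ M @ sel.c
        try:
            off = -np.linalg.solve(SMS, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise InfeasibleDynamicsError(
                f"singular selection system for A={A.tolist()}"
            ) from exc
        vec_gamma = vec_gamma + sel.S.T @ off
    Gamma = vec_gamma.reshape((p, p), order="F")
    Gamma = 0.5 * (Gamma + Gamma.T)
    # back-solve Sigma = Gamma - A Gamma A'; off-diagonals vanish by
    # construction of the selection solve
    Sigma_full = Gamma - A @ Gamma @ A.T
    sigma_diag = np.diag(Sigma_full).copy()
    if np.any(sigma_diag <= SIGMA_FLOOR):
        raise InfeasibleDynamicsError(
            "implied innovation variance non-positive: A is incompatible with "
            f"the unit-marginal-variance constraint (diag Sigma = {sigma_diag.tolist()})"
        )
    if p > 1:
        eigvals = np.linalg.eigvalsh(Gamma)
        if eigvals.min() <= 0:
            raise InfeasibleDynamicsError(
                "implied marginal covariance is not positive definite "
                f"(eigenvalues {eigvals.tolist()})"
            )
    return IdentifiedCovariances(Gamma=Gamma, Sigma=np.diag(sigma_diag))
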