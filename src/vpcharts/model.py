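"""Multivariate multiple linear regression profiles.

A profile relates ``p`` correlated responses to ``q`` explanatory variables
through ``Y_k = X B + E_k`` where ``X`` is an ``n x (q+1)`` design matrix
(first column of ones), ``B`` is the ``(q+1) x p`` coefficient matrix and the
rows of ``E_k`` are i.i.d. multivariate normal with covariance ``Sigma``.
Phase-II monitoring assumes ``B`` and ``Sigma`` known; this module holds the
in-control model, simulates samples under coefficient shifts and variance
inflation, and computes the least-squares estimator and residual summaries
the chart statistics are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


@dataclass(frozen=True)
class ProfileModel:
    """In-control profile specification.

    Parameters
    ----------
    B : ndarray, shape (q+1, p)
        Coefficient matrix; row 0 holds the intercepts.
    Sigma : ndarray, shape (p, p)
        Error covariance, symmetric positive definite.
    designs : dict[int, ndarray]
        Design matrices keyed by sample size ``n``; each is ``n x (q+1)``
        with a leading column of ones and full column rank.
    """

    B: np.ndarray
    Sigma: np.ndarray
    designs: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Sigma", Sigma)
        if Sigma.shape != (self.p, self.p):
            raise ValueError(f"Sigma must be {self.p}x{self.p}, got {Sigma.shape}")
        if not np.allclose(Sigma, Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(Sigma)[0] <= 0:
            raise ValueError("Sigma must be positive definite")
        designs = {}
        for n, X in self.designs.items():
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape != (int(n), self.q + 1):
                raise ValueError(
                    f"design for n={n} must be {n}x{self.q + 1}, got {X.shape}"
                )
            if not np.allclose(X[:, 0], 1.0):
                raise ValueError(f"design for n={n} must have a leading ones column")
            if np.linalg.matrix_rank(X) < self.q + 1:
                raise ValueError(f"design for n={n} is rank deficient")
            designs[int(n)] = X
        object.__setattr__(self, "designs", designs)

    @property
    def q(self) -> int:
        return self.B.shape[0] - 1

    @property
    def p(self) -> int:
        return self.B.shape[1]

    @property
    def m(self) -> int:
        """Length of the vectorized coefficient estimator, p(q+1)."""
        return self.p * (self.q + 1)

    def design(self, n: int) -> np.ndarray:
        try:
            return self.designs[int(n)]
        except KeyError:
            raise KeyError(
                f"no design matrix for n={n}; available: {sorted(self.designs)}"
            ) from None

    @property
    def beta_vec(self) -> np.ndarray:
        """Response-major vectorization of B: (b01..bq1, ..., b0p..bqp)."""
        return vectorize_coefficients(self.B)


@dataclass(frozen=True)
class ShiftSpec:
    """Out-of-control condition: additive coefficient shift and variance
    multiplier tau (Sigma -> tau * Sigma).  The all-zero shift with tau=1 is
    the in-control state."""

    delta_B: np.ndarray | None = None
    tau: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.delta_B is not None:
            object.__setattr__(
                self, "delta_B", np.atleast_2d(np.asarray(self.delta_B, dtype=float))
            )

    def shifted_B(self, B: np.ndarray) -> np.ndarray:
        if self.delta_B is None:
            return B
        if self.delta_B.shape != B.shape:
            raise ValueError(
                f"delta_B shape {self.delta_B.shape} does not match B {B.shape}"
            )
        return B + self.delta_B


IN_CONTROL = ShiftSpec()


@dataclass(frozen=True)
class Sample:
    """One Phase-II sample: responses Y (n x p) taken under design X."""

    Y: np.ndarray
    X: np.ndarray
    design_key: int | None = None

    def __post_init__(self):
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if Y.shape[0] != X.shape[0]:
            raise ValueError("Y and X must have the same number of rows")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class BetaHat:
    """Least-squares coefficient estimate and its response-major vector."""

    Bhat: np.ndarray

    @property
    def beta_vec(self) -> np.ndarray:
        return vectorize_coefficients(self.Bhat)


@dataclass(frozen=True)
class ResidualSummary:
    """Residual summaries against the known in-control coefficients.

    ``ebar`` is the mean residual vector, ``f`` the summed Mahalanobis norm
    of the residual rows under Sigma (chi-square with n*p df in control).
    ``W`` is the identical quantity used by the variability EWMA; the two
    coincide because residuals are taken against the true B.
    """

    ebar: np.ndarray
    f: float
    n: int

    @property
    def W(self) -> float:
        return self.f


def vectorize_coefficients(B: np.ndarray) -> np.ndarray:
    """Stack the (q+1) x p coefficient matrix response-major into a vector of
    length p(q+1): all coefficients of response 1, then response 2, ..."""
    return np.asarray(B, dtype=float).T.ravel()


def unvectorize_coefficients(beta: np.ndarray, q: int, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize_coefficients` (exact round trip)."""
    return np.asarray(beta, dtype=float).reshape(p, q + 1).T


def simulate_sample(
    model: ProfileModel,
    shift: ShiftSpec = IN_CONTROL,
    *,
    n: int,
    rng: np.random.Generator,
) -> Sample:
    """Draw one sample Y = X(B + delta_B) + E with error rows ~ N(0, tau*Sigma)."""
    X = model.design(n)
    Bs = shift.shifted_B(model.B)
    chol = linalg.cholesky(shift.tau * model.Sigma, lower=True)
    E = rng.standard_normal((X.shape[0], model.p)) @ chol.T
    return Sample(Y=X @ Bs + E, X=X, design_key=int(n))


def estimate_coefficients(sample: Sample, model: ProfileModel | None = None) -> BetaHat:
    """Least-squares solve of the normal equations, Bhat = (X'X)^-1 X'Y."""
    Bhat, _, rank, _ = np.linalg.lstsq(sample.X, sample.Y, rcond=None)
    if rank < sample.X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return BetaHat(Bhat=Bhat)


def beta_covariance(model: ProfileModel, n: int) -> np.ndarray:
    """Covariance of the vectorized coefficient estimator for sample size n.

    Block (g, h) equals sigma_gh * (X'X)^-1 under the response-major
    ordering, i.e. Sigma kron (X'X)^-1.
    """
    X = model.design(n)
    XtX_inv = linalg.inv(X.T @ X)
    return np.kron(model.Sigma, XtX_inv)


def residual_summary(sample: Sample, model: ProfileModel) -> ResidualSummary:
    """Residual mean vector and summed Mahalanobis norm against the known B."""
    resid = sample.Y - sample.X @ model.B
    Sigma_inv = linalg.inv(model.Sigma)
    f = float(np.einsum("ij,jk,ik->", resid, Sigma_inv, resid))
    return ResidualSummary(ebar=resid.mean(axis=0), f=f, n=sample.n)
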