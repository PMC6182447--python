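"""Difference-based ordinary least squares (DOLS) for the parametric part.

Model: ``y_i = x_i' beta + f(t_i) + e_i`` with deterministic design points
``0 <= t_1 <= ... <= t_n <= 1``.  Differencing with an order-``m`` sequence
removes the smooth ``f`` up to O(1/n) leakage, leaving an ordinary linear
model ``ỹ = X̃ beta + ẽ`` whose OLS solution is the DOLS estimator
``β̂ = (X̃'X̃)^{-1} X̃'ỹ``.

The limiting covariance of the standardized estimator is

    τ²_β = lim (n-m)^{-1} { Σ_i x̃_i x̃_i' Var(ẽ_i)
                            + 2 Σ_{i<j} x̃_i x̃_j' Cov(ẽ_i, ẽ_j) },

for which two finite-sample constructors are provided: a closed form valid
for iid (or exchangeable, via ``tau2_beta_exchangeable``) errors, and a
HAC-type residual plug-in with lag truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .difference_design import DifferenceSequence, apply_differencing

__all__ = [
    "PLMData",
    "DOLSFit",
    "BetaCovariance",
    "fit_dols",
    "lag_weights",
    "tau2_beta_iid",
    "tau2_beta_exchangeable",
    "tau2_beta_plugin",
    "standardize_beta",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class PLMData:
    """A partially linear model sample ``(y, X, t)``.

    ``t`` must be nondecreasing and contained in [0, 1]; ``X`` is coerced to
    an ``(n, d)`` matrix (a 1-d covariate becomes a single column).
    """

    y: np.ndarray
    X: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "t", t)
        n = y.shape[0]
        if X.shape[0] != n or t.shape[0] != n:
            raise ValueError(
                f"y, X, t must share length: got {n}, {X.shape[0]}, {t.shape[0]}"
            )
        if t.size and (t.min() < 0.0 or t.max() > 1.0):
            raise ValueError("design points t must lie in [0, 1]")
        if np.any(np.diff(t) < 0):
            raise ValueError("design points t must be nondecreasing")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class DOLSFit:
    """Result of a DOLS fit.

    ``Sigma_n = X̃'X̃``; ``residuals = ỹ - X̃ β̂`` (length ``n - m``).
    """

    beta_hat: np.ndarray
    Sigma_n: np.ndarray
    residuals: np.ndarray
    seq: DifferenceSequence
    X_tilde: np.ndarray = field(repr=False)

    @property
    def n_diff(self) -> int:
        """Number of differenced observations, ``n - m``."""
        return self.residuals.shape[0]


@dataclass(frozen=True)
class BetaCovariance:
    """A finite-sample stand-in for the limiting covariance ``τ²_β``."""

    tau2_beta: np.ndarray
    method: str
    lag_truncation: int

    def __post_init__(self) -> None:
        tb = np.atleast_2d(np.asarray(self.tau2_beta, dtype=float))
        object.__setattr__(self, "tau2_beta", tb)
        if not np.allclose(tb, tb.T, atol=0.0):
            raise ValueError("tau2_beta must be exactly symmetric")
        if np.any(np.diag(tb) < 0):
            raise ValueError("tau2_beta must have nonnegative diagonal")

    @property
    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue — a degeneracy diagnostic (the theory assumes
        the limit is positive definite but offers no finite-sample check)."""
        return float(np.linalg.eigvalsh(self.tau2_beta)[0])


def fit_dols(data: PLMData, seq: DifferenceSequence) -> DOLSFit:
    """Fit ``β̂ = Σ_n^{-1} X̃'ỹ`` on the differenced data."""
    if data.n <= seq.order + data.d:
        raise ValueError(
            f"need n > m + d, got n={data.n}, m={seq.order}, d={data.d}"
        )
    dd = apply_differencing(seq, data)
    Sigma_n = dd.X_tilde.T @ dd.X_tilde
    cond = np.linalg.cond(Sigma_n)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"Sigma_n is numerically singular (condition number {cond:.3e}); "
            "the differenced design carries too little variation"
        )
    # the condition number misses a uniformly tiny Sigma_n (e.g. a covariate
    # annihilated by differencing): compare its scale to the raw design
    scale = float(np.sum(data.X**2))
    min_eig = float(np.linalg.eigvalsh(Sigma_n).min())
    if min_eig <= 1e-12 * max(scale, 1.0):
        raise np.linalg.LinAlgError(
            f"Sigma_n is numerically singular (smallest eigenvalue {min_eig:.3e} "
            f"against design scale {scale:.3e}); differencing removed all "
            "variation from some covariate"
        )
    beta_hat = np.linalg.solve(Sigma_n, dd.X_tilde.T @ dd.y_tilde)
    residuals = dd.y_tilde - dd.X_tilde @ beta_hat
    return DOLSFit(
        beta_hat=beta_hat,
        Sigma_n=Sigma_n,
        residuals=residuals,
        seq=seq,
        X_tilde=dd.X_tilde,
    )


def lag_weights(seq: DifferenceSequence) -> np.ndarray:
    """Lag-k overlap products ``γ_k = Σ_q d_q d_{q+k}`` for k = 0..m.

    For iid errors with variance σ², ``Cov(ẽ_i, ẽ_{i+k}) = γ_k σ²`` and
    vanishes for k > m.  Note ``γ_0 = 1``.
    """
    d = seq.weights
    m = seq.order
    return np.array([d[: m + 1 - k] @ d[k:] for k in range(m + 1)])


def _banded_quadratic(X_tilde: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """(1/N) [ c_0 Σ x̃_i x̃_i' + Σ_k c_k Σ_i (x̃_i x̃_{i+k}' + x̃_{i+k} x̃_i') ]."""
    N = X_tilde.shape[0]
    total = coeffs[0] * (X_tilde.T @ X_tilde)
    for k in range(1, len(coeffs)):
        if k >= N or coeffs[k] == 0.0:
            continue
        cross = X_tilde[:-k].T @ X_tilde[k:]
        total = total + coeffs[k] * (cross + cross.T)
    return total / N


def tau2_beta_iid(
    seq: DifferenceSequence, X_tilde: np.ndarray, sigma2: float
) -> BetaCovariance:
    """Closed-form ``τ²_β`` when the raw errors are iid with variance σ²."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    X_tilde = np.atleast_2d(np.asarray(X_tilde, dtype=float))
    if X_tilde.ndim == 1:
        X_tilde = X_tilde[:, None]
    gamma = lag_weights(seq)
    tb = _banded_quadratic(X_tilde, gamma * sigma2)
    tb = (tb + tb.T) / 2.0
    return BetaCovariance(tau2_beta=tb, method="iid_closed_form", lag_truncation=seq.order)


def tau2_beta_exchangeable(
    seq: DifferenceSequence, X_tilde: np.ndarray, var: float, cov: float
) -> BetaCovariance:
    """``τ²_β`` for exchangeable errors: Var(e_i)=var, Cov(e_i,e_j)=cov (i≠j).

    Because ``Σ_q d_q = 0``, the common covariance drops out of every
    differenced moment and the exchangeable case reduces *exactly* to the iid
    closed form with effective variance ``var - cov``:
    ``Var(ẽ_i) = var - cov`` and ``Cov(ẽ_i, ẽ_{i+k}) = (var - cov) γ_k``.
    """
    return tau2_beta_iid(seq, X_tilde, var - cov)


def tau2_beta_plugin(fit: DOLSFit, lag_truncation: int | None = None) -> BetaCovariance:
    """HAC-type residual plug-in for ``τ²_β``.

    Replaces the error moments by products of differenced residuals,
    truncating cross terms at ``|i - j| <= lag_truncation``.  The default lag
    is ``m + 5``: differenced iid errors are m-dependent, and the small
    surplus guards against residual dependence.  The symmetrized matrix is
    eigenvalue-clipped at zero (with a warning) if it fails to be PSD.
    """
    N = fit.n_diff
    m = fit.seq.order
    if lag_truncation is None:
        lag_truncation = min(m + 5, N - 1)
    if lag_truncation < 0 or lag_truncation > N - 1:
        raise ValueError(f"lag_truncation must be in [0, {N - 1}], got {lag_truncation}")
    e = fit.residuals
    Xe = fit.X_tilde * e[:, None]
    total = Xe.T @ Xe
    for k in range(1, lag_truncation + 1):
        cross = Xe[:-k].T @ Xe[k:]
        total = total + cross + cross.T
    tb = (total + total.T) / (2.0 * N)
    eigval, eigvec = np.linalg.eigh(tb)
    if eigval[0] < 0:
        warnings.warn(
            f"plug-in tau2_beta not PSD (min eigenvalue {eigval[0]:.3e}); "
            "clipping negative eigenvalues at 0",
            stacklevel=2,
        )
        tb = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        tb = (tb + tb.T) / 2.0
    return BetaCovariance(tau2_beta=tb, method="residual_plugin", lag_truncation=lag_truncation)


def _inverse_sqrt(mat: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Inverse symmetric square root by eigendecomposition.

    Eigenvalues are floored at ``floor`` for numerical determinism; a
    nonpositive eigenvalue raises, since standardization is then meaningless.
    """
    eigval, eigvec = np.linalg.eigh(mat)
    if eigval[0] <= 0:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (min eigenvalue {eigval[0]:.3e}); "
            "increase n or reduce the lag truncation"
        )
    eigval = np.maximum(eigval, floor)
    return (eigvec / np.sqrt(eigval)) @ eigvec.T


def standardize_beta(
    fit: DOLSFit, cov: BetaCovariance, beta0: np.ndarray
) -> np.ndarray:
    """The standardized statistic ``(n-m)^{-1/2} τ_β^{-1} Σ_n (β̂ - β₀)``.

    Under the asymptotic-normality theorem this converges to N(0, I_d).
    """
    beta0 = np.atleast_1d(np.asarray(beta0, dtype=float))
    tau_inv = _inverse_sqrt(cov.tau2_beta)
    return fit.n_diff ** -0.5 * tau_inv @ fit.Sigma_n @ (fit.beta_hat - beta0)
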