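"""Wavelet reproducing-kernel estimation of the nonparametric component.

Given a compactly supported scaling function φ of a multiresolution
analysis, the projection kernel onto the resolution-m̃ space is

    E_m̃(t, s) = 2^m̃ Σ_k φ(2^m̃ t - k) φ(2^m̃ s - k),

and, with intervals A_i = [s_{i-1}, s_i] partitioning [0, 1] with t_i ∈ A_i,
the nonparametric component is estimated from the parametric residuals as

    f̂(t) = Σ_i (y_i - x_i' β̂) ∫_{A_i} E_m̃(t, s) ds.

The integrated kernel weights w_i(t) sum to ≈ 1 for interior t, so f̂ is a
locally weighted average of the residuals.  The pointwise limiting variance
is τ²_t = Var(Σ_i e_i w_i(t)) = w' Cov(e) w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from numpy.polynomial.legendre import leggauss

from .dols import PLMData

__all__ = [
    "ScalingFunction",
    "ReproducingKernel",
    "Partition",
    "NonparametricFit",
    "build_scaling_function",
    "choose_resolution",
    "kernel_eval",
    "kernel_weights",
    "fit_nonparametric",
    "tau2_t_plugin",
]

_GAUSS_ORDER = 8
_GAUSS_NODES, _GAUSS_WEIGHTS = leggauss(_GAUSS_ORDER)


@dataclass(frozen=True)
class ScalingFunction:
    """A scaling function tabulated on a dyadic grid over its compact support.

    Evaluation interpolates linearly between table points (φ is Lipschitz, so
    the interpolation error is O(grid_step)); an optional exact callable
    overrides the table (used for Haar, whose jump would otherwise be
    smeared over one grid step).
    """

    family: str
    grid: np.ndarray
    values: np.ndarray
    support: tuple[float, float]
    grid_step: float
    exact: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __call__(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.exact is not None:
            return self.exact(u)
        return np.interp(u, self.grid, self.values, left=0.0, right=0.0)

    @property
    def support_width(self) -> float:
        return self.support[1] - self.support[0]


def _haar_exact(u: np.ndarray) -> np.ndarray:
    return ((u >= 0.0) & (u < 1.0)).astype(float)


def build_scaling_function(family: str = "daubechies-2", refinement: int = 10) -> ScalingFunction:
    """Tabulate a scaling function by the cascade (dyadic refinement) recursion.

    Supported families: ``haar`` and ``daubechies-N`` (N vanishing moments,
    support [0, 2N-1]).  ``refinement`` is the dyadic level J of the table
    grid (step 2^-J); J >= 6 is required for Daubechies families so that the
    Lipschitz interpolation error stays below the kernel tolerances.
    """
    fam = family.lower()
    if fam == "haar":
        grid = np.linspace(0.0, 1.0, 2**refinement + 1)
        values = _haar_exact(grid)
        return ScalingFunction(
            family="haar", grid=grid, values=values, support=(0.0, 1.0),
            grid_step=2.0**-refinement, exact=_haar_exact,
        )
    if fam.startswith("daubechies-"):
        try:
            nmom = int(fam.split("-", 1)[1])
        except ValueError:
            nmom = 0
        if nmom >= 1:
            if refinement < 6:
                raise ValueError("refinement level J >= 6 required for Daubechies families")
            wavelet = pywt.Wavelet(f"db{nmom}")
            values, _, grid = wavelet.wavefun(level=refinement)
            values = np.asarray(values, dtype=float)
            grid = np.asarray(grid, dtype=float)
            return ScalingFunction(
                family=fam, grid=grid, values=values,
                support=(float(grid[0]), float(grid[-1])),
                grid_step=2.0**-refinement,
            )
    raise ValueError(
        f"unknown scaling-function family {family!r}; "
        "supported: 'haar', 'daubechies-N' (N >= 1)"
    )


def choose_resolution(n: int) -> int:
    """Resolution level from the rate condition ``2^m̃ = O(n^(1/3))``.

    Returns the smallest m̃ with ``2^m̃ >= n^(1/3)``, i.e.
    ``ceil(log2(n)/3)``.  Rounding up keeps the smoothing bias strictly
    below the stochastic error of the estimator at the evaluation point;
    rounding down would leave a bias-to-noise ratio that does not vanish.
    """
    if n < 8:
        raise ValueError(f"need n >= 8, got {n}")
    return max(1, math.ceil(math.log2(n) / 3.0 - 1e-9))


@dataclass(frozen=True)
class ReproducingKernel:
    """The projection kernel ``E_m̃`` of the resolution-m̃ space V_m̃."""

    phi: ScalingFunction
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution < 0:
            raise ValueError("resolution must be >= 0")

    @property
    def locality(self) -> float:
        """Kernel bandwidth: E(t, s) = 0 when |t - s| > support_width * 2^-m̃."""
        return self.phi.support_width * 2.0 ** -self.resolution

    def is_interior(self, t: float) -> bool:
        """Whether t is farther than one kernel bandwidth from {0, 1}."""
        return self.locality <= t <= 1.0 - self.locality

    def _shifts(self) -> np.ndarray:
        """Integer shifts k for which φ(2^m̃ u - k) can be nonzero, u ∈ [0,1]."""
        two = 2.0**self.resolution
        lo, hi = self.phi.support
        return np.arange(math.floor(0.0 - hi) - 1, math.ceil(two - lo) + 2)


def kernel_eval(kernel: ReproducingKernel, t, s) -> np.ndarray | float:
    """Evaluate ``E_m̃(t, s) = 2^m̃ Σ_k φ(2^m̃ t - k) φ(2^m̃ s - k)``.

    ``t`` and ``s`` may be scalars or broadcastable arrays in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(t < 0) or np.any(t > 1) or np.any(s < 0) or np.any(s > 1):
        raise ValueError("kernel arguments must lie in [0, 1]")
    two = 2.0**kernel.resolution
    ks = kernel._shifts()
    phi_t = kernel.phi(two * t[..., None] - ks)
    phi_s = kernel.phi(two * s[..., None] - ks)
    out = two * np.einsum("...k,...k->...", phi_t, phi_s)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Partition:
    """Breakpoints ``0 = s_0 < s_1 < ... < s_n = 1`` defining intervals A_i."""

    breakpoints: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, dtype=float)
        object.__setattr__(self, "breakpoints", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("partition needs at least two breakpoints")
        if abs(b[0]) > 1e-12 or abs(b[-1] - 1.0) > 1e-12:
            raise ValueError("partition must span [0, 1]")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def uniform(cls, n: int) -> "Partition":
        """The default partition ``s_i = i/n`` (so t_i = i/n lies in A_i)."""
        return cls(np.linspace(0.0, 1.0, n + 1))

    @property
    def n(self) -> int:
        return self.breakpoints.size - 1

    def check_spacing(self, C: float = 4.0) -> bool:
        """Mesh condition: ``max_i (s_i - s_{i-1}) <= C / n``."""
        return float(np.diff(self.breakpoints).max()) <= C / self.n

    def contains(self, t: np.ndarray) -> bool:
        """Whether ``t_i ∈ A_i = [s_{i-1}, s_i]`` for every i."""
        t = np.asarray(t, dtype=float)
        if t.size != self.n:
            return False
        return bool(
            np.all(t >= self.breakpoints[:-1] - 1e-12)
            and np.all(t <= self.breakpoints[1:] + 1e-12)
        )


def _haar_weights(kernel: ReproducingKernel, partition: Partition, t: float) -> np.ndarray:
    """Closed-form Haar weights: 2^m̃ times the overlap of A_i with t's dyadic bin."""
    two = 2.0**kernel.resolution
    b = min(math.floor(two * t), int(two) - 1)  # t = 1 belongs to the last bin
    lo, hi = b / two, (b + 1) / two
    left = np.clip(partition.breakpoints[:-1], lo, hi)
    right = np.clip(partition.breakpoints[1:], lo, hi)
    return two * np.maximum(right - left, 0.0)


def kernel_weights(
    kernel: ReproducingKernel, partition: Partition, t: float
) -> np.ndarray:
    """Integrated kernel weights ``w_i(t) = ∫_{A_i} E_m̃(t, s) ds``.

    Haar kernels use the exact interval-overlap formula; other families use
    fixed-order Gauss–Legendre quadrature (order 8) on each interval, which
    is exact enough at O(1/n) interval widths for a Lipschitz φ.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"evaluation point must lie in [0, 1], got {t}")
    if kernel.phi.family == "haar":
        return _haar_weights(kernel, partition, t)
    two = 2.0**kernel.resolution
    ks = kernel._shifts()
    phi_t = kernel.phi(two * t - ks)
    active = phi_t != 0.0
    ks, phi_t = ks[active], phi_t[active]
    b = partition.breakpoints
    mid = (b[:-1] + b[1:]) / 2.0
    half = (b[1:] - b[:-1]) / 2.0
    # quadrature nodes: (n_intervals, order)
    nodes = mid[:, None] + half[:, None] * _GAUSS_NODES
    phi_s = kernel.phi(two * nodes[..., None] - ks)  # (n, order, k)
    integrand = two * (phi_s @ phi_t)  # (n, order)
    return half * (integrand @ _GAUSS_WEIGHTS)


@dataclass(frozen=True)
class NonparametricFit:
    """``f̂`` on a grid, plus the weight matrix w_i(t) used to build it."""

    grid: np.ndarray
    f_hat: np.ndarray
    weights_matrix: np.ndarray


def fit_nonparametric(
    data: PLMData,
    beta_hat: np.ndarray,
    kernel: ReproducingKernel,
    partition: Partition,
    grid: np.ndarray,
) -> NonparametricFit:
    """Estimate f on ``grid``: ``f̂(t) = Σ_i (y_i - x_i'β̂) w_i(t)``."""
    if partition.n != data.n:
        raise ValueError(
            f"partition has {partition.n} intervals but data has {data.n} rows"
        )
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("evaluation grid must lie in [0, 1]")
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    resid = data.y - data.X @ beta_hat
    W = np.vstack([kernel_weights(kernel, partition, tg) for tg in grid])
    return NonparametricFit(grid=grid, f_hat=W @ resid, weights_matrix=W)


def tau2_t_plugin(weights: np.ndarray, error_cov) -> float:
    """Pointwise variance ``τ²_t = w' Cov(e) w``.

    ``error_cov`` is either a scalar σ² (iid errors, giving σ² Σ w_i²) or a
    full covariance matrix.  The theory defines τ²_t with the true error
    covariance; any estimate supplied here is a plug-in choice.
    """
    w = np.asarray(weights, dtype=float)
    error_cov = np.asarray(error_cov, dtype=float)
    if error_cov.ndim == 0:
        out = float(error_cov) * float(w @ w)
    else:
        out = float(w @ error_cov @ w)
    if out < 0:
        raise ValueError(
            f"negative variance ({out:.3e}): supplied error covariance is not PSD"
        )
    return out
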