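"""Exact simulation of negatively superadditive dependent (NSD) errors.

Conditioning an iid integer-valued sequence on the value of its sum yields
an NSD (in particular, exchangeable and negatively correlated) sequence.
The default error law is the three-point pmf P(0) = 0.4, P(1) = 0.2,
P(2) = 0.4 conditioned on S_n = n; subtracting the conditional coordinate
mean (target/n) gives the mean-zero errors the asymptotic theory assumes.

Sampling is exact: a dynamic-programming table of partial-sum probabilities
P(S_k = s) drives a sequential draw of e_1, e_2, ... whose joint law equals
the conditional law (no rejection step, so the cost is O(n) per draw
regardless of how unlikely the conditioning event is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dols import PLMData

__all__ = [
    "ErrorPMF",
    "NSDErrorConfig",
    "SumTable",
    "ErrorCovariance",
    "default_error_pmf",
    "conditional_sum_table",
    "conditional_marginal",
    "exact_error_moments",
    "sample_conditional",
    "generate_plm_dataset",
    "empirical_error_covariance",
]


@dataclass(frozen=True)
class ErrorPMF:
    """A probability mass function on integers."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=int)
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "probs", p)
        if sup.ndim != 1 or p.shape != sup.shape:
            raise ValueError("support and probs must be 1-d vectors of equal length")
        if np.any(np.diff(sup) <= 0):
            raise ValueError("support must be strictly increasing integers")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)

    @property
    def var(self) -> float:
        mu = self.mean
        return float(((self.support - mu) ** 2) @ self.probs)

    def abs_moment(self, p: float, center: float = 0.0) -> float:
        """``E |X - center|^p`` under the pmf."""
        return float((np.abs(self.support - center) ** p) @ self.probs)


def default_error_pmf() -> ErrorPMF:
    """The three-point error law P(0) = 0.4, P(1) = 0.2, P(2) = 0.4."""
    return ErrorPMF(support=np.array([0, 1, 2]), probs=np.array([0.4, 0.2, 0.4]))


@dataclass(frozen=True)
class NSDErrorConfig:
    """Configuration of the conditional NSD error law.

    ``target_sum = None`` defaults to ``n`` (the classical S_n = n
    conditioning).  ``independent = True`` skips the conditioning entirely
    and draws iid from the pmf — a control mode (iid sequences are the
    degenerate NSD case).  ``center = True`` subtracts the per-coordinate
    conditional mean ``target_sum / n`` (or the pmf mean when independent)
    so that the returned errors have mean-zero marginals.
    """

    pmf: ErrorPMF
    n: int
    target_sum: int | None = None
    center: bool = True
    independent: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.target_sum is None:
            object.__setattr__(self, "target_sum", int(self.n))
        lo = self.n * int(self.pmf.support.min())
        hi = self.n * int(self.pmf.support.max())
        if not self.independent and not lo <= self.target_sum <= hi:
            raise ValueError(
                f"target_sum {self.target_sum} unattainable: must lie in [{lo}, {hi}]"
            )

    @property
    def coordinate_mean(self) -> float:
        """Marginal mean of one (uncentered) coordinate."""
        return self.pmf.mean if self.independent else self.target_sum / self.n


class SumTable:
    """Dynamic-programming table of partial-sum probabilities P(S_k = s).

    Row ``k`` covers the attainable sums ``k*min(support) .. k*max(support)``.
    Each row is renormalized to sum to one, which keeps the recursion stable
    for large n (the raw masses are all O(1) here, but renormalization makes
    that a guarantee rather than an accident).
    """

    def __init__(self, pmf: ErrorPMF, n: int):
        if n < 1:
            raise ValueError("n must be >= 1")
        self.pmf = pmf
        self.n = n
        lo = int(pmf.support.min())
        span = int(pmf.support.max()) - lo
        self._lo = lo
        rows: list[np.ndarray] = [np.array([1.0])]  # S_0 = 0 with probability 1
        for k in range(1, n + 1):
            prev = rows[k - 1]
            row = np.zeros(k * span + 1)
            for a, p in zip(pmf.support, pmf.probs):
                off = int(a) - lo
                row[off : off + prev.size] += p * prev
            row /= row.sum()
            rows.append(row)
        self._rows = rows

    def prob(self, k: int, s: int) -> float:
        """P(S_k = s)."""
        if not 0 <= k <= self.n:
            raise ValueError(f"k must be in [0, {self.n}]")
        idx = int(s) - k * self._lo
        row = self._rows[k]
        if idx < 0 or idx >= row.size:
            return 0.0
        return float(row[idx])

    def row(self, k: int) -> np.ndarray:
        """The full probability vector of S_k (sums k*min .. k*max)."""
        return self._rows[k].copy()


def conditional_sum_table(pmf: ErrorPMF, n: int) -> SumTable:
    """Build the partial-sum table used by the exact conditional sampler."""
    return SumTable(pmf, n)


def conditional_marginal(config: NSDErrorConfig, table: SumTable | None = None):
    """Exact marginal law of one coordinate.

    Returns ``(values, probs)`` where values are centered iff
    ``config.center``.  By exchangeability the marginal is the same for
    every coordinate:  P(e_1 = a | S_n = T) ∝ p_a P(S_{n-1} = T - a).
    """
    pmf, n, target = config.pmf, config.n, config.target_sum
    if config.independent:
        probs = pmf.probs.copy()
    else:
        table = table if table is not None else SumTable(pmf, n)
        if n == 1:
            probs = np.array([1.0 if a == target else 0.0 for a in pmf.support])
        else:
            probs = np.array(
                [p * table.prob(n - 1, target - a) for a, p in zip(pmf.support, pmf.probs)]
            )
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"conditioning event S_n = {target} has probability zero")
        probs /= total
    values = pmf.support.astype(float)
    if config.center:
        values = values - config.coordinate_mean
    return values, probs


def exact_error_moments(config: NSDErrorConfig) -> tuple[float, float]:
    """Exact ``(Var(e_i), Cov(e_i, e_j))`` of the (possibly conditional) errors.

    Computed by enumeration over one and two coordinates against the DP
    table; centering does not affect either moment.  For the conditional law
    these satisfy ``cov = -var / (n - 1)`` exactly (the sum is constant).
    """
    pmf, n, target = config.pmf, config.n, config.target_sum
    if config.independent:
        return pmf.var, 0.0
    table = SumTable(pmf, n)
    values, probs = conditional_marginal(
        NSDErrorConfig(pmf, n, target, center=False, independent=False), table
    )
    mu = float(values @ probs)
    var = float(((values - mu) ** 2) @ probs)
    if n == 1:
        return var, 0.0
    pair = np.zeros((pmf.support.size, pmf.support.size))
    for i, a in enumerate(pmf.support):
        for j, b in enumerate(pmf.support):
            rest = target - int(a) - int(b)
            tail = 1.0 if n == 2 and rest == 0 else (table.prob(n - 2, rest) if n > 2 else 0.0)
            pair[i, j] = pmf.probs[i] * pmf.probs[j] * tail
    pair /= pair.sum()
    e_ab = float(pmf.support @ pair @ pmf.support)
    return var, e_ab - mu * mu


def _as_generator(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_conditional(
    config: NSDErrorConfig, rng_seed, size: int | None = None,
    table: SumTable | None = None,
) -> np.ndarray:
    """Draw exact samples of the error vector.

    Returns shape ``(n,)`` (``size=None``) or ``(size, n)``.  The sequential
    scheme draws ``e_i`` from P(e_i = a | e_1..e_{i-1}, S_n = target)
    ∝ p_a P(S_{n-i} = remaining - a); uncentered draws sum to ``target``
    exactly on every draw.  ``rng_seed`` may be an int or a Generator.
    """
    rng = _as_generator(rng_seed)
    pmf, n, target = config.pmf, config.n, config.target_sum
    reps = 1 if size is None else int(size)
    if config.independent:
        draws = rng.choice(pmf.support, p=pmf.probs, size=(reps, n)).astype(float)
        if config.center:
            draws -= pmf.mean
        return draws[0] if size is None else draws

    table = table if table is not None else SumTable(pmf, n)
    lo = int(pmf.support.min())
    if table.prob(n, target) <= 0:
        raise ValueError(f"conditioning event S_n = {target} has probability zero")

    # Per-step cumulative lookup: at step i (0-based), nrem = n - i - 1
    # variables remain after this one; for each attainable remaining sum r,
    # P(pick = a) ∝ p_a P(S_nrem = r - a).
    span = int(pmf.support.max()) - lo
    cums = []
    for i in range(n):
        nrem = n - i - 1
        k = nrem + 1  # variables left including the current one
        r_vals = np.arange(k * lo, k * (lo + span) + 1)
        W = np.zeros((r_vals.size, pmf.support.size))
        rest = table.row(nrem)  # sums nrem*lo .. nrem*(lo+span)
        for j, (a, p) in enumerate(zip(pmf.support, pmf.probs)):
            idx = r_vals - int(a) - nrem * lo
            ok = (idx >= 0) & (idx < rest.size)
            W[ok, j] = p * rest[idx[ok]]
        tot = W.sum(axis=1, keepdims=True)
        tot[tot == 0.0] = 1.0  # unattainable r never reached
        cums.append((k * lo, np.cumsum(W / tot, axis=1)))

    draws = np.empty((reps, n))
    remaining = np.full(reps, int(target))
    for i in range(n):
        base, cum = cums[i]
        rows = cum[remaining - base]
        u = rng.random(reps)
        picks = (u[:, None] > rows).sum(axis=1)
        vals = pmf.support[picks]
        draws[:, i] = vals
        remaining -= vals
    if config.center:
        draws -= config.coordinate_mean
    return draws[0] if size is None else draws


def _default_covariate(t: np.ndarray) -> np.ndarray:
    return np.cos(2.0 * np.pi * t)


def _default_f(t: np.ndarray) -> np.ndarray:
    return np.sin(2.0 * np.pi * t)


def generate_plm_dataset(
    n: int,
    beta=(5.0,),
    covariate_fn=None,
    f_fn=None,
    error_config: NSDErrorConfig | None = None,
    rng_seed=0,
) -> PLMData:
    """Assemble a simulated partially linear sample.

    Defaults reproduce the reference simulation design: ``t_i = i/n``,
    ``x_i = cos(2π t_i)``, ``f(t) = sin(2π t)``, ``β = 5``, and centered
    NSD errors from the three-point pmf conditioned on ``S_n = n``.
    Deterministic given the seed.
    """
    if n < 8:
        raise ValueError(f"need n >= 8, got {n}")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    covariate_fn = covariate_fn if covariate_fn is not None else _default_covariate
    f_fn = f_fn if f_fn is not None else _default_f
    if error_config is None:
        error_config = NSDErrorConfig(default_error_pmf(), n)
    if error_config.n != n:
        raise ValueError(f"error_config.n = {error_config.n} does not match n = {n}")
    t = np.arange(1, n + 1) / n
    X = np.asarray(covariate_fn(t), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape != (n, beta.size):
        raise ValueError(f"covariate_fn returned shape {X.shape}, expected ({n}, {beta.size})")
    e = sample_conditional(error_config, rng_seed)
    y = X @ beta + f_fn(t) + e
    return PLMData(y=y, X=X, t=t)


@dataclass(frozen=True)
class ErrorCovariance:
    """Exchangeable summary of the error covariance: one variance, one
    off-diagonal covariance (all pairs share it by exchangeability)."""

    var: float
    cov_offdiag: float
    n: int
    method: str

    def matrix(self) -> np.ndarray:
        C = np.full((self.n, self.n), self.cov_offdiag)
        np.fill_diagonal(C, self.var)
        return C


def empirical_error_covariance(
    config: NSDErrorConfig, reps: int, rng_seed
) -> ErrorCovariance:
    """Monte-Carlo estimate of ``Var(e_i)`` and ``Cov(e_i, e_j)``.

    Exchangeability is exploited: the single reported variance averages the
    sample covariance diagonal, the single covariance averages the
    off-diagonal entries.  For noiseless values use
    :func:`exact_error_moments` instead.
    """
    if reps < 100:
        raise ValueError(f"need reps >= 100, got {reps}")
    draws = sample_conditional(config, rng_seed, size=reps)
    S = np.cov(draws, rowvar=False)
    n = config.n
    var = float(np.trace(S) / n)
    cov = float((S.sum() - np.trace(S)) / (n * (n - 1)))
    return ErrorCovariance(var=var, cov_offdiag=cov, n=n, method="monte_carlo")
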