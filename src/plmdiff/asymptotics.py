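"""Monte-Carlo asymptotics lab.

Replicates the simulation design many times and summarizes how close the
standardized estimators are to their N(0, 1) limits (ECDF, QQ pairs,
Kolmogorov–Smirnov distance, sample mean and variance), and checks the
Rosenthal-type maximal moment inequalities for NSD partial sums by
Monte Carlo.

Standardization uses the *exact* conditional error moments (variance and
common off-diagonal covariance of the exchangeable conditional law) computed
from the dynamic-programming sum table, not per-replication residual
plug-ins: the limit theorems standardize by the theoretical τ, and plug-in
noise would contaminate the normality diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm

from .difference_design import DifferenceSequence, make_simple_sequence
from .dols import fit_dols, standardize_beta, tau2_beta_exchangeable
from .nsd_sim import (
    NSDErrorConfig,
    conditional_marginal,
    default_error_pmf,
    exact_error_moments,
    generate_plm_dataset,
)
from .wavelet_estimator import (
    Partition,
    ReproducingKernel,
    build_scaling_function,
    choose_resolution,
    kernel_weights,
    tau2_t_plugin,
)

__all__ = [
    "StudyConfig",
    "NormalityReport",
    "MomentInequalityReport",
    "run_beta_study",
    "run_f_study",
    "ks_statistic",
    "check_moment_inequality",
]

_MAX_DROP_FRACTION = 0.05


@dataclass(frozen=True)
class StudyConfig:
    """Settings of one Monte-Carlo study.

    The defaults are the reference simulation design: β = 5 on
    x = cos(2πt), f = sin(2πt), t_i = i/n, centered NSD errors from the
    three-point pmf conditioned on S_n = n, the order-3 simple difference
    sequence, and the db2 kernel at the resolution chosen from n.
    """

    n: int
    reps: int = 1000
    seq: DifferenceSequence | None = None
    kernel_family: str = "daubechies-2"
    refinement: int = 10
    resolution: int | None = None
    error_config: NSDErrorConfig | None = None
    beta0: tuple[float, ...] = (5.0,)
    t_eval: float = 0.5
    seed: int = 0
    covariate_fn: Callable | None = None
    f_fn: Callable | None = None

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError(f"need reps >= 100, got {self.reps}")
        seq = self.seq if self.seq is not None else make_simple_sequence(3)
        object.__setattr__(self, "seq", seq)
        if self.n <= seq.order + len(self.beta0):
            raise ValueError(f"need n > m + d, got n={self.n}")
        ec = (
            self.error_config
            if self.error_config is not None
            else NSDErrorConfig(default_error_pmf(), self.n)
        )
        if ec.n != self.n:
            raise ValueError("error_config.n must match n")
        object.__setattr__(self, "error_config", ec)


@dataclass(frozen=True)
class NormalityReport:
    """Standardized statistics and their distance from N(0, 1)."""

    samples: np.ndarray
    estimates: np.ndarray
    ecdf_x: np.ndarray
    ecdf_F: np.ndarray
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray
    ks_stat: float
    sample_mean: float
    sample_var: float
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "reps": int(self.samples.size),
            "n_dropped": int(self.n_dropped),
            "sample_mean": float(self.sample_mean),
            "sample_var": float(self.sample_var),
            "ks_stat": float(self.ks_stat),
        }
        out.update(self.meta)
        return out


def ks_statistic(samples: np.ndarray) -> float:
    """Sup-distance between the sample ECDF and the standard normal CDF."""
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    N = s.size
    cdf = norm.cdf(s)
    upper = np.abs(np.arange(1, N + 1) / N - cdf).max()
    lower = np.abs(np.arange(0, N) / N - cdf).max()
    return float(max(upper, lower))


def _make_report(samples: np.ndarray, estimates: np.ndarray, n_dropped: int, meta: dict) -> NormalityReport:
    s = np.sort(samples)
    N = s.size
    plotting = (np.arange(1, N + 1) - 0.5) / N
    return NormalityReport(
        samples=samples,
        estimates=estimates,
        ecdf_x=s,
        ecdf_F=np.arange(1, N + 1) / N,
        qq_theoretical=norm.ppf(plotting),
        qq_empirical=s,
        ks_stat=ks_statistic(samples),
        sample_mean=float(samples.mean()),
        sample_var=float(samples.var(ddof=1)),
        n_dropped=n_dropped,
        meta=meta,
    )


def _replicate(config: StudyConfig, rng: np.random.Generator):
    return generate_plm_dataset(
        config.n,
        beta=config.beta0,
        covariate_fn=config.covariate_fn,
        f_fn=config.f_fn,
        error_config=config.error_config,
        rng_seed=rng,
    )


def run_beta_study(config: StudyConfig) -> NormalityReport:
    """Monte-Carlo normality check of the standardized DOLS statistic.

    Each replication regenerates the design, fits DOLS, and standardizes by
    the exact finite-sample τ²_β built from the exchangeable error moments.
    With a degenerate (zero-variance) error law the statistics are reported
    unstandardized (they are identically zero when f ≡ 0).
    """
    if len(config.beta0) != 1:
        raise ValueError("normality reports currently cover scalar-β studies")
    rng = np.random.default_rng(config.seed)
    seq = config.seq
    beta0 = np.asarray(config.beta0, dtype=float)
    var_e, cov_e = exact_error_moments(config.error_config)
    sigma2_eff = var_e - cov_e

    samples = np.empty(config.reps)
    betas = np.empty(config.reps)
    cov = None
    kept = dropped = 0
    while kept < config.reps:
        data = _replicate(config, rng)
        try:
            fit = fit_dols(data, seq)
            if sigma2_eff > 0:
                if cov is None:  # deterministic design: same X̃ every replication
                    cov = tau2_beta_exchangeable(seq, fit.X_tilde, var_e, cov_e)
                M = standardize_beta(fit, cov, beta0)
            else:
                M = fit.n_diff ** -0.5 * fit.Sigma_n @ (fit.beta_hat - beta0)
        except np.linalg.LinAlgError:
            dropped += 1
            if dropped > _MAX_DROP_FRACTION * config.reps:
                raise RuntimeError(
                    f"more than {_MAX_DROP_FRACTION:.0%} of replications failed "
                    "positive-definiteness checks"
                )
            continue
        samples[kept] = M[0]
        betas[kept] = fit.beta_hat[0]
        kept += 1
    meta = {
        "statistic": "beta",
        "n": config.n,
        "var_e": var_e,
        "cov_e": cov_e,
        "beta_mean": float(betas.mean()),
        "beta_sd": float(betas.std(ddof=1)),
    }
    return _make_report(samples, betas, dropped, meta)


def run_f_study(config: StudyConfig) -> NormalityReport:
    """Monte-Carlo normality check of ``(f̂(t*) - f(t*)) / τ_t``.

    Per replication: full pipeline (DOLS, then the kernel-weighted residual
    average at t*), standardized by τ_t computed once from the exact error
    covariance.  Raises if the error law is degenerate (τ_t = 0) or if t* is
    so close to the boundary that the kernel weights fail to normalize.
    """
    if len(config.beta0) != 1:
        raise ValueError("normality reports currently cover scalar-β studies")
    rng = np.random.default_rng(config.seed)
    seq = config.seq
    beta0 = np.asarray(config.beta0, dtype=float)
    n = config.n
    resolution = (
        config.resolution if config.resolution is not None else choose_resolution(n)
    )
    kernel = ReproducingKernel(
        build_scaling_function(config.kernel_family, config.refinement), resolution
    )
    partition = Partition.uniform(n)
    w = kernel_weights(kernel, partition, config.t_eval)
    if abs(w.sum() - 1.0) > 0.05:
        raise ValueError(
            f"kernel weights at t*={config.t_eval} sum to {w.sum():.3f}; "
            "the evaluation point is too close to the boundary for this resolution"
        )
    var_e, cov_e = exact_error_moments(config.error_config)
    C = np.full((n, n), cov_e)
    np.fill_diagonal(C, var_e)
    tau2_t = tau2_t_plugin(w, C)
    if tau2_t <= 0:
        raise ValueError("tau_t = 0: the error law is degenerate (noiseless)")
    tau_t = math.sqrt(tau2_t)
    f_fn = config.f_fn if config.f_fn is not None else (lambda t: np.sin(2 * np.pi * t))
    f_true = float(np.asarray(f_fn(np.asarray([config.t_eval])))[0])

    samples = np.empty(config.reps)
    f_hats = np.empty(config.reps)
    kept = dropped = 0
    while kept < config.reps:
        data = _replicate(config, rng)
        try:
            fit = fit_dols(data, seq)
        except np.linalg.LinAlgError:
            dropped += 1
            if dropped > _MAX_DROP_FRACTION * config.reps:
                raise RuntimeError(
                    f"more than {_MAX_DROP_FRACTION:.0%} of replications failed "
                    "positive-definiteness checks"
                )
            continue
        resid = data.y - data.X @ fit.beta_hat
        f_hat = float(w @ resid)
        samples[kept] = (f_hat - f_true) / tau_t
        f_hats[kept] = f_hat
        kept += 1
    meta = {
        "statistic": "f",
        "n": config.n,
        "t_eval": config.t_eval,
        "resolution": resolution,
        "tau_t": tau_t,
        "var_e": var_e,
        "cov_e": cov_e,
        "f_true": f_true,
        "f_hat_mean": float(f_hats.mean()),
    }
    return _make_report(samples, f_hats, dropped, meta)


@dataclass(frozen=True)
class MomentInequalityReport:
    """Monte-Carlo LHS over analytic RHS of a maximal moment inequality."""

    p: float
    n: int
    reps: int
    lhs: float
    lhs_se: float
    rhs: float
    weighted: bool

    @property
    def ratio(self) -> float:
        return self.lhs / self.rhs

    @property
    def ratio_se(self) -> float:
        return self.lhs_se / self.rhs

    def holds(self, n_se: float = 3.0) -> bool:
        """Whether ratio <= 1 within ``n_se`` Monte-Carlo standard errors."""
        return self.ratio <= 1.0 + n_se * self.ratio_se


def check_moment_inequality(
    p: float,
    n: int,
    reps: int,
    seq: DifferenceSequence | None = None,
    seed: int = 0,
    error_config: NSDErrorConfig | None = None,
) -> MomentInequalityReport:
    """Monte-Carlo check of the Rosenthal-type maximal inequalities.

    Without ``seq``: bounds ``E max_k |Σ_{i<=k} e_i|^p`` by
    ``2^{3-p} Σ_i E|e_i|^p`` for 1 < p <= 2 (and the corresponding
    ``2 (15p/ln p)^p [Σ E|e_i|^p + (Σ E e_i²)^{p/2}]`` form for p > 2).

    With ``seq``: the weighted version for differenced partial sums, with
    constant ``4 m^{p-1}`` (p <= 2) or ``2^{p+1} m^{p-1} (15p/ln p)^p``
    (p > 2).  The right-hand sums run over the n - m differenced terms, the
    form the proof actually uses (the looser printed range would index
    errors beyond the sample).

    The error law defaults to the centered conditional NSD law; pass an
    ``independent=True`` config for the iid special case.  Per-coordinate
    absolute moments on the right are computed exactly from the marginal
    conditional law.
    """
    if p <= 1:
        raise ValueError(f"need p > 1, got {p}")
    if error_config is None:
        error_config = NSDErrorConfig(default_error_pmf(), n)
    if error_config.n != n:
        raise ValueError("error_config.n must match n")
    if not error_config.center:
        raise ValueError("the inequalities assume mean-zero errors; use center=True")
    rng = np.random.default_rng(seed)
    from .nsd_sim import sample_conditional  # local import to keep module load light

    draws = sample_conditional(error_config, rng, size=reps)  # (reps, n)
    values, probs = conditional_marginal(error_config)
    e_abs_p = float((np.abs(values) ** p) @ probs)
    e_sq = float((values**2) @ probs)

    if seq is None:
        series = draws
        n_terms = n
        if p <= 2:
            rhs = 2.0 ** (3.0 - p) * n_terms * e_abs_p
        else:
            rhs = 2.0 * (15.0 * p / math.log(p)) ** p * (
                n_terms * e_abs_p + (n_terms * e_sq) ** (p / 2.0)
            )
    else:
        m = seq.order
        if n <= m:
            raise ValueError("need n > m for the weighted inequality")
        d = seq.weights
        series = sum(d[q] * draws[:, q : q + n - m] for q in range(m + 1))
        n_terms = n - m
        sum_abs_d_p = float((np.abs(d) ** p).sum())
        if p <= 2:
            rhs = 4.0 * m ** (p - 1.0) * n_terms * sum_abs_d_p * e_abs_p
        else:
            const = 2.0 ** (p + 1.0) * m ** (p - 1.0) * (15.0 * p / math.log(p)) ** p
            rhs = const * (
                n_terms * sum_abs_d_p * e_abs_p
                + (n_terms * float((d**2).sum()) * e_sq) ** (p / 2.0)
            )
    stats = np.abs(np.cumsum(series, axis=1)).max(axis=1) ** p
    lhs = float(stats.mean())
    lhs_se = float(stats.std(ddof=1) / math.sqrt(reps))
    return MomentInequalityReport(
        p=p, n=n, reps=reps, lhs=lhs, lhs_se=lhs_se, rhs=float(rhs),
        weighted=seq is not None,
    )
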