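# Methods note

## Model and estimators

Observations follow y_i = x_i'β + f(t_i) + e_i with deterministic
nondecreasing design points t_i ∈ [0, 1], an unknown smooth f, and
mean-zero errors that may be negatively superadditively dependent (NSD).
The reference example of NSD dependence used throughout is an iid
integer-valued sequence conditioned on its sum, which is exchangeable with
a common negative pairwise covariance.

**DOLS.** A difference sequence d_0 … d_m (Σ d_q = 0, Σ d_q² = 1) is slid
across the sample, giving ỹ = Dy, X̃ = DX for the banded (n−m)×n matrix D.
Differencing annihilates constants exactly and smooth signals to O(1/n), so
OLS on (ỹ, X̃) estimates β free of f: β̂ = Σ_n⁻¹ X̃'ỹ, Σ_n = X̃'X̃. The
default sequence is the order-3 "simple" sequence d_0 = √(m/(m+1)),
d_q = −1/√(m(m+1)).

**Limiting variance of β̂.** For iid errors with variance σ², the
differenced errors have autocovariance Cov(ẽ_i, ẽ_{i+k}) = γ_k σ² with lag
weights γ_k = Σ_q d_q d_{q+k} (γ = [1, −1/12, −1/6, −1/4] at m = 3), giving
the closed form `tau2_beta_iid`. Exchangeable errors with variance v and
common covariance c reduce exactly to the iid form with effective variance
v − c, because differencing kills the common component
(`tau2_beta_exchangeable`). A residual-based HAC-type plug-in
(`tau2_beta_plugin`) truncates the autocovariance double sum at a lag
(default m + 5: the true autocovariance of differenced iid errors vanishes
beyond m; the surplus guards mild extra dependence). The truncated sum is
not guaranteed positive semidefinite; negative eigenvalues are clipped at
zero with a warning.

**Wavelet estimator of f.** f̂(t) = Σ_i (y_i − x_i'β̂) w_i(t) with
w_i(t) = ∫_{A_i} E_m̃(t, s) ds, where E_m̃ is the reproducing kernel of the
multiresolution space at resolution m̃ generated by a compactly supported
scaling function φ, and {A_i} is a partition of [0, 1] with t_i ∈ A_i. Its
pointwise standard deviation is τ_t = (w'Cov(e)w)^½ (`tau2_t_plugin`).

## Parameter choices and why

- **Resolution rule** (`choose_resolution`): m̃ is the smallest integer
  with 2^m̃ ≥ n^(1/3) (m̃ = 1 at n = 8, 2 at n = 64, 3 at n = 128). The
  theory requires 2^m̃ = O(n^(1/3)); taking the smallest *covering* dyadic
  rather than the largest dyadic below n^(1/3) matters in practice: at
  n = 128 the coarser choice m̃ = 2 leaves enough smoothing bias in f̂ that
  the standardized statistic acquires a mean shift growing like √n and its
  variance collapses well below 1, destroying the normal approximation the
  rule exists to serve.
- **Lag truncation** default m + 5 (see above).
- **Scaling functions**: Haar (exact closed forms for everything) and
  Daubechies-N via the cascade algorithm of PyWavelets at refinement level
  J (default 10, i.e. a table at step 2^−10 over the support [0, 2N−1]).
  φ is Lipschitz for N ≥ 2, so linear interpolation of the table has error
  O(2^−J); J ≥ 6 is enforced.
- **Quadrature** for w_i(t): fixed-order Gauss–Legendre (order 8) on each
  partition interval. Haar bypasses quadrature with the exact
  interval-overlap formula. Because the tabulated φ is piecewise linear,
  Gauss–Legendre and refined-trapezoid answers agree to ~1e−4, not machine
  precision; Haar closed forms vs quadrature on dyadic-aligned partitions
  agree to 1e−8 (the integrand is interval-wise constant there, where
  Gauss–Legendre is exact).
- **Boundary handling**: no periodization or reflection; the kernel sum is
  truncated at the edge of [0, 1]. `run_f_study` refuses evaluation points
  where the weights fail to normalize (|Σ w_i − 1| > 0.05). Interior means
  |t − edge| ≳ (support width)·2^−m̃.
- **Numerical floors**: the inverse symmetric square root used by
  `standardize_beta` refuses eigenvalues ≤ 1e−12; `fit_dols` rejects
  condition numbers above 1e12 and also rejects a Σ_n whose smallest
  eigenvalue is ≤ 1e−12 times the raw design scale Σ x² (a 1×1 matrix
  always has condition number 1, so a covariate annihilated by differencing
  would otherwise slip through).

## The error generator and its realism

`sample_conditional` draws the conditional law exactly. A
dynamic-programming table stores P(S_k = s) for all k ≤ n (each row
renormalized for stability); the sampler then draws e_i sequentially from
P(e_i = a | remaining sum r, k variables left) ∝ p_a P(S_{k−1} = r − a).
The product of these step probabilities equals the true conditional path
probability, so the scheme is exact — no rejection, O(n) per draw, and
every uncentered draw sums to the target exactly. Centering subtracts the
conditional coordinate mean target/n.

Exact moments come from one- and two-coordinate enumeration against the
same table (`exact_error_moments`); for the default three-point law at
n = 128, Var(e_i) = 0.79922 and Cov(e_i, e_j) = −0.0062930 = −Var/(n−1)
exactly (the sum is constant). The Monte-Carlo studies standardize with
these exact moments rather than per-replication residual plug-ins: the
limit theorems standardize by the theoretical τ, and plug-in noise would
contaminate the normality diagnostic.

Realism caveats: the conditional construction produces one specific NSD
family — exchangeable, integer-valued, with O(1/n) negative correlation.
It does not represent NSD sequences with strong or serially decaying
dependence, and conclusions from the studies should be read as "the
theory's reference design", not as coverage of the whole NSD class. The
`independent=True` escape hatch gives the iid special case as a control.

## Known finite-sample behavior and limitations

- **The reference design is nearly degenerate for β.** x = cos(2πt) is
  itself smooth in t, so differencing attenuates it like f: Σ_n ≈ 6π²/n
  (≈ 0.46 at n = 128) instead of growing like n. β̂ is still consistent
  and asymptotically normal, but sd(β̂) ≈ 0.115 at n = 128, HAC plug-ins
  built from these tiny differenced covariates are fragile (they can be
  clipped to zero), and real-data users should prefer covariates that are
  not smooth functions of t.
- **Exact variance of the standardized f statistic.** The statistic
  (f̂(0.5) − f(0.5))/τ_t is affine in the error vector; its exact variance
  at n = 128, m̃ = 3 is 0.830, not 1, because the β̂-error term in f̂ is
  only O(n^(−1/6)) relative to τ_t and is negatively correlated with the
  direct error term. Sample variances over 1000 replications therefore
  scatter around 0.83 with standard error ≈ 0.04 across seeds. This is a
  finite-sample property of the design, not an implementation artifact;
  the tests compare Monte-Carlo output against this exact affine-form
  oracle where tolerance matters.
- **Resolution granularity.** m̃ is an integer, so the effective bandwidth
  jumps by factors of 2; the sup-norm error of f̂ is not monotone in n
  between dyadic thresholds.
- **Moment inequalities.** The weighted maximal inequality is checked in
  the form whose right-hand sum runs over the n − m differenced terms
  (the variant that stays inside the sample); observed Monte-Carlo
  LHS/RHS ratios are far below 1 (0.01–0.35 across p ∈ [1.5, 3]).
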