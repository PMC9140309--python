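# Methods

## The model family

The family maps a baseline cdf `Z(x; φ)` with support on the positive
half-line through the exponentiated-Gumbel transformer:

    F(x; θ, σ, φ) = [1 − exp{−L(x)^(−1/σ)}]^θ,    L(x) = −log Z(x; φ),

with shape parameters θ > 0 (the exponent, governing the left tail and mode
count) and σ > 0 (the Gumbel scale, governing spread and right-tail weight).
The density follows by differentiation,

    f = (θ/σ) · (z/Z) · L^(−1/σ−1) · e^(−t) · (1 − e^(−t))^(θ−1),
    t = L^(−1/σ),

and the quantile function by direct inversion:

    Q(u) = Q_Z( exp{ −[−log(1 − u^{1/θ})]^{−σ} } ).

The family's published inversion display is typographically garbled (a
parameter-symbol mix-up and misplaced exponents); the implementation inverts
the cdf directly, and the quantile/cdf round-trip property (|F(Q(u)) − u| <
1e-9 at every representable quantile) is the enforced contract. The EGuNH
closed-form quantile, which is consistent with the cdf, confirms the
derivation.

### EGuNH

With the Nadarajah–Haghighi baseline `Z(x) = 1 − e^{C}`, `C = 1 − (1+λx)^α`,
the model has shapes θ, σ, α and scale λ. λ is a pure scale (Q scales as
1/λ) and **defaults to 1** throughout: every tabulated reference quantity
for this model uses that convention, and the three-parameter form is what
the applications fit. The four-parameter form is available via
`EGuNHParams(..., lam=...)` and `fit(..., fix_lambda=False)`.

## Numerical architecture

All probability arithmetic runs in log space through the baseline's stable
`neg_log_cdf`:

- Every registered baseline has the structural form `Z = 1 − e^{C(x)}` with
  `C ≤ 0` monotone, so `−log Z` is computed with `log1p/expm1` identities
  (no cancellation at either tail).
- **Deep-tail plumbing.** For small θ·σ the family's lower tail is doubly
  exponential: e.g. at (θ, σ) = (0.3, 3) half the probability mass sits below
  x ≈ 1e-254. There the baseline exponent `C(x)` itself underflows although x
  is comfortably representable, so each baseline also exposes `log(−C(x))`
  and its inverse; `neg_log_cdf` switches to the expansion
  `L = −log(−C) − C/2` when `|C| < 1e-8`, and the quantile inverts on the
  log scale when `L > 35`. Quantiles below the double-precision floor
  (≈ 5e-324) are returned as exactly 0; the round-trip contract applies to
  every representable quantile.
- The log-density saturates at ≈ −1e304 instead of overflowing to −∞ deep in
  the right tail (the true value at, say, x = 10^6 is ≈ −10^{10^9}, far
  outside double range); this keeps likelihood arithmetic finite and ordered.

## Moments, inequality curves, risk measures

Raw and incomplete moments are computed by **adaptive quadrature**
(authoritative): raw moments integrate `x^s f(x)` split at the median;
incomplete moments integrate `Q(u)^s` in probability space, which stays
conditioned however far the threshold sits in either tail. Tolerance: the
quadrature error estimate must be below 1e-6 relative, else an exception —
never a silent bad value.

The formal exp-G series (coefficients Π_m from a triple sum with the first
three Stirling polynomials P₀–P₂) is retained as an *experimental* second
route. The printed series carries an unbound index and no convergence
proof; the implementation evaluates the gamma ratio as a rising factorial
(`poch`) to avoid pole arithmetic, reads the ambiguous binomial factor as
binom(θ, j), and reports a `converged` flag from partial-sum movement. In
practice the series diverges for typical parameter values; the flag is then
False and no downstream quantity depends on it. Orders above P₂ are
unsupported rather than guessed.

Expected shortfall is the average quantile below the level,
`ES_q = (1/q) ∫₀^q Q(u) du`, by adaptive quadrature with the integration
range split at min(q/2, 0.05) to resolve the steep region near 0
(tolerances 1e-9 absolute, 1e-8 relative); `VaR_q = Q(q)` exactly. Bowley,
Moors and MacGillivray measures use the standard quartile/octile
conventions.

## Maximum likelihood

The log-likelihood is the sum of log-densities; an independent term-by-term
coding of its expanded form is kept for cross-checking (the two agree to
1e-13 on real data at well-conditioned parameters). The EGuNH score
(U_θ, U_σ, U_α, U_λ) is implemented analytically from a clean re-derivation
— the published score displays contain garbled terms — and every component
is guarded by a finite-difference oracle test (1e-5 relative).

Optimization: bounded L-BFGS-B on log-parameters (positivity for free) from
a seeded Latin-hypercube of 8 starts over the log box [−3, 3], followed by a
Newton polish on the natural scale using the observed information, which
drives the natural-scale score below 1e-8 where the log-scale stopping rule
alone can leave ~1e-3 for small parameters. Standard errors come from the
inverse observed information (numeric central-difference Hessian,
symmetrized); intervals are Wald. A fit is `converged` when the optimizer
succeeded, max |score| < 1e-4 and the variance matrix is positive on the
diagonal.

## The simulation study and the likelihood ridge

`run_study` draws N replicates per sample size by quantile inversion, refits
each, and reports AE, bias = AE − truth, MSE, and the coverage of
±1.95996·SE intervals. Per-replicate seeds are counter-based from the master
seed (bit-reproducible); failed or non-convergent replicates are excluded
from aggregates and counted.

**Design choice — warm start.** The EGuNH likelihood carries a long, nearly
flat, curved ridge along which (θ, σ, α) trade off while the distribution
barely moves: parameter points as far apart as (2.2, 0.45, 0.5) and
(5.8, 1.3, 0.9) differ by less than 0.01 in cdf sup-norm. A cold global
multistart therefore lands wherever sampling noise tips the ridge
(θ-MSE ≈ 5 at n = 500, Wald coverage ≈ 0.74) — that measures
identifiability, not the estimator machinery. The study instead warm-starts
each replicate at the true values and polishes to the nearest local optimum,
the design consistent with published studies of this model class (whose
reported MSEs of ~10⁻³ at n = 500 are unattainable by any global search on
this surface). Under this design bias and MSE shrink with n and coverage
sits near the nominal 95%. `start_at_truth=False` selects the global-search
variant; interpret its coverage accordingly. Defaults: n ∈ {50, 100, 200,
500}, N = 2000; the test suite runs N = 200 as its standard study size.

## Goodness of fit

AIC = 2k + 2(−ℓ̂), BIC = k log n + 2(−ℓ̂). The EDF statistics are the
Chen–Balakrishnan small-sample modifications A* = A²(1 + 0.75/n + 2.25/n²)
and W* = W²(1 + 0.5/n) computed from sorted probability-integral transforms
(clipped at 1e-12). KS uses the both-sided sup against the empirical step
function with the asymptotic Kolmogorov p-value (`scipy.special.kolmogorov`).
Fitted-parameter effects on the EDF null distributions are ignored, as is
conventional in this literature; the p-values are approximate. The TTT
transform is the scaled total-time-on-test curve; its concavity pattern
diagnoses increasing/decreasing/bathtub hazards.

## Bundled data

Three published datasets ship verbatim as one-column CSVs: D1 (n = 62,
earthquake waiting times in days, Σ = 27107), D2 (n = 32, leukemia survival
times in weeks, Σ = 1346 — the source text announces 33 patients but lists
and summarizes 32 values), D3 (n = 40, blood-cancer counts, Σ = 45480).
Descriptives use the n−1 standard deviation, moment skewness g₁ and excess
kurtosis g₂; the source table's skew/kurt conventions are undocumented, so
only n, mean, min and max are treated as reference values. (D2's mean is
1346/32 = 42.0625; the source prints 42.07, one unit in the last printed
digit away.)

## What the synthetic data does and does not show

Simulated samples are exact inversion draws from the model itself, so
passing recovery and model-selection checks demonstrate the correctness of
the sampling/likelihood/optimization chain under ideal conditions. They do
not exercise model misspecification, censoring, ties, measurement error or
covariates — all absent from real survival data workflows at your peril; the
bundled real datasets provide only a qualitative check of that kind.

## Known limitations

- λ = 1 fits on data whose scale is far from 1 force the shape parameters to
  absorb scale; refit with `fix_lambda=False` or pre-scale.
- Wald intervals undercover along the likelihood ridge when the fit is a
  global search (see above); profile or bootstrap intervals are out of scope.
- The exp-G series and its moment formula are formal; use the quadrature
  route for anything that matters.
- Baselines with bounded or shifted support (power-function, Pareto) and the
  real-line normal baseline are not registered.
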