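"""Generic exponentiated Gumbel-G (EGuG) family over any baseline.

The family maps a baseline cdf ``Z(x; phi)`` through the exponentiated-Gumbel
transformer, giving

    F(x; theta, sigma, phi) = [1 - exp{-(-log Z(x))^(-1/sigma)}]^theta,

with shape parameters ``theta > 0`` (exponent) and ``sigma > 0`` (Gumbel
scale).  All arithmetic runs in log space through the baseline's stable
``neg_log_cdf``, so the functions stay finite over the whole support.

The exp-G series machinery (``expansion_coefficients``) is an experimental
re-expression of the cdf as a linear combination of powers of the baseline
cdf; it carries a convergence diagnostic and is never the authoritative path
for any downstream quantity — quadrature and closed forms are.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import special

from .baselines import BaselineSpec

__all__ = [
    "FamilyParams",
    "ExpansionCoefficients",
    "family_cdf",
    "family_pdf",
    "family_logpdf",
    "family_sf",
    "family_hrf",
    "family_chrf",
    "family_quantile",
    "family_sample",
    "stirling_polynomial",
    "expansion_coefficients",
    "order_stat_pdf",
    "shape_diagnosis",
]


@dataclass(frozen=True)
class FamilyParams:
    """Family shape parameters plus the baseline they act on."""

    theta: float
    sigma: float
    baseline: BaselineSpec

    def __post_init__(self):
        for k in ("theta", "sigma"):
            v = getattr(self, k)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{k} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class ExpansionCoefficients:
    """Truncated exp-G series coefficients Pi_m with a convergence flag."""

    order: int
    pi_m: np.ndarray
    converged: bool


def _log1mexp(a):
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(a > -np.log(2.0), np.log(-np.expm1(a)), np.log1p(-np.exp(a)))


def _t_of_x(x, p: FamilyParams):
    """t(x) = (-log Z(x))^(-1/sigma), the transformed Gumbel argument."""
    L = p.baseline.neg_log_cdf(x)
    with np.errstate(divide="ignore", over="ignore"):
        return np.exp(-np.log(L) / p.sigma)


def family_cdf(x, p: FamilyParams):
    """EGuG cdf; 0 below the baseline support, 1 above it."""
    x = np.asarray(x, dtype=float)
    lo, hi = p.baseline.support
    t = _t_of_x(np.clip(x, lo, hi), p)
    with np.errstate(divide="ignore", invalid="ignore"):
        logF = p.theta * _log1mexp(-t)
    out = np.where(t == 0.0, 0.0, np.exp(logF))
    out = np.where(np.isinf(t), 1.0, out)
    return np.where(x <= lo, 0.0, np.where(x >= hi, 1.0, out))


def family_logpdf(x, p: FamilyParams):
    """Log of the family density at interior points (``-inf`` where pdf is 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # floor L against deep-tail underflow; cap the exponent so the huge
        # negative log-density saturates rather than overflowing to -inf
        L = np.maximum(p.baseline.neg_log_cdf(x), 1e-320)
        logL = np.log(L)
        t = np.exp(np.minimum(-logL / p.sigma, 700.0))
        lp = (
            np.log(p.theta)
            - np.log(p.sigma)
            + p.baseline.log_pdf(x)
            + L
            - (1.0 / p.sigma + 1.0) * logL
            - t
            + (p.theta - 1.0) * _log1mexp(-t)
        )
    return np.where(np.isfinite(lp), lp, -np.inf)


def family_pdf(x, p: FamilyParams):
    """EGuG density; returns 0 (not an error) where the baseline pdf is 0."""
    x = np.asarray(x, dtype=float)
    lo, hi = p.baseline.support
    inside = (x > lo) & (x < hi)
    with np.errstate(invalid="ignore", over="ignore"):
        # the density exceeds the double range at unrepresentably small x for
        # some shape combinations; inf is the faithful answer there
        val = np.exp(family_logpdf(np.clip(x, lo, hi), p))
    return np.where(inside, val, 0.0)


def family_sf(x, p: FamilyParams):
    return 1.0 - family_cdf(x, p)


def family_hrf(x, p: FamilyParams):
    """Hazard rate pdf/sf; raises where the survival function underflows to 0."""
    sf = family_sf(x, p)
    if np.any(sf <= 0.0):
        raise FloatingPointError("hazard rate undefined: survival function underflows to 0")
    return family_pdf(x, p) / sf


def family_chrf(x, p: FamilyParams):
    """Cumulative hazard -log S(x)."""
    with np.errstate(divide="ignore"):
        return -np.log(family_sf(x, p))


def family_quantile(u, p: FamilyParams):
    """Quantile by direct inversion of the family cdf.

    Q(u) = Q_Z(exp{-[-log(1 - u^(1/theta))]^(-sigma)}); the inner probability
    is routed through the baseline's ``quantile_from_neg_log_cdf`` so that
    extreme u do not underflow.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("family_quantile: u must lie strictly inside (0, 1)")
    # t = -log(1 - u^{1/theta}) ; L = t^{-sigma} ; Z = exp(-L)
    t = -_log1mexp(np.log(u) / p.theta)
    L = np.exp(-p.sigma * np.log(t))
    return p.baseline.quantile_from_neg_log_cdf(L)


def family_sample(n: int, p: FamilyParams, seed: int):
    """n i.i.d. draws by quantile inversion of uniforms; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # keep u strictly interior (uniform() is [0,1))
    u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    return family_quantile(u, p)


# -- exp-G series machinery (experimental) -------------------------------------

_STIRLING = {
    0: lambda c: 0.5,
    1: lambda c: c * (3.0 * c + 5.0) / 24.0,
    2: lambda c: c * (c**2 + 5.0 * c + 6.0) / 48.0,
}


def stirling_polynomial(k: int, c: float) -> float:
    """Stirling polynomials P_k(c): only orders 0..2 are defined here.

    P_0 = 1/2, P_1(c) = c(3c+5)/24, P_2(c) = c(c^2+5c+6)/48.  Higher orders
    are not supported.
    """
    if k not in _STIRLING:
        raise ValueError(f"stirling_polynomial: unsupported order k={k} (only 0, 1, 2)")
    return float(_STIRLING[k](c))


def _log_binom_real(a: float, j: int) -> tuple[float, float]:
    """(sign, log|binom(a, j)|) for real a > 0, integer j >= 1."""
    # binom(a, j) = a (a-1) ... (a-j+1) / j!
    terms = a - np.arange(j)
    sign = np.prod(np.sign(terms))
    with np.errstate(divide="ignore"):
        logmag = np.sum(np.log(np.abs(terms))) - lgamma(j + 1)
    return float(sign), float(logmag)


def expansion_coefficients(
    p: FamilyParams,
    M: int,
    i_max: int = 40,
    j_max: int = 40,
    tol: float = 1e-6,
) -> ExpansionCoefficients:
    """Coefficients Pi_m of the formal exp-G series F(x) = sum_m Pi_m Z(x)^m.

    The triple sum over (i, j, k) uses the three printed Stirling polynomials
    and a rising-factorial evaluation of the gamma ratio.  The series has no
    convergence guarantee; ``converged`` reports whether the partial sums of
    sum_m Pi_m (which should approach 1) moved less than ``tol`` over the last
    decade of m.  Non-convergence is a flag, never an error.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    i_arr = np.arange(1, i_max + 1)
    j_arr = np.arange(1, j_max + 1)
    # per-j: (-1)^j * binom(theta, j) / j!  (signed log)
    j_sign = np.empty(j_max)
    j_logmag = np.empty(j_max)
    for jj, j in enumerate(j_arr):
        s, lm = _log_binom_real(p.theta, j)
        j_sign[jj] = s * (-1.0) ** j
        j_logmag[jj] = lm - lgamma(j + 1)
    pi = np.zeros(M)
    for m in range(1, M + 1):
        total = 0.0
        for k in (0, 1, 2):
            a_i = -(i_arr / p.sigma) * (k + 1)  # gamma-ratio argument per i
            ratio = special.poch(a_i, m)  # Gamma(a+m)/Gamma(a)
            Pk = np.array([stirling_polynomial(k, -i / p.sigma) for i in i_arr])
            # sum over i, j of (-1)^{i+j} j^i binom(theta,j) ratio_i Pk_i /(i! j! m)
            with np.errstate(divide="ignore"):
                log_i = -special.gammaln(i_arr + 1)
            for jj, j in enumerate(j_arr):
                with np.errstate(over="ignore"):
                    mag = np.exp(i_arr * np.log(j) + log_i + j_logmag[jj])
                term = ((-1.0) ** i_arr) * j_sign[jj] * mag * ratio * Pk
                term = term[np.isfinite(term)]
                total += term.sum()
        pi[m - 1] = ((-1.0) ** (m + 1)) * total / m
    pi = np.where(np.isfinite(pi), pi, 0.0)
    csum = np.cumsum(pi)
    tail = max(1, M // 10)
    movement = float(np.max(np.abs(np.diff(csum[-(tail + 1):])))) if M > 1 else np.inf
    return ExpansionCoefficients(order=M, pi_m=pi, converged=bool(movement < tol))


def order_stat_pdf(x, i: int, n: int, p: FamilyParams):
    """Density of the i-th order statistic of an EGuG sample of size n.

    Exact beta form f_{i:n} = f F^{i-1} (1-F)^{n-i} / B(i, n-i+1).
    """
    if not (1 <= i <= n):
        raise ValueError(f"rank i={i} out of range for n={n}")
    F = family_cdf(x, p)
    f = family_pdf(x, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = (i - 1) * np.log(F) + (n - i) * np.log1p(-F) - special.betaln(i, n - i + 1)
        out = f * np.exp(logw)
    return np.where(np.isfinite(out), out, 0.0)


# -- numeric shape diagnosis ---------------------------------------------------

def _refine_crossing(fun, a, b, it=80):
    fa = fun(a)
    for _ in range(it):
        m = 0.5 * (a + b)
        fm = fun(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def _critical_points(logf, grid):
    d = np.diff(logf) / np.diff(np.log(grid))
    finite = np.isfinite(d)
    crits = []
    kinds = []
    for idx in range(len(d) - 1):
        if not (finite[idx] and finite[idx + 1]):
            continue
        if d[idx] > 0 >= d[idx + 1]:
            crits.append(0.5 * (grid[idx] + grid[idx + 2]))
            kinds.append("max")
        elif d[idx] < 0 <= d[idx + 1]:
            crits.append(0.5 * (grid[idx] + grid[idx + 2]))
            kinds.append("min")
    # merge near-duplicates
    merged, mk = [], []
    for c, k in zip(crits, kinds):
        if merged and abs(c - merged[-1]) < 1e-6:
            continue
        merged.append(c)
        mk.append(k)
    return merged, mk


def shape_diagnosis(p: FamilyParams, n_grid: int = 2000):
    """Classify pdf and hazard shape from sign changes of numeric derivatives.

    Returns a dict with keys ``pdf_shape`` (monotone-decreasing | unimodal |
    other), ``hrf_shape`` (increasing | decreasing | bathtub |
    upside-down-bathtub | other) and the located interior critical points.
    Ambiguous patterns at the configured resolution return "other".
    """
    qlo, qhi = family_quantile(np.array([1e-4, 1.0 - 1e-4]), p)
    qlo = max(qlo, 1e-12)
    grid = np.geomspace(qlo, qhi, n_grid)
    logf = family_logpdf(grid, p)
    f_crit, f_kind = _critical_points(logf, grid)

    with np.errstate(divide="ignore"):
        loghrf = logf - np.log(family_sf(grid, p))
    h_crit, h_kind = _critical_points(loghrf, grid)

    d0 = logf[1] - logf[0]
    if not f_crit:
        pdf_shape = "monotone-decreasing" if d0 < 0 else "other"
    elif f_kind == ["max"]:
        pdf_shape = "unimodal"
    else:
        pdf_shape = "other"

    h0 = loghrf[1] - loghrf[0]
    if not h_crit:
        hrf_shape = "increasing" if h0 > 0 else "decreasing"
    elif h_kind == ["min"]:
        hrf_shape = "bathtub"
    elif h_kind == ["max"]:
        hrf_shape = "upside-down-bathtub"
    else:
        hrf_shape = "other"

    return {
        "pdf_shape": pdf_shape,
        "pdf_critical_points": f_crit,
        "hrf_shape": hrf_shape,
        "hrf_critical_points": h_crit,
    }
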