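"""Baseline distributions for the exponentiated Gumbel-G construction.

Each baseline supplies its cdf ``Z(x; phi)``, pdf ``z(x; phi)``, quantile
``Q_Z`` and, crucially, a numerically stable ``neg_log_cdf`` giving
``-log Z(x; phi)`` — the quantity the family's link function consumes.

All registered baselines share the structural form ``Z(x) = 1 - exp(C(x))``
with ``C(x) <= 0`` nonincreasing (exponential: C = -a x; Weibull: C = -a x^b;
Rayleigh: C = -a x^2; Burr XII: C = -b log(1 + x^a); Nadarajah-Haghighi:
C = 1 - (1 + lam x)^alpha).  This lets every derived quantity be computed
through log1p/expm1 identities without cancellation at either tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np

__all__ = ["BaselineSpec", "make_baseline", "registered_baselines"]


def _log1mexp(a):
    """log(1 - exp(a)) for a < 0, stable at both ends."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            a > -np.log(2.0),
            np.log(-np.expm1(a)),
            np.log1p(-np.exp(a)),
        )


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline distribution expressed through its exponent function C.

    ``cdf(x) = 1 - exp(C(x))`` on ``support``; ``C`` is nonpositive and
    nonincreasing, with ``C -> 0`` at the lower support endpoint and
    ``C -> -inf`` at the upper one.
    """

    name: str
    phi: Dict[str, float]
    support: Tuple[float, float]
    _C: Callable[[np.ndarray, Dict[str, float]], np.ndarray] = field(repr=False)
    _log_neg_C_prime: Callable[[np.ndarray, Dict[str, float]], np.ndarray] = field(repr=False)
    _C_inv: Callable[[np.ndarray, Dict[str, float]], np.ndarray] = field(repr=False)
    # log(-C(x)) and its inverse: keep the deep-left tail alive where C itself
    # underflows (|C| < 1e-308) although x is comfortably representable
    _log_neg_C: Callable[[np.ndarray, Dict[str, float]], np.ndarray] = field(repr=False)
    _C_inv_from_log: Callable[[np.ndarray, Dict[str, float]], np.ndarray] = field(repr=False)

    # -- distribution functions -------------------------------------------------

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = -np.expm1(self._C(np.clip(x, *self.support), self.phi))
        return np.where(x <= self.support[0], 0.0, np.where(x >= self.support[1], 1.0, out))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x > self.support[0]) & (x < self.support[1])
        xc = np.clip(x, self.support[0], self.support[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = self.log_pdf(xc)
        return np.where(inside, np.exp(lp), 0.0)

    def log_pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self._log_neg_C_prime(x, self.phi) + self._C(x, self.phi)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile: u must lie in [0, 1]")
        return self._C_inv(np.log1p(-u), self.phi)

    # -- stable link-side primitives -------------------------------------------

    def neg_log_cdf(self, x):
        """-log Z(x; phi), computed without cancellation at either tail.

        Near the lower support bound, where C(x) -> 0-, the expansion
        Z = -C (1 + C/2 + ...) gives L = -log(-C) - C/2 through the baseline's
        log-scale exponent, valid even where C itself underflows to -0.0.
        """
        x = np.asarray(x, dtype=float)
        C = self._C(x, self.phi)
        with np.errstate(divide="ignore", invalid="ignore"):
            small = C > -1e-8
            direct = -_log1mexp(np.where(small, -1.0, C))
            series = -self._log_neg_C(x, self.phi) - C / 2.0
        return np.where(small, series, direct)

    def quantile_from_neg_log_cdf(self, L):
        """Inverse of ``neg_log_cdf``: x with -log Z(x) = L, for L > 0.

        Used by the family quantile, where Z = exp(-L) may under/overflow as a
        probability but L itself is well scaled.  For large L the target C is
        -e^{-L}(1 + e^{-L}/2 + ...) and the inversion runs on log(-C) = -L.
        """
        L = np.asarray(L, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            big = L > 35.0
            direct = self._C_inv(_log1mexp(np.where(big, 1.0, -L)), self.phi)
            deep = self._C_inv_from_log(-L, self.phi)
        return np.where(big, deep, direct)


def _require_positive(phi: Dict[str, float], names) -> None:
    for k in names:
        if k not in phi:
            raise ValueError(f"missing parameter {k!r}")
        v = phi[k]
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"parameter {k!r} must be strictly positive, got {v!r}")


# -- registry ------------------------------------------------------------------

def _make_exponential(phi):
    _require_positive(phi, ["alpha"])
    return BaselineSpec(
        name="exponential",
        phi=dict(phi),
        support=(0.0, np.inf),
        _C=lambda x, p: -p["alpha"] * x,
        _log_neg_C_prime=lambda x, p: np.full_like(np.asarray(x, float), np.log(p["alpha"])),
        _C_inv=lambda c, p: -c / p["alpha"],
        _log_neg_C=lambda x, p: np.log(p["alpha"]) + np.log(x),
        _C_inv_from_log=lambda lc, p: np.exp(lc - np.log(p["alpha"])),
    )


def _make_weibull(phi):
    _require_positive(phi, ["a", "b"])
    return BaselineSpec(
        name="weibull",
        phi=dict(phi),
        support=(0.0, np.inf),
        _C=lambda x, p: -p["a"] * x ** p["b"],
        _log_neg_C_prime=lambda x, p: np.log(p["a"] * p["b"]) + (p["b"] - 1) * np.log(x),
        _C_inv=lambda c, p: (-c / p["a"]) ** (1.0 / p["b"]),
        _log_neg_C=lambda x, p: np.log(p["a"]) + p["b"] * np.log(x),
        _C_inv_from_log=lambda lc, p: np.exp((lc - np.log(p["a"])) / p["b"]),
    )


def _make_rayleigh(phi):
    _require_positive(phi, ["a"])
    return BaselineSpec(
        name="rayleigh",
        phi=dict(phi),
        support=(0.0, np.inf),
        _C=lambda x, p: -p["a"] * x**2,
        _log_neg_C_prime=lambda x, p: np.log(2.0 * p["a"]) + np.log(x),
        _C_inv=lambda c, p: np.sqrt(-c / p["a"]),
        _log_neg_C=lambda x, p: np.log(p["a"]) + 2.0 * np.log(x),
        _C_inv_from_log=lambda lc, p: np.exp((lc - np.log(p["a"])) / 2.0),
    )


def _burr12_log_neg_C(x, p):
    # log(b log(1 + x^a)); for tiny x^a, log1p(x^a) ~ x^a
    t = p["a"] * np.log(np.asarray(x, dtype=float))
    with np.errstate(over="ignore"):
        general = np.log(np.log1p(np.exp(t)))
    return np.log(p["b"]) + np.where(t < -30.0, t, general)


def _burr12_C_inv_from_log(lc, p):
    # log1p(x^a) = exp(lc)/b; for a tiny right-hand side, x^a ~ rhs
    w = np.exp(lc - np.log(p["b"]))
    with np.errstate(divide="ignore"):
        general = np.log(np.expm1(w))
    t = np.where(w < 1e-15, np.log(w), general)  # t = a log x
    return np.exp(t / p["a"])


def _make_burr12(phi):
    _require_positive(phi, ["a", "b"])
    return BaselineSpec(
        name="burr12",
        phi=dict(phi),
        support=(0.0, np.inf),
        _C=lambda x, p: -p["b"] * np.log1p(x ** p["a"]),
        _log_neg_C_prime=lambda x, p: (
            np.log(p["a"] * p["b"]) + (p["a"] - 1) * np.log(x) - np.log1p(x ** p["a"])
        ),
        _C_inv=lambda c, p: np.expm1(-c / p["b"]) ** (1.0 / p["a"]),
        _log_neg_C=_burr12_log_neg_C,
        _C_inv_from_log=_burr12_C_inv_from_log,
    )


def _nh_log_neg_C(x, p):
    # log(expm1(alpha log1p(lam x))); for a tiny argument expm1(u) ~ u
    u = p["alpha"] * np.log1p(p["lam"] * np.asarray(x, dtype=float))
    with np.errstate(divide="ignore"):
        small = np.log(p["alpha"]) + np.log(np.log1p(p["lam"] * np.asarray(x, dtype=float)))
        general = np.log(np.expm1(np.where(u > 1e-10, u, 1.0)))
    return np.where(u > 1e-10, general, small)


def _nh_C_inv_from_log(lc, p):
    # expm1(alpha log1p(lam x)) = exp(lc)
    v = np.exp(lc)
    u = np.where(v < 1e-15, v, np.log1p(v))  # u = alpha log1p(lam x)
    return np.expm1(u / p["alpha"]) / p["lam"]


def _make_nh(phi):
    _require_positive(phi, ["alpha", "lam"])
    return BaselineSpec(
        name="nh",
        phi=dict(phi),
        support=(0.0, np.inf),
        _C=lambda x, p: -np.expm1(p["alpha"] * np.log1p(p["lam"] * x)),
        _log_neg_C_prime=lambda x, p: (
            np.log(p["alpha"] * p["lam"]) + (p["alpha"] - 1) * np.log1p(p["lam"] * x)
        ),
        _C_inv=lambda c, p: np.expm1(np.log1p(-c) / p["alpha"]) / p["lam"],
        _log_neg_C=_nh_log_neg_C,
        _C_inv_from_log=_nh_C_inv_from_log,
    )


_REGISTRY: Dict[str, Callable[[Dict[str, float]], BaselineSpec]] = {
    "exponential": _make_exponential,
    "weibull": _make_weibull,
    "rayleigh": _make_rayleigh,
    "burr12": _make_burr12,
    "nh": _make_nh,
}


def registered_baselines():
    """Names of the available baselines."""
    return sorted(_REGISTRY)


def make_baseline(name: str, **phi: float) -> BaselineSpec:
    """Construct a validated :class:`BaselineSpec` from the registry.

    Parameters are strictly positive; boundary values are rejected, not
    clamped.  Unknown names raise ``KeyError``.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown baseline {name!r}; choose from {registered_baselines()}"
        ) from None
    return factory(phi)
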