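"""Model-comparison statistics and diagnostic transforms.

Implements the information criteria (AIC/BIC), the Chen-Balakrishnan
small-sample modified Anderson-Darling and Cramer-von Mises statistics

    A* = A^2 (1 + 0.75/n + 2.25/n^2),   W* = W^2 (1 + 0.5/n),

the one-sample Kolmogorov-Smirnov statistic with its asymptotic p-value, the
scaled total-time-on-test (TTT) transform whose concavity pattern diagnoses
hazard shape, and a multi-model comparison report.

Fitted-parameter effects on the null distributions of the EDF statistics are
ignored (the statistics are computed against the fitted cdf as if it were
fully specified); treat the p-values as approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .baselines import make_baseline
from .egunh import EGuNHParams, egunh_cdf
from .estimation import FitResult, fit
from .family_core import FamilyParams, family_cdf

__all__ = [
    "GoFReport",
    "information_criteria",
    "ad_cvm",
    "ks_test",
    "ttt_transform",
    "compare_models",
    "model_cdf",
]


def information_criteria(fit_result: FitResult, n: int) -> Tuple[float, float]:
    """(AIC, BIC) = (2k + 2(-l), k log n + 2(-l)) with k free parameters."""
    k = fit_result.n_free
    nll = -fit_result.loglik
    return 2.0 * k + 2.0 * nll, k * np.log(n) + 2.0 * nll


def ad_cvm(data, cdf: Callable[[np.ndarray], np.ndarray]) -> Tuple[float, float]:
    """Modified Anderson-Darling A* and Cramer-von Mises W* statistics.

    Probability-integral transforms are clipped to [1e-12, 1-1e-12]; a
    transform exactly at 0 or 1 after clipping raises, since the AD weight
    diverges there.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("ad_cvm requires n >= 2")
    u = np.clip(np.asarray(cdf(x), dtype=float), 1e-12, 1.0 - 1e-12)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("fitted cdf values must lie strictly inside (0, 1)")
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))
    w2 = np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1.0 / (12 * n)
    a_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    w_star = w2 * (1.0 + 0.5 / n)
    return float(a_star), float(w_star)


def ks_test(data, cdf: Callable[[np.ndarray], np.ndarray]) -> Tuple[float, float]:
    """One-sample KS statistic (both-sided sup) with asymptotic p-value."""
    x = np.sort(np.asarray(data, dtype=float))
    n = len(x)
    u = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    d = float(max(d_plus, d_minus))
    p = float(special.kolmogorov(np.sqrt(n) * d))
    return d, min(max(p, 0.0), 1.0)


def ttt_transform(data) -> np.ndarray:
    """Scaled TTT curve: rows (i/n, T_i), i = 0..n, starting (0,0), ending (1,1).

    T_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_(j).  A curve hugging the
    diagonal indicates a near-constant hazard; concave/convex/S patterns
    indicate increasing/decreasing/bathtub hazards.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("ttt_transform requires n >= 2")
    total = float(np.sum(x))
    if total <= 0:
        raise ValueError("ttt_transform requires a positive total")
    csum = np.cumsum(x)
    i = np.arange(1, n + 1)
    t = (csum + (n - i) * x) / total
    return np.column_stack([np.concatenate([[0.0], i / n]), np.concatenate([[0.0], t])])


# -- model comparison ----------------------------------------------------------

def model_cdf(model: str, params: Dict[str, float], baseline: Optional[str] = None):
    """A vectorized fitted-cdf callable for a named model and parameter dict."""
    if model == "egunh":
        p = EGuNHParams(**{**{"lam": 1.0}, **params})
        return lambda x: egunh_cdf(x, p)
    if model in ("nh", "exponential", "weibull", "rayleigh", "burr12"):
        phi = dict(params)
        if model == "exponential" and "rate" in phi:
            phi = {"alpha": phi["rate"]}
        b = make_baseline(model, **phi)
        return b.cdf
    if model == "egug":
        if baseline is None:
            raise ValueError("model 'egug' requires a baseline name")
        phi = {k: v for k, v in params.items() if k not in ("theta", "sigma")}
        fp = FamilyParams(
            theta=params["theta"], sigma=params["sigma"], baseline=make_baseline(baseline, **phi)
        )
        return lambda x: family_cdf(x, fp)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class GoFReport:
    """Per-model comparison table plus rankings by each criterion."""

    table: pd.DataFrame
    fits: Dict[str, FitResult]
    errors: Dict[str, str]

    def ranking(self, by: str = "aic") -> pd.Series:
        ascending = by != "ks_pvalue"
        return self.table.sort_values(by, ascending=ascending)["model"].reset_index(drop=True)


def compare_models(
    data,
    models: Sequence[str] = ("egunh", "nh"),
    seed: int = 0,
    n_starts: int = 8,
) -> GoFReport:
    """Fit each named model and assemble an information-criteria report.

    A model whose fit fails contributes an error row without aborting the
    others.  Rows are sorted by AIC.
    """
    x = np.asarray(data, dtype=float)
    n = len(x)
    rows = []
    fits: Dict[str, FitResult] = {}
    errors: Dict[str, str] = {}
    for m in models:
        try:
            fr = fit(x, model=m, seed=seed, n_starts=n_starts)
        except Exception as exc:
            errors[m] = str(exc)
            continue
        fits[m] = fr
        aic, bic = information_criteria(fr, n)
        cdf = model_cdf(m, fr.params_hat)
        a_star, w_star = ad_cvm(x, cdf)
        d_star, p_val = ks_test(x, cdf)
        rows.append(
            {
                "model": m,
                "neg_loglik": -fr.loglik,
                "aic": aic,
                "bic": bic,
                "a_star": a_star,
                "w_star": w_star,
                "ks_stat": d_star,
                "ks_pvalue": p_val,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("aic").reset_index(drop=True)
        table["rank_aic"] = np.arange(1, len(table) + 1)
    return GoFReport(table=table, fits=fits, errors=errors)
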