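"""Shared numerical helpers for the test suite."""

import numpy as np
from scipy import integrate

from egug.family_core import family_cdf, family_logpdf, family_quantile, family_sf


def integrated_mass(p, probs=(1e-7, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 1 - 1e-7)):
    """Total probability mass of a family member, integrated in log-x space.

    The density is integrated between representable quantiles (segments wider
    than ~20 log-units are chunked so the adaptive rule cannot overlook
    concentrated mass), and the cdf/sf supply the mass outside the window.
    Should equal 1 for a true density.
    """
    knots = np.array([float(family_quantile(u, p)) for u in probs])
    knots = np.clip(knots, 1e-315, None)
    s = np.unique(np.log(knots))
    edges = []
    for a, b in zip(s[:-1], s[1:]):
        chunks = max(1, int(np.ceil((b - a) / 20.0)))
        edges.extend(np.linspace(a, b, chunks + 1)[:-1])
    edges.append(s[-1])
    def integrand(t):
        # f(e^t) e^t evaluated jointly in log space: the density alone can
        # exceed the double range where x is tiny although f(x)*x is moderate
        return float(np.exp(family_logpdf(np.exp(t), p) + t))

    total = sum(
        integrate.quad(integrand, a, b, limit=200)[0] for a, b in zip(edges[:-1], edges[1:])
    )
    outside = float(family_cdf(np.exp(s[0]), p)) + float(family_sf(np.exp(s[-1]), p))
    return total + outside
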