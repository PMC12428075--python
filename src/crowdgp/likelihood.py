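"""Heteroscedastic crowd likelihood terms.

Each observed annotation y is modelled as Gaussian around the latent ground
truth f1 with variance exp(fl), where fl is the annotator's log-variance
latent function.  Under independent Gaussian marginals
N(f1 | m1, s1) and N(fl | ml, sl) the expected log density has a closed form
because E[exp(-fl)] = exp(-ml + sl/2) for a Gaussian fl.
"""

from __future__ import annotations

import numpy as np


def expected_log_density(y, m1, s1, ml, sl):
    """E[ log N(y | f1, exp(fl)) ] under f1 ~ N(m1, s1), fl ~ N(ml, sl).

    Closed form:
    ``-0.5*log(2*pi) - 0.5*ml - 0.5*((y - m1)**2 + s1) * exp(-ml + sl/2)``.
    Accepts scalars or broadcastable arrays.
    """
    y, m1, s1, ml, sl = map(np.asarray, (y, m1, s1, ml, sl))
    if not all(np.all(np.isfinite(a)) for a in (y, m1, s1, ml, sl)):
        raise ValueError("non-finite input to expected_log_density")
    if np.any(s1 < 0) or np.any(sl < 0):
        raise ValueError("variances must be non-negative")
    E = np.exp(-ml + 0.5 * sl)
    return -0.5 * np.log(2.0 * np.pi) - 0.5 * ml - 0.5 * ((y - m1) ** 2 + s1) * E


def expected_log_density_grads(y, m1, s1, ml, sl):
    """Gradients of :func:`expected_log_density` w.r.t. (m1, s1, ml, sl)."""
    y, m1, s1, ml, sl = map(np.asarray, (y, m1, s1, ml, sl))
    E = np.exp(-ml + 0.5 * sl)
    r = y - m1
    quad = r**2 + s1
    d_m1 = r * E
    d_s1 = -0.5 * E
    d_ml = -0.5 + 0.5 * quad * E
    d_sl = -0.25 * quad * E
    return d_m1, d_s1, d_ml, d_sl


def expected_log_density_gh(y, m1, s1, ml, sl, n_nodes: int = 20):
    """Gauss-Hermite cross-check of the closed form (quadrature over fl only;
    the f1 expectation is itself analytic for fixed fl)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    fl = ml + np.sqrt(sl) * nodes  # probabilists' nodes: fl ~ N(ml, sl)
    inner = -0.5 * np.log(2.0 * np.pi) - 0.5 * fl - 0.5 * ((y - m1) ** 2 + s1) * np.exp(-fl)
    return float(np.sum(weights * inner) / np.sqrt(2.0 * np.pi))


def lognormal_moments(mu, sigma2):
    """Mean and variance of exp(Z) for Z ~ N(mu, sigma2).

    These are the posterior moments of an annotator's noise variance when the
    log-variance latent function has marginal N(mu, sigma2).
    """
    mu, sigma2 = np.asarray(mu, dtype=float), np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be non-negative")
    mean = np.exp(mu + 0.5 * sigma2)
    var = np.exp(2.0 * mu + sigma2) * (np.exp(sigma2) - 1.0)
    return mean, var
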