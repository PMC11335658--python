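"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation's code paths: the BCPNN oracle
samples the three Beta posteriors directly; the EBGM oracle integrates the
posterior density by adaptive quadrature and finds quantiles by bisection on
the integrated CDF.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def bcpnn_mc_moments(a, b, c, d, n_draws: int = 200_000, seed: int = 0):
    """Monte-Carlo E(IC), V(IC) and their standard errors by sampling the
    independent Beta posteriors of the joint and marginal probabilities."""
    nxy, nx, ny, n = a, a + b, a + c, a + b + c + d
    a1 = b1 = g11 = 1.0
    al = be = 2.0
    gamma = g11 * (n + al) * (n + be) / ((nx + a1) * (ny + b1))
    rng = np.random.default_rng(seed)
    p_xy = rng.beta(nxy + g11, n - nxy + gamma - g11, size=n_draws)
    p_x = rng.beta(nx + a1, n - nx + al - a1, size=n_draws)
    p_y = rng.beta(ny + b1, n - ny + be - b1, size=n_draws)
    ic = np.log2(p_xy / (p_x * p_y))
    e_ic = float(np.mean(ic))
    v_ic = float(np.var(ic, ddof=1))
    se_e = float(np.std(ic, ddof=1) / np.sqrt(n_draws))
    # standard error of the sample variance via the fourth central moment
    m4 = float(np.mean((ic - e_ic) ** 4))
    se_v = float(np.sqrt(max(m4 - v_ic**2, 0.0) / n_draws))
    return e_ic, v_ic, se_e, se_v


def _posterior_pdf(lam, a, expected, hyper):
    w1 = stats.nbinom.pmf(a, hyper.alpha1, hyper.beta1 / (hyper.beta1 + expected))
    w2 = stats.nbinom.pmf(a, hyper.alpha2, hyper.beta2 / (hyper.beta2 + expected))
    q1 = hyper.p_mix * w1 / (hyper.p_mix * w1 + (1 - hyper.p_mix) * w2)
    return q1 * stats.gamma.pdf(lam, hyper.alpha1 + a, scale=1 / (hyper.beta1 + expected)) + (
        1 - q1
    ) * stats.gamma.pdf(lam, hyper.alpha2 + a, scale=1 / (hyper.beta2 + expected))


def _upper_limit(a, expected, hyper) -> float:
    return float(
        max(
            stats.gamma.ppf(1 - 1e-13, hyper.alpha1 + a, scale=1 / (hyper.beta1 + expected)),
            stats.gamma.ppf(1 - 1e-13, hyper.alpha2 + a, scale=1 / (hyper.beta2 + expected)),
        )
    )


def ebgm_quadrature(a, expected, hyper) -> float:
    """exp(E[ln lambda | a]) by adaptive quadrature over the posterior."""
    upper = _upper_limit(a, expected, hyper)
    val, _ = integrate.quad(
        lambda lam: np.log(lam) * _posterior_pdf(lam, a, expected, hyper),
        0.0, upper, limit=400,
    )
    return float(np.exp(val))


def posterior_quantile_bisect(q, a, expected, hyper, tol: float = 1e-9) -> float:
    """Posterior quantile by bisection on the quadrature-integrated CDF."""

    def cdf(x: float) -> float:
        val, _ = integrate.quad(
            lambda lam: _posterior_pdf(lam, a, expected, hyper), 0.0, x, limit=400
        )
        return val

    lo, hi = 0.0, _upper_limit(a, expected, hyper)
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
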