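"""The four disproportionality statistics and their signal classifications.

For one 2x2 table (a, b, c, d) with n = a+b+c+d:

* **ROR** — reporting odds ratio, (a.d)/(b.c), Wald 95% CI on the log scale.
* **PRR** — proportional reporting ratio, [a/(a+b)] / [c/(c+d)], with its
  Wald CI, conventionally screened together with the Pearson chi-square
  (Yates-corrected) and a minimum case count.
* **BCPNN IC** — the information component log2[P(drug,event)/(P(drug)P(event))]
  under the Bayesian confidence propagation neural network model: independent
  Beta posteriors for the joint and the two marginal reporting probabilities.
  Moments are available exactly (digamma/trigamma, the default) or via the
  classic closed-form approximation; IC025 = E(IC) - 2*sqrt(V(IC)).
* **MGPS EBGM** — the multi-item gamma Poisson shrinker: a ~ Poisson(lambda.E)
  with lambda drawn from a two-component gamma mixture prior whose five
  hyperparameters are fitted by maximum marginal likelihood across all
  drug-event cells of the database.  EBGM = exp(E[ln lambda | a]) (the
  posterior geometric mean) and EBGM05 is the posterior 5th percentile.

Zero cells: ROR/PRR/chi-square apply the Haldane-Anscombe +0.5 continuity
adjustment when any cell is zero; the two Bayesian methods handle zeros
natively.  Undefined statistics are reported as NaN markers and classify as
non-signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, expit, logit, polygamma

from .contingency import ContingencyTable
from .errors import ConfigurationError, DataError

_LN2 = math.log(2.0)
_Z95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = [
    "IntervalEstimate", "IcResult", "EbgmResult", "BcpnnPrior", "MgpsHyperParams",
    "Thresholds", "SignalFlags", "SignalScores",
    "ror", "prr", "chi_square", "ic_bcpnn", "fit_mgps_prior", "ebgm",
    "ebgm_from_counts", "classify", "score_table",
]


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class IntervalEstimate:
    estimate: float
    lo95: float
    hi95: float
    zero_adjusted: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


_UNDEFINED = IntervalEstimate(float("nan"), float("nan"), float("nan"))


@dataclass(frozen=True)
class IcResult:
    ic: float         # E(IC), bits
    var: float        # V(IC), bits^2
    ic025: float
    ic975: float
    method: str = "exact"


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float       # posterior geometric mean of lambda
    ebgm05: float
    ebgm95: float
    q1: float         # posterior weight of mixture component 1
    posterior_mean: float


@dataclass(frozen=True)
class BcpnnPrior:
    """Margin/joint Beta prior parameters; the defaults put the prior IC at 0."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def validate(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ConfigurationError("BCPNN prior parameters must be positive")


@dataclass(frozen=True)
class MgpsHyperParams:
    """The five parameters of the DuMouchel two-component gamma mixture prior.

    lambda ~ p_mix * Gamma(alpha1, rate beta1) + (1 - p_mix) * Gamma(alpha2, rate beta2)
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")
    converged: bool = False

    def validate(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ConfigurationError("MGPS hyperparameters must be positive")
        if not (0.0 < self.p_mix < 1.0):
            raise ConfigurationError("p_mix must lie strictly in (0, 1)")


#: DuMouchel's published starting point for the hyperparameter search.
DUMOUCHEL_START = MgpsHyperParams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class Thresholds:
    """Per-algorithm signal criteria (the standard screening battery).

    ROR: lower 95% bound > 1 with a >= min_a; PRR: PRR >= 2 and chi2 >= 4 and
    a >= 3; BCPNN: IC025 > 0 (strict); MGPS: EBGM05 >= 2.  ``combine``
    controls the combined flag: ALL (default), ANY, or PER_ALGORITHM (no
    combined flag).
    """

    min_a: int = 3
    ror_lo95_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_a: int = 3
    ic025_gt: float = 0.0
    ebgm05_min: float = 2.0
    combine: str = "ALL"

    def validate(self) -> None:
        if self.min_a < 0:
            raise ConfigurationError("min_a must be >= 0")
        if self.combine not in {"ALL", "ANY", "PER_ALGORITHM"}:
            raise ConfigurationError(f"unknown combine mode '{self.combine}'")


@dataclass(frozen=True)
class SignalFlags:
    ror: bool
    prr: bool
    bcpnn: bool
    mgps: bool
    combined: bool | None


@dataclass(frozen=True)
class SignalScores:
    """All statistics for one (term, level, subgroup) pair."""

    term: str
    level: str
    a: int
    expected: float
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_lo95: float
    prr_hi95: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: SignalFlags
    subgroup: str = ""


# ---------------------------------------------------------------------------
# Frequentist statistics


def _adjusted_cells(table: ContingencyTable, zero_policy: str) -> tuple[float, float, float, float, bool]:
    a, b, c, d = table.cells()
    if zero_policy not in {"haldane", "none"}:
        raise ConfigurationError(f"unknown zero policy '{zero_policy}'")
    if zero_policy == "haldane" and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def ror(table: ContingencyTable, zero_policy: str = "haldane") -> IntervalEstimate:
    """Reporting odds ratio (a.d)/(b.c) with Wald 95% CI.

    ``zero_policy="haldane"`` (default) adds 0.5 to all four cells when any
    cell is zero; the adjustment is recorded on the result.  An all-zero
    table yields the undefined marker (NaN).
    """
    if table.n == 0:
        return _UNDEFINED
    a, b, c, d, adjusted = _adjusted_cells(table, zero_policy)
    if min(a, b, c, d) <= 0:
        return _UNDEFINED
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(estimate)
    return IntervalEstimate(
        estimate, math.exp(log_est - _Z95 * se), math.exp(log_est + _Z95 * se), adjusted
    )


def prr(table: ContingencyTable, zero_policy: str = "haldane") -> IntervalEstimate:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with Wald 95% CI."""
    if table.n == 0:
        return _UNDEFINED
    a, b, c, d, adjusted = _adjusted_cells(table, zero_policy)
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return _UNDEFINED
    estimate = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    log_est = math.log(estimate)
    return IntervalEstimate(
        estimate, math.exp(log_est - _Z95 * se), math.exp(log_est + _Z95 * se), adjusted
    )


def chi_square(table: ContingencyTable, yates: bool = True, zero_policy: str = "none") -> float:
    """Pearson chi-square on the 2x2 table, Yates-corrected by default.

    Yates: n(|ad - bc| - n/2)^2 / [(a+b)(c+d)(a+c)(b+d)], floored at 0 when
    |ad - bc| <= n/2.  A zero margin yields the undefined marker (NaN).
    """
    a, b, c, d, _ = _adjusted_cells(table, zero_policy)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0 or n <= 0:
        return float("nan")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


# ---------------------------------------------------------------------------
# BCPNN information component


def ic_bcpnn(
    table: ContingencyTable,
    prior: BcpnnPrior = BcpnnPrior(),
    method: str = "exact",
) -> IcResult:
    """Posterior moments of the information component, in bits.

    Model: p_joint ~ Beta(Nxy + g11, N - Nxy + g - g11), p_drug ~
    Beta(Nx + a1, N - Nx + a - a1), p_event ~ Beta(Ny + b1, N - Ny + b - b1),
    independent, with g = g11 (N + a)(N + b) / ((Nx + a1)(Ny + b1)) scaling
    the joint prior so the prior IC is centred on independence.

    ``method="exact"`` (default) evaluates E(IC) and V(IC) exactly with
    digamma/trigamma; ``method="approx"`` uses the classic closed-form
    log-of-posterior-mean approximation (error O(1/count)).  Both return
    ic025/ic975 = E(IC) -/+ 2*sqrt(V(IC)).
    """
    prior.validate()
    if method not in {"exact", "approx"}:
        raise ConfigurationError(f"unknown IC method '{method}'")
    nxy, nx, ny, n = table.a, table.a + table.b, table.a + table.c, table.n
    a1, b1, al, be, g11 = prior.alpha1, prior.beta1, prior.alpha, prior.beta, prior.gamma11
    gamma = g11 * (n + al) * (n + be) / ((nx + a1) * (ny + b1))
    if method == "approx":
        e_ic = math.log2(
            (nxy + g11) * (n + al) * (n + be) / ((n + gamma) * (nx + a1) * (ny + b1))
        )
        v_ic = (1 / _LN2) ** 2 * (
            (n - nxy + gamma - g11) / ((nxy + g11) * (1 + n + gamma))
            + (n - nx + al - a1) / ((nx + a1) * (1 + n + al))
            + (n - ny + be - b1) / ((ny + b1) * (1 + n + be))
        )
    else:
        # E[log p] for Beta(x, s-x) is psi(x) - psi(s); Var is psi'(x) - psi'(s).
        e_ic = (
            digamma(nxy + g11) - digamma(n + gamma)
            - digamma(nx + a1) + digamma(n + al)
            - digamma(ny + b1) + digamma(n + be)
        ) / _LN2
        v_ic = (
            polygamma(1, nxy + g11) - polygamma(1, n + gamma)
            + polygamma(1, nx + a1) - polygamma(1, n + al)
            + polygamma(1, ny + b1) - polygamma(1, n + be)
        ) / _LN2**2
    sd = math.sqrt(max(v_ic, 0.0))
    return IcResult(float(e_ic), float(v_ic), float(e_ic - 2 * sd), float(e_ic + 2 * sd), method)


# ---------------------------------------------------------------------------
# MGPS: hyperparameter fit and EBGM


def _mixture_logpmf(a, expected, params: MgpsHyperParams, component: int | None = None):
    """log P(a | E) under the negative-binomial mixture marginal."""
    a = np.asarray(a, dtype=float)
    expected = np.asarray(expected, dtype=float)
    l1 = stats.nbinom.logpmf(a, params.alpha1, params.beta1 / (params.beta1 + expected))
    l2 = stats.nbinom.logpmf(a, params.alpha2, params.beta2 / (params.beta2 + expected))
    if component == 1:
        return l1
    if component == 2:
        return l2
    return np.logaddexp(math.log(params.p_mix) + l1, math.log1p(-params.p_mix) + l2)


_THETA_BOUND = 20.0  # exp(+-20) spans any plausible hyperparameter


def _theta_to_params(theta: np.ndarray) -> MgpsHyperParams:
    clipped = np.clip(theta, -_THETA_BOUND, _THETA_BOUND)
    return MgpsHyperParams(
        alpha1=math.exp(clipped[0]), beta1=math.exp(clipped[1]),
        alpha2=math.exp(clipped[2]), beta2=math.exp(clipped[3]),
        p_mix=float(expit(clipped[4])),
    )


def _params_to_theta(p: MgpsHyperParams) -> np.ndarray:
    return np.array([
        math.log(p.alpha1), math.log(p.beta1),
        math.log(p.alpha2), math.log(p.beta2),
        float(logit(p.p_mix)),
    ])


def _canonical(p: MgpsHyperParams) -> MgpsHyperParams:
    """Order components by prior mean (alpha/beta ascending) to fix labels."""
    if p.alpha1 / p.beta1 > p.alpha2 / p.beta2:
        return replace(
            p, alpha1=p.alpha2, beta1=p.beta2, alpha2=p.alpha1, beta2=p.beta1,
            p_mix=1.0 - p.p_mix,
        )
    return p


def fit_mgps_prior(
    counts,
    expected,
    weights=None,
    seed: int | None = 0,
    n_restarts: int = 4,
    truncated: bool = False,
    start: MgpsHyperParams = DUMOUCHEL_START,
) -> MgpsHyperParams:
    """Fit the five DuMouchel hyperparameters by maximum marginal likelihood.

    ``counts``/``expected`` are the (a_i, E_i) of every drug-event cell
    (a = 0 cells included).  The marginal of a under the gamma mixture is a
    two-component negative-binomial mixture; its log-likelihood is maximised
    on transformed parameters (log for positives, logit for p_mix) with
    L-BFGS-B from the DuMouchel starting point plus ``n_restarts`` jittered
    restarts; the best log-likelihood wins.  ``truncated=True`` conditions
    the likelihood on a >= 1.  Identical (a, E) cells are grouped with
    multiplicity weights, which leaves the likelihood unchanged.
    """
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    if a.size < 2:
        raise DataError("MGPS fit requires at least 2 cells")
    if np.any(e <= 0):
        raise DataError("all expected counts must be positive")
    if not np.any(a > 0):
        raise DataError("degenerate input: every cell has a = 0")

    # Group identical (a, E) pairs; exact reweighting, big speedup on grids.
    keys = np.stack([a, e], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    wu = np.bincount(inverse, weights=w, minlength=uniq.shape[0])
    au, eu = uniq[:, 0], uniq[:, 1]

    def nll(theta: np.ndarray) -> float:
        params = _theta_to_params(theta)
        ll = _mixture_logpmf(au, eu, params)
        if truncated:
            log_p0 = _mixture_logpmf(np.zeros_like(au), eu, params)
            ll = ll - np.log1p(-np.exp(log_p0))
        value = -float(np.dot(wu, ll))
        return value if np.isfinite(value) else 1e300

    rng = np.random.default_rng(seed)
    theta0 = _params_to_theta(start)
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(scale=0.7, size=5))

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(
            nll, s, method="L-BFGS-B", bounds=[(-_THETA_BOUND, _THETA_BOUND)] * 5
        )
        if best is None or res.fun < best.fun:
            best = res
            any_success = res.success
        elif res.fun == best.fun and res.success:
            any_success = True
    if best is None or not np.isfinite(best.fun):
        raise DataError("MGPS hyperparameter optimisation failed on all restarts")
    fitted = _canonical(_theta_to_params(best.x))
    return replace(fitted, loglik=-float(best.fun), converged=bool(any_success or best.success))


def _posterior_q1(a: int, expected: float, hyper: MgpsHyperParams) -> float:
    """Posterior probability that lambda came from mixture component 1."""
    l1 = float(_mixture_logpmf(a, expected, hyper, component=1))
    l2 = float(_mixture_logpmf(a, expected, hyper, component=2))
    t1 = math.log(hyper.p_mix) + l1
    t2 = math.log1p(-hyper.p_mix) + l2
    m = max(t1, t2)
    return math.exp(t1 - m) / (math.exp(t1 - m) + math.exp(t2 - m))


def _mixture_posterior_cdf(x: float, a: int, expected: float, hyper: MgpsHyperParams, q1: float) -> float:
    c1 = stats.gamma.cdf(x, hyper.alpha1 + a, scale=1.0 / (hyper.beta1 + expected))
    c2 = stats.gamma.cdf(x, hyper.alpha2 + a, scale=1.0 / (hyper.beta2 + expected))
    return q1 * c1 + (1.0 - q1) * c2


def _mixture_quantile(q: float, a: int, expected: float, hyper: MgpsHyperParams, q1: float) -> float:
    lo = min(
        stats.gamma.ppf(q, hyper.alpha1 + a, scale=1.0 / (hyper.beta1 + expected)),
        stats.gamma.ppf(q, hyper.alpha2 + a, scale=1.0 / (hyper.beta2 + expected)),
    )
    hi = max(
        stats.gamma.ppf(q, hyper.alpha1 + a, scale=1.0 / (hyper.beta1 + expected)),
        stats.gamma.ppf(q, hyper.alpha2 + a, scale=1.0 / (hyper.beta2 + expected)),
    )
    if hi <= lo:
        return lo

    def objective(x: float) -> float:
        return _mixture_posterior_cdf(x, a, expected, hyper, q1) - q

    # widen slightly: the root may sit numerically on a component quantile
    lo_b, hi_b = lo * (1 - 1e-9), hi * (1 + 1e-9)
    f_lo, f_hi = objective(lo_b), objective(hi_b)
    if f_lo >= 0.0:
        return lo
    if f_hi <= 0.0:
        return hi
    return float(optimize.brentq(objective, lo_b, hi_b, xtol=1e-12, rtol=1e-12))


def ebgm_from_counts(a: int, expected: float, hyper: MgpsHyperParams) -> EbgmResult:
    """EBGM and posterior quantiles for one cell.

    The posterior of lambda given a is Q.Gamma(alpha1+a, beta1+E) +
    (1-Q).Gamma(alpha2+a, beta2+E); EBGM = exp(E[ln lambda | a]) via digamma,
    EBGM05/EBGM95 by monotone root-finding on the mixture CDF.
    """
    hyper.validate()
    if expected <= 0:
        raise DataError("expected count must be positive")
    q1 = _posterior_q1(a, expected, hyper)
    log_gm = q1 * (digamma(hyper.alpha1 + a) - math.log(hyper.beta1 + expected)) + (
        1.0 - q1
    ) * (digamma(hyper.alpha2 + a) - math.log(hyper.beta2 + expected))
    mean = q1 * (hyper.alpha1 + a) / (hyper.beta1 + expected) + (1.0 - q1) * (
        hyper.alpha2 + a
    ) / (hyper.beta2 + expected)
    return EbgmResult(
        ebgm=float(math.exp(log_gm)),
        ebgm05=_mixture_quantile(0.05, a, expected, hyper, q1),
        ebgm95=_mixture_quantile(0.95, a, expected, hyper, q1),
        q1=q1,
        posterior_mean=float(mean),
    )


def ebgm(table: ContingencyTable, hyper: MgpsHyperParams) -> EbgmResult:
    """EBGM for one 2x2 table; E = (a+b)(a+c)/n."""
    return ebgm_from_counts(table.a, table.expected, hyper)


# ---------------------------------------------------------------------------
# Classification


def _ge(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x >= threshold


def _gt(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x > threshold


def classify(scores: SignalScores, thresholds: Thresholds = Thresholds()) -> SignalFlags:
    """Apply the per-algorithm screening rules; undefined statistics never flag."""
    thresholds.validate()
    a_ok = scores.a >= thresholds.min_a
    f_ror = a_ok and _gt(scores.ror_lo95, thresholds.ror_lo95_gt)
    f_prr = (
        scores.a >= thresholds.prr_min_a
        and _ge(scores.prr, thresholds.prr_min)
        and _ge(scores.chi2, thresholds.chi2_min)
    )
    f_ic = _gt(scores.ic025, thresholds.ic025_gt)
    f_ebgm = _ge(scores.ebgm05, thresholds.ebgm05_min)
    if thresholds.combine == "ALL":
        combined = f_ror and f_prr and f_ic and f_ebgm
    elif thresholds.combine == "ANY":
        combined = f_ror or f_prr or f_ic or f_ebgm
    else:
        combined = None
    return SignalFlags(ror=f_ror, prr=f_prr, bcpnn=f_ic, mgps=f_ebgm, combined=combined)


def score_table(
    table: ContingencyTable,
    hyper: MgpsHyperParams,
    prior: BcpnnPrior = BcpnnPrior(),
    thresholds: Thresholds = Thresholds(),
    zero_policy: str = "haldane",
    yates: bool = True,
    ic_method: str = "exact",
    subgroup: str = "",
) -> SignalScores:
    """All four statistics plus flags for one contingency table."""
    r = ror(table, zero_policy)
    p = prr(table, zero_policy)
    x2 = chi_square(table, yates=yates, zero_policy=zero_policy)
    ic = ic_bcpnn(table, prior, method=ic_method)
    eb = ebgm(table, hyper)
    scores = SignalScores(
        term=table.term, level=table.level, a=table.a, expected=table.expected,
        ror=r.estimate, ror_lo95=r.lo95, ror_hi95=r.hi95,
        prr=p.estimate, prr_lo95=p.lo95, prr_hi95=p.hi95,
        chi2=x2, ic=ic.ic, ic025=ic.ic025,
        ebgm=eb.ebgm, ebgm05=eb.ebgm05,
        flags=SignalFlags(False, False, False, False, None),
        subgroup=subgroup,
    )
    return replace(scores, flags=classify(scores, thresholds))
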