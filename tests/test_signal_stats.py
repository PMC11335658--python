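import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import digamma

from pvsignal.contingency import ContingencyTable
from pvsignal.errors import ConfigurationError, DataError
from pvsignal.signal_stats import (
    BcpnnPrior,
    MgpsHyperParams,
    SignalFlags,
    SignalScores,
    Thresholds,
    chi_square,
    classify,
    ebgm_from_counts,
    fit_mgps_prior,
    ic_bcpnn,
    prr,
    ror,
)

from _oracles import bcpnn_mc_moments, ebgm_quadrature

T = ContingencyTable


class TestRor:
    def test_worked_example(self):
        r = ror(T(10, 20, 30, 240))
        assert r.estimate == pytest.approx(4.0)
        assert r.lo95 == pytest.approx(math.exp(math.log(4) - 1.959963984540054 * math.sqrt(0.1875)), rel=1e-12)
        assert (r.lo95, r.hi95) == (pytest.approx(1.71, abs=0.005), pytest.approx(9.35, abs=0.005))

    def test_symmetric_table(self):
        assert ror(T(5, 5, 5, 5)).estimate == pytest.approx(1.0)

    def test_haldane_adjustment_on_zero_cell(self):
        r = ror(T(4, 0, 3, 100))
        assert r.zero_adjusted
        assert r.estimate == pytest.approx((4.5 * 100.5) / (0.5 * 3.5))

    def test_all_zero_table_is_undefined(self):
        assert math.isnan(ror(T(0, 0, 0, 0)).estimate)

    def test_zero_policy_none_leaves_zero_undefined(self):
        assert math.isnan(ror(T(4, 0, 3, 100), zero_policy="none").estimate)


class TestPrr:
    def test_worked_example(self):
        p = prr(T(10, 20, 30, 240))
        assert p.estimate == pytest.approx(3.0)

    def test_independence_table(self):
        assert prr(T(1, 9, 9, 81)).estimate == pytest.approx(1.0)

    def test_matches_ror_in_rare_event_limit(self):
        """Table-5 pattern: with a<<a+b and c<<c+d the two agree to <1%."""
        p, r = prr(T(4, 342686, 400, 50526617)), ror(T(4, 342686, 400, 50526617))
        assert abs(r.estimate - p.estimate) / p.estimate < 0.01


class TestChiSquare:
    def test_yates_worked_example(self):
        assert chi_square(T(10, 20, 30, 240)) == pytest.approx(300 * 1650**2 / 84_240_000)

    def test_pearson_worked_example(self):
        assert chi_square(T(10, 20, 30, 240), yates=False) == pytest.approx(300 * 1800**2 / 84_240_000)

    def test_independence_gives_zero(self):
        assert chi_square(T(1, 9, 9, 81), yates=False) == 0.0

    def test_yates_floors_at_zero(self):
        # |ad - bc| = 16 < n/2 = 18
        assert chi_square(T(4, 4, 4, 6)) == 0.0

    def test_zero_margin_undefined(self):
        assert math.isnan(chi_square(T(0, 0, 3, 5)))


class TestIcBcpnn:
    def test_closed_form_worked_example(self):
        ic = ic_bcpnn(T(10, 20, 30, 240), method="approx")
        assert ic.ic == pytest.approx(1.09, abs=0.005)
        assert ic.ic025 == pytest.approx(0.015, abs=0.005)

    def test_prior_centred_on_independence(self):
        ic = ic_bcpnn(T(100, 900, 9900, 89100))
        assert abs(ic.ic) < 0.05

    def test_zero_count_gives_finite_negative_ic(self):
        ic = ic_bcpnn(T(0, 30, 40, 230))
        assert math.isfinite(ic.ic) and ic.ic < 0

    def test_exact_moments_match_beta_posterior_sampler(self):
        for cells, seed in [((10, 20, 30, 240), 1), ((3, 97, 50, 9850), 2), ((0, 30, 40, 230), 3)]:
            ic = ic_bcpnn(T(*cells), method="exact")
            e_mc, v_mc, se_e, se_v = bcpnn_mc_moments(*cells, n_draws=50_000, seed=seed)
            assert abs(ic.ic - e_mc) < 3 * se_e
            assert abs(ic.var - v_mc) < 3 * se_v

    def test_interval_ordering(self):
        ic = ic_bcpnn(T(10, 20, 30, 240))
        assert ic.ic025 <= ic.ic <= ic.ic975

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(ConfigurationError):
            ic_bcpnn(T(1, 1, 1, 1), BcpnnPrior(alpha1=0.0))


class TestEbgm:
    def test_single_component_reduction_via_digamma(self):
        hyper = MgpsHyperParams(1, 1, 1, 1, 0.5)
        result = ebgm_from_counts(10, 2.0, hyper)
        assert result.ebgm == pytest.approx(math.exp(digamma(11) - math.log(3)), rel=1e-12)
        assert result.ebgm == pytest.approx(3.50, abs=0.005)

    def test_zero_count_shrinks_below_one(self):
        hyper = MgpsHyperParams(2.0, 2.0, 20.0, 20.0, 0.5)  # both components centred at 1
        for expected in (1.0, 4.0, 10.0):
            assert ebgm_from_counts(0, expected, hyper).ebgm < 1.0

    def test_large_count_limit_approaches_ratio(self):
        hyper = MgpsHyperParams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
        result = ebgm_from_counts(10_000, 1_000.0, hyper)
        assert result.ebgm == pytest.approx(10.0, rel=0.05)

    def test_quantiles_bracket_point_estimate(self):
        hyper = MgpsHyperParams(0.5, 0.3, 3.0, 1.5, 0.4)
        result = ebgm_from_counts(7, 2.5, hyper)
        assert result.ebgm05 <= result.ebgm <= result.ebgm95

    def test_matches_quadrature_oracle(self):
        hyper = MgpsHyperParams(0.7, 0.4, 4.0, 2.0, 0.3)
        for a, e in [(0, 2.0), (3, 0.8), (25, 6.0)]:
            assert ebgm_from_counts(a, e, hyper).ebgm == pytest.approx(
                ebgm_quadrature(a, e, hyper), abs=1e-6, rel=1e-6
            )

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ebgm_from_counts(1, 1.0, MgpsHyperParams(1, -1, 1, 1, 0.5))


class TestCrossStatisticProperties:
    @given(
        st.tuples(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    )
    def test_sign_agreement(self, cells):
        a, b, c, d = cells
        table = T(a, b, c, d)
        r, p = ror(table).estimate, prr(table).estimate
        assert (r >= 1) == (p >= 1) == (a * d >= b * c)

    def test_monotone_in_a_with_margins_fixed(self):
        """With a+b, a+c and n held fixed, every statistic is nondecreasing in a."""
        nx, ny, n = 40, 60, 1000
        hyper = MgpsHyperParams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
        prev = None
        for a in range(0, min(nx, ny) + 1):
            table = T(a, nx - a, ny - a, n - nx - ny + a)
            values = (
                ror(table).estimate if a > 0 else 0.0,
                prr(table).estimate if a > 0 else 0.0,
                ic_bcpnn(table).ic,
                ebgm_from_counts(a, table.expected, hyper).ebgm,
            )
            if prev is not None and a > 1:
                assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(prev, values))
            prev = values

    def test_independence_exactness(self):
        for k in (1, 3, 9):
            table = T(k, 9 * k, 9 * k, 81 * k)
            assert ror(table).estimate == pytest.approx(1.0, abs=1e-15)
            assert prr(table).estimate == pytest.approx(1.0, abs=1e-15)
            assert chi_square(table, yates=False) == 0.0


class TestFitMgpsPrior:
    def test_null_cells_concentrate_prior_near_one(self):
        rng = np.random.default_rng(5)
        e = rng.lognormal(np.log(5.0), 1.0, size=5000)
        a = rng.poisson(e)  # lambda = 1 everywhere
        fit = fit_mgps_prior(a, e, seed=5)
        assert fit.converged
        from scipy import stats as sps

        mass = fit.p_mix * (
            sps.gamma.cdf(2.0, fit.alpha1, scale=1 / fit.beta1)
            - sps.gamma.cdf(0.5, fit.alpha1, scale=1 / fit.beta1)
        ) + (1 - fit.p_mix) * (
            sps.gamma.cdf(2.0, fit.alpha2, scale=1 / fit.beta2)
            - sps.gamma.cdf(0.5, fit.alpha2, scale=1 / fit.beta2)
        )
        assert mass >= 0.9

    def test_all_zero_cells_is_an_error(self):
        with pytest.raises(DataError, match="degenerate"):
            fit_mgps_prior([0, 0, 0], [1.0, 2.0, 3.0])

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(DataError):
            fit_mgps_prior([1], [1.0])

    def test_weighted_grouping_is_exact(self):
        a = [0, 0, 1, 1, 5]
        e = [1.0, 1.0, 2.0, 2.0, 1.5]
        full = fit_mgps_prior(a, e, seed=3)
        grouped = fit_mgps_prior([0, 1, 5], [1.0, 2.0, 1.5], weights=[2, 2, 1], seed=3)
        assert full.loglik == pytest.approx(grouped.loglik, rel=1e-9)


class TestClassify:
    def _scores(self, **kw):
        base = dict(
            term="x", level="PT", a=5, expected=1.0,
            ror=3.0, ror_lo95=1.2, ror_hi95=7.0,
            prr=2.5, prr_lo95=1.1, prr_hi95=6.0, chi2=5.0,
            ic=1.0, ic025=0.1, ebgm=2.5, ebgm05=2.2,
            flags=SignalFlags(False, False, False, False, None),
        )
        base.update(kw)
        return SignalScores(**base)

    def test_all_criteria_met(self):
        flags = classify(self._scores())
        assert flags == SignalFlags(True, True, True, True, True)

    def test_min_case_count_gates_ror_and_prr(self):
        flags = classify(self._scores(a=2, ror=500.0, ror_lo95=50.0))
        assert not flags.ror and not flags.prr
        assert flags.bcpnn and flags.mgps

    def test_ic025_boundary_is_strict(self):
        assert not classify(self._scores(ic025=0.0)).bcpnn

    def test_undefined_statistics_never_flag(self):
        nan = float("nan")
        flags = classify(self._scores(ror_lo95=nan, prr=nan, chi2=nan, ic025=nan, ebgm05=nan))
        assert flags == SignalFlags(False, False, False, False, False)

    def test_combine_any(self):
        flags = classify(self._scores(ic025=-1.0), Thresholds(combine="ANY"))
        assert flags.combined is True

    def test_combine_per_algorithm_has_no_combined_flag(self):
        assert classify(self._scores(), Thresholds(combine="PER_ALGORITHM")).combined is None
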