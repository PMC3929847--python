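"""Tests of the five tail approximations against the exact chi-square oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lancaster import (
    Moments,
    PValueVector,
    WeightVector,
    combine_pvalues,
    cornish_fisher_pvalue,
    cornish_fisher_quantile,
    exact_independent_pvalue,
    normal_approx_pvalue,
    saddlepoint_pvalue,
    satterthwaite_params,
    tail_prob_TA,
)


def independent_moments(v):
    """Moments of a plain chi-square(v): the c=1 case, so T is on the chi2_v scale."""
    return Moments(mean=float(v), variance=2.0 * float(v))


class TestSatterthwaite:
    @pytest.mark.parametrize(
        "mean,var,c,v",
        [(4.0, 8.0, 1.0, 4.0), (4.0, 12.0, 2.0 / 3.0, 8.0 / 3.0), (6.0, 24.0, 0.5, 3.0)],
    )
    def test_parameter_formulas(self, mean, var, c, v):
        params = satterthwaite_params(Moments(mean=mean, variance=var))
        assert params.c == pytest.approx(c)
        assert params.v == pytest.approx(v)

    def test_nonpositive_moments_rejected(self):
        with pytest.raises(ValueError):
            satterthwaite_params(Moments(mean=0.0, variance=1.0))


class TestExactIndependent:
    def test_zero_statistic(self):
        assert exact_independent_pvalue(0.0, WeightVector.from_array([2.0, 2.0])) == 1.0

    def test_chi2_4_closed_form(self):
        # P(chi2_4 > 4) = e^{-2} (1 + 2)
        w = WeightVector.from_array([2.0, 2.0])
        assert exact_independent_pvalue(4.0, w) == pytest.approx(3 * np.exp(-2), abs=1e-10)

    def test_chi2_4_five_percent_point(self):
        w = WeightVector.from_array([2.0, 2.0])
        assert exact_independent_pvalue(9.4877, w) == pytest.approx(0.05, abs=1e-4)


class TestOracleAgreement:
    """Each approximation reproduces the exact chi2_v tail within its tolerance."""

    TOLS = {"TB": 0.01, "TC": 0.005, "TD": 0.002, "TE": 0.002}

    @pytest.mark.parametrize("v", [3, 8, 20, 50, 100])
    @pytest.mark.parametrize("tail", [0.2, 0.1, 0.05, 0.01, 0.001])
    def test_grid(self, v, tail):
        q = stats.chi2.isf(tail, v)
        m = independent_moments(v)
        assert normal_approx_pvalue(q, m, v, "fisher") == pytest.approx(
            tail, abs=self.TOLS["TB"]
        )
        assert normal_approx_pvalue(q, m, v, "wilson_hilferty") == pytest.approx(
            tail, abs=self.TOLS["TC"]
        )
        assert cornish_fisher_pvalue(q, m, v) == pytest.approx(tail, abs=self.TOLS["TD"])
        assert saddlepoint_pvalue(q, m, v) == pytest.approx(tail, abs=self.TOLS["TE"])

    def test_ta_is_exact_in_independent_case(self):
        v = 7.3
        q = stats.chi2.isf(0.03, v)
        params = satterthwaite_params(independent_moments(v))
        assert tail_prob_TA(q, params) == pytest.approx(0.03, abs=1e-12)


class TestNormalApprox:
    def test_fisher_needs_v_above_half(self):
        with pytest.raises(ValueError):
            normal_approx_pvalue(1.0, independent_moments(0.4), 0.4, "fisher")

    def test_limit_at_large_T(self):
        m = independent_moments(20)
        assert normal_approx_pvalue(1e6, m, 20, "fisher") == pytest.approx(0.0, abs=1e-12)
        assert normal_approx_pvalue(1e6, m, 20, "wilson_hilferty") == pytest.approx(
            0.0, abs=1e-12
        )


class TestCornishFisher:
    def test_median_v4_analytic(self):
        # x_alpha = 0: v - 2/3 + 32/(405 v)
        assert cornish_fisher_quantile(0.5, 4) == pytest.approx(
            4 - 2 / 3 + 32 / (405 * 4), abs=1e-12
        )

    @pytest.mark.parametrize("alpha", [0.05, 0.95])
    def test_chi2_20_percentage_points(self, alpha):
        assert cornish_fisher_quantile(alpha, 20) == pytest.approx(
            stats.chi2.ppf(alpha, 20), abs=0.05
        )

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            cornish_fisher_quantile(0.0, 4)

    def test_inversion_identity(self):
        v = 11.0
        m = independent_moments(v)
        target = cornish_fisher_quantile(0.95, v)
        # T with vT/E(T) = target, i.e. T = target since c = 1 here
        assert cornish_fisher_pvalue(target, m, v) == pytest.approx(0.05, abs=1e-8)

    def test_zero_statistic_clamps_to_one(self):
        assert cornish_fisher_pvalue(0.0, independent_moments(4), 4) == 1.0


class TestSaddlepoint:
    def test_mean_point_matches_exact_cdf(self):
        v = 20
        assert saddlepoint_pvalue(20.0, independent_moments(v), v) == pytest.approx(
            stats.chi2.sf(20, 20), abs=0.002
        )

    def test_five_percent_point(self):
        v = 20
        q = stats.chi2.isf(0.05, v)
        assert saddlepoint_pvalue(q, independent_moments(v), v) == pytest.approx(
            0.05, abs=0.002
        )

    def test_continuous_through_mean_singularity(self):
        v = 12
        m = independent_moments(v)
        ys = np.array([1 - 2e-4, 1 - 5e-5, 1.0, 1 + 5e-5, 1 + 2e-4])
        ps = [saddlepoint_pvalue(y * v, m, v) for y in ys]
        assert np.all(np.diff(ps) < 0)
        assert max(ps) - min(ps) < 1e-3

    def test_nonpositive_scaled_statistic(self):
        assert saddlepoint_pvalue(0.0, independent_moments(5), 5) == 1.0


class TestCombine:
    def test_independent_reduction(self):
        p = PValueVector.from_arrays([0.5, 0.5])
        w = WeightVector.from_array([2.0, 2.0])
        res = combine_pvalues(p, w)
        assert res.params.c == pytest.approx(1.0, abs=1e-14)
        assert res.params.v == pytest.approx(4.0, abs=1e-14)
        # oracle: P(chi2_4 > -2 ln 0.25) = e^{-T/2}(1 + T/2)
        expected = np.exp(-res.T / 2) * (1 + res.T / 2)
        assert res.pvalues["TA"] == pytest.approx(expected, abs=1e-12)
        assert res.pvalues["TA"] == res.pvalues["independent"]

    def test_all_ones_give_zero_statistic(self):
        p = PValueVector.from_arrays([1.0, 1.0, 1.0])
        w = WeightVector.from_array([2.0, 1.0, 0.5])
        res = combine_pvalues(p, w)
        assert res.T == 0.0
        assert all(pv == pytest.approx(1.0) for pv in res.pvalues.values())

    def test_correlation_raises_pvalue(self):
        """Positive dependence widens Var(T), so the adjusted p-value must
        exceed the naive independent one for a statistic above its mean."""
        p = PValueVector.from_arrays([0.01, 0.02, 0.05])
        w = WeightVector.from_array([2.0, 2.0, 2.0])
        rho = np.full((3, 3), 2.0)
        res = combine_pvalues(p, w, rho)
        assert res.pvalues["TA"] > res.pvalues["independent"]

    def test_unknown_method_rejected(self):
        p = PValueVector.from_arrays([0.5])
        w = WeightVector.from_array([2.0])
        with pytest.raises(ValueError):
            combine_pvalues(p, w, methods=("TZ",))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    v=st.floats(min_value=1.0, max_value=150.0),
    scale=st.floats(min_value=0.2, max_value=5.0),
)
def test_monotone_in_statistic(v, scale):
    """Every method's p-value is nonincreasing in T for fixed moments."""
    mean = v * scale
    m = Moments(mean=mean, variance=2.0 * v * scale**2)
    Ts = np.linspace(0.0, 6.0 * mean, 40)
    for fn in (
        lambda T: normal_approx_pvalue(T, m, v, "fisher"),
        lambda T: normal_approx_pvalue(T, m, v, "wilson_hilferty"),
        lambda T: cornish_fisher_pvalue(T, m, v),
        lambda T: saddlepoint_pvalue(T, m, v),
    ):
        ps = np.array([fn(T) for T in Ts])
        assert np.all(np.diff(ps) <= 1e-9)
        assert np.all((ps >= 0.0) & (ps <= 1.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    v=st.floats(min_value=0.05, max_value=1000.0),
    T=st.floats(min_value=0.0, max_value=1e12),
)
def test_probabilities_stay_in_unit_interval(v, T):
    m = Moments(mean=max(v, 1e-6), variance=2.0 * max(v, 1e-6))
    for name, p in {
        "TC": normal_approx_pvalue(T, m, v, "wilson_hilferty"),
        "TD": cornish_fisher_pvalue(T, m, v),
        "TE": saddlepoint_pvalue(T, m, v),
    }.items():
        assert 0.0 <= p <= 1.0, name
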