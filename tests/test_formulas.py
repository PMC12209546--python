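"""Closed-form collider-bias expressions checked against independent oracles
(exact enumeration, Gauss-Hermite quadrature, truncated Poisson sums)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from colliderbias import (
    OutcomeModelParams,
    conditional_odds_ratio,
    conditional_risk_ratio_logbinomial,
    generalized_or_ratio,
    linear_coef_bias,
    poisson_coef_bias,
)
from colliderbias.formulas import (
    BiasResult,
    conditional_mean_general,
    linear_conditional_mean,
    logodds_coef_bias,
    odds_ratio_bias,
    poisson_conditional_rate,
    poisson_conditional_rate_generalized,
    risk_ratio_bias,
    risk_ratio_difference_logbinomial,
)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "or_uncond, delta3, expected",
        [
            (2.0, 0.0, 2.0),
            (1.0, 0.5, 1.6487212707001282),
            (1.5, -0.3, 1.1112273152077088),
        ],
    )
    def test_conditional_or_values(self, or_uncond, delta3, expected):
        assert conditional_odds_ratio(or_uncond, delta3) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonpositive_or(self):
        with pytest.raises(ValueError):
            conditional_odds_ratio(0.0, 0.1)

    def test_logodds_bias_is_interaction(self):
        assert logodds_coef_bias(0.37) == 0.37

    def test_matches_enumeration_oracle(self, rng):
        """OR among selected units equals OR * exp(d3) on random valid models."""
        for _ in range(50):
            d0, d1, d2, d3 = oracles.draw_valid_log_additive(rng)
            py = {0.0: rng.uniform(0.05, 0.95), 1.0: rng.uniform(0.05, 0.95)}
            oracle = oracles.enumerate_binary(py, d0, d1, d2, d3)
            closed = conditional_odds_ratio(oracle["or_uncond"], d3)
            assert closed == pytest.approx(oracle["or_cond"], rel=1e-10)

    def test_bias_result_ratio_invariant(self):
        r = odds_ratio_bias(2.0, 0.4)
        assert r.is_ratio
        assert r.conditional == pytest.approx(r.unconditional * r.bias, rel=1e-12)


class TestGeneralizedOR:
    def test_constant_g3_is_unbiased(self):
        assert generalized_or_ratio(lambda x: 0.7, 3.5) == pytest.approx(1.0)

    def test_linear_g3_reduces_to_plain_interaction(self):
        assert generalized_or_ratio(lambda x: 0.2 * x, 3.0) == pytest.approx(math.exp(0.2))

    def test_quadratic_g3_against_enumeration(self, rng):
        g3 = lambda x: 0.1 * x * x
        assert generalized_or_ratio(g3, 1.0) == pytest.approx(math.exp(0.3), rel=1e-10)
        # full check: enumeration with non-linear main effects too
        g1 = lambda x: -0.2 * abs(x)
        g2 = lambda y: -0.1 * y
        for _ in range(20):
            py = {1.0: rng.uniform(0.1, 0.9), 2.0: rng.uniform(0.1, 0.9)}
            shift = lambda x, y=1.0: g1(x) + g2(y) + g3(x) * y
            d0 = -max(shift(x, y) for x in (1.0, 2.0) for y in (0.0, 1.0)) - 0.01
            oracle = oracles.enumerate_or_generalized(
                py, lambda x: g1(x) + d0, g2, g3, (1.0, 2.0)
            )
            py_odds = lambda p: p / (1 - p)
            or_uncond = py_odds(py[2.0]) / py_odds(py[1.0])
            assert oracle == pytest.approx(
                or_uncond * generalized_or_ratio(g3, 1.0), rel=1e-10
            )

    def test_nonfinite_g3_rejected(self):
        with pytest.raises(ValueError):
            generalized_or_ratio(lambda x: float("inf"), 0.0)


class TestRiskRatio:
    def test_no_bias_when_outcome_collider_terms_vanish(self):
        out = OutcomeModelParams("log_binomial", beta0=-1.0, beta1=0.2)
        rr = conditional_risk_ratio_logbinomial(0.0, out, delta2=0.0, delta3=0.0)
        assert rr == pytest.approx(math.exp(0.2), rel=1e-12)
        assert risk_ratio_difference_logbinomial(0.0, out, 0.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_no_bias_when_no_interaction_and_null_effect(self):
        out = OutcomeModelParams("log_binomial", beta0=-1.0, beta1=0.0)
        rr = conditional_risk_ratio_logbinomial(0.0, out, delta2=0.4, delta3=0.0)
        assert rr == pytest.approx(1.0, rel=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        out = OutcomeModelParams("log_binomial", beta0=-1.0, beta1=0.2)
        py = {x: math.exp(out.beta0 + out.beta1 * x) for x in (0.0, 1.0)}
        for _ in range(50):
            d0, d1, d2, d3 = oracles.draw_valid_log_additive(rng)
            oracle = oracles.enumerate_binary(py, d0, d1, d2, d3)
            closed = conditional_risk_ratio_logbinomial(0.0, out, d2, d3)
            assert closed == pytest.approx(oracle["rr_cond"], rel=1e-10)
            diff = risk_ratio_difference_logbinomial(0.0, out, d2, d3)
            assert diff == pytest.approx(
                oracle["rr_uncond"] - oracle["rr_cond"], rel=1e-9, abs=1e-12
            )

    def test_rr_biased_without_interaction(self):
        """Unlike the OR, the RR can be biased with delta3=0 when delta2 and
        beta1 are both nonzero."""
        out = OutcomeModelParams("log_binomial", beta0=-1.0, beta1=0.3)
        diff = risk_ratio_difference_logbinomial(0.0, out, delta2=-0.5, delta3=0.0)
        assert abs(diff) > 1e-3

    def test_invalid_probability_names_x(self):
        out = OutcomeModelParams("log_binomial", beta0=-0.1, beta1=0.2)
        with pytest.raises(ValueError, match="x=1"):
            conditional_risk_ratio_logbinomial(0.0, out, 0.1, 0.1)

    def test_bias_result_builder(self):
        out = OutcomeModelParams("log_binomial", beta0=-1.0, beta1=0.2)
        r = risk_ratio_bias(0.0, out, 0.3, 0.2)
        assert r.conditional == pytest.approx(r.unconditional * r.bias, rel=1e-12)


class TestLinear:
    @pytest.mark.parametrize(
        "d2, d3, sigma, expected",
        [
            (0.3, 0.0, 0.5, (0.075, 0.0)),
            (0.0, 0.4, 0.5, (0.0, 0.1)),
            (0.7, -0.2, 1.0, (0.7, -0.2)),
        ],
    )
    def test_bias_values(self, d2, d3, sigma, expected):
        b0, b1 = linear_coef_bias(d2, d3, sigma)
        assert (b0, b1) == pytest.approx(expected, abs=1e-12)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            linear_coef_bias(0.1, 0.1, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        d2=st.floats(-1, 1),
        d3=st.floats(-1, 1),
        sigma=st.floats(0.1, 1.0),
        x=st.floats(-2, 2),
    )
    def test_conditional_mean_matches_quadrature(self, d2, d3, sigma, x):
        """E(Y|X=x,S=1) from Gaussian-tilt quadrature equals the closed form
        (beta0 + d2*sigma^2) + (beta1 + d3*sigma^2) x."""
        out = OutcomeModelParams("linear", beta0=0.1, beta1=0.2, sigma=sigma)
        oracle = oracles.gauss_hermite_mean(x, out.beta0, out.beta1, sigma, d2, d3)
        assert linear_conditional_mean(x, out, d2, d3) == pytest.approx(oracle, abs=1e-8)

    def test_general_mean_function(self):
        m = lambda x: math.sin(x)
        val = conditional_mean_general(m, 0.7, delta2=0.3, delta3=-0.2, sigma=0.5)
        assert val == pytest.approx(math.sin(0.7) + 0.25 * 0.3 - 0.25 * 0.2 * 0.7)


class TestPoisson:
    @pytest.mark.parametrize("d2, d3", [(0.3, 0.2), (0.0, 0.0), (-0.4, 0.1)])
    def test_bias_equals_main_effect_and_interaction(self, d2, d3):
        assert poisson_coef_bias(d2, d3) == (d2, d3)

    def test_conditional_rate_matches_truncated_sum(self):
        out = OutcomeModelParams("poisson", beta0=0.0, beta1=0.2)
        oracle = oracles.truncated_poisson_mean(1.0, out.beta0, out.beta1, 0.3, -0.5)
        assert poisson_conditional_rate(1.0, out, 0.3, -0.5) == pytest.approx(oracle, rel=1e-10)

    def test_generalized_rate(self):
        out = OutcomeModelParams("poisson", beta0=0.0, beta1=0.2)
        g3 = lambda x: -0.1 * x * x
        oracle = oracles.truncated_poisson_mean(2.0, 0.0, 0.2, -0.2, 0.0, cap=400)
        # g3(2) = -0.4 plays the role of d3*x with d2 = -0.2 absorbed separately
        val = poisson_conditional_rate_generalized(2.0, out, -0.2, g3)
        assert val == pytest.approx(math.exp(0.4 - 0.2 - 0.4), rel=1e-12)
        assert oracle == pytest.approx(math.exp(0.4 - 0.2), rel=1e-10)


class TestZeroInteractionNeutrality:
    """delta3 = 0 implies exactly zero bias on the OR, log-odds, linear-slope
    and Poisson-slope scales."""

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(d2=st.floats(-1, 1), sigma=st.floats(0.1, 2.0), orr=st.floats(0.1, 10))
    def test_all_slope_targets(self, d2, sigma, orr):
        assert conditional_odds_ratio(orr, 0.0) == orr
        assert logodds_coef_bias(0.0) == 0.0
        assert linear_coef_bias(d2, 0.0, sigma)[1] == 0.0
        assert poisson_coef_bias(d2, 0.0)[1] == 0.0


def test_bias_result_rejects_unknown_target():
    with pytest.raises(ValueError):
        BiasResult("wrong", 1.0, 1.0, 0.0)
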