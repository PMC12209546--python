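"""Closed-form collider-bias expressions under the log-additive selection model.

All results compare an unconditional exposure-outcome association with the
same association computed among selected units (S=1), when selection follows

    log P(S=1 | X, Y) = delta0 + delta1*X + delta2*Y + delta3*X*Y.

Key facts implemented here:

* Odds-ratio scale (binary Y): OR_{XY|S=1}(x) = OR_{XY}(x) * exp(delta3); the
  bias in a correctly specified logistic regression coefficient is exactly
  delta3, whatever the exposure distribution.
* Risk-ratio scale (binary Y): the conditional risk ratio depends on both
  delta2 and delta3; delta3 = 0 alone does not remove bias.
* Linear model Y = beta0 + beta1*X + N(0, sigma^2): slope bias delta3*sigma^2,
  intercept bias delta2*sigma^2.
* Poisson model: Y | X, S=1 remains Poisson with rate
  exp{(beta0+delta2) + (beta1+delta3)*X}; slope bias delta3, intercept bias
  delta2.

Ratio-scale targets report bias multiplicatively (conditional =
unconditional * bias); coefficient-scale targets additively (conditional =
unconditional + bias).  ``BiasResult.target`` disambiguates.

For a vector-valued exposure the same statements hold per coefficient: the
bias in the coefficient of X_j equals the X_j-by-Y interaction in the
selection model, and exposure-exposure interactions in the selection model do
not contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .params import OutcomeModelParams

RATIO_TARGETS = frozenset({"odds_ratio_ratio", "risk_ratio"})
COEF_TARGETS = frozenset(
    {"logodds_coef", "linear_intercept", "linear_slope", "poisson_intercept", "poisson_slope"}
)


@dataclass(frozen=True)
class BiasResult:
    """An unconditional association, its S=1 conditional version, and the bias.

    ``bias`` is multiplicative for ratio targets (conditional =
    unconditional * bias) and additive for coefficient targets (conditional =
    unconditional + bias).
    """

    target: str
    unconditional: float
    conditional: float
    bias: float

    def __post_init__(self) -> None:
        if self.target not in RATIO_TARGETS | COEF_TARGETS:
            raise ValueError(f"unknown bias target {self.target!r}")

    @property
    def is_ratio(self) -> bool:
        return self.target in RATIO_TARGETS

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "unconditional": self.unconditional,
            "conditional": self.conditional,
            "bias": self.bias,
        }


# ---------------------------------------------------------------------------
# Odds-ratio scale


def conditional_odds_ratio(or_uncond: float, delta3: float) -> float:
    """Odds ratio among selected units: OR * exp(delta3).

    Holds for any exposure at any reference point x, and more generally when
    the selection main effects are arbitrary functions g1(X), g2(Y), as long
    as the interaction term is linear (delta3*X*Y).
    """
    if not or_uncond > 0:
        raise ValueError(f"odds ratio must be positive, got {or_uncond}")
    return or_uncond * math.exp(delta3)


def logodds_coef_bias(delta3: float) -> float:
    """Bias of the logistic-regression exposure coefficient: exactly delta3."""
    return float(delta3)


def odds_ratio_bias(or_uncond: float, delta3: float) -> BiasResult:
    cond = conditional_odds_ratio(or_uncond, delta3)
    return BiasResult("odds_ratio_ratio", or_uncond, cond, math.exp(delta3))


def generalized_or_ratio(g3: Callable[[float], float], x: float) -> float:
    """Multiplicative OR distortion exp{g3(x+1) - g3(x)} under an
    exposure-dependent interaction coefficient g3.

    Equals 1 for every x iff g3 is constant: collider bias on the OR scale
    occurs exactly when exposure and outcome interact in their effect on
    selection.
    """
    a, b = g3(x), g3(x + 1.0)
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError(f"g3 non-finite at x={x} or x+1 ({a}, {b})")
    return math.exp(b - a)


# ---------------------------------------------------------------------------
# Risk-ratio scale (binary outcome)


def conditional_risk_ratio(
    p_x: float, p_x1: float, delta2: float, delta3: float, x: float = 0.0
) -> float:
    """Conditional risk ratio RR_{XY|S=1}(x) for arbitrary P(Y=1|X).

    Parameters
    ----------
    p_x, p_x1
        P(Y=1 | X=x) and P(Y=1 | X=x+1); both must lie in (0, 1).
    """
    for label, p in (("x", p_x), ("x+1", p_x1)):
        if not 0 < p < 1:
            raise ValueError(f"P(Y=1|X={label}) = {p} outside (0,1)")
    a = math.exp(delta2 + delta3 * (x + 1.0))
    rr = p_x1 / p_x
    num = a * p_x + math.exp(delta3) * (1.0 - p_x)
    den = a * p_x1 + (1.0 - p_x1)
    return rr * num / den


def conditional_risk_ratio_logbinomial(
    x: float, outcome: OutcomeModelParams, delta2: float, delta3: float
) -> float:
    """Conditional risk ratio at x under a log-binomial outcome model."""
    if outcome.family != "log_binomial":
        raise ValueError("outcome family must be log_binomial")
    p = [None, None]
    for i, xi in enumerate((x, x + 1.0)):
        pi = math.exp(outcome.beta0 + outcome.beta1 * xi)
        if pi >= 1.0:
            raise ValueError(f"log-binomial probability >= 1 at x={xi:.6g}")
        p[i] = pi
    return conditional_risk_ratio(p[0], p[1], delta2, delta3, x)


def risk_ratio_difference_logbinomial(
    x: float, outcome: OutcomeModelParams, delta2: float, delta3: float
) -> float:
    """Difference RR_{XY}(x) - RR_{XY|S=1}(x) under a log-binomial outcome.

    Zero when delta2 = delta3 = 0, and when delta3 = 0 and beta1 = 0; but a
    nonzero delta2 alone generally biases the risk ratio even without an
    interaction.
    """
    rr_uncond = math.exp(outcome.beta1)
    rr_cond = conditional_risk_ratio_logbinomial(x, outcome, delta2, delta3)
    return rr_uncond - rr_cond


def risk_ratio_bias(
    x: float, outcome: OutcomeModelParams, delta2: float, delta3: float
) -> BiasResult:
    rr_uncond = math.exp(outcome.beta1)
    rr_cond = conditional_risk_ratio_logbinomial(x, outcome, delta2, delta3)
    return BiasResult("risk_ratio", rr_uncond, rr_cond, rr_cond / rr_uncond)


# ---------------------------------------------------------------------------
# Linear model


def linear_coef_bias(delta2: float, delta3: float, sigma: float) -> tuple[float, float]:
    """(intercept bias, slope bias) = (delta2*sigma^2, delta3*sigma^2)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    v = sigma * sigma
    return delta2 * v, delta3 * v


def linear_conditional_mean(
    x: float, outcome: OutcomeModelParams, delta2: float, delta3: float
) -> float:
    """E(Y | X=x, S=1) = (beta0 + delta2*sigma^2) + (beta1 + delta3*sigma^2) x."""
    if outcome.family != "linear":
        raise ValueError("outcome family must be linear")
    b0, b1 = linear_coef_bias(delta2, delta3, outcome.sigma)
    return (outcome.beta0 + b0) + (outcome.beta1 + b1) * x


def conditional_mean_general(
    m: Callable[[float], float], x: float, delta2: float, delta3: float, sigma: float
) -> float:
    """E(Y|X=x, S=1) = m(x) + sigma^2*delta2 + sigma^2*delta3*x for a general
    mean function m with homoscedastic normal residuals.

    ``m`` is evaluated pointwise; no smoothness is required of the supplied
    function beyond finiteness at x.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    v = sigma * sigma
    return m(x) + v * delta2 + v * delta3 * x


def linear_bias(outcome: OutcomeModelParams, delta2: float, delta3: float) -> tuple[BiasResult, BiasResult]:
    b0, b1 = linear_coef_bias(delta2, delta3, outcome.sigma)
    return (
        BiasResult("linear_intercept", outcome.beta0, outcome.beta0 + b0, b0),
        BiasResult("linear_slope", outcome.beta1, outcome.beta1 + b1, b1),
    )


# ---------------------------------------------------------------------------
# Poisson model


def poisson_coef_bias(delta2: float, delta3: float) -> tuple[float, float]:
    """(intercept bias, slope bias) = (delta2, delta3)."""
    return float(delta2), float(delta3)


def poisson_conditional_rate(
    x: float, outcome: OutcomeModelParams, delta2: float, delta3: float
) -> float:
    """Rate of Y | X=x, S=1, which stays Poisson:
    exp{(beta0+delta2) + (beta1+delta3) x}."""
    if outcome.family != "poisson":
        raise ValueError("outcome family must be poisson")
    return math.exp((outcome.beta0 + delta2) + (outcome.beta1 + delta3) * x)


def poisson_conditional_rate_generalized(
    x: float, outcome: OutcomeModelParams, delta2: float, g3: Callable[[float], float]
) -> float:
    """Conditional Poisson rate exp{beta0 + beta1*x + delta2 + g3(x)} under an
    exposure-dependent interaction coefficient g3."""
    if outcome.family != "poisson":
        raise ValueError("outcome family must be poisson")
    return math.exp(outcome.beta0 + outcome.beta1 * x + delta2 + g3(x))


def poisson_bias(outcome: OutcomeModelParams, delta2: float, delta3: float) -> tuple[BiasResult, BiasResult]:
    b0, b1 = poisson_coef_bias(delta2, delta3)
    return (
        BiasResult("poisson_intercept", outcome.beta0, outcome.beta0 + b0, b0),
        BiasResult("poisson_slope", outcome.beta1, outcome.beta1 + b1, b1),
    )
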