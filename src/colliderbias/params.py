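"""Parameter containers for the selection (collider) model, the exposure-outcome
model, and the exposure distribution.

The central object is the log-additive selection model

    log P(S=1 | X, Y) = delta0 + delta1*X + delta2*Y + delta3*X*Y,

whose exposure-outcome interaction coefficient ``delta3`` governs the collider
bias induced by restricting an analysis to selected (S=1) units.  Alternative
selection mechanisms (logistic, probit, and a two-tailed "double-threshold"
latent-normal rule) share the same linear predictor but map it to a selection
probability differently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.special import expit

SELECTION_FAMILIES = ("log_additive", "logistic", "probit", "double_threshold")
OUTCOME_FAMILIES = ("logistic", "linear", "poisson", "log_binomial")
EXPOSURE_DISTRIBUTIONS = ("bernoulli", "normal")


@dataclass(frozen=True)
class SelectionModelParams:
    """Coefficients and family of the model for P(S=1 | X, Y).

    Parameters
    ----------
    family
        One of ``log_additive``, ``logistic``, ``probit``, ``double_threshold``.
    delta0, delta1, delta2, delta3
        Intercept, exposure main effect, outcome main effect, and
        exposure-outcome interaction, on the family's native scale
        (log-probability, log-odds, or latent mean).
    latent_sd
        Residual SD of the latent variable S' for the probit and
        double-threshold families; unused otherwise.
    r1, r2
        Double-threshold cut points: S=1 when S' < r1 or S' > r2.
    """

    family: str
    delta0: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    delta3: float = 0.0
    latent_sd: float = 1.6
    r1: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.family not in SELECTION_FAMILIES:
            raise ValueError(
                f"unknown selection family {self.family!r}; "
                f"expected one of {SELECTION_FAMILIES}"
            )
        if self.family in ("probit", "double_threshold") and not self.latent_sd > 0:
            raise ValueError("latent_sd must be positive for latent-variable families")
        if self.family == "double_threshold" and self.r1 is not None and self.r2 is not None:
            if not self.r1 < self.r2:
                raise ValueError(f"require r1 < r2, got r1={self.r1}, r2={self.r2}")

    def linear_predictor(self, x, y):
        """delta0 + delta1*x + delta2*y + delta3*x*y, elementwise."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.delta0 + self.delta1 * x + self.delta2 * y + self.delta3 * x * y

    def selection_probability(self, x, y):
        """Marginal (over latent noise) probability of selection given (x, y).

        For the log-additive family the model is only valid where the linear
        predictor is non-positive; evaluation at a point with exp(lp) > 1
        raises a ``ValueError``.
        """
        lp = self.linear_predictor(x, y)
        if self.family == "log_additive":
            p = np.exp(lp)
            if np.any(p > 1.0):
                bad = np.max(lp)
                raise ValueError(
                    "log-additive selection probability exceeds 1 "
                    f"(max linear predictor {bad:.6g} > 0); the model is invalid "
                    "on this support"
                )
            return p
        if self.family == "logistic":
            return expit(lp)
        if self.family == "probit":
            return stats.norm.cdf(lp / self.latent_sd)
        # double threshold: S=1 in either tail of S' ~ N(lp, latent_sd^2)
        if self.r1 is None or self.r2 is None:
            raise ValueError("double_threshold family requires cut points r1 < r2")
        lower = stats.norm.cdf((self.r1 - lp) / self.latent_sd)
        upper = stats.norm.sf((self.r2 - lp) / self.latent_sd)
        return lower + upper

    def validate_log_additive(self, x_support, y_support) -> None:
        """Check exp-linear-predictor <= 1 on the cartesian product of supports."""
        if self.family != "log_additive":
            return
        xg, yg = np.meshgrid(np.asarray(x_support), np.asarray(y_support))
        self.selection_probability(xg.ravel(), yg.ravel())

    def replace(self, **kwargs) -> "SelectionModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class OutcomeModelParams:
    """Family and coefficients of the exposure-outcome model.

    ``logistic``:     logit P(Y=1|X) = beta0 + beta1*X
    ``linear``:       Y = beta0 + beta1*X + eps, eps ~ N(0, sigma^2)
    ``poisson``:      Y|X ~ Poisson(exp(beta0 + beta1*X))
    ``log_binomial``: log P(Y=1|X) = beta0 + beta1*X
    """

    family: str
    beta0: float = 0.0
    beta1: float = 0.2
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in OUTCOME_FAMILIES:
            raise ValueError(
                f"unknown outcome family {self.family!r}; expected one of {OUTCOME_FAMILIES}"
            )
        if self.family == "linear":
            if self.sigma is None or not self.sigma > 0:
                raise ValueError("linear outcome requires sigma > 0")

    def mean(self, x):
        """E(Y | X=x) under the model."""
        x = np.asarray(x, dtype=float)
        lp = self.beta0 + self.beta1 * x
        if self.family == "logistic":
            return expit(lp)
        if self.family == "linear":
            return lp
        if self.family == "poisson":
            return np.exp(lp)
        # log-binomial success probability
        p = np.exp(lp)
        if np.any(p >= 1.0):
            xbad = np.asarray(x).ravel()[np.argmax(np.asarray(p).ravel())]
            raise ValueError(
                f"log-binomial probability >= 1 at x={xbad:.6g}; model invalid there"
            )
        return p

    def replace(self, **kwargs) -> "OutcomeModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ExposureSpec:
    """Marginal distribution of the exposure X."""

    distribution: str
    p: float | None = None
    mu: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in EXPOSURE_DISTRIBUTIONS:
            raise ValueError(
                f"unknown exposure distribution {self.distribution!r}; "
                f"expected one of {EXPOSURE_DISTRIBUTIONS}"
            )
        if self.distribution == "bernoulli":
            if self.p is None or not 0 < self.p < 1:
                raise ValueError("bernoulli exposure requires 0 < p < 1")
        else:
            if self.mu is None or self.sd is None or not self.sd > 0:
                raise ValueError("normal exposure requires mu and sd > 0")

    def draw(self, n: int, rng: np.random.Generator):
        if self.distribution == "bernoulli":
            return rng.binomial(1, self.p, size=n).astype(float)
        return rng.normal(self.mu, self.sd, size=n)


@dataclass(frozen=True)
class GeneralizedSelectionModel:
    """Selection model log P(S=1|X,Y) = g1(X) + g2(Y) + g3(X)*Y.

    ``g3`` is an exposure-dependent interaction coefficient; a constant g3
    reduces to the plain log-additive model with delta2 absorbed into g2.
    When the linear ``delta2 * Y`` outcome term applies, set ``g2 = None`` and
    supply ``delta2``.
    """

    g1: Callable[[float], float]
    g2: Callable[[float], float] | None
    g3: Callable[[float], float]
    delta2: float = 0.0

    def log_probability(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        g2 = self.delta2 * y if self.g2 is None else np.vectorize(self.g2)(y)
        return np.vectorize(self.g1)(x) + g2 + np.vectorize(self.g3)(x) * y

    def validate(self, x_support, y_support) -> None:
        xg, yg = np.meshgrid(np.asarray(x_support), np.asarray(y_support))
        lp = self.log_probability(xg.ravel(), yg.ravel())
        if np.any(lp > 0):
            raise ValueError("generalized selection log-probability exceeds 0 on support")
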