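"""Independent numerical oracles used to verify the closed-form bias
expressions.

Each oracle computes conditional (S=1) associations directly from the joint
law under the log-additive selection model

    P(S=1|X=x, Y=y) = exp(d0 + d1*x + d2*y + d3*x*y)

without using any of the closed forms it checks:

* exact enumeration over the four cells of binary (X, Y);
* Gauss-Hermite quadrature of E(Y | X=x, S=1) for a normal outcome;
* truncated summation of E(Y | X=x, S=1) for a Poisson outcome.
"""

from __future__ import annotations

import math

import numpy as np


def _cell_weight(x: float, y: float, d0: float, d1: float, d2: float, d3: float) -> float:
    lp = d0 + d1 * x + d2 * y + d3 * x * y
    if lp > 0:
        raise ValueError(f"invalid log-additive model: lp={lp} > 0 at (x={x}, y={y})")
    return math.exp(lp)


def enumerate_binary(
    py: dict[float, float],
    d0: float,
    d1: float,
    d2: float,
    d3: float,
    x_values: tuple[float, float] = (0.0, 1.0),
) -> dict[str, float]:
    """Conditional and unconditional OR and RR by summation over binary Y.

    ``py`` maps each of the two exposure values to P(Y=1 | X=x).  The
    conditional quantities are computed from P(Y=y | X=x, S=1) obtained by
    direct normalization of P(Y=y|X=x) * P(S=1|x,y).
    """
    x0, x1 = x_values
    p_cond = {}
    for x in (x0, x1):
        w1 = py[x] * _cell_weight(x, 1.0, d0, d1, d2, d3)
        w0 = (1.0 - py[x]) * _cell_weight(x, 0.0, d0, d1, d2, d3)
        p_cond[x] = w1 / (w1 + w0)
    odds = lambda p: p / (1.0 - p)
    return {
        "or_uncond": odds(py[x1]) / odds(py[x0]),
        "or_cond": odds(p_cond[x1]) / odds(p_cond[x0]),
        "rr_uncond": py[x1] / py[x0],
        "rr_cond": p_cond[x1] / p_cond[x0],
    }


def enumerate_or_generalized(
    py: dict[float, float],
    g1,
    g2,
    g3,
    x_values: tuple[float, float],
) -> float:
    """Conditional OR over binary Y under log P(S=1) = g1(x) + g2(y) + g3(x)*y."""
    x0, x1 = x_values
    p_cond = {}
    for x in (x0, x1):
        lps = {y: g1(x) + g2(y) + g3(x) * y for y in (0.0, 1.0)}
        if max(lps.values()) > 0:
            raise ValueError("invalid generalized selection model on support")
        w1 = py[x] * math.exp(lps[1.0])
        w0 = (1.0 - py[x]) * math.exp(lps[0.0])
        p_cond[x] = w1 / (w1 + w0)
    odds = lambda p: p / (1.0 - p)
    return odds(p_cond[x1]) / odds(p_cond[x0])


def gauss_hermite_mean(
    x: float,
    beta0: float,
    beta1: float,
    sigma: float,
    d2: float,
    d3: float,
    nodes: int = 96,
) -> float:
    """E(Y | X=x, S=1) for Y = beta0 + beta1*x + N(0, sigma^2) by quadrature.

    The selection factor exp(d2*y + d3*x*y) tilts the normal density; the
    intercept and exposure main effect of the selection model cancel in the
    conditional expectation and are not needed.
    """
    t, w = np.polynomial.hermite.hermgauss(nodes)
    mu = beta0 + beta1 * x
    y = mu + math.sqrt(2.0) * sigma * t
    tilt = np.exp((d2 + d3 * x) * y)
    return float(np.sum(w * y * tilt) / np.sum(w * tilt))


def truncated_poisson_mean(
    x: float,
    beta0: float,
    beta1: float,
    d2: float,
    d3: float,
    cap: int | None = None,
) -> float:
    """E(Y | X=x, S=1) for Y|X ~ Poisson(exp(beta0+beta1*x)) by summation.

    Sums y * P(y) * exp((d2+d3*x)*y) up to a cap far beyond the tilted mean,
    so the truncation error is negligible relative to test tolerances.
    """
    lam = math.exp(beta0 + beta1 * x)
    tilted = lam * math.exp(d2 + d3 * x)
    if cap is None:
        cap = int(max(200, tilted + 20.0 * math.sqrt(tilted)))
    ys = np.arange(cap + 1)
    from scipy.stats import poisson

    w = poisson.pmf(ys, lam) * np.exp((d2 + d3 * x) * ys)
    return float(np.sum(ys * w) / np.sum(w))


def draw_valid_log_additive(
    rng: np.random.Generator,
    y_support: tuple[float, ...] = (0.0, 1.0),
    x_support: tuple[float, ...] = (0.0, 1.0),
    scale: float = 0.5,
    margin: float = 0.05,
) -> tuple[float, float, float, float]:
    """Random (d0, d1, d2, d3) with exp-linear-predictor strictly below 1 on
    the given support: d0 is shifted below minus the max of the rest."""
    d1, d2, d3 = rng.uniform(-scale, scale, size=3)
    rest = max(
        d1 * x + d2 * y + d3 * x * y for x in x_support for y in y_support
    )
    d0 = -rest - margin - rng.uniform(0.0, 1.0)
    return d0, d1, d2, d3
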