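"""Numerical asymptotic study: collider bias versus the log-additive
exposure-outcome interaction.

For each value of the interaction parameter on a grid, one large cohort is
generated under a chosen (outcome model, selection model) pair with the
selection fraction calibrated to a target.  Two quantities are computed per
grid point:

* ``bias_hat`` — the exposure coefficient fitted on selected units minus the
  true coefficient (the collider bias at that grid point);
* ``delta3_s0_hat`` — the interaction MLE from fitting the (generally
  misspecified) log-additive selection model to the same cohort.

A least-squares line of bias on the estimated log-additive interaction
quantifies the theory's prediction: slope 1 for logistic and Poisson
outcomes, sigma^2 for linear outcomes, regardless of the true selection
mechanism (for a binary exposure) and of the selection fraction.
"""

from __future__ import annotations

import gc
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fitters import fit_outcome, fit_selection_log_additive
from .params import ExposureSpec, OutcomeModelParams, SelectionModelParams
from .simulate import calibrate_selection, derive_seed, draw_cohort

logger = logging.getLogger(__name__)

#: default parameter preset of the numerical study
DEFAULT_PRESET = {
    "beta0": 0.0,
    "beta1": 0.2,
    "sigma": 0.5,
    "delta1": 0.3,
    "delta2": 0.3,
    "latent_sd": 1.6,
    "exposure_p": 0.3,
}

#: interaction grid used throughout the study
DEFAULT_DELTA3_GRID = (-0.5, -0.4, -0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def make_outcome(family: str, preset: dict | None = None) -> OutcomeModelParams:
    p = {**DEFAULT_PRESET, **(preset or {})}
    sigma = p["sigma"] if family == "linear" else None
    return OutcomeModelParams(family=family, beta0=p["beta0"], beta1=p["beta1"], sigma=sigma)


def make_selection(family: str, delta3: float, preset: dict | None = None) -> SelectionModelParams:
    p = {**DEFAULT_PRESET, **(preset or {})}
    return SelectionModelParams(
        family=family,
        delta0=0.0,
        delta1=p["delta1"],
        delta2=p["delta2"],
        delta3=delta3,
        latent_sd=p["latent_sd"],
    )


def make_exposure(preset: dict | None = None) -> ExposureSpec:
    p = {**DEFAULT_PRESET, **(preset or {})}
    return ExposureSpec(distribution="bernoulli", p=p["exposure_p"])


def estimate_slope(
    points: list[tuple[float, float]], weights=None
) -> tuple[float, float, float]:
    """Ordinary (or weighted) least squares with intercept.

    Returns (slope, slope standard error, intercept).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissae: zero variance in x")
    exog = sm.add_constant(x)
    if weights is None:
        res = sm.OLS(y, exog).fit()
    else:
        res = sm.WLS(y, exog, weights=np.asarray(weights, float)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.params[0])


@dataclass(frozen=True)
class BiasCurve:
    """Bias and estimated log-additive interaction across an interaction grid."""

    dgm_label: str
    selection_fraction: float
    grid: pd.DataFrame  # delta3_true, bias_hat, delta3_s0_hat, mc_se, converged
    slope_vs_true: float | None = None
    slope_vs_s0: float | None = None
    slope_se: float | None = None
    intercept_vs_s0: float | None = None

    def summary(self) -> dict:
        return {
            "dgm_label": self.dgm_label,
            "selection_fraction": self.selection_fraction,
            "slope_vs_true": self.slope_vs_true,
            "slope_vs_s0": self.slope_vs_s0,
            "slope_se": self.slope_se,
            "intercept_vs_s0": self.intercept_vs_s0,
        }

    def record(self, delta3_true: float) -> pd.Series:
        rows = self.grid[self.grid["delta3_true"] == delta3_true]
        if rows.empty:
            raise KeyError(f"no grid record at delta3_true={delta3_true}")
        return rows.iloc[0]


def run_bias_experiment(
    outcome_family: str,
    selection_family: str,
    delta3_grid=DEFAULT_DELTA3_GRID,
    selection_fraction: float = 0.5,
    n: int = 500_000,
    seed: int = 0,
    preset: dict | None = None,
    calibration_n: int | None = None,
) -> BiasCurve:
    """Sweep the interaction grid for one (outcome, selection) pair.

    Per grid point: calibrate the selection intercept (or thresholds) to the
    target fraction, draw one cohort of size n, fit the outcome model on
    selected units, and fit the log-additive selection model with
    interaction.  Slopes of bias on the estimated and true interaction are
    then fitted by OLS with intercept over the converged grid points.
    """
    if len(delta3_grid) == 0:
        raise ValueError("delta3 grid must be nonempty")
    if not 0 < selection_fraction < 1:
        raise ValueError("selection_fraction must be in (0, 1)")
    exposure = make_exposure(preset)
    outcome = make_outcome(outcome_family, preset)
    beta1_true = outcome.beta1
    dgm_label = f"{outcome_family}+{selection_family}"
    cal_kwargs = {} if calibration_n is None else {"presample_n": calibration_n}

    records = []
    for delta3 in sorted(delta3_grid):
        sel = make_selection(selection_family, delta3, preset)
        sel = calibrate_selection(sel, exposure, outcome, selection_fraction, **cal_kwargs)
        # common random numbers: one stream per DGM, shared across grid
        # points and fractions, so grid-point noise cancels in slope and
        # cross-fraction contrasts
        cell = f"{dgm_label}|f={selection_fraction:g}|d3={delta3:g}"
        cohort_seed = derive_seed(seed, dgm_label)
        logger.info("cell %s seed=%d", cell, cohort_seed)
        cohort = draw_cohort(exposure, outcome, sel, n, cohort_seed, dgm_label=cell)
        out_fit = fit_outcome(cohort, outcome_family, subset="selected")
        s0_fit = fit_selection_log_additive(cohort, include_interaction=True)
        ok = out_fit.converged and s0_fit.converged
        if not ok:
            warnings.warn(
                f"non-converged fit at {cell}; excluded from slope "
                f"({out_fit.message or s0_fit.message})",
                RuntimeWarning,
            )
        records.append(
            {
                "delta3_true": delta3,
                "bias_hat": out_fit.estimates["beta1"] - beta1_true,
                "delta3_s0_hat": s0_fit.estimates.get("delta3", np.nan),
                "mc_se": out_fit.standard_errors["beta1"],
                "converged": ok,
                "selected_fraction": cohort.selected_fraction,
                "n_truncated": cohort.n_truncated,
            }
        )
        # GLM results hold reference cycles over n-length arrays; reclaim
        # them now so long sweeps stay within a workstation's memory
        del cohort, out_fit, s0_fit
        gc.collect()
    grid = pd.DataFrame.from_records(records).sort_values("delta3_true", ignore_index=True)

    good = grid[grid["converged"]]
    slope_vs_true = slope_vs_s0 = slope_se = intercept_vs_s0 = None
    if len(good) >= 3:
        slope_vs_true, _, _ = estimate_slope(
            list(zip(good["delta3_true"], good["bias_hat"]))
        )
        slope_vs_s0, slope_se, intercept_vs_s0 = estimate_slope(
            list(zip(good["delta3_s0_hat"], good["bias_hat"]))
        )
    return BiasCurve(
        dgm_label=dgm_label,
        selection_fraction=selection_fraction,
        grid=grid,
        slope_vs_true=slope_vs_true,
        slope_vs_s0=slope_vs_s0,
        slope_se=slope_se,
        intercept_vs_s0=intercept_vs_s0,
    )


def selection_fraction_sweep(
    outcome_family: str,
    selection_family: str,
    fractions,
    delta3_grid=DEFAULT_DELTA3_GRID,
    n: int = 500_000,
    seed: int = 0,
    preset: dict | None = None,
    calibration_n: int | None = None,
) -> list[BiasCurve]:
    """One BiasCurve per selection fraction, sharing the master seed so grid
    points are comparable across fractions."""
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"selection fraction {f} outside (0, 1)")
    return [
        run_bias_experiment(
            outcome_family, selection_family, delta3_grid, f, n, seed, preset,
            calibration_n=calibration_n,
        )
        for f in fractions
    ]


def sweep_summary(curves: list[BiasCurve]) -> dict:
    """Across-fraction summary: the slopes and their maximum pairwise spread."""
    slopes = {c.selection_fraction: c.slope_vs_s0 for c in curves}
    diffs = [
        abs(a - b)
        for a, b in combinations([s for s in slopes.values() if s is not None], 2)
    ]
    return {
        "slopes_vs_s0": slopes,
        "max_pairwise_slope_diff": max(diffs) if diffs else None,
    }


def plot_curves(curves: list[BiasCurve], x_axis: str = "delta3_s0_hat", path=None):
    """3x3 panel figure of bias against the true or estimated interaction.

    Rows are selection families, columns outcome families, matching the
    study's usual layout.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outs = sorted({c.dgm_label.split("+")[0] for c in curves})
    sels = sorted({c.dgm_label.split("+")[1] for c in curves})
    fig, axes = plt.subplots(len(sels), len(outs), figsize=(3.2 * len(outs), 3.0 * len(sels)),
                             squeeze=False)
    for c in curves:
        o, s = c.dgm_label.split("+")
        ax = axes[sels.index(s)][outs.index(o)]
        ax.plot(c.grid[x_axis], c.grid["bias_hat"], "o-", ms=3,
                label=f"{c.selection_fraction:.0%}")
        ax.axhline(0, lw=0.5, color="gray")
        ax.axvline(0, lw=0.5, color="gray")
        ax.set_title(c.dgm_label, fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("interaction" if x_axis == "delta3_true" else "estimated log-additive interaction")
    for row in axes:
        row[0].set_ylabel("collider bias")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
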