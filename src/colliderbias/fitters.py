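"""Maximum-likelihood fitting of outcome and selection models.

Outcome models (logistic / linear / Poisson) are fitted by GLM on either all
units or the selected (S=1) subset.  Selection models are fitted on the full
cohort with S as the response.  The log-additive selection model is fitted by
log-link Poisson-regression estimating equations applied to the binary
indicator: the score equations of a log-link count-family GLM evaluated at a
0/1 response are exactly the quasi-likelihood equations of the log-additive
binary model.  Fitted probabilities above 1 are permitted during that fit but
counted and reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .simulate import SimulatedCohort

_OUTCOME_GLM_FAMILIES = {
    "logistic": sm.families.Binomial,
    "linear": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
}


@dataclass(frozen=True)
class FitResult:
    """Point estimates and model-based standard errors from one fit."""

    model_label: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    n_used: int
    subset: str = "all"
    message: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.estimates) != set(self.standard_errors):
            raise ValueError("estimates and standard_errors must share names")
        if not self.converged and not self.message:
            raise ValueError("non-converged fits must carry a diagnostic message")

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_label": self.model_label,
                "estimates": self.estimates,
                "standard_errors": self.standard_errors,
                "converged": self.converged,
                "n_used": self.n_used,
                "subset": self.subset,
                "message": self.message,
                "extras": self.extras,
            },
            indent=2,
        )


def _glm_fit(
    endog: np.ndarray,
    exog: np.ndarray,
    family,
    names: list[str],
    label: str,
    subset: str,
    weights: np.ndarray | None = None,
    start_params: np.ndarray | None = None,
    maxiter: int = 100,
    tol: float = 1e-8,
    count_fitted_gt1: bool = False,
) -> FitResult:
    kwargs = {}
    if weights is not None:
        kwargs["var_weights"] = weights
    try:
        model = sm.GLM(endog, exog, family=family, **kwargs)
        res = model.fit(start_params=start_params, maxiter=maxiter, tol=tol)
        converged = bool(getattr(res, "converged", True))
        message = "" if converged else f"IRLS did not converge in {maxiter} iterations"
        est = dict(zip(names, map(float, res.params)))
        se = dict(zip(names, map(float, res.bse)))
        extras = {"deviance": float(res.deviance)}
        if count_fitted_gt1:
            extras["n_fitted_gt1"] = int(np.sum(res.fittedvalues > 1.0))
        return FitResult(label, est, se, converged, len(endog), subset, message, extras)
    except Exception as exc:  # separation, singular design, ...
        nan = {nm: float("nan") for nm in names}
        return FitResult(
            label, nan, nan, False, len(endog), subset,
            f"fit failed: {type(exc).__name__}: {exc}",
        )


def fit_outcome(
    cohort: SimulatedCohort,
    family: str,
    subset: str = "selected",
    weights: np.ndarray | None = None,
) -> FitResult:
    """ML fit of the outcome model Y ~ intercept + X on all or selected units.

    ``weights`` (aligned with the full cohort) turn the score equations into
    weighted estimating equations, as used for inverse-probability weighting.
    """
    if family not in _OUTCOME_GLM_FAMILIES:
        raise ValueError(f"unknown outcome family {family!r}")
    if subset not in ("all", "selected"):
        raise ValueError(f"subset must be 'all' or 'selected', got {subset!r}")
    mask = np.ones(cohort.n, dtype=bool) if subset == "all" else cohort.s == 1
    if not mask.any():
        raise ValueError("no units in the requested subset")
    x, y = cohort.x[mask], cohort.y[mask]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct exposure values in the subset")
    exog = sm.add_constant(x)
    w = None if weights is None else np.asarray(weights, float)[mask]
    return _glm_fit(
        y, exog, _OUTCOME_GLM_FAMILIES[family](),
        names=["beta0", "beta1"],
        label=f"outcome:{family}",
        subset=subset,
        weights=w,
    )


def _selection_design(cohort: SimulatedCohort, include_interaction: bool):
    cols = [np.ones(cohort.n), cohort.x, cohort.y]
    names = ["delta0", "delta1", "delta2"]
    if include_interaction:
        cols.append(cohort.x * cohort.y)  # raw product, no centering
        names.append("delta3")
    return np.column_stack(cols), names


def _check_selection_variation(cohort: SimulatedCohort) -> None:
    s = np.asarray(cohort.s)
    if s.min() == s.max():
        raise ValueError("selection indicator is constant; cannot fit a selection model")


def fit_selection_log_additive(
    cohort: SimulatedCohort, include_interaction: bool = True
) -> FitResult:
    """Fit log P(S=1|X,Y) = delta0 + delta1 X + delta2 Y (+ delta3 XY) by
    log-link Poisson estimating equations on the binary indicator.

    The ``extras`` dict reports ``n_fitted_gt1``, the number of fitted
    probabilities above 1 (expected to be nonzero when the log-additive form
    is misspecified for the data).
    """
    _check_selection_variation(cohort)
    exog, names = _selection_design(cohort, include_interaction)
    start = np.zeros(len(names))
    start[0] = np.log(cohort.s.mean())
    return _glm_fit(
        cohort.s.astype(float), exog, sm.families.Poisson(),
        names=names, label="selection:log_additive", subset="all",
        start_params=start, count_fitted_gt1=True,
    )


def fit_selection_logistic(
    cohort: SimulatedCohort, include_interaction: bool = True
) -> FitResult:
    """Logistic ML fit of S on X, Y (+ XY if requested) on the full cohort."""
    _check_selection_variation(cohort)
    exog, names = _selection_design(cohort, include_interaction)
    return _glm_fit(
        cohort.s.astype(float), exog, sm.families.Binomial(),
        names=names, label="selection:logistic", subset="all",
    )
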