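"""Seeded cohort simulation under the study's data-generating mechanisms.

A cohort is (X, Y, S): exposure, outcome, and a binary selection indicator.
Outcomes follow one of three regression models (logistic, linear, Poisson)
and selection follows one of four mechanisms sharing the linear predictor
delta0 + delta1*X + delta2*Y + delta3*X*Y:

* ``logistic``          P(S=1) = expit(lp)
* ``probit``            S = 1{S' > 0},       S' ~ N(lp, latent_sd^2)
* ``double_threshold``  S = 1{S' < r1 or S' > r2}  (both tails)
* ``log_additive``      P(S=1) = exp(lp), valid only where lp <= 0

When a log-additive request would yield exp(lp) > 1 for some draws (possible
with an unbounded outcome), the probability is truncated at 1 and a warning
reports the truncated fraction, which is also stored on the cohort.

``calibrate_selection`` tunes the intercept delta0 (or, for the
double-threshold model, the cut points r1, r2) so that the marginal selection
probability hits a target fraction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .params import ExposureSpec, OutcomeModelParams, SelectionModelParams

#: fixed seed for the calibration presample so that calibrated intercepts are
#: reproducible and independent of the cohort-generating stream
CALIBRATION_SEED = 202_406_17
DEFAULT_CALIBRATION_N = 1_000_000


def derive_seed(master_seed: int, label: str) -> int:
    """Stable sub-seed below 2**31 derived from a master seed and a label.

    Used to give every (DGM, grid point, fraction) cell of an experiment its
    own reproducible stream.
    """
    return zlib.crc32(f"{int(master_seed)}|{label}".encode()) % (2**31)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort with its generating parameters.

    Regenerating with identical parameters and seed reproduces the arrays
    bit-identically.
    """

    x: np.ndarray
    y: np.ndarray
    s: np.ndarray
    seed: int
    dgm_label: str
    exposure: ExposureSpec
    outcome: OutcomeModelParams
    selection: SelectionModelParams
    n_truncated: int = 0

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def selected_fraction(self) -> float:
        return float(self.s.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "y": self.y, "s": self.s})

    def save(self, path: str | Path, sep: str = "\t") -> None:
        """Write a headered delimited table (x, y, s) plus a JSON sidecar of
        the generating parameters and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index=False)
        meta = {
            "seed": self.seed,
            "dgm_label": self.dgm_label,
            "n": self.n,
            "n_truncated": self.n_truncated,
            "exposure": dataclasses.asdict(self.exposure),
            "outcome": dataclasses.asdict(self.outcome),
            "selection": dataclasses.asdict(self.selection),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _draw_xy(
    exposure: ExposureSpec,
    outcome: OutcomeModelParams,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    x = exposure.draw(n, rng)
    lp = outcome.beta0 + outcome.beta1 * x
    if outcome.family == "logistic":
        y = (rng.random(n) < expit(lp)).astype(float)
    elif outcome.family == "linear":
        y = lp + rng.normal(0.0, outcome.sigma, size=n)
    elif outcome.family == "poisson":
        y = rng.poisson(np.exp(lp)).astype(float)
    else:  # log_binomial
        p = np.exp(lp)
        if np.any(p >= 1.0):
            raise ValueError("log-binomial outcome probability >= 1 on drawn exposures")
        y = (rng.random(n) < p).astype(float)
    return x, y


def _selection_draw(
    selection: SelectionModelParams, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Draw S given (x, y); returns (s, number of truncated log-additive draws)."""
    lp = selection.linear_predictor(x, y)
    n_trunc = 0
    if selection.family == "log_additive":
        p = np.exp(lp)
        over = p > 1.0
        n_trunc = int(over.sum())
        if n_trunc:
            warnings.warn(
                f"log-additive selection probability truncated at 1 for "
                f"{n_trunc} of {len(p)} draws ({n_trunc / len(p):.2e})",
                RuntimeWarning,
                stacklevel=3,
            )
            p = np.minimum(p, 1.0)
        s = (rng.random(len(p)) < p).astype(np.int8)
    elif selection.family == "logistic":
        s = (rng.random(len(lp)) < expit(lp)).astype(np.int8)
    elif selection.family == "probit":
        latent = rng.normal(lp, selection.latent_sd)
        s = (latent > 0.0).astype(np.int8)
    else:  # double_threshold: selection in either tail of the latent variable
        if selection.r1 is None or selection.r2 is None:
            raise ValueError("double_threshold selection requires cut points r1 < r2")
        latent = rng.normal(lp, selection.latent_sd)
        s = ((latent < selection.r1) | (latent > selection.r2)).astype(np.int8)
    return s, n_trunc


def draw_cohort(
    exposure: ExposureSpec,
    outcome: OutcomeModelParams,
    selection: SelectionModelParams,
    n: int,
    seed: int,
    dgm_label: str | None = None,
) -> SimulatedCohort:
    """Generate a seeded cohort (X, Y, S) of size n."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    x, y = _draw_xy(exposure, outcome, n, rng)
    s, n_trunc = _selection_draw(selection, x, y, rng)
    label = dgm_label or f"{outcome.family}+{selection.family}"
    return SimulatedCohort(
        x=x, y=y, s=s, seed=int(seed), dgm_label=label,
        exposure=exposure, outcome=outcome, selection=selection,
        n_truncated=n_trunc,
    )


def _mean_selection_probability(
    selection: SelectionModelParams, x: np.ndarray, y: np.ndarray, delta0: float
) -> float:
    """E[P(S=1|X,Y)] on a presample, as a function of the intercept.

    Log-additive probabilities are clipped at 1 so the map stays monotone in
    delta0 over the whole real line.
    """
    sel = selection.replace(delta0=delta0)
    lp = sel.linear_predictor(x, y)
    if selection.family == "log_additive":
        return float(np.minimum(np.exp(lp), 1.0).mean())
    if selection.family == "logistic":
        return float(expit(lp).mean())
    # probit
    from scipy.stats import norm

    return float(norm.cdf(lp / selection.latent_sd).mean())


def calibrate_selection(
    selection: SelectionModelParams,
    exposure: ExposureSpec,
    outcome: OutcomeModelParams,
    target_fraction: float,
    tol: float = 1e-3,
    presample_n: int = DEFAULT_CALIBRATION_N,
    calibration_seed: int = CALIBRATION_SEED,
) -> SelectionModelParams:
    """Tune the selection model so the marginal selection fraction hits
    ``target_fraction``.

    Intercept families (log-additive, logistic, probit) get delta0 adjusted by
    root-finding on the Monte-Carlo expectation of P(S=1) over a dedicated
    presample of (X, Y) with a fixed internal seed.  The double-threshold
    model instead sets delta0 = 0 and the cut points to the alpha/2 and
    1 - alpha/2 quantiles of the latent variable S', with alpha the target
    fraction (at 50% these are the first and third quartiles).

    For the log-additive family the solution is kept inside the valid region
    (probabilities <= 1 on the presample) when the target is attainable
    there; otherwise probabilities are truncated during calibration and a
    warning reports the expected truncated fraction.
    """
    if not 0 < target_fraction < 1:
        raise ValueError(f"target_fraction must be in (0,1), got {target_fraction}")
    rng = np.random.default_rng(calibration_seed)
    x, y = _draw_xy(exposure, outcome, presample_n, rng)

    if selection.family == "double_threshold":
        sel0 = selection.replace(delta0=0.0, r1=None, r2=None)
        lp = sel0.linear_predictor(x, y)
        latent = rng.normal(lp, selection.latent_sd)
        alpha = target_fraction
        r1, r2 = np.quantile(latent, [alpha / 2.0, 1.0 - alpha / 2.0])
        return selection.replace(delta0=0.0, r1=float(r1), r2=float(r2))

    rest = (
        selection.delta1 * x + selection.delta2 * y + selection.delta3 * x * y
    )

    if selection.family == "log_additive":
        # largest intercept keeping exp(lp) <= 1 on the presample
        d0_valid = -float(rest.max())
        attainable = float(np.exp(rest + d0_valid).mean())
        if target_fraction > attainable:
            bounded = (
                exposure.distribution == "bernoulli"
                and outcome.family in ("logistic", "log_binomial")
            )
            if bounded:
                raise ValueError(
                    f"target fraction {target_fraction} unattainable for a valid "
                    f"log-additive model on this support; attainable range is "
                    f"(0, {attainable:.4f}]"
                )
            warnings.warn(
                "log-additive calibration target exceeds the valid-model cap "
                f"({attainable:.4f}); probabilities will be truncated at 1",
                RuntimeWarning,
                stacklevel=2,
            )

    def objective(d0: float) -> float:
        return _mean_selection_probability(selection, x, y, d0) - target_fraction

    # bracket the root; the mean probability is monotone increasing in delta0
    lo, hi = -40.0, 40.0
    d0 = brentq(objective, lo, hi, xtol=min(tol, 1e-6) * 0.1)
    achieved = _mean_selection_probability(selection, x, y, d0)
    if abs(achieved - target_fraction) > tol:
        raise ValueError(
            f"calibration failed: achieved fraction {achieved:.5f} vs "
            f"target {target_fraction} (tol {tol})"
        )
    return selection.replace(delta0=float(d0))


def load_cohort(path: str | Path, sep: str = "\t") -> SimulatedCohort:
    """Read a cohort written by :meth:`SimulatedCohort.save`."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SimulatedCohort(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        s=df["s"].to_numpy(np.int8),
        seed=meta["seed"],
        dgm_label=meta["dgm_label"],
        exposure=ExposureSpec(**meta["exposure"]),
        outcome=OutcomeModelParams(**meta["outcome"]),
        selection=SelectionModelParams(**meta["selection"]),
        n_truncated=meta.get("n_truncated", 0),
    )
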