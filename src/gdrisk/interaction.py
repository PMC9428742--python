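"""Gene-environment interaction logistic model.

The model is

    logit P(Y=1 | X1..X4) = a + b*X1 + c*X2 + d*X3 + e*X4 + f*X3*X4

with Y the GD outcome, X1 age (years) and X2 BMI (kg/m^2) as optional
confounders, X3 the high-PRS indicator (top quartile vs rest) and X4 the
low-activity indicator (METs < 450).  The interaction coefficient f carries
the non-additivity of genetic predisposition and inactivity on the log-odds
scale; its Wald z-test against f = 0 is the formal interaction test.

Without confounders the design is saturated over the four (X3, X4) cells,
so the maximum-likelihood coefficients equal the closed-form cell log-odds
contrasts and the fitted probabilities equal the empirical cell rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort


@dataclass
class InteractionFit:
    a: float                       # intercept
    d: float                       # high-PRS main effect
    e: float                       # low-METs main effect
    f: float                       # interaction
    se_f: float
    p_f: float                     # Wald p-value, H0: f = 0
    converged: bool
    n: int
    b: Optional[float] = None      # age (per year), adjusted model only
    c: Optional[float] = None      # BMI (per kg/m^2), adjusted model only
    adjusted: bool = False
    model_spec: str = ""
    loglik: float = float("nan")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class SeparationError(RuntimeError):
    pass


def _design(cohort: Cohort, adjust_confounders: bool) -> tuple[np.ndarray, pd.DataFrame]:
    n = len(cohort)
    y = np.empty(n)
    x3 = np.empty(n)
    x4 = np.empty(n)
    x1 = np.empty(n) if adjust_confounders else None
    x2 = np.empty(n) if adjust_confounders else None
    for i, p in enumerate(cohort):
        if p.gd is None or p.prs_top25 is None or p.mets_low is None:
            raise ValueError(
                f"participant {p.id}: gd/prs_top25/mets_low required for the interaction model"
            )
        y[i] = float(p.gd)
        x3[i] = float(p.prs_top25)
        x4[i] = float(p.mets_low)
        if adjust_confounders:
            if p.age is None or p.bmi is None:
                raise ValueError(f"participant {p.id}: age and BMI required when adjusting")
            x1[i] = p.age
            x2[i] = p.bmi
    cols = {"x1_age": x1, "x2_bmi": x2} if adjust_confounders else {}
    cols.update({"x3_high_prs": x3, "x4_low_mets": x4, "x3x4": x3 * x4})
    return y, sm.add_constant(pd.DataFrame(cols), has_constant="add")


def fit_interaction(cohort: Cohort, adjust_confounders: bool = False) -> InteractionFit:
    """Maximum-likelihood logistic fit of the interaction model.

    Newton iterations, convergence when the log-likelihood change falls
    below 1e-8 (at most 100 iterations).  Complete separation raises
    ``SeparationError`` with a diagnostic.
    """
    y, X = _design(cohort, adjust_confounders)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            "complete or quasi-complete separation in the interaction design; "
            "check for empty or pure (all-case / all-control) design cells"
        ) from exc
    converged = bool(res.mle_retvals.get("converged", True))
    if (not converged and (np.abs(res.params).max() > 30
                           or not np.all(np.isfinite(res.bse))
                           or np.nanmax(res.bse) > 1e3)):
        # diverging coefficients with a failed line search: separation
        raise SeparationError(
            "logistic fit diverged (quasi-complete separation); a design cell "
            "is pure (all cases or all controls)"
        )
    params = res.params
    fit = InteractionFit(
        a=float(params["const"]),
        d=float(params["x3_high_prs"]),
        e=float(params["x4_low_mets"]),
        f=float(params["x3x4"]),
        se_f=float(res.bse["x3x4"]),
        p_f=float(res.pvalues["x3x4"]),
        converged=converged,
        n=len(y),
        adjusted=adjust_confounders,
        model_spec="gd ~ " + " + ".join(c for c in X.columns if c != "const"),
        loglik=float(res.llf),
    )
    if adjust_confounders:
        fit.b = float(params["x1_age"])
        fit.c = float(params["x2_bmi"])
    return fit


def saturated_cell_logits(t00, t10, t01, t11) -> tuple[float, float, float, float]:
    """Closed-form coefficients of the saturated two-binary-covariate model
    from the four design cells, each given as (cases, controls):
    a = logit(p00), d = logit(p10) - a, e = logit(p01) - a,
    f = logit(p11) - a - d - e.  Cell order: (X3, X4) = (0,0), (1,0), (0,1), (1,1).
    """
    def cell_logit(cc):
        cases, controls = cc
        if cases == 0 or controls == 0:
            raise ValueError(f"pure cell {cc}: saturated logits undefined")
        return float(np.log(cases / controls))

    a = cell_logit(t00)
    d = cell_logit(t10) - a
    e = cell_logit(t01) - a
    f = cell_logit(t11) - a - d - e
    return a, d, e, f
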