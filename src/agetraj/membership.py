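"""Baseline predictors of trajectory-class membership (multinomial logistic).

Class A (Stable Low-Risk) is the reference outcome; odds ratios for classes
B, C and D are reported with the study's clinical scaling: age and BMI per
5-unit increment, binary predictors per level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z975 = 1.959964

DEFAULT_PREDICTORS = ["age", "gender", "bmi", "hypertension", "diabetes"]

#: per-predictor OR scaling (units per reported increment)
DEFAULT_SCALES = {"age": 5.0, "bmi": 5.0}


def rescale_or(beta: float, se: float, scale: float = 1.0):
    """Odds ratio and Wald 95% CI for a ``scale``-unit increment.

    OR = exp(scale*beta); the CI endpoints transform identically, so a
    per-unit fit rescaled to 5 units equals a direct fit on the 5-unit
    variable.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return (
        float(np.exp(scale * beta)),
        float(np.exp(scale * (beta - Z975 * se))),
        float(np.exp(scale * (beta + Z975 * se))),
    )


@dataclass
class MembershipFit:
    or_table: pd.DataFrame  # outcome_class, predictor, scale, or, ci_low, ci_high, p
    coef: pd.DataFrame  # raw per-unit betas (rows: predictor incl const, cols: class)
    se: pd.DataFrame
    converged: bool
    classes: list[str]
    model: object = None  # fitted statsmodels result, for prediction


def fit_multinomial(
    data: pd.DataFrame,
    predictors: list[str] | None = None,
    reference: str = "A",
    scales: dict | None = None,
    class_col: str = "class_label",
) -> MembershipFit:
    """Maximum-likelihood multinomial logit of class membership on baseline predictors.

    Raises on an empty outcome class; non-convergence (e.g. separation) is
    flagged on the returned fit rather than raised.
    """
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)
    scales = dict(DEFAULT_SCALES) if scales is None else dict(scales)
    classes = sorted(data[class_col].astype(str).unique())
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} absent from data")
    counts = data[class_col].value_counts()
    if (counts == 0).any() or len(classes) < 2:
        raise ValueError("every outcome class must be nonempty")
    # statsmodels MNLogit takes the first category code as reference
    ordered = [reference] + [c for c in classes if c != reference]
    y = pd.Categorical(data[class_col].astype(str), categories=ordered).codes
    X = sm.add_constant(data[predictors].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=0)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            fit = sm.MNLogit(y, X).fit_regularized(alpha=1e-8, disp=0)
            converged = False

    coef = pd.DataFrame(fit.params.values, index=X.columns, columns=ordered[1:])
    se = pd.DataFrame(fit.bse.values, index=X.columns, columns=ordered[1:])
    rows = []
    for cls in ordered[1:]:
        for pred in predictors:
            b, s = float(coef.loc[pred, cls]), float(se.loc[pred, cls])
            scale = float(scales.get(pred, 1.0))
            or_, lo, hi = rescale_or(b, s, scale)
            rows.append(
                {
                    "outcome_class": cls,
                    "predictor": pred,
                    "scale": scale,
                    "or": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": float(2.0 * stats.norm.sf(abs(b / s))) if s > 0 else np.nan,
                }
            )
    return MembershipFit(
        or_table=pd.DataFrame(rows),
        coef=coef,
        se=se,
        converged=converged,
        classes=ordered,
        model=fit,
    )


def predicted_probabilities(fit: MembershipFit, data: pd.DataFrame, predictors=None) -> pd.DataFrame:
    """Per-subject class-membership probabilities (rows sum to 1)."""
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)
    X = sm.add_constant(data[predictors].astype(float), has_constant="add")
    probs = fit.model.predict(X)
    return pd.DataFrame(np.asarray(probs), columns=fit.classes, index=data.index)
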