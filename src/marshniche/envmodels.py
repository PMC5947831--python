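"""Linear models comparing environmental conditions across marsh age classes.

Ordinary least squares with treatment (reference-level) coding: natural
marshes (NAT) and Essex are the reference levels, so coefficients read as
contrasts of restored marshes (MR, AR) against natural ones.  Quadrats are
pooled (no site-level random effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from marshniche.survey import SurveyDataset

REFERENCE_AGE = "NAT"
REFERENCE_REGION = "Essex"


@dataclass
class LinearModelResult:
    """OLS coefficient table for one environmental response.

    ``coefficients`` maps term name to ``(estimate, se, t, p)``; aliased
    (rank-deficient) terms are listed in ``aliased`` rather than silently
    dropped.
    """

    response: str
    coefficients: dict[str, tuple[float, float, float, float]]
    residual_df: int
    reference_levels: dict[str, str]
    aliased: list[str]
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, *v) for k, v in self.coefficients.items()],
            columns=["term", "estimate", "se", "t", "p"],
        )


def _fit_ols(df: pd.DataFrame, formula: str, response: str) -> LinearModelResult:
    model = smf.ols(formula, data=df)
    res = model.fit()
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    aliased: list[str] = []
    if rank < exog.shape[1]:
        # identify columns linearly dependent on the preceding ones
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : j + 1]) == np.linalg.matrix_rank(exog[:, :j]):
                aliased.append(model.exog_names[j])
    coefs = {
        name: (float(res.params[name]), float(res.bse[name]),
               float(res.tvalues[name]), float(res.pvalues[name]))
        for name in res.params.index
        if name not in aliased
    }
    return LinearModelResult(
        response=response,
        coefficients=coefs,
        residual_df=int(res.df_resid),
        reference_levels={"age_class": REFERENCE_AGE, "region": REFERENCE_REGION},
        aliased=aliased,
        r_squared=float(res.rsquared),
    )


def fit_env_by_age(dataset: SurveyDataset, response: str) -> LinearModelResult:
    """OLS of RTH or redox on marsh age class and region.

    Coefficients for MR and AR are contrasts against natural marshes, with
    two-sided p-values from the t distribution on the residual df.
    """
    if response not in ("rth", "redox"):
        raise ValueError("response must be 'rth' or 'redox'")
    df = dataset.quadrats
    if df["age_class"].nunique() < 2:
        raise ValueError("need at least 2 age classes")
    formula = (
        f"{response} ~ C(age_class, Treatment('{REFERENCE_AGE}'))"
        f" + C(region, Treatment('{REFERENCE_REGION}'))"
    )
    return _fit_ols(df, formula, response)


def fit_redox_rth_interaction(dataset: SurveyDataset) -> LinearModelResult:
    """OLS of redox on RTH x marsh age (plus region).

    The RTH main effect is the natural-marsh redox-RTH slope (mV per RTH
    unit); the interaction contrasts test whether that slope steepens or
    flattens on restored marshes.
    """
    df = dataset.quadrats
    if df["age_class"].nunique() < 2:
        raise ValueError("need at least 2 age classes")
    formula = (
        f"redox ~ rth * C(age_class, Treatment('{REFERENCE_AGE}'))"
        f" + C(region, Treatment('{REFERENCE_REGION}'))"
    )
    return _fit_ols(df, formula, "redox")
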