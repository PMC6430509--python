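"""Environmental detrending of yield: OLS on scaled, centered predictors.

Yield (t/ha) is regressed on the four soil ilr balances, pH and the three
weather indices, all standardized to mean 0 / sd 1, so slopes are comparable
in t/ha per standard deviation. The residuals — *residual yield*, the part of
yield the environment does not explain — are the response for the downstream
microbiome screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConstantPredictorError, SingularDesignError

__all__ = [
    "DEFAULT_PREDICTORS",
    "standardize",
    "fit_yield_model",
    "significant_predictors",
    "YieldModelResult",
]

#: Predictor set for the yield model: the four soil balances plus pH and the
#: three weather indices.
DEFAULT_PREDICTORS = (
    "[Clay, Silt, Sand | N, C]",
    "[Clay | Silt, Sand]",
    "[Silt | Sand]",
    "[N | C]",
    "pH",
    "PPT",
    "SDI",
    "GDD",
)


def standardize(raw: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample sd 1 (n-1 denominator)."""
    sd = raw.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise ConstantPredictorError(f"constant or degenerate predictor columns: {bad}")
    return (raw - raw.mean()) / sd


@dataclass(frozen=True)
class YieldModelResult:
    """OLS fit of yield on standardized predictors.

    coefficients are in t/ha per predictor standard deviation; residuals are
    the per-sample residual yield in t/ha.
    """

    intercept: float
    coefficients: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    residuals: pd.Series
    fitted: pd.Series
    r_squared: float

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: slope, 95% CI bounds and two-sided p per predictor."""
        return pd.DataFrame(
            {
                "slope": self.coefficients,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
            }
        ).rename_axis("predictor")


def fit_yield_model(X: pd.DataFrame, y: pd.Series, alpha: float = 0.05) -> YieldModelResult:
    """Fit yield ~ standardized predictors by OLS with t-based (1-alpha) CIs.

    ``X`` must already be standardized (see :func:`standardize`); sample order
    of ``X`` and ``y`` must agree.
    """
    if not X.index.equals(y.index):
        raise ValueError("X and y sample ids differ or are ordered differently")
    if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y.to_numpy(dtype=float))):
        raise ValueError("non-finite values in design or response")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularDesignError("rank-deficient design matrix")
    fit = sm.OLS(y.astype(float), design).fit()
    ci = fit.conf_int(alpha=alpha)
    return YieldModelResult(
        intercept=float(fit.params["const"]),
        coefficients=fit.params.drop("const"),
        ci_low=ci[0].drop("const"),
        ci_high=ci[1].drop("const"),
        pvalues=fit.pvalues.drop("const"),
        residuals=pd.Series(fit.resid, index=y.index, name="residual_yield"),
        fitted=pd.Series(fit.fittedvalues, index=y.index, name="fitted_yield"),
        r_squared=float(fit.rsquared),
    )


def significant_predictors(model: YieldModelResult, alpha: float = 0.05) -> pd.DataFrame:
    """Predictors with two-sided p < alpha, with the slope sign attached."""
    keep = model.pvalues < alpha
    out = pd.DataFrame(
        {
            "slope": model.coefficients[keep],
            "p": model.pvalues[keep],
            "sign": np.where(model.coefficients[keep] > 0, "+", "-"),
        }
    ).rename_axis("predictor")
    return out
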