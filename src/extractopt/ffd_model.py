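"""OLS fitting of the factorial model with inference and fit diagnostics.

The response surface is the first-order-with-interactions model

    y = b0 + b1*X1 + b2*X2 + b3*X3 + b12*X1X2 + b13*X1X3 + b23*X2X3
        + b123*X1X2X3

on coded factors.  Coefficients come from ordinary least squares; per-term
standard errors use MSE * diag((X'X)^-1) and two-sided t tests on the
residual degrees of freedom (n - 8 = 19 for the full 27-run design).

Diagnostics follow the conventions of response-surface software:

* ``pred_r2`` via the leave-one-out PRESS statistic computed with the
  leverage shortcut PRESS = sum( (e_i / (1 - h_ii))^2 ) — exact for OLS,
  no refitting loop;
* ``adequate_precision`` = (max fitted - min fitted) / sqrt(p * MSE / n),
  a signal-to-noise ratio for which values above 4 indicate a model usable
  for navigating the design space;
* prediction intervals are for a new single observation,
  fit +/- t_{0.975, df} * sqrt(MSE + SE_fit^2).

No data transformation is applied to responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignPoint, ModelMatrix
from .dataset import ResponseTable

__all__ = [
    "SingularDesignError",
    "FitResult",
    "FitStatistics",
    "Prediction",
    "fit_ols",
    "fit_response",
    "fit_all",
    "term_pvalues",
    "significant_terms",
    "fit_statistics",
    "predict",
    "regression_equation",
    "residual_normality_data",
    "residual_table",
]

#: Below this predicted-R2 (and the usability floor on adequate precision)
#: a response model is flagged inadequate and excluded from optimization.
ADEQUATE_PRECISION_FLOOR = 4.0


class SingularDesignError(ValueError):
    """The model matrix is rank deficient."""


@dataclass
class FitResult:
    """An OLS fit of the factorial model to one response."""

    response_name: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    coefficient_se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    residuals: np.ndarray
    fitted: np.ndarray
    y: np.ndarray
    mse: float
    df_residual: int
    xtx_inverse: np.ndarray
    leverages: np.ndarray
    matrix: ModelMatrix

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    @property
    def sse(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def sst(self) -> float:
        y = self.y
        return float(((y - y.mean()) ** 2).sum())


@dataclass(frozen=True)
class FitStatistics:
    """Model-adequacy summary for one fitted response."""

    std_dev: float
    mean: float
    cv_pct: float
    r2: float
    adj_r2: float
    press: float
    pred_r2: float
    adequate_precision: float

    @property
    def is_adequate(self) -> bool:
        """Usability flag: negative predicted R2 or a signal-to-noise ratio
        below 4 marks the model as unsuitable for optimization."""
        return self.pred_r2 >= 0 and self.adequate_precision > ADEQUATE_PRECISION_FLOOR


@dataclass(frozen=True)
class Prediction:
    """A model prediction with its standard error and 95% prediction interval
    for a new single observation."""

    fit: float
    se_fit: float
    pi95_low: float
    pi95_high: float
    extrapolated: bool = False


def fit_ols(matrix: ModelMatrix, y: np.ndarray, response_name: str = "y") -> FitResult:
    """Least-squares fit of the named response on the model matrix."""
    y = np.asarray(y, dtype=float)
    X = matrix.values
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} runs to fit {p} terms with error df, got {n}")
    if np.linalg.matrix_rank(X, tol=1e-10 * np.linalg.norm(X)) < p:
        raise SingularDesignError("model matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    influence = res.get_influence()
    terms = matrix.terms
    return FitResult(
        response_name=response_name,
        terms=terms,
        coefficients=dict(zip(terms, res.params)),
        coefficient_se=dict(zip(terms, res.bse)),
        t_values=dict(zip(terms, res.tvalues)),
        p_values=dict(zip(terms, res.pvalues)),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        y=y,
        mse=float(res.mse_resid),
        df_residual=int(res.df_resid),
        xtx_inverse=np.asarray(res.normalized_cov_params),
        leverages=np.asarray(influence.hat_matrix_diag),
        matrix=matrix,
    )


def fit_response(table: ResponseTable, response: str) -> FitResult:
    """Fit the factorial model to one response column of a run table."""
    return fit_ols(table.model_matrix(), table.response(response), response)


def fit_all(table: ResponseTable, responses: Sequence[str] | None = None) -> dict[str, FitResult]:
    names = list(responses) if responses is not None else list(table.response_names)
    return {r: fit_response(table, r) for r in names}


def term_pvalues(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term two-sided p-values (t^2 = F with (1, df_residual)) and the
    significance flag at the given level."""
    rows = []
    for t in fit.terms:
        rows.append(
            {
                "term": t,
                "coefficient": fit.coefficients[t],
                "se": fit.coefficient_se[t],
                "t": fit.t_values[t],
                "p_value": fit.p_values[t],
                "significant": fit.p_values[t] < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def significant_terms(fit: FitResult, alpha: float = 0.05) -> tuple[str, ...]:
    return tuple(t for t in fit.terms if t != "intercept" and fit.p_values[t] < alpha)


def fit_statistics(fit: FitResult) -> FitStatistics:
    """R2, adjusted/predicted R2, PRESS, CV% and adequate precision."""
    n = len(fit.y)
    p = len(fit.terms)
    sse = fit.sse
    sst = fit.sst
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    h = fit.leverages
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a leverage of 1 makes PRESS undefined")
    press = float(((fit.residuals / (1.0 - h)) ** 2).sum())
    pred_r2 = 1.0 - press / sst
    std_dev = float(np.sqrt(fit.mse))
    mean = float(fit.y.mean())
    ap = float((fit.fitted.max() - fit.fitted.min()) / np.sqrt(p * fit.mse / n))
    return FitStatistics(
        std_dev=std_dev,
        mean=mean,
        cv_pct=100.0 * std_dev / mean,
        r2=r2,
        adj_r2=adj_r2,
        press=press,
        pred_r2=pred_r2,
        adequate_precision=ap,
    )


def _row_for_point(fit: FitResult, point: DesignPoint) -> np.ndarray:
    from .design import model_matrix as _mm

    return _mm([point], fit.matrix.factor_names).values[0]


def predict(fit: FitResult, point: DesignPoint) -> Prediction:
    """Predict the response at a design point, with SE of the fit and the 95%
    prediction interval for a new observation.

    Points outside the factor cube are allowed; the result is flagged as an
    extrapolation.
    """
    x = _row_for_point(fit, point)
    fit_value = float(x @ fit.coef_vector)
    se_fit = float(np.sqrt(x @ fit.xtx_inverse @ x * fit.mse))
    t_crit = stats.t.ppf(0.975, fit.df_residual)
    half = t_crit * np.sqrt(fit.mse + se_fit**2)
    return Prediction(
        fit=fit_value,
        se_fit=se_fit,
        pi95_low=fit_value - half,
        pi95_high=fit_value + half,
        extrapolated=point.is_extrapolation,
    )


def regression_equation(fit: FitResult, decimals: int = 2) -> str:
    """The fitted equation as a human-readable string in coded variables."""
    parts = [f"{fit.coefficients['intercept']:+.{decimals}f}"]
    for t in fit.terms:
        if t == "intercept":
            continue
        parts.append(f"{fit.coefficients[t]:+.{decimals}f} {t}")
    return f"{fit.response_name} = " + " ".join(parts)


def residual_normality_data(fit: FitResult) -> pd.DataFrame:
    """Sorted residuals against standard-normal quantiles (QQ-plot data)."""
    r = np.sort(fit.residuals)
    n = len(r)
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)  # Blom plotting positions
    return pd.DataFrame({"normal_quantile": stats.norm.ppf(probs), "residual": r})


def residual_table(fit: FitResult) -> pd.DataFrame:
    """Observed, fitted, residual and leverage per run (flat CSV export)."""
    return pd.DataFrame(
        {
            "run": np.arange(1, len(fit.y) + 1),
            "observed": fit.y,
            "fitted": fit.fitted,
            "residual": fit.residuals,
            "leverage": fit.leverages,
        }
    )


def fit_report(fit: FitResult) -> dict:
    """JSON-serializable fit summary: coefficients, inference, diagnostics."""
    stats_ = fit_statistics(fit)
    return {
        "response": fit.response_name,
        "equation": regression_equation(fit),
        "coefficients": fit.coefficients,
        "se": fit.coefficient_se,
        "p_values": fit.p_values,
        "fit_statistics": {
            "std_dev": stats_.std_dev,
            "mean": stats_.mean,
            "cv_pct": stats_.cv_pct,
            "r2": stats_.r2,
            "adj_r2": stats_.adj_r2,
            "press": stats_.press,
            "pred_r2": stats_.pred_r2,
            "adequate_precision": stats_.adequate_precision,
            "is_adequate": stats_.is_adequate,
        },
    }
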