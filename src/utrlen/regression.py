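"""Multiple linear regression of log10 5'UTR length on composition features.

The model is

    Y = b0 + b1*X1 + ... + bp*Xp + eps,

with Y the log10 UTR length and X the candidate features.  Around the plain
OLS fit this module provides the three statistics used to interrogate it:

* **backward elimination** — iteratively drops the predictor with the
  largest t-test p-value while that p-value exceeds alpha;
* **VIF** (variance inflation factor) — 1/(1-R^2_j) from regressing each
  predictor on all the others; values above 10 indicate collinearity strong
  enough to make per-feature effects uninterpretable;
* **RCVE** (relative contribution to variability explained) —
  (R^2_full - R^2_reduced,j) / R^2_full, the fractional drop in unadjusted
  R^2 when predictor j is removed and the model refit on the same rows;
* **partial correlation** — correlation between response and one predictor
  after the linear effects of the remaining predictors are removed from
  both; identical to t/sqrt(t^2 + df) from the full-model t-statistic.

Fits go through statsmodels OLS (orthogonal-decomposition based); the raw
normal-equations solver exists only in the test-suite as an independent
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import PREDICTORS, RESPONSE

VIF_FLAG_THRESHOLD = 10.0


@dataclass
class RegressionResult:
    """One fitted OLS model (intercept first in all coefficient arrays)."""

    predictor_names: list[str]          # without the intercept
    coefficients: np.ndarray            # [intercept, b1..bp]
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    r2: float
    adjusted_r2: float
    residuals: np.ndarray
    n_obs: int
    df_resid: int

    @property
    def coef(self) -> pd.Series:
        return pd.Series(
            self.coefficients, index=["intercept"] + self.predictor_names
        )

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.p_values, index=["intercept"] + self.predictor_names)


@dataclass
class SelectionStep:
    removed: str
    p_value: float
    r2_after: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_predictors: list[str] = field(default_factory=list)
    alpha: float = 0.05


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    X = table[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(table)), X])


def _check_rank(design: np.ndarray, predictors: Sequence[str]) -> None:
    # QR diagnostics: a near-zero diagonal of R names the collinear columns
    r_diag = np.abs(np.diag(np.linalg.qr(design, mode="r")))
    tol = design.shape[0] * np.finfo(float).eps * max(r_diag.max(), 1.0)
    bad = np.flatnonzero(r_diag < tol)
    if bad.size:
        names = ["intercept"] + list(predictors)
        raise ValueError(
            "rank-deficient design; near-collinear columns: "
            + ", ".join(names[i] for i in bad)
        )


def fit_ols(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(PREDICTORS),
    response: str = RESPONSE,
) -> RegressionResult:
    """Ordinary least squares of ``response`` on ``predictors`` + intercept.

    An empty predictor list yields the intercept-only model (R^2 = 0).
    Raises ``ValueError`` for too few observations or a rank-deficient
    design (naming the collinear columns).
    """
    predictors = list(predictors)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need n > p + 1 observations (n={n}, p={len(predictors)})"
        )
    y = table[response].to_numpy(dtype=float)
    X = _design(table, predictors)
    _check_rank(X, predictors)
    # constant responses make statsmodels' R^2 a harmless 0/0 (evaluated
    # lazily, hence the wide errstate); callers that need R^2 (rcve) reject
    # the resulting NaN explicitly
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sm.OLS(y, X).fit()
        return RegressionResult(
            predictor_names=predictors,
            coefficients=np.asarray(fit.params),
            standard_errors=np.asarray(fit.bse),
            t_statistics=np.asarray(fit.tvalues),
            p_values=np.asarray(fit.pvalues),
            r2=float(fit.rsquared) if predictors else 0.0,
            adjusted_r2=float(fit.rsquared_adj) if predictors else 0.0,
            residuals=np.asarray(fit.resid),
            n_obs=n,
            df_resid=int(fit.df_resid),
        )


def _aic(result: RegressionResult) -> float:
    rss = float(result.residuals @ result.residuals)
    n = result.n_obs
    k = n - result.df_resid  # fitted parameters incl. intercept
    return n * np.log(rss / n) + 2 * k


def backward_select(
    table: pd.DataFrame,
    candidates: Sequence[str] = tuple(PREDICTORS),
    alpha: float = 0.05,
    response: str = RESPONSE,
    criterion: str = "pvalue",
) -> tuple[RegressionResult, SelectionTrace]:
    """Backward elimination on per-coefficient t-test p-values.

    While the largest p-value among the current (non-intercept) predictors
    exceeds ``alpha``, that single predictor is dropped and the model refit;
    the intercept is never removed.  Every removal is recorded in the trace.

    ``criterion="aic"`` switches to AIC-based elimination: the predictor
    whose removal lowers AIC the most is dropped while any removal lowers
    it (``alpha`` is then ignored; recorded step p-values still come from
    the t-tests, for the report).
    """
    if criterion not in ("pvalue", "aic"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    current = list(candidates)
    trace = SelectionTrace(alpha=alpha)
    result = fit_ols(table, current, response)
    while current:
        pvals = result.p_values[1:]  # skip intercept
        if criterion == "pvalue":
            worst = int(np.nanargmax(pvals))
            if not (pvals[worst] > alpha):
                break
        else:
            fits = [
                fit_ols(table, current[:j] + current[j + 1 :], response)
                for j in range(len(current))
            ]
            aics = [_aic(f) for f in fits]
            worst = int(np.argmin(aics))
            if aics[worst] >= _aic(result):
                break
        removed = current.pop(worst)
        p_at_removal = float(pvals[worst])
        result = fit_ols(table, current, response)
        trace.steps.append(SelectionStep(removed, p_at_removal, result.r2))
    trace.final_predictors = list(current)
    return result, trace


def vif(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(PREDICTORS),
) -> pd.DataFrame:
    """Variance inflation factors, with a flag for values above 10.

    Computed as the diagonal of the inverse predictor correlation matrix,
    which equals 1/(1-R^2_j) from regressing predictor j on all the others
    with an intercept.  Perfect collinearity yields infinite VIF (flagged)
    rather than an exception.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = table[predictors].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"zero-variance predictors: {bad}")
    R = np.corrcoef(X, rowvar=False)
    try:
        values = np.diag(np.linalg.inv(R)).copy()
        if np.any(values < 0.5):  # numerically meaningless inverse
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # singular correlation matrix: fall back to per-predictor fits
        values = np.empty(len(predictors))
        for j in range(len(predictors)):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(len(X)), others])
            resid = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
            sst = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            r2_j = 1.0 - resid @ resid / sst
            values[j] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    values = np.maximum(values, 1.0)  # VIF >= 1 up to rounding
    return pd.DataFrame(
        {"vif": values, "flagged": values > VIF_FLAG_THRESHOLD},
        index=pd.Index(predictors, name="predictor"),
    )


def rcve(
    table: pd.DataFrame,
    full_predictors: Sequence[str] = tuple(PREDICTORS),
    response: str = RESPONSE,
    use_adjusted: bool = False,
) -> pd.Series:
    """Relative contribution to variability explained, per predictor.

    RCVE_j = (R2_full - R2_reduced_without_j) / R2_full, both models fit on
    the same rows.  Unadjusted R^2 by default; ``use_adjusted=True`` is a
    sensitivity variant (values may then be negative).
    """
    full_predictors = list(full_predictors)
    full = fit_ols(table, full_predictors, response)
    r2_full = full.adjusted_r2 if use_adjusted else full.r2
    if not full.r2 > 0.0:  # catches 0 and the constant-response NaN
        raise ValueError("RCVE undefined: full-model R^2 is 0")
    out = {}
    for j, name in enumerate(full_predictors):
        reduced_predictors = full_predictors[:j] + full_predictors[j + 1 :]
        reduced = fit_ols(table, reduced_predictors, response)
        r2_red = reduced.adjusted_r2 if use_adjusted else reduced.r2
        if not use_adjusted and r2_red > full.r2 + 1e-10:
            raise AssertionError(
                f"nested-model monotonicity violated for {name}: "
                f"{r2_red} > {full.r2}"
            )
        out[name] = (r2_full - r2_red) / r2_full
    return pd.Series(out, name="rcve")


def _residualize(y: np.ndarray, A: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ beta


def partial_correlation(
    table: pd.DataFrame,
    target_predictor: str,
    others: Sequence[str],
    response: str = RESPONSE,
) -> float:
    """Partial correlation of response and one predictor given the others.

    Residual method: both response and target are regressed on the other
    predictors (plus intercept) and the two residual vectors correlated.
    Equals t/sqrt(t^2 + df) from the full-model t-statistic.
    """
    others = list(others)
    y = table[response].to_numpy(dtype=float)
    x = table[target_predictor].to_numpy(dtype=float)
    A = _design(table, others)
    ry = _residualize(y, A)
    rx = _residualize(x, A)
    # residual variance at rounding level of the inputs counts as zero
    if not (ry.std() > 1e-10 * y.std() and rx.std() > 1e-10 * x.std()):
        raise ValueError("degenerate residuals (zero variance)")
    return float(np.corrcoef(ry, rx)[0, 1])


def partial_correlations(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(PREDICTORS),
    response: str = RESPONSE,
) -> pd.Series:
    """Partial correlation of every predictor given all the others."""
    predictors = list(predictors)
    out = {}
    for j, name in enumerate(predictors):
        others = predictors[:j] + predictors[j + 1 :]
        out[name] = partial_correlation(table, name, others, response)
    return pd.Series(out, name="partial_correlation")


def importance_report(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(PREDICTORS),
    response: str = RESPONSE,
) -> pd.DataFrame:
    """Joint per-predictor report: coefficient, p, VIF, RCVE, partial r."""
    predictors = list(predictors)
    full = fit_ols(table, predictors, response)
    report = pd.DataFrame(
        {
            "coefficient": full.coefficients[1:],
            "p_value": full.p_values[1:],
        },
        index=pd.Index(predictors, name="predictor"),
    )
    report["vif"] = vif(table, predictors)["vif"]
    report["rcve"] = rcve(table, predictors, response)
    report["partial_correlation"] = partial_correlations(
        table, predictors, response
    )
    return report
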