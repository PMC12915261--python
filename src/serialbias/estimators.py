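"""Central-tendency and serial-dependence estimators.

Two families of estimators are implemented for log-scale reproduction
errors e_t = r_t - s_t:

* Simple linear regressions (SLR): central tendency as the slope of
  e_t on s_t, and serial dependence as the slope of e_t on s_{t-1}.
  These are the naive estimators; when the stimulus sequence is
  autocorrelated, the serial-dependence slope absorbs central tendency
  leaking through the stimulus chain and turns spuriously repulsive.

* The multiple linear regression (MLR) derived from the causal graph of
  the task via the single-door criterion:

      e_t = b0 + CT * s_t + SD1 * s_{t-1} + b1 * e_{t-1} + eps

  whose partial coefficients CT and SD1 identify the direct effects
  under the assumed graph, in both autocorrelation conditions.

A lag-2 variant (regressors s_{t-2}, s_{t-1}, e_{t-1}) checks the graph's
implication that e_t is conditionally independent of s_{t-2} given the
lag-1 variables: its s_{t-2} coefficient should be indistinguishable
from zero.

All fits run ordinary least squares on lagged design rows built from
consecutive valid trials of a single condition.  OLS is solved by
singular-value decomposition with an explicit rank check, since under
high autocorrelation s_t and s_{t-1} are nearly collinear and silent
instability would be worse than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import CollinearityError, DegenerateInputError, InsufficientDataError
from .trials import validate_trial_table

__all__ = [
    "BiasEstimate",
    "PartialRegression",
    "build_design",
    "fit_slr_ct",
    "fit_slr_sd",
    "fit_mlr",
    "fit_lag2_check",
    "partial_regression",
    "estimate_table",
]

#: Relative tolerance below which a singular value marks rank deficiency.
RANK_RTOL = 1e-10

_MLR_REGRESSORS = ["s_t", "s_prev", "e_prev"]
_LAG2_REGRESSORS = ["s_prev2", "s_prev", "e_prev"]


@dataclass(frozen=True)
class BiasEstimate:
    """A fitted bias estimate.

    Attributes
    ----------
    method : str
        ``"SLR"``, ``"MLR"`` or ``"MLR_lag2"``.
    ct : float or None
        Central-tendency slope (coefficient of s_t).  -1 means complete
        regression to the mean, 0 none, positive values anti-central
        tendency.
    sd1 : float or None
        Lag-1 serial-dependence slope (coefficient of s_{t-1}); positive
        is attractive, negative repulsive.
    intercept : float
    error_lag_coef : float or None
        Coefficient of e_{t-1} (MLR and lag-2 models).
    lag2_coef, lag2_se, lag2_p : float or None
        Coefficient of s_{t-2} with standard error and two-sided p-value
        (lag-2 model only).
    n_used : int
        Number of design rows entering the fit.
    r_squared : float
        Coefficient of determination, in [0, 1].
    """

    method: str
    ct: float | None
    sd1: float | None
    intercept: float
    error_lag_coef: float | None
    n_used: int
    r_squared: float
    lag2_coef: float | None = None
    lag2_se: float | None = None
    lag2_p: float | None = None


@dataclass(frozen=True)
class PartialRegression:
    """Added-variable (partial regression) values for one MLR regressor."""

    focal: str
    x_resid: np.ndarray
    y_resid: np.ndarray
    slope: float


def _single_condition(table: pd.DataFrame) -> pd.DataFrame:
    validate_trial_table(table)
    if table["condition"].nunique() != 1:
        raise ValueError(
            "fit operates on a single condition; split the table "
            "(e.g. with estimate_table) first"
        )
    return table


def build_design(table: pd.DataFrame, include_lag2: bool = False) -> pd.DataFrame:
    """Materialize lagged design rows from a trial table.

    One row is produced per trial whose own and required lagged trials are
    all valid and physically consecutive (trial indices differing by one).
    Trials adjacent to an excluded trial therefore contribute no row, and
    rows never span a condition boundary.

    Parameters
    ----------
    table : pandas.DataFrame
        Trial table (may contain several conditions).
    include_lag2 : bool
        Also require and include the twice-lagged stimulus ``s_prev2``.

    Returns
    -------
    pandas.DataFrame
        Columns ``condition, trial, e_t, s_t, s_prev, e_prev`` plus
        ``s_prev2`` when requested.
    """
    validate_trial_table(table)
    parts = []
    for cond, group in table.groupby("condition", sort=False):
        group = group.sort_values("trial")
        t = group["trial"].to_numpy()
        v = group["valid"].to_numpy(dtype=bool)
        s = group["stimulus_log"].to_numpy()
        e = group["error_log"].to_numpy()
        if len(group) < 3:
            continue
        step = np.diff(t) == 1
        if include_lag2:
            mask = v[2:] & v[1:-1] & v[:-2] & step[1:] & step[:-1]
            rows = pd.DataFrame(
                {
                    "condition": cond,
                    "trial": t[2:][mask],
                    "e_t": e[2:][mask],
                    "s_t": s[2:][mask],
                    "s_prev": s[1:-1][mask],
                    "e_prev": e[1:-1][mask],
                    "s_prev2": s[:-2][mask],
                }
            )
        else:
            mask = v[1:] & v[:-1] & step
            rows = pd.DataFrame(
                {
                    "condition": cond,
                    "trial": t[1:][mask],
                    "e_t": e[1:][mask],
                    "s_t": s[1:][mask],
                    "s_prev": s[:-1][mask],
                    "e_prev": e[:-1][mask],
                }
            )
        parts.append(rows)
    if not parts:
        raise InsufficientDataError("no usable design rows (need >= 3 trials)")
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class _OlsFit:
    coef: np.ndarray       # intercept first
    se: np.ndarray
    pvalues: np.ndarray
    n: int
    r_squared: float


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> _OlsFit:
    """OLS with intercept via SVD, with a rank check at RANK_RTOL.

    On rank deficiency the offending columns are located with a pivoted QR
    factorization and reported by name.
    """
    y = np.asarray(y, dtype=float)
    X1 = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    n, p = X1.shape
    if n < p + 1:
        raise InsufficientDataError(f"need at least {p + 1} rows for {p - 1} regressors, got {n}")
    u, sv, vt = np.linalg.svd(X1, full_matrices=False)
    if sv[-1] <= sv[0] * RANK_RTOL:
        rank = int(np.sum(sv > sv[0] * RANK_RTOL))
        _, _, piv = sla.qr(X1, mode="economic", pivoting=True)
        all_names = ["intercept"] + list(names)
        offending = sorted(all_names[j] for j in piv[rank:])
        raise CollinearityError(offending)
    coef = vt.T @ ((u.T @ y) / sv)
    resid = y - X1 @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    r_squared = min(max(r_squared, 0.0), 1.0)
    df = n - p
    sigma2 = rss / df if df > 0 else np.nan
    cov = (vt.T * sv**-2) @ vt * sigma2
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvalues = 2.0 * stats.t.sf(np.abs(tvals), df)
    return _OlsFit(coef=coef, se=se, pvalues=pvalues, n=n, r_squared=r_squared)


def fit_slr_ct(table: pd.DataFrame) -> BiasEstimate:
    """Naive central tendency: OLS slope of e_t on s_t over all valid trials."""
    table = _single_condition(table)
    rows = table[table["valid"]]
    if len(rows) < 3:
        raise InsufficientDataError("need >= 3 valid trials")
    s = rows["stimulus_log"].to_numpy()
    if np.ptp(s) == 0:
        raise DegenerateInputError("stimulus has zero variance")
    fit = _ols(rows["error_log"].to_numpy(), s[:, None], ["s_t"])
    return BiasEstimate(
        method="SLR",
        ct=float(fit.coef[1]),
        sd1=None,
        intercept=float(fit.coef[0]),
        error_lag_coef=None,
        n_used=fit.n,
        r_squared=fit.r_squared,
    )


def fit_slr_sd(table: pd.DataFrame) -> BiasEstimate:
    """Naive serial dependence: OLS slope of e_t on the previous stimulus s_{t-1}."""
    table = _single_condition(table)
    design = build_design(table)
    s_prev = design["s_prev"].to_numpy()
    if np.ptp(s_prev) == 0:
        raise DegenerateInputError("previous stimulus has zero variance")
    fit = _ols(design["e_t"].to_numpy(), s_prev[:, None], ["s_prev"])
    return BiasEstimate(
        method="SLR",
        ct=None,
        sd1=float(fit.coef[1]),
        intercept=float(fit.coef[0]),
        error_lag_coef=None,
        n_used=fit.n,
        r_squared=fit.r_squared,
    )


def fit_mlr(table: pd.DataFrame) -> BiasEstimate:
    """Adjusted estimator: e_t regressed on s_t, s_{t-1} and e_{t-1}.

    The regressor sets follow from the single-door criterion on the task's
    causal graph: {s_{t-1}} suffices for CT, {s_t, e_{t-1}} for SD1, and the
    union identifies both in one model.  ``ct`` and ``sd1`` are the partial
    coefficients of s_t and s_{t-1}.
    """
    table = _single_condition(table)
    design = build_design(table)
    if len(design) < 5:
        raise InsufficientDataError("need >= 5 usable design rows for the MLR")
    X = design[_MLR_REGRESSORS].to_numpy()
    fit = _ols(design["e_t"].to_numpy(), X, _MLR_REGRESSORS)
    return BiasEstimate(
        method="MLR",
        ct=float(fit.coef[1]),
        sd1=float(fit.coef[2]),
        intercept=float(fit.coef[0]),
        error_lag_coef=float(fit.coef[3]),
        n_used=fit.n,
        r_squared=fit.r_squared,
    )


def fit_lag2_check(table: pd.DataFrame) -> BiasEstimate:
    """Conditional-independence check: does s_{t-2} predict e_t beyond lag 1?

    Fits e_t = b0 + b1*s_{t-2} + b2*s_{t-1} + b3*e_{t-1} + eps.  Under the
    assumed causal graph, e_t is conditionally independent of s_{t-2} given
    s_{t-1} and e_{t-1}, so b1 should be statistically indistinguishable
    from zero; ``lag2_coef``/``lag2_se``/``lag2_p`` report the evidence.
    """
    table = _single_condition(table)
    design = build_design(table, include_lag2=True)
    if len(design) < 5:
        raise InsufficientDataError("need >= 5 usable design rows for the lag-2 model")
    X = design[_LAG2_REGRESSORS].to_numpy()
    fit = _ols(design["e_t"].to_numpy(), X, _LAG2_REGRESSORS)
    return BiasEstimate(
        method="MLR_lag2",
        ct=None,
        sd1=float(fit.coef[2]),
        intercept=float(fit.coef[0]),
        error_lag_coef=float(fit.coef[3]),
        n_used=fit.n,
        r_squared=fit.r_squared,
        lag2_coef=float(fit.coef[1]),
        lag2_se=float(fit.se[1]),
        lag2_p=float(fit.pvalues[1]),
    )


def partial_regression(table: pd.DataFrame, focal: str) -> PartialRegression:
    """Added-variable values for one regressor of the MLR.

    Residualizes both the focal regressor and the response on the remaining
    regressors (each with an intercept); by the Frisch-Waugh-Lovell theorem
    the slope of ``y_resid`` on ``x_resid`` equals the focal coefficient of
    :func:`fit_mlr`.  The returned residual pairs are what an added-variable
    scatter plot displays.

    Parameters
    ----------
    table : pandas.DataFrame
    focal : str
        One of ``"s_t"`` (central tendency), ``"s_prev"`` (serial
        dependence) or ``"e_prev"``.
    """
    if focal not in _MLR_REGRESSORS:
        raise ValueError(f"focal must be one of {_MLR_REGRESSORS}")
    table = _single_condition(table)
    design = build_design(table)
    if len(design) < 5:
        raise InsufficientDataError("need >= 5 usable design rows")
    others = [r for r in _MLR_REGRESSORS if r != focal]
    Z = design[others].to_numpy()
    x = design[focal].to_numpy()
    y = design["e_t"].to_numpy()
    fx = _ols(x, Z, others)
    fy = _ols(y, Z, others)
    Z1 = np.column_stack([np.ones(len(x)), Z])
    x_resid = x - Z1 @ fx.coef
    y_resid = y - Z1 @ fy.coef
    slope_fit = _ols(y_resid, x_resid[:, None], [focal])
    return PartialRegression(
        focal=focal, x_resid=x_resid, y_resid=y_resid, slope=float(slope_fit.coef[1])
    )


def estimate_table(table: pd.DataFrame, method: str = "mlr") -> pd.DataFrame:
    """Fit the requested estimator per condition of a (possibly mixed) table.

    Parameters
    ----------
    table : pandas.DataFrame
    method : {"slr", "mlr", "lag2"}
        For ``"slr"`` the CT and SD1 slopes come from the two separate
        simple regressions; intercept, n_used and r_squared are reported
        from the CT fit.

    Returns
    -------
    pandas.DataFrame
        One row per condition with columns ``method, condition, ct, sd1,
        intercept, error_lag_coef, n_used, r_squared``.
    """
    validate_trial_table(table)
    method = method.lower()
    records = []
    for cond, group in table.groupby("condition", sort=False):
        if method == "slr":
            est_ct = fit_slr_ct(group)
            est_sd = fit_slr_sd(group)
            rec = {
                "method": "SLR",
                "condition": cond,
                "ct": est_ct.ct,
                "sd1": est_sd.sd1,
                "intercept": est_ct.intercept,
                "error_lag_coef": np.nan,
                "n_used": est_ct.n_used,
                "r_squared": est_ct.r_squared,
            }
        elif method == "mlr":
            est = fit_mlr(group)
            rec = {
                "method": "MLR",
                "condition": cond,
                "ct": est.ct,
                "sd1": est.sd1,
                "intercept": est.intercept,
                "error_lag_coef": est.error_lag_coef,
                "n_used": est.n_used,
                "r_squared": est.r_squared,
            }
        elif method == "lag2":
            est = fit_lag2_check(group)
            rec = {
                "method": "MLR_lag2",
                "condition": cond,
                "ct": np.nan,
                "sd1": est.sd1,
                "intercept": est.intercept,
                "error_lag_coef": est.error_lag_coef,
                "n_used": est.n_used,
                "r_squared": est.r_squared,
                "lag2_coef": est.lag2_coef,
                "lag2_p": est.lag2_p,
            }
        else:
            raise ValueError("method must be one of 'slr', 'mlr', 'lag2'")
        records.append(rec)
    return pd.DataFrame.from_records(records)
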