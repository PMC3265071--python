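"""Derivation of the model coefficients from summary-level tables.

Every shipped constant is an output of one of these fits:

* ``fit_loglinear_concentration`` — ordinary least squares of mean log free
  estradiol on median BMI across >= 3 BMI strata (the exclusion rule for
  source tables), giving a :class:`~estrorisk.models.LogLinearModel`.
* ``fit_ert_ratio`` — OLS of the per-stratum difference of user and non-user
  mean log concentrations on median BMI (the log of the user/non-user ratio).
* ``fit_rr_doubling_through_reference`` — a log-log line of relative risk on
  free estradiol constrained to pass through the reference quantile (RR = 1),
  returning the per-doubling risk 2**slope.
* ``compose_risk_model`` — closes the loop: concentration model x per-doubling
  transform -> closed-form RR-vs-BMI line referenced at RR(ref BMI) = 1.

Table interchange is headered CSV; in memory, pandas DataFrames with the
column schemas below.  Fits delegate to statsmodels OLS/WLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import (
    ComposedRiskModel,
    DoublingRiskModel,
    InvalidInputError,
    LogLinearModel,
    SaturationPolicy,
)

__all__ = [
    "CONCENTRATION_COLUMNS",
    "QUANTILE_COLUMNS",
    "InsufficientStrataError",
    "SingularFitError",
    "AlignmentError",
    "ReferenceRowError",
    "FitResult",
    "read_concentration_table",
    "read_quantile_risk_table",
    "validate_concentration_table",
    "validate_quantile_risk_table",
    "fit_loglinear_concentration",
    "fit_ert_ratio",
    "fit_rr_doubling_through_reference",
    "compose_risk_model",
]

#: CSV schema for concentration summary tables (open bounds are empty fields).
CONCENTRATION_COLUMNS = ["bmi_low", "bmi_high", "median_bmi", "mean_log_e2f", "n"]

#: CSV schema for quantile relative-risk tables.
QUANTILE_COLUMNS = ["e2f_mid_mol_per_L", "rr", "is_reference", "n_cases"]

MIN_STRATA = 3  # source tables with fewer BMI strata are excluded


class InsufficientStrataError(InvalidInputError):
    """Fewer BMI strata than the minimum of three."""


class SingularFitError(InvalidInputError):
    """The design is degenerate (e.g. identical median BMIs)."""


class AlignmentError(InvalidInputError):
    """Paired tables do not share the same BMI categories."""


class ReferenceRowError(InvalidInputError):
    """A quantile-risk table must contain exactly one reference row with RR = 1."""


@dataclass(frozen=True)
class FitResult:
    """Diagnostics of a least-squares fit.

    ``intercept`` is None for a through-reference fit (the line is constrained
    through the reference point, so only the slope is free).
    """

    slope: float
    intercept: Optional[float]
    rss: float
    n_points: int


def read_concentration_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_concentration_table(df)
    return df


def read_quantile_risk_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_quantile_risk_table(df)
    return df


def validate_concentration_table(table: pd.DataFrame) -> None:
    missing = [c for c in CONCENTRATION_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"concentration table missing columns {missing}")
    if len(table) < MIN_STRATA:
        raise InsufficientStrataError(
            f"need at least {MIN_STRATA} BMI strata, got {len(table)}"
        )
    med = table["median_bmi"].to_numpy(float)
    if np.unique(med).size != med.size:
        raise SingularFitError("median BMIs must be distinct")
    order = table.sort_values("median_bmi")
    low = order["bmi_low"].to_numpy(float)
    high = order["bmi_high"].to_numpy(float)
    med = order["median_bmi"].to_numpy(float)
    for i in range(len(order)):
        lo = low[i] if np.isfinite(low[i]) else -np.inf
        hi = high[i] if np.isfinite(high[i]) else np.inf
        if not lo <= med[i] <= hi:
            raise InvalidInputError(
                f"median BMI {med[i]} outside its category [{lo}, {hi}]"
            )
        if i and np.isfinite(high[i - 1]) and np.isfinite(low[i]) and low[i] < high[i - 1]:
            raise InvalidInputError("BMI categories overlap")


def validate_quantile_risk_table(table: pd.DataFrame) -> None:
    missing = [c for c in QUANTILE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"quantile-risk table missing columns {missing}")
    rr = table["rr"].to_numpy(float)
    if np.any(~np.isfinite(rr)) or np.any(rr <= 0):
        raise InvalidInputError("relative risks must be positive and finite")
    mid = table["e2f_mid_mol_per_L"].to_numpy(float)
    if np.any(np.diff(mid) <= 0):
        raise InvalidInputError("e2f midpoints must be strictly increasing")
    ref = table["is_reference"].astype(bool)
    if int(ref.sum()) != 1:
        raise ReferenceRowError(
            f"expected exactly one reference row, got {int(ref.sum())}"
        )
    if not math.isclose(float(table.loc[ref, "rr"].iloc[0]), 1.0, rel_tol=1e-9):
        raise ReferenceRowError("the reference row must have rr = 1")


def _wls(
    x: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray]
) -> Tuple[float, float, float]:
    """Weighted least squares of y on (1, x); returns slope, intercept, rss."""
    if np.ptp(x) == 0:
        raise SingularFitError("degenerate predictor: all x values identical")
    X = sm.add_constant(x)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    res = sm.WLS(y, X, weights=w).fit()
    fitted = res.predict(X)
    rss = float(np.sum(w * (y - fitted) ** 2))
    return float(res.params[1]), float(res.params[0]), rss


def fit_loglinear_concentration(
    table: pd.DataFrame,
    weight_by_n: bool = False,
    full_output: bool = False,
):
    """Least-squares line of mean log free estradiol on median BMI.

    Unweighted OLS by default; ``weight_by_n`` weights each stratum by its
    number of women (sensitivity analysis only).
    """
    validate_concentration_table(table)
    x = table["median_bmi"].to_numpy(float)
    y = table["mean_log_e2f"].to_numpy(float)
    w = table["n"].to_numpy(float) if weight_by_n else None
    slope, intercept, rss = _wls(x, y, w)
    model = LogLinearModel(slope, intercept)
    if full_output:
        return model, FitResult(slope, intercept, rss, len(table))
    return model


def fit_ert_ratio(
    user_table: pd.DataFrame,
    nonuser_table: pd.DataFrame,
    weight_by_n: bool = False,
    full_output: bool = False,
):
    """Log-linear model of the user/non-user concentration ratio vs. BMI.

    The response is the per-stratum difference of mean log concentrations
    (= log of the ratio of geometric means); the tables must share the same
    BMI categories.  With ``weight_by_n`` each stratum is weighted by the
    harmonic combination 1/(1/n_user + 1/n_nonuser), the inverse variance of a
    difference of two stratum means.
    """
    validate_concentration_table(user_table)
    validate_concentration_table(nonuser_table)
    u = user_table.sort_values("median_bmi").reset_index(drop=True)
    v = nonuser_table.sort_values("median_bmi").reset_index(drop=True)
    if len(u) != len(v) or not np.allclose(
        u["median_bmi"].to_numpy(float), v["median_bmi"].to_numpy(float)
    ):
        raise AlignmentError("user and non-user tables must share BMI categories")
    x = u["median_bmi"].to_numpy(float)
    y = u["mean_log_e2f"].to_numpy(float) - v["mean_log_e2f"].to_numpy(float)
    w = None
    if weight_by_n:
        nu = u["n"].to_numpy(float)
        nv = v["n"].to_numpy(float)
        w = 1.0 / (1.0 / nu + 1.0 / nv)
    slope, intercept, rss = _wls(x, y, w)
    model = LogLinearModel(slope, intercept)
    if full_output:
        return model, FitResult(slope, intercept, rss, len(u))
    return model


def fit_rr_doubling_through_reference(
    table: pd.DataFrame,
    weight_by_cases: bool = False,
    include_reference: bool = False,
    full_output: bool = False,
):
    """Per-doubling risk from a quantile RR table, fit through the reference.

    Minimises sum of w_i * (ln rr_i - s * (ln e2f_i - ln e2f_ref))^2, i.e. a
    no-intercept least-squares line on the log-log plot anchored at the
    reference quantile (RR = 1).  Returns rr_per_doubling = 2**s.

    ``include_reference`` adds the reference row to the residual sum; since it
    lies exactly on the constrained line its residual is zero and the result
    is unchanged (both readings of the procedure are therefore available).
    """
    validate_quantile_risk_table(table)
    ref_mask = table["is_reference"].astype(bool).to_numpy()
    if len(table) - 1 < 2:
        raise InvalidInputError("need at least two non-reference quantiles")
    log_e = np.log(table["e2f_mid_mol_per_L"].to_numpy(float))
    log_rr = np.log(table["rr"].to_numpy(float))
    x = log_e - log_e[ref_mask][0]
    y = log_rr
    keep = np.ones(len(table), bool) if include_reference else ~ref_mask
    w = (
        table["n_cases"].to_numpy(float)[keep]
        if weight_by_cases
        else np.ones(int(keep.sum()))
    )
    xx, yy = x[keep], y[keep]
    if np.all(xx == 0):
        raise SingularFitError("all quantiles coincide with the reference")
    res = sm.WLS(yy, xx[:, None], weights=w).fit()
    slope = float(res.params[0])
    rss = float(np.sum(w * (yy - slope * xx) ** 2))
    model = DoublingRiskModel.from_exponent(slope)
    if full_output:
        return model, FitResult(slope, None, rss, int(keep.sum()))
    return model


def compose_risk_model(
    e2f_model: LogLinearModel,
    risk: DoublingRiskModel,
    reference_bmi: float = 23.0,
    saturation: SaturationPolicy = SaturationPolicy.none(),
) -> ComposedRiskModel:
    """Compose concentration model and per-doubling risk into a RR-vs-BMI line.

    The closed-form ln-RR slope is ``e2f_model.slope * risk.exponent``; the
    intercept is fixed by RR(reference_bmi) = 1 rather than transcribed, so the
    composition is internally consistent.  Raises if the reference BMI's
    concentration is at or above the cap.
    """
    return ComposedRiskModel(
        e2f_model=e2f_model,
        risk=risk,
        reference_bmi=float(reference_bmi),
        saturation=saturation,
    )
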