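"""Validation machinery: re-reference study RR tables and calibrate predictions.

Published studies report breast-cancer relative risks by BMI category, each
with its own reference category.  To compare them with the model they are put
on a common footing:

1. ``assign_category_bmi`` — each category gets a representative BMI: the
   arithmetic midpoint for bounded interior categories, a conditional median
   from a BMI distribution for the lowest/highest (or any open-ended) ones.
2. ``rescale_to_reference`` — all RRs (and CI bounds) are divided by the
   study's observed RR at the common reference BMI (23 by default), obtained
   by log-linear interpolation between the bracketing categories.
3. ``calibration_regression`` — observed vs. model-predicted RRs are fit by
   OLS and by case-count-weighted WLS; perfect calibration is slope 1,
   intercept 0.

``predict_validation_table`` chains the three into a flat, plot-ready table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import ComposedRiskModel, InvalidInputError
from .population import BmiDistribution, category_median

__all__ = [
    "STUDY_COLUMNS",
    "ExtrapolationError",
    "CalibrationResult",
    "read_study_table",
    "validate_study_table",
    "assign_category_bmi",
    "rescale_to_reference",
    "calibration_regression",
    "predict_validation_table",
]

#: CSV schema for study RR tables; open bounds and absent CIs are empty fields.
STUDY_COLUMNS = [
    "study",
    "bmi_low",
    "bmi_high",
    "rr",
    "ci_low",
    "ci_high",
    "n_cases",
    "is_reference",
]


class ExtrapolationError(InvalidInputError):
    """The reference BMI lies outside the span of the study's categories."""


@dataclass(frozen=True)
class CalibrationResult:
    """Observed-vs-predicted regression lines (unweighted and case-weighted)."""

    slope: float
    intercept: float
    weighted_slope: float
    weighted_intercept: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "weighted_slope": self.weighted_slope,
            "weighted_intercept": self.weighted_intercept,
            "n_points": self.n_points,
        }


def read_study_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_study_table(df)
    return df


def validate_study_table(table: pd.DataFrame, require_unit_reference: bool = True) -> None:
    """Check the study-table schema.

    ``require_unit_reference=False`` skips the "reference row has RR = 1"
    check, which holds for published tables but not for already-rescaled ones.
    """
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"study table missing columns {missing}")
    if len(table) < 2:
        raise InvalidInputError("study table needs at least two categories")
    ref = table["is_reference"].astype(bool)
    if int(ref.sum()) != 1:
        raise InvalidInputError(
            f"expected exactly one reference row, got {int(ref.sum())}"
        )
    rr = table["rr"].to_numpy(float)
    if np.any(~np.isfinite(rr)) or np.any(rr <= 0):
        raise InvalidInputError("relative risks must be positive and finite")
    rr_ref = float(table.loc[ref, "rr"].iloc[0])
    if require_unit_reference and not math.isclose(rr_ref, 1.0, rel_tol=1e-9):
        raise InvalidInputError("the reference row must have rr = 1")
    lo = table["bmi_low"].to_numpy(float)
    hi = table["bmi_high"].to_numpy(float)
    both = np.isfinite(lo) & np.isfinite(hi)
    if np.any(lo[both] >= hi[both]):
        raise InvalidInputError("bounded categories need bmi_low < bmi_high")
    cl = table["ci_low"].to_numpy(float)
    ch = table["ci_high"].to_numpy(float)
    has_ci = np.isfinite(cl) & np.isfinite(ch)
    if np.any(cl[has_ci] > rr[has_ci]) or np.any(rr[has_ci] > ch[has_ci]):
        raise InvalidInputError("need ci_low <= rr <= ci_high where CIs are present")


def assign_category_bmi(
    table: pd.DataFrame,
    dist: Optional[BmiDistribution] = None,
    midpoint: str = "closed",
) -> np.ndarray:
    """Representative BMI per study row.

    Bounded interior categories take the arithmetic midpoint of their bounds;
    the lowest and highest categories — and any open-ended category — take the
    conditional median of ``dist`` restricted to the category.  If no
    distribution is supplied, bounded extreme categories fall back to their
    midpoint; open-ended ones raise.  ``midpoint`` ("closed" or "half-open")
    is accepted for interface completeness; the arithmetic midpoint is the
    same under either bound convention.
    """
    if midpoint not in ("closed", "half-open"):
        raise InvalidInputError("midpoint must be 'closed' or 'half-open'")
    lo = table["bmi_low"].to_numpy(float)
    hi = table["bmi_high"].to_numpy(float)
    order = np.argsort(np.where(np.isfinite(lo), lo, -np.inf))
    first, last = order[0], order[-1]
    out = np.empty(len(table), float)
    for i in range(len(table)):
        open_ended = not (np.isfinite(lo[i]) and np.isfinite(hi[i]))
        extreme = i in (first, last)
        if open_ended or extreme:
            if dist is None:
                if open_ended:
                    raise InvalidInputError(
                        "open-ended BMI category requires a BMI distribution"
                    )
                out[i] = (lo[i] + hi[i]) / 2.0
            else:
                out[i] = category_median(
                    dist,
                    low=None if not np.isfinite(lo[i]) else lo[i],
                    high=None if not np.isfinite(hi[i]) else hi[i],
                )
        else:
            out[i] = (lo[i] + hi[i]) / 2.0
    return out


def _reference_divisor(
    bmis: np.ndarray, rrs: np.ndarray, reference_bmi: float, method: str
) -> float:
    order = np.argsort(bmis)
    b = bmis[order]
    log_rr = np.log(rrs[order])
    if not b[0] <= reference_bmi <= b[-1]:
        raise ExtrapolationError(
            f"reference BMI {reference_bmi:g} outside the span "
            f"[{b[0]:g}, {b[-1]:g}] of the study's categories"
        )
    if method == "interpolate":
        return float(np.exp(np.interp(reference_bmi, b, log_rr)))
    if method == "nearest":
        i = int(np.argmin(np.abs(b - reference_bmi)))
        return float(np.exp(log_rr[i]))
    raise InvalidInputError("method must be 'interpolate' or 'nearest'")


def rescale_to_reference(
    table: pd.DataFrame,
    representative_bmis: Sequence[float],
    reference_bmi: float = 23.0,
    method: str = "interpolate",
) -> pd.DataFrame:
    """Re-reference a study's RRs (and CIs) to a common reference BMI.

    Every RR and CI bound is divided by the study's observed RR at
    ``reference_bmi``, obtained by log-linear interpolation of ln(RR) between
    the two representative BMIs bracketing it (or the nearest category's RR
    with ``method='nearest'``).  Ratios between rows are preserved, CI
    ordering is preserved, and the operation is idempotent.
    """
    validate_study_table(table, require_unit_reference=False)
    bmis = np.asarray(representative_bmis, float)
    if bmis.shape != (len(table),):
        raise InvalidInputError("need one representative BMI per study row")
    divisor = _reference_divisor(
        bmis, table["rr"].to_numpy(float), float(reference_bmi), method
    )
    out = table.copy()
    for col in ("rr", "ci_low", "ci_high"):
        out[col] = out[col].to_numpy(float) / divisor
    return out


def _line(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray]):
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate predictor: all predicted RRs identical")
    X = sm.add_constant(x)
    weights = np.ones_like(y) if w is None else np.asarray(w, float)
    res = sm.WLS(y, X, weights=weights).fit()
    return float(res.params[1]), float(res.params[0])


def calibration_regression(
    observed: Sequence[float],
    predicted: Sequence[float],
    case_weights: Optional[Sequence[float]] = None,
    log_scale: bool = False,
) -> CalibrationResult:
    """Regression of observed on predicted RRs, unweighted and case-weighted.

    On the RR scale by default (the scale the published calibration lines are
    of order slope 1, intercept 0 on); ``log_scale`` regresses ln(observed) on
    ln(predicted) instead.  With no ``case_weights`` the weighted fit equals
    the unweighted one.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length vectors")
    if obs.size < 2:
        raise InvalidInputError("need at least two points for a calibration line")
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise InvalidInputError("relative risks must be positive")
    x, y = (np.log(pred), np.log(obs)) if log_scale else (pred, obs)
    slope, intercept = _line(x, y, None)
    if case_weights is None:
        w_slope, w_intercept = slope, intercept
    else:
        w = np.asarray(case_weights, float)
        if w.shape != obs.shape or np.any(w <= 0):
            raise InvalidInputError("case weights must be positive, one per point")
        w_slope, w_intercept = _line(x, y, w)
    return CalibrationResult(slope, intercept, w_slope, w_intercept, obs.size)


def predict_validation_table(
    tables: Iterable[pd.DataFrame],
    model: ComposedRiskModel,
    dist: Optional[BmiDistribution] = None,
    reference_bmi: float = 23.0,
    method: str = "interpolate",
) -> pd.DataFrame:
    """Pair rescaled observed RRs with model predictions, across studies.

    Returns one flat table (study, bmi, rr_observed, ci_low, ci_high,
    rr_predicted, n_cases, is_reference) ready for plotting or for
    ``calibration_regression``.
    """
    records = []
    for table in tables:
        validate_study_table(table)
        bmis = assign_category_bmi(table, dist=dist)
        rescaled = rescale_to_reference(
            table, bmis, reference_bmi=reference_bmi, method=method
        )
        predicted = np.array([model.rr(b) for b in bmis])
        out = pd.DataFrame(
            {
                "study": rescaled["study"].to_numpy(),
                "bmi": bmis,
                "rr_observed": rescaled["rr"].to_numpy(float),
                "ci_low": rescaled["ci_low"].to_numpy(float),
                "ci_high": rescaled["ci_high"].to_numpy(float),
                "rr_predicted": predicted,
                "n_cases": rescaled["n_cases"].to_numpy(),
                "is_reference": rescaled["is_reference"].astype(bool).to_numpy(),
            }
        )
        records.append(out)
    if not records:
        raise InvalidInputError("no study tables supplied")
    return pd.concat(records, ignore_index=True)
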