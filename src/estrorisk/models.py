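"""Closed-form models linking BMI, ERT use, free estradiol, and breast-cancer risk.

The model chain has two stages.  First, a log-linear model maps BMI to a free
(non-protein-bound) serum estradiol concentration::

    E2F(BMI) = exp(slope * BMI + intercept)        [mol/L]

Postmenopausal women (not on hormone therapy) have a positive slope: adipose
aromatisation makes estradiol rise with adiposity.  Premenopausal follicular
estradiol falls with BMI (negative slope).  Estrogen-only hormone replacement
therapy (ERT) multiplies the postmenopausal concentration by a BMI-dependent
ratio, itself log-linear in BMI.

Second, concentration maps to relative risk (RR) through a per-doubling risk
model: a two-fold increase in free estradiol multiplies breast-cancer risk by
``rr_per_doubling``, so

    RR = (E2F1 / E2F2) ** log2(rr_per_doubling).

For postmenopausal women a saturation level is hypothesised: free estradiol
above a cap (7.50e-13 mol/L, the concentration a non-user reaches at BMI 30)
confers no further risk, so concentrations are clipped at the cap before the
ratio is taken.  The premenopausal model carries no cap.

All arithmetic is done with natural logs; the per-doubling power is stored as
``ln(rr) / ln(2)`` so that ``ratio ** exponent == exp(exponent * ln(ratio))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ModelValidityWarning",
    "InvalidInputError",
    "BMI_VALID_RANGE",
    "E2F_PLAUSIBLE_RANGE",
    "LogLinearModel",
    "DoublingRiskModel",
    "SaturationPolicy",
    "ComposedRiskModel",
    "check_bmi",
    "check_concentration",
    "e2f_postmenopausal",
    "e2f_premenopausal_follicular",
    "ert_ratio",
    "e2f_ert_user",
    "rr_from_concentrations",
    "rr_bmi_postmeno_nonhrt",
    "rr_bmi_premeno",
    "rr_bmi_ert_user",
    "rr_ert_vs_nonuser",
]

#: BMI range (kg/m^2) over which the model has been exercised against cohort
#: data; values outside trigger a warning, not an error.
BMI_VALID_RANGE = (15.0, 50.0)

#: Plausible free-estradiol magnitudes (mol/L) for this model.
E2F_PLAUSIBLE_RANGE = (1e-15, 1e-10)


class ModelValidityWarning(UserWarning):
    """Input lies outside the range the model was built and validated on."""


class InvalidInputError(ValueError):
    """Input violates a hard model precondition (e.g. non-positive BMI)."""


def check_bmi(bmi: float) -> float:
    """Validate a BMI value; error if non-positive, warn if outside validity range."""
    b = float(bmi)
    if not math.isfinite(b) or b <= 0.0:
        raise InvalidInputError(f"BMI must be a positive finite number, got {bmi!r}")
    lo, hi = BMI_VALID_RANGE
    if not lo <= b <= hi:
        warnings.warn(
            f"BMI {b:g} kg/m^2 is outside the model's validated range "
            f"[{lo:g}, {hi:g}]; extrapolating",
            ModelValidityWarning,
            stacklevel=3,
        )
    return b


def check_concentration(value: float) -> float:
    """Validate a free-estradiol concentration (mol/L)."""
    x = float(value)
    if not math.isfinite(x) or x <= 0.0:
        raise InvalidInputError(
            f"concentration must be a positive finite number, got {value!r}"
        )
    lo, hi = E2F_PLAUSIBLE_RANGE
    if not lo <= x <= hi:
        warnings.warn(
            f"free estradiol {x:g} mol/L is outside the plausible range "
            f"[{lo:g}, {hi:g}] for this model",
            ModelValidityWarning,
            stacklevel=3,
        )
    return x


@dataclass(frozen=True)
class LogLinearModel:
    """A line in (BMI, ln concentration) space: ln y = slope * bmi + intercept.

    ``slope`` has units 1/(kg/m^2); ``intercept`` is ln(concentration in mol/L)
    at BMI = 0 (or ln of a dimensionless ratio, for the ERT ratio model).
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise InvalidInputError("slope and intercept must be finite")

    def log_predict(self, bmi: float) -> float:
        return self.slope * bmi + self.intercept

    def predict(self, bmi: float) -> float:
        """exp(slope * bmi + intercept); strictly monotone when slope != 0."""
        return math.exp(self.log_predict(bmi))

    def compose(self, other: "LogLinearModel") -> "LogLinearModel":
        """Pointwise product of two log-linear models (sum of coefficients)."""
        return LogLinearModel(self.slope + other.slope, self.intercept + other.intercept)


@dataclass(frozen=True)
class DoublingRiskModel:
    """Relative risk per doubling of free estradiol.

    ``exponent`` is log2(rr_per_doubling): the power applied to a concentration
    ratio, since (E2F1/E2F2)**log2(rr) doubles risk by ``rr`` per concentration
    doubling.
    """

    rr_per_doubling: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rr_per_doubling) and self.rr_per_doubling > 0):
            raise InvalidInputError(
                f"rr_per_doubling must be positive, got {self.rr_per_doubling!r}"
            )

    @property
    def exponent(self) -> float:
        return math.log(self.rr_per_doubling) / math.log(2.0)

    @classmethod
    def from_exponent(cls, exponent: float) -> "DoublingRiskModel":
        """Build from a log-log slope (the power itself): rr = 2**exponent."""
        return cls(2.0 ** exponent)

    def rr_for_ratio(self, ratio: float) -> float:
        """Relative risk for a given concentration ratio."""
        if ratio <= 0:
            raise InvalidInputError("concentration ratio must be positive")
        return math.exp(self.exponent * math.log(ratio))


@dataclass(frozen=True)
class SaturationPolicy:
    """Concentration cap above which additional estradiol adds no risk.

    ``cap`` is a concentration in mol/L, or None to disable saturation (the
    premenopausal model has no cap).  ``saturate`` is idempotent and monotone
    non-decreasing.
    """

    cap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cap is not None and not (math.isfinite(self.cap) and self.cap > 0):
            raise InvalidInputError(f"saturation cap must be positive, got {self.cap!r}")

    @classmethod
    def none(cls) -> "SaturationPolicy":
        return cls(cap=None)

    @property
    def enabled(self) -> bool:
        return self.cap is not None

    def saturate(self, concentration: float) -> float:
        if concentration <= 0:
            raise InvalidInputError("concentration must be positive")
        if self.cap is None:
            return concentration
        return min(self.cap, concentration)

    def log_saturate(self, log_concentration: float) -> float:
        if self.cap is None:
            return log_concentration
        return min(math.log(self.cap), log_concentration)


def e2f_postmenopausal(bmi: float, model: LogLinearModel) -> float:
    """Postmenopausal (non-HRT) free estradiol, mol/L, at the given BMI.

    With the default coefficients (slope 0.068847, intercept -29.984) this is
    strictly increasing in BMI; e.g. 4.6325e-13 mol/L at BMI 23.
    """
    b = check_bmi(bmi)
    return check_concentration(model.predict(b))


def e2f_premenopausal_follicular(bmi: float, model: LogLinearModel) -> float:
    """Premenopausal follicular-phase free estradiol, mol/L (decreasing in BMI)."""
    b = check_bmi(bmi)
    return check_concentration(model.predict(b))


def ert_ratio(bmi: float, ratio_model: LogLinearModel) -> float:
    """Ratio of free estradiol in current ERT users to non-users at a BMI.

    Dimensionless; > 1 over the model's validity range (the default ratio
    exp(-0.023098 * BMI + 1.2617) crosses 1 only near BMI 55).
    """
    b = check_bmi(bmi)
    return ratio_model.predict(b)


def e2f_ert_user(
    bmi: float, base: LogLinearModel, ratio_model: LogLinearModel
) -> float:
    """Free estradiol of a current ERT user: base concentration times ERT ratio.

    Computed through the composed log-linear model (summed slopes/intercepts),
    which is exactly the product of the two factors.
    """
    b = check_bmi(bmi)
    return check_concentration(base.compose(ratio_model).predict(b))


def rr_from_concentrations(
    e2f1: float,
    e2f2: float,
    risk: DoublingRiskModel,
    saturation: SaturationPolicy = SaturationPolicy.none(),
) -> float:
    """Relative risk between two free-estradiol concentrations.

    RR = (saturate(e2f1) / saturate(e2f2)) ** log2(rr_per_doubling).  Equals 1
    when both concentrations are at or above the cap; satisfies
    rr(a, b) * rr(b, a) == 1.
    """
    x1 = check_concentration(e2f1)
    x2 = check_concentration(e2f2)
    log_ratio = saturation.log_saturate(math.log(x1)) - saturation.log_saturate(
        math.log(x2)
    )
    return math.exp(risk.exponent * log_ratio)


def rr_bmi_postmeno_nonhrt(
    bmi: float,
    reference_bmi: float,
    base: LogLinearModel,
    risk: DoublingRiskModel,
    saturation: SaturationPolicy,
) -> float:
    """RR at a BMI vs. a reference BMI for postmenopausal non-HRT users.

    The numerator concentration is saturated; the reference concentration must
    lie below the cap (otherwise the construction's reference risk is
    undefined) and is used unsaturated.  Constant (plateau) for every BMI whose
    predicted concentration meets the cap.
    """
    b = check_bmi(bmi)
    ref = check_bmi(reference_bmi)
    log_ref = base.log_predict(ref)
    if saturation.enabled and log_ref >= math.log(saturation.cap):
        raise InvalidInputError(
            "reference BMI's predicted concentration is at or above the "
            "saturation cap; reference relative risk is undefined"
        )
    log_num = saturation.log_saturate(base.log_predict(b))
    return math.exp(risk.exponent * (log_num - log_ref))


def rr_bmi_premeno(
    bmi: float,
    reference_bmi: float,
    base: LogLinearModel,
    risk: DoublingRiskModel,
) -> float:
    """RR at a BMI vs. a reference BMI for premenopausal women (no saturation)."""
    b = check_bmi(bmi)
    ref = check_bmi(reference_bmi)
    return math.exp(risk.exponent * (base.log_predict(b) - base.log_predict(ref)))


def rr_bmi_ert_user(
    bmi: float,
    ert: LogLinearModel,
    risk: DoublingRiskModel,
    saturation: SaturationPolicy,
    reference_bmi: float = 23.0,
) -> float:
    """RR for an ERT user at a BMI relative to an ERT user at the reference BMI.

    ``ert`` is the combined (base x ratio) concentration model.  The reference
    concentration is the *saturated* ERT-user concentration at the reference
    BMI — with the default coefficients min(cap, e2f_ert(23)) equals the cap,
    so the RR is exactly 1 wherever the ERT-user concentration meets the cap
    (all BMI >= 18, hence "no BMI effect among ERT users").
    """
    b = check_bmi(bmi)
    ref = check_bmi(reference_bmi)
    log_ref = saturation.log_saturate(ert.log_predict(ref))
    log_num = saturation.log_saturate(ert.log_predict(b))
    return math.exp(risk.exponent * (log_num - log_ref))


def rr_ert_vs_nonuser(
    bmi: float,
    base: LogLinearModel,
    ert: LogLinearModel,
    risk: DoublingRiskModel,
    saturation: SaturationPolicy,
) -> float:
    """RR of a current ERT user vs. a non-user at the same BMI.

    Both concentrations are saturated before the ratio is taken.  With the
    default coefficients the excess risk attenuates with BMI (1.6 at BMI 18,
    1.2 at 25) and vanishes (RR = 1.0) once the non-user concentration itself
    reaches the cap, at BMI 30.
    """
    b = check_bmi(bmi)
    log_num = saturation.log_saturate(ert.log_predict(b))
    log_den = saturation.log_saturate(base.log_predict(b))
    return math.exp(risk.exponent * (log_num - log_den))


@dataclass(frozen=True)
class ComposedRiskModel:
    """Closed-form RR-vs-BMI model obtained by composing the two stages.

    In the unsaturated regime ln RR is linear in BMI with
    ``slope = e2f_model.slope * risk.exponent`` and intercept fixed by the
    reference condition RR(reference_bmi) = 1 (so ``intercept = -slope * ref``).
    ``rr`` applies the saturation cap; ``rr_closed_form`` is the bare line.
    """

    e2f_model: LogLinearModel
    risk: DoublingRiskModel
    reference_bmi: float = 23.0
    saturation: SaturationPolicy = field(default_factory=SaturationPolicy.none)

    def __post_init__(self) -> None:
        ref = float(self.reference_bmi)
        if not (math.isfinite(ref) and ref > 0):
            raise InvalidInputError(f"reference BMI must be positive, got {ref!r}")
        if self.saturation.enabled and self.e2f_model.log_predict(ref) >= math.log(
            self.saturation.cap
        ):
            raise InvalidInputError(
                "reference BMI's concentration is at or above the saturation cap"
            )

    @property
    def slope(self) -> float:
        """Change in ln(RR) per unit BMI (unsaturated regime)."""
        return self.e2f_model.slope * self.risk.exponent

    @property
    def intercept(self) -> float:
        """ln(RR) at BMI = 0 on the unsaturated line; RR(reference_bmi) == 1."""
        return -self.slope * self.reference_bmi

    def rr_closed_form(self, bmi: float) -> float:
        """exp(slope * bmi + intercept), ignoring saturation."""
        b = check_bmi(bmi)
        return math.exp(self.slope * b + self.intercept)

    def rr(self, bmi: float) -> float:
        """Relative risk vs. the reference BMI, with saturation applied."""
        b = check_bmi(bmi)
        log_num = self.saturation.log_saturate(self.e2f_model.log_predict(b))
        log_ref = self.e2f_model.log_predict(self.reference_bmi)
        return math.exp(self.risk.exponent * (log_num - log_ref))

    def rr_per_unit_bmi(self) -> float:
        """Multiplicative RR change per +1 kg/m^2 in the unsaturated regime."""
        return math.exp(self.slope)
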