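"""BMI distributions and population-averaged relative risks.

A :class:`BmiDistribution` is a discrete probability mass function on a BMI
grid.  Parametric families (lognormal, normal) are discretized by assigning
each grid point the probability mass of its cell (cdf differences at the cell
edges), truncated to the stated support and renormalised.  Conditional
medians interpolate linearly within grid cells, so they are stable under grid
refinement.

``weighted_mean_rr`` computes the expectation of a BMI -> RR function under
the distribution — e.g. the overall relative risk associated with ERT use,
averaged over the BMI distribution of postmenopausal women.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .models import InvalidInputError

__all__ = [
    "ZeroMassError",
    "BmiDistribution",
    "category_median",
    "weighted_mean_rr",
]

_WEIGHT_TOL = 1e-9


class ZeroMassError(InvalidInputError):
    """The requested BMI category carries no probability mass."""


class BmiDistribution:
    """Discrete BMI distribution: grid values (kg/m^2) with normalised weights."""

    def __init__(self, values, weights):
        v = np.asarray(values, float)
        w = np.asarray(weights, float)
        if v.ndim != 1 or v.shape != w.shape or v.size == 0:
            raise InvalidInputError("values and weights must be equal-length 1-d arrays")
        if np.any(~np.isfinite(v)) or np.any(~np.isfinite(w)) or np.any(w < 0):
            raise InvalidInputError("weights must be finite and non-negative")
        order = np.argsort(v)
        v, w = v[order], w[order]
        if np.any(np.diff(v) <= 0):
            raise InvalidInputError("BMI grid values must be distinct")
        total = w.sum()
        if total <= 0:
            raise InvalidInputError("weights must have positive total mass")
        if abs(total - 1.0) > _WEIGHT_TOL:
            w = w / total
        self.values = v
        self.weights = w

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_discrete(cls, values, weights) -> "BmiDistribution":
        return cls(values, weights)

    @classmethod
    def _from_frozen(
        cls, dist, low: float, high: float, step: float
    ) -> "BmiDistribution":
        if step <= 0 or high <= low:
            raise InvalidInputError("need step > 0 and high > low")
        grid = np.arange(low, high + step / 2, step)
        edges = np.concatenate([[grid[0] - step / 2], grid + step / 2])
        w = np.diff(dist.cdf(edges))
        if w.sum() <= 0:
            raise InvalidInputError("distribution has no mass on the stated support")
        return cls(grid, w / w.sum())

    @classmethod
    def from_lognormal(
        cls,
        mu: float,
        sigma: float,
        low: float = 15.0,
        high: float = 60.0,
        step: float = 0.1,
    ) -> "BmiDistribution":
        """Lognormal BMI: ln(BMI) ~ Normal(mu, sigma), discretized on a grid."""
        if sigma <= 0:
            raise InvalidInputError("sigma must be positive")
        return cls._from_frozen(
            stats.lognorm(s=sigma, scale=math.exp(mu)), low, high, step
        )

    @classmethod
    def from_normal(
        cls,
        mean: float,
        sd: float,
        low: float = 15.0,
        high: float = 60.0,
        step: float = 0.1,
    ) -> "BmiDistribution":
        if sd <= 0:
            raise InvalidInputError("sd must be positive")
        return cls._from_frozen(stats.norm(loc=mean, scale=sd), low, high, step)

    @classmethod
    def point_mass(cls, bmi: float) -> "BmiDistribution":
        return cls([float(bmi)], [1.0])

    @classmethod
    def from_spec(cls, spec: Mapping) -> "BmiDistribution":
        """Build from a config mapping: {family: lognormal|normal|empirical, ...}."""
        family = str(spec.get("family", "")).lower()
        if family == "lognormal":
            return cls.from_lognormal(
                float(spec["mu"]),
                float(spec["sigma"]),
                low=float(spec.get("low", 15.0)),
                high=float(spec.get("high", 60.0)),
                step=float(spec.get("step", 0.1)),
            )
        if family == "normal":
            return cls.from_normal(
                float(spec["mean"]),
                float(spec["sd"]),
                low=float(spec.get("low", 15.0)),
                high=float(spec.get("high", 60.0)),
                step=float(spec.get("step", 0.1)),
            )
        if family == "empirical":
            return cls(spec["bmi"], spec["weight"])
        raise InvalidInputError(
            f"unknown distribution family {spec.get('family')!r}; "
            "expected lognormal, normal or empirical"
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "BmiDistribution":
        df = pd.read_csv(path, comment="#")
        for col in ("bmi", "weight"):
            if col not in df.columns:
                raise InvalidInputError(f"distribution CSV missing column {col!r}")
        return cls(df["bmi"].to_numpy(float), df["weight"].to_numpy(float))

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"bmi": self.values, "weight": self.weights}).to_csv(
            path, index=False, float_format="%.12g"
        )

    # -- summaries -----------------------------------------------------------
    def mean(self) -> float:
        return float(self.weights @ self.values)

    def shifted(self, delta: float) -> "BmiDistribution":
        """The same distribution translated by ``delta`` kg/m^2."""
        return BmiDistribution(self.values + float(delta), self.weights)

    def _cell_edges(self) -> np.ndarray:
        v = self.values
        if v.size == 1:
            return np.array([v[0], v[0]])
        inner = (v[1:] + v[:-1]) / 2.0
        first = v[0] - (inner[0] - v[0])
        last = v[-1] + (v[-1] - inner[-1])
        return np.concatenate([[first], inner, [last]])


def category_median(
    dist: BmiDistribution,
    low: Optional[float] = None,
    high: Optional[float] = None,
) -> float:
    """Conditional median of the distribution restricted to [low, high).

    Open bounds are passed as None.  The median interpolates linearly within
    the grid cell in which the conditional cumulative mass crosses one half,
    treating each grid point's mass as uniform over its cell.
    """
    lo = -math.inf if low is None else float(low)
    hi = math.inf if high is None else float(high)
    mask = (dist.values >= lo) & (dist.values < hi)
    if not mask.any():
        raise ZeroMassError(f"no probability mass in BMI category [{lo}, {hi})")
    v = dist.values[mask]
    w = dist.weights[mask]
    total = w.sum()
    if total <= 0:
        raise ZeroMassError(f"zero probability mass in BMI category [{lo}, {hi})")
    if v.size == 1:
        return float(v[0])
    sub = BmiDistribution(v, w / total)
    edges = sub._cell_edges()
    cum = np.concatenate([[0.0], np.cumsum(sub.weights)])
    half = 0.5
    i = int(np.searchsorted(cum, half))  # first edge index with cum >= half
    i = min(max(i, 1), len(sub.weights))
    mass_in_cell = cum[i] - cum[i - 1]
    if mass_in_cell <= 0:
        return float(edges[i - 1])
    frac = (half - cum[i - 1]) / mass_in_cell
    return float(edges[i - 1] + frac * (edges[i] - edges[i - 1]))


def weighted_mean_rr(
    dist: BmiDistribution, rr_function: Callable[[float], float]
) -> float:
    """Expectation of a BMI -> relative-risk function under the distribution.

    Raises if the function is undefined or non-finite anywhere on the support.
    Per-point extrapolation warnings are suppressed: the distribution's
    declared support, not each grid point, defines the averaging domain.
    """
    import warnings

    from .models import ModelValidityWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelValidityWarning)
        rr = np.array([float(rr_function(b)) for b in dist.values])
    if np.any(~np.isfinite(rr)):
        bad = dist.values[~np.isfinite(rr)][0]
        raise InvalidInputError(f"rr_function is non-finite at BMI {bad:g}")
    return float(dist.weights @ rr)
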