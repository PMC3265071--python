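"""Synthetic generators for every input table the pipeline consumes.

The generators emulate the statistical structure the analysis assumes, so the
whole chain (fit -> compose -> predict -> validate -> average) is testable
without any external data:

* concentration summary tables: per-stratum mean log free estradiol is the
  true line plus Normal(0, sd/sqrt(n)) noise — the sampling error of a mean of
  ``n`` lognormal concentrations with log-scale spread ``sd``;
* paired user/non-user tables for the ERT ratio fit;
* quantile RR tables: ln RR is the true log-log line through the reference
  plus noise (reference RR is exactly 1);
* study RR-by-BMI-category tables: category RRs are model predictions (with
  optional log-scale noise and power distortion), re-expressed relative to the
  study's own reference category, with lognormal CIs from
  SE(ln RR) = sqrt(1/cases_i + 1/cases_ref);
* BMI distributions (delegating to :class:`~estrorisk.population.BmiDistribution`).

Noise enters only on the log scale (all model relations are log-linear).
Identical parameters and seed give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import (
    CONCENTRATION_COLUMNS,
    MIN_STRATA,
    InsufficientStrataError,
    QUANTILE_COLUMNS,
)
from .models import ComposedRiskModel, InvalidInputError, LogLinearModel
from .population import BmiDistribution, category_median
from .validation import STUDY_COLUMNS

__all__ = [
    "DEFAULT_SEED",
    "DEFAULT_CATEGORIES",
    "GeneratorSpec",
    "generate_concentration_table",
    "generate_ratio_tables",
    "generate_quantile_risk_table",
    "generate_study_table",
    "generate_bmi_distribution",
    "generate",
    "write_table",
]

#: Default random seed for all generators.
DEFAULT_SEED = 20120116

#: Common epidemiological BMI cuts (kg/m^2); None encodes an open bound.
DEFAULT_CATEGORIES: List[Tuple[Optional[float], Optional[float]]] = [
    (None, 22.5),
    (22.5, 25.0),
    (25.0, 27.5),
    (27.5, 30.0),
    (30.0, None),
]

DEFAULT_MEDIANS = (21.0, 24.0, 27.0, 31.0)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset (for the CLI).

    ``kind`` is one of concentration | ratio-pair | quantile-risk |
    study-table | bmi-distribution; ``params`` holds the generating parameters
    for the corresponding ``generate_*`` function.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(DEFAULT_SEED if seed is None else int(seed))


def _categories_from_medians(
    medians: np.ndarray,
) -> List[Tuple[Optional[float], Optional[float]]]:
    cuts = (medians[1:] + medians[:-1]) / 2.0
    bounds = [None, *cuts.tolist(), None]
    return [(bounds[i], bounds[i + 1]) for i in range(len(medians))]


def generate_concentration_table(
    slope: float,
    intercept: float,
    median_bmis: Sequence[float] = DEFAULT_MEDIANS,
    noise_sd: float = 0.0,
    n_per_stratum: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Concentration summary table from a true log-linear model.

    Per stratum, mean_log_e2f = slope*median + intercept + eps with
    eps ~ Normal(0, noise_sd / sqrt(n_per_stratum)).
    """
    medians = np.asarray(median_bmis, float)
    if medians.size < MIN_STRATA:
        raise InsufficientStrataError(
            f"need at least {MIN_STRATA} BMI categories, got {medians.size}"
        )
    if np.any(np.diff(medians) <= 0):
        raise InvalidInputError("median BMIs must be strictly increasing")
    if noise_sd < 0 or n_per_stratum < 1:
        raise InvalidInputError("need noise_sd >= 0 and n_per_stratum >= 1")
    gen = _rng(seed, rng)
    eps = gen.normal(0.0, noise_sd / np.sqrt(n_per_stratum), size=medians.size)
    cats = _categories_from_medians(medians)
    return pd.DataFrame(
        {
            "bmi_low": [c[0] for c in cats],
            "bmi_high": [c[1] for c in cats],
            "median_bmi": medians,
            "mean_log_e2f": slope * medians + intercept + eps,
            "n": n_per_stratum,
        },
        columns=CONCENTRATION_COLUMNS,
    )


def generate_ratio_tables(
    base: LogLinearModel,
    ratio: LogLinearModel,
    median_bmis: Sequence[float] = DEFAULT_MEDIANS,
    noise_sd: float = 0.0,
    n_per_stratum: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Matched (user, nonuser) concentration tables sharing BMI categories."""
    gen = _rng(seed, rng)
    nonuser = generate_concentration_table(
        base.slope, base.intercept, median_bmis, noise_sd, n_per_stratum, rng=gen
    )
    user = generate_concentration_table(
        base.slope + ratio.slope,
        base.intercept + ratio.intercept,
        median_bmis,
        noise_sd,
        n_per_stratum,
        rng=gen,
    )
    return user, nonuser


def generate_quantile_risk_table(
    exponent: float,
    e2f_midpoints: Sequence[float],
    reference_index: int = 0,
    noise_sd: float = 0.0,
    n_cases: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Quantile RR table: ln RR = exponent * (ln e2f - ln e2f_ref) + noise.

    The reference row's RR is exactly 1 (no noise is added to it).
    """
    mids = np.asarray(e2f_midpoints, float)
    if mids.size < 3:
        raise InvalidInputError("need at least three quantiles")
    if np.any(mids <= 0) or np.any(np.diff(mids) <= 0):
        raise InvalidInputError("e2f midpoints must be positive and increasing")
    if not 0 <= reference_index < mids.size:
        raise InvalidInputError(
            f"reference_index {reference_index} not a valid quantile index"
        )
    gen = _rng(seed, rng)
    log_rr = exponent * (np.log(mids) - np.log(mids[reference_index]))
    eps = gen.normal(0.0, noise_sd, size=mids.size)
    eps[reference_index] = 0.0
    log_rr = log_rr + eps
    is_ref = np.zeros(mids.size, bool)
    is_ref[reference_index] = True
    return pd.DataFrame(
        {
            "e2f_mid_mol_per_L": mids,
            "rr": np.exp(log_rr),
            "is_reference": is_ref,
            "n_cases": n_cases,
        },
        columns=QUANTILE_COLUMNS,
    )


def generate_study_table(
    model: ComposedRiskModel,
    categories: Sequence[Tuple[Optional[float], Optional[float]]] = tuple(
        DEFAULT_CATEGORIES
    ),
    reference_index: Optional[int] = None,
    dist: Optional[BmiDistribution] = None,
    noise_sd: float = 0.0,
    case_counts: Union[int, Sequence[int]] = 200,
    power: float = 1.0,
    study: str = "synthetic-study",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Synthetic study RR-by-BMI-category table driven by a composed model.

    Per category: ln RR = power * ln(model prediction at the representative
    BMI) + Normal(0, noise_sd), then re-expressed relative to the reference
    category (whose final RR is exactly 1).  ``power`` != 1 produces a
    log-scale power distortion (observed = predicted**power).  95% CIs come
    from SE(ln RR) = sqrt(1/cases_i + 1/cases_ref); the reference row has no
    CI.  The default reference is the category containing the model's
    reference BMI.
    """
    cats = list(categories)
    if len(cats) < 2:
        raise InvalidInputError("need at least two BMI categories")
    lows = np.array([-np.inf if c[0] is None else float(c[0]) for c in cats])
    highs = np.array([np.inf if c[1] is None else float(c[1]) for c in cats])
    if reference_index is None:
        ref_hits = np.nonzero((lows <= model.reference_bmi) & (model.reference_bmi < highs))[0]
        if ref_hits.size == 0:
            raise InvalidInputError(
                "no category contains the model's reference BMI; "
                "pass reference_index explicitly"
            )
        reference_index = int(ref_hits[0])
    if not 0 <= reference_index < len(cats):
        raise InvalidInputError("reference_index out of range")
    cases = np.asarray(
        [case_counts] * len(cats) if np.isscalar(case_counts) else case_counts, float
    )
    if cases.shape != (len(cats),) or np.any(cases < 1):
        raise InvalidInputError("need a positive case count per category")
    gen = _rng(seed, rng)

    rep = np.empty(len(cats))
    for i, (lo, hi) in enumerate(cats):
        if lo is None or hi is None or i in (0, len(cats) - 1):
            if dist is None:
                if lo is None or hi is None:
                    raise InvalidInputError(
                        "open-ended category requires a BMI distribution"
                    )
                rep[i] = (lo + hi) / 2.0
            else:
                rep[i] = category_median(dist, low=lo, high=hi)
        else:
            rep[i] = (lo + hi) / 2.0

    log_rr = power * np.log([model.rr(b) for b in rep])
    log_rr = log_rr + gen.normal(0.0, noise_sd, size=len(cats))
    log_rr = log_rr - log_rr[reference_index]
    rr = np.exp(log_rr)
    se = np.sqrt(1.0 / cases + 1.0 / cases[reference_index])
    ci_low = rr * np.exp(-_Z95 * se)
    ci_high = rr * np.exp(_Z95 * se)
    is_ref = np.zeros(len(cats), bool)
    is_ref[reference_index] = True
    rr[reference_index] = 1.0
    ci_low[reference_index] = np.nan
    ci_high[reference_index] = np.nan
    return pd.DataFrame(
        {
            "study": study,
            "bmi_low": [c[0] for c in cats],
            "bmi_high": [c[1] for c in cats],
            "rr": rr,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n_cases": cases.astype(int),
            "is_reference": is_ref,
        },
        columns=STUDY_COLUMNS,
    )


def generate_bmi_distribution(family: str, **params) -> BmiDistribution:
    """Build a BMI distribution from family parameters (see BmiDistribution)."""
    return BmiDistribution.from_spec({"family": family, **params})


def generate(spec: GeneratorSpec, suite=None):
    """Dispatch a GeneratorSpec to the matching generator (CLI entry).

    ``study-table`` needs model context: a ModelSuite (default: the shipped
    one) selected by ``params['population']`` (default postmeno-nonhrt).
    """
    p = dict(spec.params)
    if spec.kind == "concentration":
        return generate_concentration_table(seed=spec.seed, **p)
    if spec.kind == "ratio-pair":
        base = LogLinearModel(p.pop("base_slope"), p.pop("base_intercept"))
        ratio = LogLinearModel(p.pop("ratio_slope"), p.pop("ratio_intercept"))
        return generate_ratio_tables(base, ratio, seed=spec.seed, **p)
    if spec.kind == "quantile-risk":
        return generate_quantile_risk_table(seed=spec.seed, **p)
    if spec.kind == "study-table":
        from .config import default_suite

        s = suite or default_suite()
        population = p.pop("population", "postmeno-nonhrt")
        dist_spec = p.pop("distribution", None)
        dist = BmiDistribution.from_spec(dist_spec) if dist_spec else None
        return generate_study_table(s.composed(population), dist=dist, seed=spec.seed, **p)
    if spec.kind == "bmi-distribution":
        return generate_bmi_distribution(**p)
    raise InvalidInputError(f"unknown generator kind {spec.kind!r}")


def write_table(
    df: pd.DataFrame, path: Union[str, Path], spec: Optional[GeneratorSpec] = None
) -> None:
    """Write a table as headered CSV, with a provenance comment when generated."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if spec is not None:
            fh.write(
                f"# estrorisk synthetic table kind={spec.kind} seed={spec.seed} "
                f"params={json.dumps(spec.params, sort_keys=True, default=str)}\n"
            )
        df.to_csv(fh, index=False, float_format="%.12g")
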