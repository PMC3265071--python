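"""Configuration: shipped default coefficients and the ModelSuite container.

The shipped config (``data/defaults.yaml``) holds the published model
constants; ``load_config`` deep-merges a user config over it, so a partial
config overriding one block is valid.  ``ModelSuite`` bundles the coefficient
objects and exposes per-population concentration and relative-risk functions.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import yaml

from .models import (
    ComposedRiskModel,
    DoublingRiskModel,
    InvalidInputError,
    LogLinearModel,
    SaturationPolicy,
)

__all__ = [
    "POPULATIONS",
    "ModelSuite",
    "load_config",
    "default_config",
    "suite_from_config",
    "default_suite",
    "suite_to_config",
    "dump_config",
    "config_hash",
]

#: Populations the risk functions are defined for.
POPULATIONS = ("premeno", "postmeno-nonhrt", "postmeno-ert", "ert-vs-nonuser")


def _read_yaml(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    return data


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """The shipped default configuration as a plain dict."""
    ref = resources.files("estrorisk").joinpath("data/defaults.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return data


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Load a config file, with unspecified fields falling back to the defaults."""
    cfg = default_config()
    if path is not None:
        cfg = _deep_merge(cfg, _read_yaml(path))
    return cfg


def dump_config(cfg: Mapping, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config (for provenance lines in outputs)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ModelSuite:
    """All fitted/default coefficients needed to evaluate every population."""

    postmeno_e2f: LogLinearModel
    premeno_e2f: LogLinearModel
    ert_ratio: LogLinearModel
    rr_doubling_postmeno: DoublingRiskModel
    rr_doubling_premeno: DoublingRiskModel
    saturation: SaturationPolicy
    reference_bmi: float = 23.0

    @property
    def ert_e2f(self) -> LogLinearModel:
        """Combined ERT-user concentration model (base x ratio)."""
        return self.postmeno_e2f.compose(self.ert_ratio)

    # -- concentration -----------------------------------------------------
    def e2f(self, population: str, bmi: float) -> float:
        """Free estradiol (mol/L) for the population's exposed group at a BMI.

        For ``ert-vs-nonuser`` this is the ERT user's concentration.
        """
        from . import models

        if population == "premeno":
            return models.e2f_premenopausal_follicular(bmi, self.premeno_e2f)
        if population == "postmeno-nonhrt":
            return models.e2f_postmenopausal(bmi, self.postmeno_e2f)
        if population in ("postmeno-ert", "ert-vs-nonuser"):
            return models.e2f_ert_user(bmi, self.postmeno_e2f, self.ert_ratio)
        raise InvalidInputError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )

    # -- relative risk ------------------------------------------------------
    def rr(
        self,
        population: str,
        bmi: float,
        reference_bmi: Optional[float] = None,
        saturation: Optional[bool] = None,
    ) -> float:
        """Relative risk at a BMI for the chosen population.

        ``reference_bmi`` defaults to the suite's (23).  ``saturation=False``
        disables the cap for the postmenopausal equations (it never applies to
        the premenopausal one).
        """
        from . import models

        ref = self.reference_bmi if reference_bmi is None else float(reference_bmi)
        sat = self.saturation
        if saturation is False:
            sat = SaturationPolicy.none()
        if population == "premeno":
            return models.rr_bmi_premeno(bmi, ref, self.premeno_e2f, self.rr_doubling_premeno)
        if population == "postmeno-nonhrt":
            return models.rr_bmi_postmeno_nonhrt(
                bmi, ref, self.postmeno_e2f, self.rr_doubling_postmeno, sat
            )
        if population == "postmeno-ert":
            return models.rr_bmi_ert_user(
                bmi, self.ert_e2f, self.rr_doubling_postmeno, sat, reference_bmi=ref
            )
        if population == "ert-vs-nonuser":
            return models.rr_ert_vs_nonuser(
                bmi, self.postmeno_e2f, self.ert_e2f, self.rr_doubling_postmeno, sat
            )
        raise InvalidInputError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )

    def rr_function(
        self, population: str, reference_bmi: Optional[float] = None
    ) -> Callable[[float], float]:
        """A BMI -> RR callable, e.g. for population averaging."""
        return lambda bmi: self.rr(population, bmi, reference_bmi=reference_bmi)

    def composed(self, population: str) -> ComposedRiskModel:
        """Closed-form composed RR model for a single-cohort population."""
        if population == "premeno":
            return ComposedRiskModel(
                self.premeno_e2f,
                self.rr_doubling_premeno,
                self.reference_bmi,
                SaturationPolicy.none(),
            )
        if population == "postmeno-nonhrt":
            return ComposedRiskModel(
                self.postmeno_e2f,
                self.rr_doubling_postmeno,
                self.reference_bmi,
                self.saturation,
            )
        if population == "postmeno-ert":
            return ComposedRiskModel(
                self.ert_e2f,
                self.rr_doubling_postmeno,
                self.reference_bmi,
                self.saturation,
            )
        raise InvalidInputError(
            "composed() is defined for premeno, postmeno-nonhrt and postmeno-ert"
        )


def _loglinear(block: Mapping, name: str) -> LogLinearModel:
    try:
        return LogLinearModel(float(block["slope"]), float(block["intercept"]))
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"config block {name!r} needs slope and intercept") from exc


def suite_from_config(cfg: Mapping) -> ModelSuite:
    """Build a ModelSuite from a config dict (see ``data/defaults.yaml``)."""
    m = cfg["model"] if "model" in cfg else cfg
    base = _loglinear(m["postmeno_e2f"], "postmeno_e2f")
    cap_raw = m.get("saturation_cap", None)
    if cap_raw is None:
        sat = SaturationPolicy.none()
    elif cap_raw == "computed":
        # the cap re-derived as the non-user concentration at BMI 30
        sat = SaturationPolicy(cap=base.predict(30.0))
    else:
        sat = SaturationPolicy(cap=float(cap_raw))
    return ModelSuite(
        postmeno_e2f=base,
        premeno_e2f=_loglinear(m["premeno_e2f"], "premeno_e2f"),
        ert_ratio=_loglinear(m["ert_ratio"], "ert_ratio"),
        rr_doubling_postmeno=DoublingRiskModel(float(m["rr_doubling_postmeno"])),
        rr_doubling_premeno=DoublingRiskModel(float(m["rr_doubling_premeno"])),
        saturation=sat,
        reference_bmi=float(m.get("reference_bmi", 23.0)),
    )


def suite_to_config(suite: ModelSuite) -> dict:
    """Serialise a ModelSuite back to the config ``model`` block."""
    return {
        "model": {
            "postmeno_e2f": {
                "slope": suite.postmeno_e2f.slope,
                "intercept": suite.postmeno_e2f.intercept,
            },
            "premeno_e2f": {
                "slope": suite.premeno_e2f.slope,
                "intercept": suite.premeno_e2f.intercept,
            },
            "ert_ratio": {
                "slope": suite.ert_ratio.slope,
                "intercept": suite.ert_ratio.intercept,
            },
            "rr_doubling_postmeno": suite.rr_doubling_postmeno.rr_per_doubling,
            "rr_doubling_premeno": suite.rr_doubling_premeno.rr_per_doubling,
            "saturation_cap": suite.saturation.cap,
            "reference_bmi": suite.reference_bmi,
        }
    }


@lru_cache(maxsize=1)
def default_suite() -> ModelSuite:
    """ModelSuite built from the shipped default config."""
    return suite_from_config(default_config())
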