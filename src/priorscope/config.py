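"""Structured (YAML) run configuration: parsing, validation, defaults.

Configs are strict: unknown keys raise an error naming them rather than
being ignored, every defaulted field is logged with its provenance, and a
parsed config serializes back to an equivalent document (round-trip safe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import FixtureSpec
from .model_core import (
    ChainSettings,
    ConfigurationError,
    FixedResidualVariance,
    InverseGammaPrior,
    NormalPrior,
    PriorSet,
    RegressionData,
    DEFAULT_INTERCEPT_PRIOR,
    DEFAULT_RESIDUAL_PRIOR,
)
from .sensitivity import Alternative, SensitivityPlan
from .simulation import PopulationSpec

__all__ = ["RunConfig", "parse_config"]

log = logging.getLogger("priorscope")

_TOP_KEYS = {
    "command", "dataset", "fixture", "outcome", "predictors", "priors",
    "sensitivity", "chain", "hpd_level", "study", "output_dir", "verbosity",
}
_CHAIN_KEYS = {"iterations", "burn_in", "chains", "seed"}
_PRIOR_KEYS = {"intercept", "coefficients", "residual_variance"}
_NORMAL_KEYS = {"mean", "variance"}
_RESID_KEYS = {"shape", "scale", "proper", "fixed"}
_ALT_KEYS = {"label", "parameter", "prior", "parameters"}
_SENS_KEYS = {"alternatives"}
_STUDY_KEYS = {
    "sample_sizes", "conditions", "replications", "correlation", "population",
}
_POP_KEYS = {
    "predictor_means", "predictor_variances", "intercept",
    "residual_variance", "coefficients",
}
_FIXTURE_KEYS = {
    "n", "sex_probability", "trust_mean", "trust_sd", "intercept",
    "sex_effect", "trust_effect", "residual_sd", "seed",
}
_COMMANDS = {"fit", "sensitivity", "simulate", "fixture"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    if not isinstance(section, dict):
        raise ConfigurationError(f"{where} must be a mapping, got {type(section).__name__}")
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {where}: {unknown}")


def _default(section: dict, key: str, value, where: str):
    if key not in section or section[key] is None:
        log.info("config: defaulted %s.%s = %r", where, key, value)
        return value
    return section[key]


def _normal_prior_dict(raw: dict, where: str) -> dict:
    _check_keys(raw, _NORMAL_KEYS, where)
    if "mean" not in raw or "variance" not in raw:
        raise ConfigurationError(f"{where} needs both 'mean' and 'variance' (a VARIANCE, not an SD)")
    return {"mean": float(raw["mean"]), "variance": float(raw["variance"])}


@dataclass
class RunConfig:
    """Fully validated run configuration with defaults filled.

    Stores plain-Python structures (round-trip friendly); builder methods
    construct the domain objects.
    """

    command: str | None = None
    dataset: str | None = None
    fixture: dict | None = None
    outcome: str | None = None
    predictors: list = field(default_factory=list)
    priors: dict = field(default_factory=dict)
    sensitivity: dict | None = None
    chain: dict = field(default_factory=dict)
    hpd_level: float = 0.90
    study: dict | None = None
    output_dir: str = "priorscope_out"
    verbosity: int = 1

    # -- builders ---------------------------------------------------------

    def chain_settings(self, seed_override: int | None = None) -> ChainSettings:
        seed = self.chain["seed"] if seed_override is None else int(seed_override)
        return ChainSettings(
            total_iterations=self.chain["iterations"],
            burn_in=self.chain["burn_in"],
            n_chains=self.chain["chains"],
            seed=seed,
        )

    def _prior_from_dict(self, raw: dict) -> NormalPrior:
        return NormalPrior(mean=raw["mean"], variance=raw["variance"])

    def residual_prior(self):
        raw = self.priors.get("residual_variance")
        if raw is None:
            return DEFAULT_RESIDUAL_PRIOR
        if "fixed" in raw:
            return FixedResidualVariance(float(raw["fixed"]))
        return InverseGammaPrior(
            shape=float(raw["shape"]),
            scale=float(raw["scale"]),
            proper_flag=bool(raw.get("proper", raw["shape"] > 0 and raw["scale"] > 0)),
        )

    def prior_set(self, label: str = "original") -> PriorSet:
        coeff_section = self.priors.get("coefficients", {})
        missing = [p for p in self.predictors if p not in coeff_section]
        if missing:
            raise ConfigurationError(
                f"missing coefficient prior(s) for predictor(s): {missing}"
            )
        intercept_raw = self.priors.get("intercept")
        intercept = (
            DEFAULT_INTERCEPT_PRIOR
            if intercept_raw is None
            else self._prior_from_dict(intercept_raw)
        )
        return PriorSet(
            intercept=intercept,
            coefficients=tuple(
                self._prior_from_dict(coeff_section[p]) for p in self.predictors
            ),
            residual_variance=self.residual_prior(),
            label=label,
        )

    def sensitivity_plan(self) -> SensitivityPlan:
        if self.sensitivity is None:
            raise ConfigurationError("config has no 'sensitivity' section")
        alternatives = []
        for raw in self.sensitivity["alternatives"]:
            if "parameters" in raw:
                repl = {
                    name: self._prior_from_dict(pr)
                    for name, pr in raw["parameters"].items()
                }
            else:
                repl = {raw["parameter"]: self._prior_from_dict(raw["prior"])}
            alternatives.append(Alternative(label=raw["label"], replacements=repl))
        return SensitivityPlan(
            original=self.prior_set(),
            alternatives=tuple(alternatives),
            level=self.hpd_level,
        )

    def fixture_spec(self, seed_override: int | None = None) -> FixtureSpec:
        raw = dict(self.fixture or {})
        if seed_override is not None:
            raw["seed"] = int(seed_override)
        return FixtureSpec(**raw)

    def population_spec(self) -> PopulationSpec:
        if self.study is None:
            raise ConfigurationError("config has no 'study' section")
        pop = dict(self.study.get("population") or {})
        for key in ("predictor_means", "predictor_variances", "coefficients"):
            if key in pop:
                pop[key] = tuple(float(v) for v in pop[key])
        return PopulationSpec(
            predictor_correlation=float(self.study["correlation"]), **pop
        )

    def load_data(self, seed_override: int | None = None) -> RegressionData:
        from .fixtures import make_cynicism_like_dataset

        if self.dataset is not None:
            if self.outcome is None or not self.predictors:
                raise ConfigurationError(
                    "dataset input requires 'outcome' and 'predictors' columns"
                )
            return RegressionData.from_csv(self.dataset, self.outcome, list(self.predictors))
        if self.fixture is not None:
            return make_cynicism_like_dataset(self.fixture_spec(seed_override))
        raise ConfigurationError("config declares neither 'dataset' nor 'fixture'")

    # -- round trip -------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "command": self.command,
            "dataset": self.dataset,
            "fixture": self.fixture,
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "priors": self.priors,
            "sensitivity": self.sensitivity,
            "chain": dict(self.chain),
            "hpd_level": self.hpd_level,
            "study": self.study,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }
        return {k: v for k, v in out.items() if v is not None}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _validate_study(raw: dict) -> dict:
    _check_keys(raw, _STUDY_KEYS, "study")
    if "correlation" not in raw or raw["correlation"] is None:
        raise ConfigurationError(
            "study.correlation is required: the population predictor correlation "
            "is a design choice with no default"
        )
    out = {
        "sample_sizes": [int(v) for v in _default(raw, "sample_sizes", [25, 100, 1000], "study")],
        "conditions": [int(v) for v in _default(raw, "conditions", list(range(1, 12)), "study")],
        "replications": int(_default(raw, "replications", 500, "study")),
        "correlation": float(raw["correlation"]),
    }
    if raw.get("population") is not None:
        _check_keys(raw["population"], _POP_KEYS, "study.population")
        out["population"] = raw["population"]
    return out


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML config file into a :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    _check_keys(raw, _TOP_KEYS, "config")

    command = raw.get("command")
    if command is not None and command not in _COMMANDS:
        raise ConfigurationError(f"unknown command {command!r}; valid: {sorted(_COMMANDS)}")

    if raw.get("dataset") is not None and raw.get("fixture") is not None:
        raise ConfigurationError("specify exactly one input source: 'dataset' XOR 'fixture'")

    chain_raw = raw.get("chain") or {}
    _check_keys(chain_raw, _CHAIN_KEYS, "chain")
    iterations = int(_default(chain_raw, "iterations", 5000, "chain"))
    chain = {
        "iterations": iterations,
        "burn_in": int(_default(chain_raw, "burn_in", iterations // 2, "chain")),
        "chains": int(_default(chain_raw, "chains", 1, "chain")),
        "seed": int(_default(chain_raw, "seed", 0, "chain")),
    }

    priors_raw = raw.get("priors") or {}
    _check_keys(priors_raw, _PRIOR_KEYS, "priors")
    priors: dict = {}
    if priors_raw.get("intercept") is not None:
        priors["intercept"] = _normal_prior_dict(priors_raw["intercept"], "priors.intercept")
    if priors_raw.get("coefficients") is not None:
        coeffs = priors_raw["coefficients"]
        if not isinstance(coeffs, dict):
            raise ConfigurationError("priors.coefficients must map predictor -> prior")
        priors["coefficients"] = {
            name: _normal_prior_dict(pr, f"priors.coefficients.{name}")
            for name, pr in coeffs.items()
        }
    if priors_raw.get("residual_variance") is not None:
        resid = priors_raw["residual_variance"]
        _check_keys(resid, _RESID_KEYS, "priors.residual_variance")
        if "fixed" in resid and ({"shape", "scale"} & set(resid)):
            raise ConfigurationError(
                "priors.residual_variance: give either 'fixed' or shape/scale, not both"
            )
        if "fixed" not in resid and not {"shape", "scale"} <= set(resid):
            raise ConfigurationError(
                "priors.residual_variance needs 'shape' and 'scale' (or 'fixed')"
            )
        priors["residual_variance"] = resid

    sens = raw.get("sensitivity")
    if sens is not None:
        _check_keys(sens, _SENS_KEYS, "sensitivity")
        alts = sens.get("alternatives") or []
        for i, alt in enumerate(alts):
            _check_keys(alt, _ALT_KEYS, f"sensitivity.alternatives[{i}]")
            if "label" not in alt:
                raise ConfigurationError(f"sensitivity.alternatives[{i}] needs a 'label'")
            has_single = "parameter" in alt and "prior" in alt
            has_multi = "parameters" in alt
            if has_single == has_multi:
                raise ConfigurationError(
                    f"sensitivity.alternatives[{i}] needs either parameter+prior "
                    "(single) or parameters (combined)"
                )
            if has_single:
                _normal_prior_dict(alt["prior"], f"sensitivity.alternatives[{i}].prior")
            else:
                for name, pr in alt["parameters"].items():
                    _normal_prior_dict(pr, f"sensitivity.alternatives[{i}].parameters.{name}")
        sens = {"alternatives": alts}

    fixture = raw.get("fixture")
    if fixture is not None:
        _check_keys(fixture, _FIXTURE_KEYS, "fixture")

    predictors = raw.get("predictors") or []
    if predictors and len(set(predictors)) != len(predictors):
        raise ConfigurationError(f"duplicate predictor names: {predictors}")

    study = _validate_study(raw["study"]) if raw.get("study") is not None else None

    cfg = RunConfig(
        command=command,
        dataset=raw.get("dataset"),
        fixture=fixture,
        outcome=raw.get("outcome"),
        predictors=list(predictors),
        priors=priors,
        sensitivity=sens,
        chain=chain,
        hpd_level=float(_default(raw, "hpd_level", 0.90, "config")),
        study=study,
        output_dir=str(_default(raw, "output_dir", "priorscope_out", "config")),
        verbosity=int(_default(raw, "verbosity", 1, "config")),
    )
    # construct domain objects eagerly where possible so errors surface at parse time
    cfg.chain_settings()
    if cfg.sensitivity is not None and cfg.predictors:
        cfg.sensitivity_plan()
    if cfg.study is not None:
        cfg.population_spec()
    if cfg.fixture is not None:
        cfg.fixture_spec()
    return cfg
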