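"""Configuration files, run manifests, and table writers.

A run configuration is a YAML (or JSON) document with up to three blocks::

    design:
      event_rates: [0.10, 0.15, 0.25, 0.30]   # control first
      n_stage1_per_arm: 20
      n_stage2_per_arm: 124
      threshold_delta: 0.3
      ...
    oc:
      n_replicates: 5000
      master_seed: 1
      ...
    prior:
      shape: 0.001
      rate: 0.001
    mcmc:
      draws: 6000
      burnin: 1000
      seed: 0

Unknown keys are rejected by name; every invariant violation is collected and
reported in one pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .historical import PriorSpec
from .oc import OCConfig, OCResult
from .trial import DesignConfig

__all__ = ["RunConfig", "MCMCSettings", "RunManifest", "load_config", "write_oc_table"]

_DESIGN_KEYS = {
    "event_rates",
    "arm_names",
    "n_stage1_per_arm",
    "n_stage2_per_arm",
    "threshold_delta",
    "surrogate_maturation_weeks",
    "followup_weeks",
    "enrollment_rate",
    "dropout_3yr",
    "alpha_one_sided",
    "n_select",
    "weights",
}
_OC_KEYS = {
    "n_replicates",
    "parameter_mode",
    "fixed_params",
    "master_seed",
    "compute_counterfactual",
    "compute_tests",
}
_PRIOR_KEYS = {"shape", "rate", "on"}
_MCMC_KEYS = {"draws", "burnin", "seed"}


@dataclass(frozen=True)
class MCMCSettings:
    draws: int = 6000
    burnin: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    design: DesignConfig
    oc: OCConfig
    prior: PriorSpec
    mcmc: MCMCSettings


def _check_unknown(block: dict, allowed: set, name: str, problems: list):
    for key in block:
        if key not in allowed:
            problems.append(f"{name}.{key}: unknown key")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigurationError([f"config file is empty: {path}"])
    if not isinstance(raw, dict):
        raise ConfigurationError([f"config root must be a mapping, got {type(raw).__name__}"])

    problems: list[str] = []
    _check_unknown(raw, {"design", "oc", "prior", "mcmc"}, "root", problems)
    design_raw = dict(raw.get("design") or {})
    oc_raw = dict(raw.get("oc") or {})
    prior_raw = dict(raw.get("prior") or {})
    mcmc_raw = dict(raw.get("mcmc") or {})
    _check_unknown(design_raw, _DESIGN_KEYS, "design", problems)
    _check_unknown(oc_raw, _OC_KEYS, "oc", problems)
    _check_unknown(prior_raw, _PRIOR_KEYS, "prior", problems)
    _check_unknown(mcmc_raw, _MCMC_KEYS, "mcmc", problems)
    if problems:
        raise ConfigurationError(problems)

    event_rates = design_raw.pop("event_rates", [0.10, 0.15, 0.25, 0.30])
    arm_names = design_raw.pop("arm_names", None)
    if "weights" in design_raw and design_raw["weights"] is not None:
        design_raw["weights"] = tuple(float(w) for w in design_raw["weights"])
    if "fixed_params" in oc_raw:
        oc_raw["fixed_params"] = tuple(float(v) for v in oc_raw["fixed_params"])

    try:
        design = DesignConfig.from_event_rates(event_rates, arm_names=arm_names, **design_raw)
    except ConfigurationError as err:
        problems += [f"design.{f}" for f in err.fields]
        design = None
    try:
        oc = OCConfig(**oc_raw)
    except ConfigurationError as err:
        problems += [f"oc.{f}" for f in err.fields]
        oc = None
    try:
        prior = PriorSpec(
            scale_prior_shape=float(prior_raw.get("shape", 0.001)),
            scale_prior_rate=float(prior_raw.get("rate", 0.001)),
            scale_prior_on=prior_raw.get("on", "precision"),
        )
    except ValueError as err:
        problems.append(f"prior: {err}")
        prior = None
    mcmc = MCMCSettings(
        draws=int(mcmc_raw.get("draws", 6000)),
        burnin=int(mcmc_raw.get("burnin", 1000)),
        seed=int(mcmc_raw.get("seed", 0)),
    )
    if problems:
        raise ConfigurationError(problems)
    return RunConfig(design=design, oc=oc, prior=prior, mcmc=mcmc)


def write_oc_table(results, path) -> pd.DataFrame:
    """Write OC results as a CSV with a stable column order.

    ``results`` may be an OCResult, a list of OCResult, or a DataFrame (as
    returned by the sweep/scan helpers).  Floats are written at full
    precision so a round-trip read (with pandas ``float_precision=
    "round_trip"``) reproduces values bitwise.
    """
    if isinstance(results, OCResult):
        results = [results]
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        if not results:
            raise ConfigurationError(["results: must be non-empty"])
        df = pd.DataFrame([r.to_dict() for r in results])
    df.to_csv(path, index=False, float_format=None)
    return df


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, version, outputs."""

    command: str
    master_seed: int
    config: dict
    outputs: list = field(default_factory=list)
    package_version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def design_to_dict(design: DesignConfig) -> dict:
    d = asdict(design)
    d["arms"] = [asdict(a) if not isinstance(a, dict) else a for a in design.arms]
    return d
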