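"""Run configuration: YAML/JSON loading with strict validation.

Unknown keys are rejected with the offending field named, so a typo in a
config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .cea import EconParams
from .errors import ConfigurationError
from .lifetable import DEFAULT_LIFE_TABLE, LifeTable, load_life_table_csv
from .nathist import DEFAULT_NATHIST, NatHistParams, StageSurvival
from .screening import (ColonoscopyProfile, Strategy, SurveillancePolicy,
                        TestProfile, blood_strategy, colonoscopy_10y,
                        fit_annual, no_screening)
from .threshold import ScenarioSpec


@dataclass
class RunConfig:
    natural_history: NatHistParams = field(default_factory=NatHistParams)
    life_table: LifeTable = field(default_factory=lambda: DEFAULT_LIFE_TABLE)
    strategies: list[Strategy] = field(default_factory=lambda: [
        no_screening(), fit_annual(), colonoscopy_10y(), blood_strategy()])
    colonoscopy: ColonoscopyProfile = field(default_factory=ColonoscopyProfile)
    econ: EconParams = field(default_factory=EconParams)
    scenario_spec: ScenarioSpec = field(default_factory=ScenarioSpec)
    cohort_n: int = 20_000
    seed: int = 1
    output_dir: Path = Path("results")

    def validate(self) -> None:
        self.natural_history.validate()
        self.econ.validate()
        self.colonoscopy.validate()
        self.scenario_spec.validate()
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ConfigurationError("strategies: duplicate strategy names")
        for s in self.strategies:
            s.validate()
        if self.cohort_n < 1:
            raise ConfigurationError("cohort_n must be >= 1")

    def config_hash(self) -> str:
        """Short digest of the configuration for output provenance headers."""
        def enc(obj: Any):
            if isinstance(obj, LifeTable):
                return {"ages": obj.ages.tolist(), "q": obj.q.tolist()}
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            return obj
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict, context: str, transforms: Optional[dict] = None):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    kwargs = dict(data)
    for key, fn in (transforms or {}).items():
        if key in kwargs:
            kwargs[key] = fn(kwargs[key])
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


def _nathist_from(data: dict) -> NatHistParams:
    transforms = {
        "dwell_nonadv_to_adv": tuple, "dwell_adv_to_preclinical": tuple,
        "sojourn_time": tuple, "stage_fractions_clinical": tuple,
        "stage_fractions_screen": tuple,
        "crc_survival": lambda d: {
            stage: StageSurvival(**sv) for stage, sv in d.items()},
    }
    return _build(NatHistParams, data, "natural_history", transforms)


def _strategy_from(data: dict) -> Strategy:
    data = dict(data)
    context = f"strategies[{data.get('name', '?')}]"
    builtin = data.pop("builtin", None)
    if builtin is not None:
        factory = {"no_screening": no_screening, "fit_annual": fit_annual,
                   "colonoscopy_10y": colonoscopy_10y}.get(builtin)
        if factory is None:
            raise ConfigurationError(f"{context}: unknown builtin '{builtin}'")
        base = factory()
        if data:
            base = replace(base, **data)
        return base
    if "primary_test" in data and isinstance(data["primary_test"], dict):
        data["primary_test"] = _build(TestProfile, data["primary_test"],
                                      f"{context}.primary_test")
    if "surveillance" in data and isinstance(data["surveillance"], dict):
        data["surveillance"] = _build(SurveillancePolicy, data["surveillance"],
                                      f"{context}.surveillance")
    if data.get("interval") in ("inf", ".inf", None) and "interval" in data:
        data["interval"] = math.inf
    return _build(Strategy, data, context)


def config_from_dict(data: dict, base_dir: Path = Path(".")) -> RunConfig:
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"config: unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "natural_history" in data:
        kwargs["natural_history"] = _nathist_from(data["natural_history"])
    if "life_table" in data:
        lt = data["life_table"]
        kwargs["life_table"] = (load_life_table_csv(base_dir / lt)
                                if isinstance(lt, str) else lt)
    if "strategies" in data:
        kwargs["strategies"] = [_strategy_from(s) for s in data["strategies"]]
    if "colonoscopy" in data:
        kwargs["colonoscopy"] = _build(ColonoscopyProfile, data["colonoscopy"],
                                       "colonoscopy")
    if "econ" in data:
        kwargs["econ"] = _build(EconParams, data["econ"], "econ")
    if "scenario_spec" in data:
        kwargs["scenario_spec"] = _build(
            ScenarioSpec, data["scenario_spec"], "scenario_spec",
            {k: tuple for k in ("crc_sens_levels", "aa_sens_levels",
                                "intervals", "costs")})
    for key in ("cohort_n", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "output_dir" in data:
        kwargs["output_dir"] = Path(data["output_dir"])
    config = RunConfig(**kwargs)
    config.validate()
    return config


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    return config_from_dict(data, base_dir=path.parent)
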