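"""Configuration loading and validation.

All model parameters live in one YAML document. A packaged default config
ships with the library; a user file only needs to state the keys it
overrides. Validation errors name the offending key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .excavation import ExcavationSpec
from .survival import (
    DepthCorrectionSpec,
    MeanDepthModel,
    SurvivalCurveSpec,
    SurvivalModelSpec,
)
from .synthetic import GeneratorParams

__all__ = ["ConfigError", "RunConfig", "load_config", "default_config_text"]

log = logging.getLogger("avarescue")


class ConfigError(ValueError):
    """Configuration file missing, unparseable, or violating an invariant."""


@dataclass(frozen=True)
class RunConfig:
    survival: SurvivalModelSpec
    excavation: ExcavationSpec
    generator: GeneratorParams
    scenarios: dict[str, dict[str, float]]
    seed: int = 0
    verbosity: str = "info"


def default_config_text() -> str:
    return (
        resources.files("avarescue").joinpath("data/default_config.yaml").read_text()
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _build(section: str, factory, payload: dict):
    try:
        return factory(**payload)
    except TypeError as err:
        raise ConfigError(f"{section}: unknown or missing key ({err})") from err
    except ValueError as err:
        raise ConfigError(f"{section}: {err}") from err


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``path=None`` (or an empty file) yields the packaged defaults; a user
    file is deep-merged over them, so partial overrides are fine.
    """
    data = yaml.safe_load(default_config_text())
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            user = yaml.safe_load(path.read_text())
        except yaml.YAMLError as err:
            raise ConfigError(f"cannot parse {path}: {err}") from err
        if user is not None:
            if not isinstance(user, dict):
                raise ConfigError(f"{path}: top level must be a mapping")
            data = _merge(data, user)

    surv_cfg = data.get("survival", {})
    survival = SurvivalModelSpec(
        curve=_build(
            "survival.curve",
            SurvivalCurveSpec,
            {
                "breakpoints": tuple(
                    tuple(p) for p in surv_cfg.get("curve", {}).get("breakpoints", [])
                )
            },
        ),
        mean_depth=_build("survival.mean_depth", MeanDepthModel, surv_cfg.get("mean_depth", {})),
        correction=_build(
            "survival.correction",
            DepthCorrectionSpec,
            {"bins": tuple(tuple(b) for b in surv_cfg.get("correction", {}).get("bins", []))},
        ),
    )
    excavation = _build("excavation", ExcavationSpec, data.get("excavation", {}))
    generator = _build("generator", GeneratorParams, data.get("generator", {}))

    scenarios = data.get("scenarios", {})
    if not isinstance(scenarios, dict) or not scenarios:
        raise ConfigError("scenarios: must be a non-empty mapping")
    for name, scn in scenarios.items():
        if not isinstance(scn, dict):
            raise ConfigError(f"scenarios.{name}: must be a mapping")
        for key in ("search1_min", "treatment_min", "search2_min"):
            if key not in scn:
                raise ConfigError(f"scenarios.{name}: missing key {key}")
            if scn[key] < 0:
                raise ConfigError(f"scenarios.{name}.{key}: must be non-negative")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")

    cfg = RunConfig(
        survival=survival,
        excavation=excavation,
        generator=generator,
        scenarios={k: dict(v) for k, v in scenarios.items()},
        seed=seed,
        verbosity=str(data.get("verbosity", "info")),
    )
    log.info("loaded config (seed=%d, scenarios=%s)", cfg.seed, sorted(cfg.scenarios))
    return cfg
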