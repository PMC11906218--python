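"""Run configuration: schema, defaults, file loading and fixtures.

Configs are plain YAML/TOML/JSON mappings validated against a strict
pydantic schema (unknown keys are rejected, values are range-checked) and
filled with the platform defaults: 8 x 8 array of 3.125 nL droplets,
detector precision 0.985, safe gap 1 electrode, 128 x 128 routing grid.
"""

from __future__ import annotations

import json
import logging
import tomllib
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import sipp
from .loading import ChipGeometry

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "generate_fixture"]

logger = logging.getLogger("dmfsort")


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


class _Section(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Section):
    electrode_pitch_um: float = pydantic.Field(250.0, gt=0)
    gap_height_um: float = pydantic.Field(50.0, gt=0)
    array_rows: int = pydantic.Field(8, ge=1)
    array_cols: int = pydantic.Field(8, ge=1)

    def to_geometry(self) -> ChipGeometry:
        return ChipGeometry(
            self.electrode_pitch_um,
            self.gap_height_um,
            self.array_rows,
            self.array_cols,
        )


class LoadingConfig(_Section):
    lambda_target: float = pydantic.Field(1.0, gt=0)
    ratio: float = pydantic.Field(1.0, gt=0)


class ClassifierConfig(_Section):
    precision: float = pydantic.Field(0.985, ge=0, le=1)
    precision_background: float | None = pydantic.Field(None, ge=0, le=1)


class PolicyConfig(_Section):
    n_droplets: int = pydantic.Field(64, ge=1)
    n_cycles: int = pydantic.Field(3, ge=1)
    # fate overrides by predicted label, e.g. {"empty": "retain"}
    fates: dict[
        Literal["empty", "target_only", "background_only", "mixed"],
        Literal["collect", "waste", "retain"],
    ] = pydantic.Field(default_factory=dict)


class PlannerConfig(_Section):
    safe_gap: int = pydantic.Field(1, ge=0)
    grid_rows: int = pydantic.Field(128, ge=1)
    grid_cols: int = pydantic.Field(128, ge=1)
    zone_spacing: int = pydantic.Field(2, ge=1)


class RunConfig(_Section):
    """Validated, fully-defaulted configuration of one run."""

    experiment: Literal[
        "proportions", "precision_sweep", "ratio_sweep", "cycle_study", "presort"
    ] = "cycle_study"
    geometry: GeometryConfig = pydantic.Field(default_factory=GeometryConfig)
    loading: LoadingConfig = pydantic.Field(default_factory=LoadingConfig)
    classifier: ClassifierConfig = pydantic.Field(default_factory=ClassifierConfig)
    policy: PolicyConfig = pydantic.Field(default_factory=PolicyConfig)
    planner: PlannerConfig = pydantic.Field(default_factory=PlannerConfig)
    n_replicates: int = pydantic.Field(10, ge=1)
    root_seed: int = pydantic.Field(0, ge=0)
    out: str | None = None
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


_LOADERS = {
    ".yaml": lambda text: yaml.safe_load(text),
    ".yml": lambda text: yaml.safe_load(text),
    ".json": lambda text: json.loads(text) if text.strip() else None,
    ".toml": lambda text: tomllib.loads(text),
}


def load_config(path) -> RunConfig:
    """Load and validate a config file; empty files mean all defaults."""
    path = Path(path)
    loader = _LOADERS.get(path.suffix.lower())
    if loader is None:
        raise ConfigError(f"unsupported config dialect {path.suffix!r}")
    raw = loader(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config value at {key!r}: {first['msg']}") from exc
    logger.info("effective config: %s", json.dumps(dump_config(cfg), sort_keys=True))
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Plain-dict form of a config; load(dump(x)) == x."""
    return cfg.model_dump(mode="json")


def generate_fixture(kind: str, params: dict | None, seed: int, path) -> Path:
    """Write a deterministic synthetic input file.

    ``occupancy_csv``
        Per-droplet Poisson object counts (columns droplet_id, n_objects),
        emulating counts read off a split droplet array.  Params: ``lam``
        (default 1.2), ``n`` (default 64).
    ``planner_instance``
        Random routing instance JSON with safe start/goal gaps.  Params:
        ``rows``, ``cols`` (default 16), ``n_droplets`` (default 6),
        ``safe_gap`` (default 1).
    ``sorting_config``
        A canned cycle-study YAML config; params override top-level keys.
    """
    params = dict(params or {})
    path = Path(path)
    rng = np.random.default_rng(seed)
    if kind == "occupancy_csv":
        lam = float(params.pop("lam", 1.2))
        n = int(params.pop("n", 64))
        _reject_unknown(kind, params)
        counts = rng.poisson(lam, n)
        pd.DataFrame({"droplet_id": np.arange(n), "n_objects": counts}).to_csv(
            path, index=False
        )
    elif kind == "planner_instance":
        rows = int(params.pop("rows", 16))
        cols = int(params.pop("cols", 16))
        n_droplets = int(params.pop("n_droplets", 6))
        safe_gap = int(params.pop("safe_gap", 1))
        _reject_unknown(kind, params)
        grid, request = sipp.random_instance(rng, rows, cols, n_droplets, safe_gap)
        payload = {
            "rows": grid.rows,
            "cols": grid.cols,
            "safe_gap": request.safe_gap,
            "droplets": [
                {
                    "id": d,
                    "start": list(request.starts[d]),
                    "goal": list(request.goals[d]),
                }
                for d in sorted(request.starts)
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif kind == "sorting_config":
        cfg = RunConfig.model_validate({"experiment": "cycle_study", **params})
        cfg = cfg.model_copy(update={"root_seed": seed})
        path.write_text(yaml.safe_dump(dump_config(cfg), sort_keys=True))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path


def _reject_unknown(kind: str, leftover: dict) -> None:
    if leftover:
        raise ValueError(f"unknown {kind} fixture params: {sorted(leftover)}")
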