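"""Structured run configuration, CSV/dot writers, and the run log.

Every experiment run is reproducible from a single YAML config (plus a
master seed); ``write_outputs`` emits deterministic files so that two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .dag import CausalDAG, NodeRoles, build_dag

__all__ = ["ConfigError", "RunConfig", "parse_config", "parse_dag_block", "write_outputs"]

COMMANDS = (
    "simulate",
    "classify",
    "grid",
    "attenuation",
    "interaction",
    "example-preeclampsia",
)


class ConfigError(ValueError):
    """Malformed or unknown configuration."""


@dataclass
class RunConfig:
    """Validated configuration for one command run."""

    command: str
    template: str = "fig1b"
    coefficients: dict = field(default_factory=dict)  # "E->D": value
    noise_sds: dict = field(default_factory=dict)
    interaction: Optional[float] = None
    adjust: tuple = ()
    edges: tuple = ()            # custom DAG for `classify`, "A -> B" strings
    roles: dict = field(default_factory=dict)
    n: int = 200_000
    replicates: int = 20
    master_seed: int = 20230210
    noise_grid: tuple = (0.0, 0.1, 0.25, 0.5, 1.0)
    out_dir: str = "effectpath_out"
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ConfigError(
                f"unknown command {self.command!r}; choose from {COMMANDS}"
            )
        for name, value in (("n", self.n), ("replicates", self.replicates)):
            if not isinstance(value, int) or value < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not isinstance(self.master_seed, int):
            raise ConfigError("master_seed must be an integer")
        self.adjust = tuple(self.adjust)
        self.edges = tuple(self.edges)
        self.noise_grid = tuple(float(x) for x in self.noise_grid)


def parse_config(
    path: Optional[str] = None, overrides: Optional[Mapping] = None
) -> RunConfig:
    """Load a YAML config file and apply flag overrides.

    Unknown keys are rejected by name rather than silently ignored -- a
    misspelled key would otherwise change the experiment without warning.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("the config file must contain a mapping")
        raw.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            raw[key] = value
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "command" not in raw:
        raise ConfigError("a command is required")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def parse_dag_block(edges, roles_mapping: Mapping) -> tuple:
    """Parse the config DAG block: "A -> B" edge strings plus a roles map."""
    parsed = []
    for item in edges:
        parent, sep, child = str(item).partition("->")
        if not sep or not parent.strip() or not child.strip():
            raise ConfigError(f"malformed edge {item!r}; expected 'A -> B'")
        parsed.append((parent.strip(), child.strip()))
    dag = build_dag(parsed)
    known = {
        "exposure",
        "outcome",
        "selection",
        "risk_factors_pre",
        "risk_factors_measured",
        "confounders",
        "measured",
    }
    unknown = set(roles_mapping) - known
    if unknown:
        raise ConfigError(f"unknown role keys: {sorted(unknown)}")
    kwargs = dict(roles_mapping)
    for key in ("risk_factors_pre", "risk_factors_measured", "confounders", "measured"):
        if key in kwargs:
            kwargs[key] = frozenset(kwargs[key])
    roles = NodeRoles(**kwargs)
    roles.validate(dag)
    return dag, roles


def write_outputs(results: Mapping, config: RunConfig, out_dir: Optional[str] = None):
    """Write result tables/texts plus a run log echoing the configuration.

    ``results`` maps file stems to DataFrames (written as CSV), strings
    (written as text), or JSON-serializable mappings.  The run log contains
    the full effective configuration, the master seed, and the package
    version -- everything needed to reproduce the run exactly.  No
    timestamps are written, so identical runs give identical files.
    """
    out = Path(out_dir or config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {out}: {exc}") from exc
    written = []
    for stem, payload in results.items():
        if isinstance(payload, pd.DataFrame):
            target = out / f"{stem}.csv"
            payload.to_csv(target, index=False, float_format="%.12g")
        elif isinstance(payload, str):
            target = out / f"{stem}.txt"
            target.write_text(payload + "\n")
        else:
            target = out / f"{stem}.json"
            target.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(target)
    log = {
        "package": "effectpath",
        "version": __version__,
        "config": asdict(config),
        "outputs": sorted(p.name for p in written),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written.append(log_path)
    return written
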