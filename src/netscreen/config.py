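"""Run configuration: YAML file + flag merging, effective-config logging."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import yaml

from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config_file", "resolve_config"]


@dataclass
class RunConfig:
    """Effective, fully serializable configuration of one command run."""

    command: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"command": self.command, **self.params}

    def __getitem__(self, key: str):
        return self.params[key]


def load_config_file(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping of option -> value")
    # YAML 1.1 parses a bare `null` key as None; we use it as an option name
    return {("null" if k is None else k): v for k, v in data.items()}


def resolve_config(ctx: click.Context, config_path: str | None, params: dict) -> RunConfig:
    """Merge a YAML config under the CLI flags.

    Explicit command-line flags win; unknown config keys are rejected by
    name.  The effective configuration is logged at INFO level.
    """
    params = dict(params)
    if config_path:
        file_cfg = load_config_file(config_path)
        unknown = sorted(set(file_cfg) - set(params))
        if unknown:
            raise click.UsageError(f"unknown config key {unknown[0]!r} in {config_path}")
        for key, value in file_cfg.items():
            if ctx.get_parameter_source(key) != click.core.ParameterSource.COMMANDLINE:
                params[key] = value
    cfg = RunConfig(command=ctx.command.name, params=params)
    logger.info("effective config: %s", cfg.to_dict())
    return cfg
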