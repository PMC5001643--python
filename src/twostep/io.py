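"""Configuration loading and run manifests.

Configs are YAML mappings validated against a small schema of known
keys with documented defaults; every artifact-producing command writes
a JSON manifest recording the resolved configuration, master seed and
output paths, so any run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__

__all__ = ["ConfigError", "load_config", "RunManifest", "get_logger"]

logger = logging.getLogger("twostep")

# key -> (default, validator); validators raise ConfigError with the
# offending field name.
_SCHEMA = {
    "task": ("daw", lambda v: isinstance(v, str)),
    "n_trials": (None, lambda v: v is None or (isinstance(v, int) and v > 0)),
    "n_reps": (1000, lambda v: isinstance(v, int) and v > 0),
    "seed": (0, lambda v: isinstance(v, int)),
    "lam": (0.5, lambda v: 0 <= float(v) <= 1),
    "alpha": (0.5, lambda v: 0 <= float(v) <= 1),
    "beta": (5.0, lambda v: float(v) >= 0),
    "w": (0.5, lambda v: 0 <= float(v) <= 1),
    "pi": (0.0, lambda v: True),
    "rho": (0.0, lambda v: True),
    "w_grid": (
        [i / 10 for i in range(11)],
        lambda v: isinstance(v, list) and len(v) >= 2,
    ),
    "beta_grid": (None, lambda v: v is None or isinstance(v, list)),
    "alpha_grid": (None, lambda v: v is None or isinstance(v, list)),
    "sigmas": (
        [0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5],
        lambda v: isinstance(v, list),
    ),
    "n_subjects": (10, lambda v: isinstance(v, int) and v >= 0),
    "n_agents": (200, lambda v: isinstance(v, int) and v > 0),
    "n_restarts": (25, lambda v: isinstance(v, int) and v > 0),
    "scheme": ("median", lambda v: v in ("fixed", "uniform", "median")),
    "timeout_rate": (0.0, lambda v: 0 <= float(v) < 1),
    "belief_mode": (
        None,
        lambda v: v in (None, "known", "one_shot", "three_structure"),
    ),
}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML config, resolving all defaults.

    Unknown keys are rejected with a field-level message.  ``overrides``
    (e.g. command-line options) take precedence over the file.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    resolved = {}
    for key, (default, check) in _SCHEMA.items():
        value = raw.get(key, default)
        try:
            ok = check(value)
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ConfigError(f"invalid value for {key!r}: {value!r}")
        resolved[key] = value
    if len(resolved["w_grid"]) != 11:
        logger.warning(
            "w_grid has %d points; the standard analysis uses 11",
            len(resolved["w_grid"]),
        )
    return resolved


@dataclass
class RunManifest:
    """Provenance record written alongside every command's outputs."""

    command: str
    config: dict
    seed: int
    outputs: list = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        return self

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def get_logger(verbosity: int = 0) -> logging.Logger:
    """Package logger writing to standard error."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbosity > 1 else
                    logging.INFO if verbosity == 1 else logging.WARNING)
    return logger
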