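"""Flat key/value configuration, logging and seeded randomness.

Precedence for any setting is CLI flag > config file > built-in default;
:func:`resolve` implements it. Every stochastic operation in the package
takes an explicit integer seed; :func:`derive_seed` maps a single global
seed plus a stream index to independent child seeds so that adding a new
consumer never perturbs existing streams.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError

log = logging.getLogger("amphihap")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


def load_config(path) -> dict[str, Any]:
    """Load a flat YAML key/value document."""
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if doc is None:
        return {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: config must be a mapping, got {type(doc).__name__}")
    for key, value in doc.items():
        if isinstance(value, (dict, list)):
            raise ConfigError(f"{path}: config key {key!r} must be a scalar")
    return dict(doc)


def resolve(cli_value, config: Mapping[str, Any], key: str, default):
    """CLI > config > default."""
    if cli_value is not None:
        return cli_value
    if key in config:
        return config[key]
    return default


def derive_seed(master: int, stream: int) -> int:
    """A child seed (< 2**31) for stream index *stream* under *master*."""
    ss = np.random.SeedSequence([int(master), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, stream))


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
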