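"""Configuration loading.

All study constants — screening thresholds, advice rules, health-space
options, reference-group moments and the observed outcome tables — ship as
declarative YAML (``data/defaults.yaml``) so that every threshold the
pipeline applies is inspectable and overridable without code changes.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["load_defaults", "load_config", "merge_config"]


@lru_cache(maxsize=1)
def _defaults_raw() -> dict:
    text = resources.files("nutrispace.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_defaults() -> dict:
    """Return a deep copy of the shipped default configuration."""
    return copy.deepcopy(_defaults_raw())


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (override wins)."""
    out = dict(copy.deepcopy(base))
    for key, value in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load the default config, optionally merged with a user YAML file."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    return cfg
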