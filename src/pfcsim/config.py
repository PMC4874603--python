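"""Shipped model configuration (parameter tables as structured YAML)."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

_DEFAULT_CACHE: dict | None = None


def default_config() -> dict:
    """Return a deep copy of the shipped default configuration.

    The configuration bundles the intrinsic-parameter distributions per cell
    type, the laminar cell-type composition, the pairwise connection table,
    synaptic kinetics, short-term-plasticity classes and their assignment
    map, wiring rules and the default background currents.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        with resources.files("pfcsim.data").joinpath("default.yaml").open() as fh:
            _DEFAULT_CACHE = yaml.safe_load(fh)
    return copy.deepcopy(_DEFAULT_CACHE)


def load_config(path: str | Path | None = None) -> dict:
    """Load a configuration file, falling back to the shipped default.

    A user file only needs the keys it overrides; top-level sections are
    merged shallowly into the default.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
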