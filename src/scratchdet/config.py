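"""YAML config loading for the command-line workflow.

A config file is a flat mapping with up to three sections — ``synthetic``,
``model``, ``training`` — whose keys mirror the corresponding dataclass
fields.  Unknown keys fail loudly rather than being ignored.
"""

from __future__ import annotations

import dataclasses

import yaml

from .model import CRNNConfig
from .synthetic import SyntheticConfig
from .training import TrainingConfig

__all__ = ["load_config", "build_section"]

_SECTIONS = {
    "synthetic": SyntheticConfig,
    "model": CRNNConfig,
    "training": TrainingConfig,
}


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    return data


def build_section(data: dict, section: str, **overrides):
    """Instantiate the dataclass for ``section`` from the config mapping,
    applying keyword overrides last (tuples accepted for list values)."""
    cls = _SECTIONS[section]
    kwargs = dict(data.get(section) or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    if unknown := set(kwargs) - valid:
        raise ValueError(f"unknown {section} keys: {sorted(unknown)}")
    kwargs.update(overrides)
    for key, val in kwargs.items():
        if isinstance(val, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in val)
    return cls(**kwargs)
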