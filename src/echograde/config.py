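"""YAML experiment-configuration files.

A config file is a flat mapping per section, e.g.::

    roi_net:   {input_size: 96, base_filters: 8}
    grade_net: {input_size: 96, base_filters: 8, fc_sizes: [64, 32, 5]}
    train:     {epochs: 10, learning_rate: 0.05, seed: 0}
    chan_vese: {alpha: 1.0, max_iter: 50}
    augment:   {kind: roi, max_shift: 20}

Unknown keys raise rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .augment import AugPolicy
from .grade_net import GNetConfig
from .refine import ChanVeseParams
from .roi_net import RoiNetConfig, TrainConfig

SECTIONS = {
    "roi_net": RoiNetConfig,
    "grade_net": GNetConfig,
    "train": TrainConfig,
    "chan_vese": ChanVeseParams,
    "augment": AugPolicy,
}

__all__ = ["load_config", "from_mapping", "SECTIONS"]


def from_mapping(cls, mapping: dict):
    """Build a config dataclass from a mapping, validating key names."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> dict:
    """Load a YAML file into instantiated config objects per section."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {name: from_mapping(SECTIONS[name], section or {})
            for name, section in raw.items()}
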