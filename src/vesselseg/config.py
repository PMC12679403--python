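"""YAML run-configuration loading with schema validation and seed fan-out.

A single YAML file can carry ``network:``, ``train:``, ``loss:``,
``sampler:``, ``augmentation:`` and ``phantom:`` sections; each maps onto
the corresponding dataclass. Unknown keys are rejected by name so typos
fail loudly. A single global seed fans out to per-module seeds through
``numpy``'s SeedSequence splitter, keeping modules independently
reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .losses import LossSpec
from .nn.unet import NetworkConfig
from .patches import AugmentationConfig, SamplerPolicy
from .phantom import PhantomConfig
from .train import TrainConfig

__all__ = ["load_yaml", "build_dataclass", "split_seed",
           "train_config_from_dict", "network_config_from_dict",
           "phantom_config_from_dict"]

# fan-out order is part of the format: changing it changes reproducibility
SEED_STREAMS = ("phantom", "sampler", "network_init", "train", "inference")


def split_seed(global_seed: int) -> dict[str, int]:
    """Derive one independent 31-bit seed per module from a global seed."""
    seq = np.random.SeedSequence(global_seed)
    children = seq.spawn(len(SEED_STREAMS))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(SEED_STREAMS, children)}


def build_dataclass(cls, data: dict, section: str = ""):
    """Instantiate ``cls`` from a dict, rejecting unknown keys by name."""
    fields = set(cls.__dataclass_fields__)
    unknown = set(data) - fields
    if unknown:
        where = f" in section {section!r}" if section else ""
        raise ValueError(f"unknown config key(s){where}: "
                         f"{', '.join(sorted(unknown))}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in data.items()}
    return cls(**coerced)


def load_yaml(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def train_config_from_dict(data: dict) -> TrainConfig:
    data = dict(data)
    loss = build_dataclass(LossSpec, data.pop("loss", {}), "loss")
    sampler = build_dataclass(SamplerPolicy, data.pop("sampler", {}),
                              "sampler")
    aug_data = data.pop("augmentation", {})
    augmentation = (None if aug_data is None
                    else build_dataclass(AugmentationConfig, aug_data,
                                         "augmentation"))
    cfg = build_dataclass(TrainConfig, data, "train")
    cfg.loss = loss
    cfg.sampler = sampler
    cfg.augmentation = augmentation
    return cfg


def network_config_from_dict(data: dict) -> NetworkConfig:
    return build_dataclass(NetworkConfig, data, "network")


def phantom_config_from_dict(data: dict) -> PhantomConfig:
    return build_dataclass(PhantomConfig, data, "phantom")
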