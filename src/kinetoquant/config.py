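"""YAML/JSON run configuration for the command-line interface.

A config file declares what the image files cannot: the channel-role
map, the pixel size at acquisition, crop geometry and per-image
condition labels. Example::

    pixel_size_um: 0.1075
    crop_side_px: 250
    channel_roles: {0: dna, 1: reference_kt, 2: measure_1}
    channel_classes: {measure_1: corrected}
    control_label: ctrl
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    pixel_size_um: float
    channel_roles: dict[int, str]
    crop_side_px: int = 250
    n_spots: int = 20
    roi_diameter_px: int = 8
    bg_size_px: int = 52
    tophat_radius_px: int = 5
    channel_classes: dict[str, str] = field(default_factory=dict)
    control_label: str | None = None
    condition_labels: dict[str, str] = field(default_factory=dict)  # filename -> label


def load_config(path) -> RunConfig:
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    if "pixel_size_um" not in data or "channel_roles" not in data:
        raise ValueError("config must declare pixel_size_um and channel_roles")
    data["channel_roles"] = {int(k): str(v) for k, v in data["channel_roles"].items()}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
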