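"""Operating-point configuration for the three overlay (OVL) modes.

The deployed system exposes three operational validity levels built from two
model outputs: a segmentation probability map and scored detection boxes.
OVL1 thresholds the map at a sensitive (low) cut-off for wide-field
retrieval, OVL2 adds detector boxes on top of OVL1 for signet-ring cell
coverage, and OVL3 uses a specific (high) cut-off — the ROC Youden
cut-off — for confirmation at high magnification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Deployed segmentation threshold for OVL1/OVL2 (sensitive retrieval).
DEFAULT_SEG_THRESHOLD_LOW = 0.899
#: Deployed segmentation threshold for OVL3 (the ROC cut-off point).
DEFAULT_SEG_THRESHOLD_HIGH = 0.977
#: Deployed detector score threshold for OVL2.
DEFAULT_DET_THRESHOLD = 0.8


@dataclass(frozen=True)
class OVLConfig:
    """Thresholds and rendering parameters for OVL construction.

    ``overlay_opacity`` is the weight of the highlight color in the
    composite: 0.75 renders a "25% transparent" dark-red overlay in the
    sense that 25% of the underlying pixel shows through. Both the color
    value and the compositing convention are configurable because neither
    is pinned down beyond "dark red, 25% transparent".
    """

    seg_threshold_low: float = DEFAULT_SEG_THRESHOLD_LOW
    seg_threshold_high: float = DEFAULT_SEG_THRESHOLD_HIGH
    det_threshold: float = DEFAULT_DET_THRESHOLD
    overlay_color: tuple[int, int, int] = (139, 0, 0)
    overlay_opacity: float = 0.75
    #: Minimum true pixels for a sample-level positive call (1 = any ROI
    #: pixel flags the sample; larger values model wide-field perception).
    min_positive_pixels: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.seg_threshold_low <= self.seg_threshold_high <= 1.0:
            raise ValueError("require 0 <= seg_threshold_low <= seg_threshold_high <= 1")
        if not 0.0 <= self.det_threshold <= 1.0:
            raise ValueError("det_threshold must lie in [0, 1]")
        if not 0.0 <= self.overlay_opacity <= 1.0:
            raise ValueError("overlay_opacity must lie in [0, 1]")
        if len(self.overlay_color) != 3 or not all(
            0 <= int(c) <= 255 for c in self.overlay_color
        ):
            raise ValueError("overlay_color must be an RGB triple in 0..255")
        object.__setattr__(self, "overlay_color", tuple(int(c) for c in self.overlay_color))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["overlay_color"] = list(self.overlay_color)
        return d


def load_config(path: str | Path) -> OVLConfig:
    """Load an :class:`OVLConfig` from a JSON or YAML file.

    The file holds a flat mapping of OVLConfig fields; unknown keys are
    rejected so that typos do not silently fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = set(OVLConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "overlay_color" in data:
        data["overlay_color"] = tuple(data["overlay_color"])
    return OVLConfig(**data)


def save_config(cfg: OVLConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
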