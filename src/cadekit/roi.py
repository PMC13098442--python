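"""Binary ROI construction and diagnostic-support overlay rendering.

An ROI is extracted from the probability map by strict thresholding
(value > t), optionally merged with rasterized detector boxes by logical
OR, and composited onto the H&E image as a semi-transparent highlight.
Three operating modes are provided:

========  ==============================  =====================
mode      segmentation threshold          detector boxes
========  ==============================  =====================
OVL1      low (sensitive retrieval)       no
OVL2      low                             yes (score > det thr.)
OVL3      high (specific confirmation)    no
========  ==============================  =====================

With default thresholds the three masks nest: OVL3 <= OVL1 <= OVL2.
No morphological post-processing (hole filling, small-component removal)
is applied: the displayed ROI is exactly the thresholded set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import OVLConfig
from .types import BinaryMask, DetectionSet, ProbabilityMap

OVL_MODES = ("OVL1", "OVL2", "OVL3")


@dataclass(frozen=True)
class OVLMode:
    """One overlay operating mode: which threshold applies and whether
    detector boxes are merged in."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in OVL_MODES:
            raise ValueError(f"unknown OVL mode {self.name!r}; expected one of {OVL_MODES}")

    @property
    def uses_detector(self) -> bool:
        return self.name == "OVL2"

    @property
    def seg_threshold_key(self) -> str:
        return "seg_threshold_high" if self.name == "OVL3" else "seg_threshold_low"


def binarize(pmap: ProbabilityMap, threshold: float) -> BinaryMask:
    """Threshold a probability map: true exactly where value > threshold.

    The inequality is strict, so ties at the threshold are excluded and a
    threshold of 1.0 yields an all-false mask.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return BinaryMask(pmap.values > threshold, role="roi")


def boxes_to_mask(dets: DetectionSet, threshold: float, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize detector boxes with score > threshold as filled rectangles.

    Boxes are half-open [x, x+w) x [y, y+h), clipped to ``shape``. An
    empty detection set yields an empty mask.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    for b in dets:
        if b.score > threshold:
            y0, y1 = max(b.y, 0), min(b.y + b.height, h)
            x0, x1 = max(b.x, 0), min(b.x + b.width, w)
            if y0 < y1 and x0 < x1:
                out[y0:y1, x0:x1] = True
    return BinaryMask(out, role="roi")


def integrate_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixel-wise logical OR of two ROIs (the integrated ROI)."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.values | b.values, role="roi")


def build_ovl(
    pmap: ProbabilityMap,
    dets: Optional[DetectionSet],
    mode: OVLMode | str,
    cfg: OVLConfig = OVLConfig(),
) -> BinaryMask:
    """Construct the ROI for one overlay mode.

    OVL1 = binarize(map, low); OVL2 = OVL1 OR boxes(score > det threshold);
    OVL3 = binarize(map, high). Detections are required for OVL2 only.
    """
    if isinstance(mode, str):
        mode = OVLMode(mode)
    seg = binarize(pmap, getattr(cfg, mode.seg_threshold_key))
    if not mode.uses_detector:
        return seg
    if dets is None:
        raise ValueError("OVL2 requires a DetectionSet")
    det_mask = boxes_to_mask(dets, cfg.det_threshold, pmap.shape)
    return integrate_masks(seg, det_mask)


def render_overlay(image: np.ndarray, roi: BinaryMask, cfg: OVLConfig = OVLConfig()) -> np.ndarray:
    """Composite the ROI onto an RGB image as a semi-transparent highlight.

    On-ROI pixels become ``(1 - opacity) * image + opacity * color``,
    rounded half-up per channel; off-ROI pixels are returned bit-exact.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3) RGB")
    if image.shape[:2] != roi.shape:
        raise ValueError(f"image shape {image.shape[:2]} != roi shape {roi.shape}")
    out = image.astype(np.uint8).copy()
    if roi.count() == 0:
        return out
    alpha = cfg.overlay_opacity
    color = np.array(cfg.overlay_color, dtype=float)
    blended = (1.0 - alpha) * image[roi.values].astype(float) + alpha * color
    out[roi.values] = np.floor(blended + 0.5).astype(np.uint8)
    return out
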