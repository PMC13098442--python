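"""Domain types for the CADe post-inference pipeline.

The unit of analysis throughout is the *sample*: one biopsy tissue fragment
on a slide. A whole-slide image (WSI) usually carries several fragments, so
one ``wsi_id`` may own several :class:`SampleRecord` objects.

Coordinate convention: rasters are 0-based, row-major, origin at the
top-left; detection boxes are half-open ``[x, x+width) x [y, y+height)`` in
pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: Group-level biopsy classification: G1 benign ... G5 malignancy.
GRADES = ("G1", "G2", "G3", "G4", "G5")

#: Histological subtypes handled by the pipeline. ``benign`` covers
#: non-neoplastic mucosa; ``adenoma`` covers tubular adenoma with low-grade
#: dysplasia (graded G2/G3); the remainder are malignant subtypes.
SUBTYPES = (
    "benign",
    "adenoma",
    "Tub_well",
    "Tub_mod",
    "Pap",
    "Por_solid",
    "Por_nonsolid",
    "Sig",
    "Muc",
    "MALT",
    "DLBCL",
    "GIST",
)

MASK_ROLES = ("roi", "tissue", "ground_truth")


@dataclass(frozen=True)
class ProbabilityMap:
    """Pixel-wise malignancy probability map from a segmentation model.

    Parameters
    ----------
    values
        2-D float array with every entry in [0, 1].
    pixel_size_um
        Physical pixel pitch in microns. The native scan resolution is
        0.23 um/px (40x equivalent); downsampled maps carry the
        correspondingly larger pitch.
    sample_id
        Identifier of the tissue fragment the map belongs to.
    """

    values: np.ndarray
    pixel_size_um: float = 0.23
    sample_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("probability map must be a non-empty 2-D grid")
        if np.isnan(values).any() or values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("probability values must lie in [0, 1]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Box:
    """One scored detection box, half-open in both axes."""

    x: int
    y: int
    width: int
    height: int
    score: float

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("box width and height must be >= 1 px")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("box score must lie in [0, 1]")


@dataclass(frozen=True)
class DetectionSet:
    """Scored rectangular boxes from the object detector (signet-ring cell
    candidates), all living in a common pixel frame."""

    boxes: tuple[Box, ...]
    sample_id: str = ""
    frame: Optional[tuple[int, int]] = None  # (height, width)

    def __init__(
        self,
        boxes: Sequence[Box | tuple] = (),
        sample_id: str = "",
        frame: Optional[tuple[int, int]] = None,
    ) -> None:
        norm = tuple(b if isinstance(b, Box) else Box(*b) for b in boxes)
        if frame is not None:
            h, w = frame
            for b in norm:
                if b.x < 0 or b.y < 0 or b.x + b.width > w or b.y + b.height > h:
                    raise ValueError(
                        f"box {b} exceeds frame {frame} "
                        "(boxes must lie within the pixel grid)"
                    )
        object.__setattr__(self, "boxes", norm)
        object.__setattr__(self, "sample_id", sample_id)
        object.__setattr__(self, "frame", tuple(frame) if frame is not None else None)

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[Box]:
        return iter(self.boxes)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster with a declared role (roi, tissue, ground_truth)."""

    values: np.ndarray
    role: str = "roi"

    def __post_init__(self) -> None:
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "values", values.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        """Number of true pixels."""
        return int(self.values.sum())


@dataclass
class SampleRecord:
    """One biopsy tissue fragment: the independent unit of analysis.

    Malignant grades (G4/G5) must carry a non-empty ground-truth lesion
    mask; benign fragments have none.
    """

    sample_id: str
    wsi_id: str
    grade: str
    subtype: str
    tissue_mask: Optional[BinaryMask] = None
    gt_mask: Optional[BinaryMask] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; expected one of {GRADES}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.grade in ("G4", "G5"):
            if self.gt_mask is None or self.gt_mask.count() == 0:
                raise ValueError(
                    f"sample {self.sample_id}: malignant grade {self.grade} "
                    "requires a non-empty ground-truth mask"
                )
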