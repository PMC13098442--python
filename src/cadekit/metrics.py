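"""Sample-level diagnostic evaluation of OVL outputs.

Covers the confusion-matrix metrics (sensitivity, specificity, positive
and negative predictive value), the grade-to-binary mapping (G1-G3 benign,
G4-G5 malignant), per-subtype sensitivity, the detectability
stratification (lesions under 30% of the tissue area are "likely to be
overlooked"), and false-positive area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import BinaryMask, SampleRecord

#: Lesion/tissue area fraction below which a sample is "likely to be
#: overlooked" (strict less-than).
OVERLOOK_AREA_FRACTION = 0.30


def grade_to_binary(grade: str) -> str:
    """Map a G1-G5 group call to the benign/malignant dichotomy."""
    if grade in ("G1", "G2", "G3"):
        return "benign"
    if grade in ("G4", "G5"):
        return "malignant"
    raise ValueError(f"unknown grade {grade!r}")


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the four derived ratios.

    Ratios with a zero denominator are ``None`` (absent), never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def percent(x: Optional[float], decimals: int = 1) -> Optional[float]:
    """Format a proportion as a percentage, rounded half-up (table style)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


def ovl_sample_call(ovl: BinaryMask, min_positive_pixels: int = 1) -> str:
    """Sample-level call from an ROI mask: positive iff it carries at least
    ``min_positive_pixels`` true pixels.

    The default of 1 means any visible ROI flags the sample; larger values
    model the wide-field setting where tiny ROIs go unnoticed at low
    magnification.
    """
    return "positive" if ovl.count() >= min_positive_pixels else "negative"


def evaluate(calls: Mapping[str, str], labels: Mapping[str, str]) -> EvalMetrics:
    """Confusion counts and ratios for per-sample calls against truth.

    ``calls`` maps sample_id to positive|negative, ``labels`` to
    benign|malignant; the two must cover the same sample set.
    """
    if set(calls) != set(labels):
        only_c = set(calls) - set(labels)
        only_l = set(labels) - set(calls)
        raise ValueError(f"sample sets differ (calls only: {sorted(only_c)[:5]}, labels only: {sorted(only_l)[:5]})")
    tp = fp = tn = fn = 0
    for sid, call in calls.items():
        if call not in ("positive", "negative"):
            raise ValueError(f"call for {sid} must be positive|negative, got {call!r}")
        malignant = labels[sid] == "malignant"
        if call == "positive":
            tp, fp = tp + malignant, fp + (not malignant)
        else:
            fn, tn = fn + malignant, tn + (not malignant)
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def subtype_sensitivity(calls: Mapping[str, str], records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Per-subtype sensitivity over the malignant samples.

    Returns a DataFrame with columns subtype, n, tp, sensitivity; subtypes
    with zero malignant samples are omitted.
    """
    rows = []
    malignant = [r for r in records if grade_to_binary(r.grade) == "malignant"]
    for subtype in sorted({r.subtype for r in malignant}):
        group = [r for r in malignant if r.subtype == subtype]
        tp = sum(calls[r.sample_id] == "positive" for r in group)
        rows.append((subtype, len(group), tp, tp / len(group)))
    return pd.DataFrame(rows, columns=["subtype", "n", "tp", "sensitivity"])


@dataclass(frozen=True)
class DetectabilityLabel:
    """Stratification of a malignant sample by lesion burden."""

    category: str  # "easily_detectable" | "likely_overlooked"
    malignant_area_fraction: float


def detectability(record: SampleRecord) -> DetectabilityLabel:
    """Classify a malignant sample by its lesion/tissue area fraction.

    fraction = |gt AND tissue| / |tissue|; strictly below 30% means small
    or dispersed malignant foci, i.e. likely to be overlooked.
    """
    if record.gt_mask is None or record.tissue_mask is None:
        raise ValueError(f"sample {record.sample_id}: detectability needs gt and tissue masks")
    tissue = record.tissue_mask.values
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError(f"sample {record.sample_id}: empty tissue mask")
    frac = float((record.gt_mask.values & tissue).sum() / n_tissue)
    category = "likely_overlooked" if frac < OVERLOOK_AREA_FRACTION else "easily_detectable"
    return DetectabilityLabel(category=category, malignant_area_fraction=frac)


def fp_area_fraction(ovl: BinaryMask, gt: Optional[BinaryMask], tissue: BinaryMask) -> float:
    """Fraction of the tissue area covered by false-positive ROI.

    |ovl AND tissue AND NOT gt| / |tissue|; a missing ground-truth mask
    (benign sample) makes every in-tissue ROI pixel false positive.
    """
    if ovl.shape != tissue.shape or (gt is not None and gt.shape != tissue.shape):
        raise ValueError("mask shapes must match")
    n_tissue = tissue.count()
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    fp = ovl.values & tissue.values
    if gt is not None:
        fp = fp & ~gt.values
    return float(fp.sum() / n_tissue)
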