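"""Sample-level ROC analysis and threshold optimization.

Each tissue fragment contributes one score per algorithm: the maximum of
its pixel-wise malignancy probability map (segmentation channel) and the
maximum detection-box score (detector channel, 0 when no boxes fire). A
fragment is called positive at threshold t when its score strictly
exceeds t; sweeping t over the observed scores yields TPR/FPR pairs, the
AUC by trapezoidal integration, and the Youden-index cut-off

    J(t) = TPR(t) + 1 - FPR(t),

maximized over the threshold grid with ties broken toward the largest
threshold (the most specific operating point).

The *integrated* two-algorithm curve scores each sample by
max(seg_score, det_score): flagging by either algorithm at a common
threshold, matching the logical-OR ROI integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import BinaryMask, ProbabilityMap


@dataclass(frozen=True)
class SampleScore:
    """Per-sample algorithm scores with the benign/malignant truth label."""

    sample_id: str
    seg_score: float
    det_score: float
    label: str  # "benign" | "malignant"

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"label must be benign|malignant, got {self.label!r}")
        for name in ("seg_score", "det_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ROCResult:
    """Threshold-swept ROC curve with AUC and Youden cut-off.

    ``thresholds`` descend from 1 to 0 so TPR/FPR are non-decreasing along
    the arrays; the curve runs from (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    cutoff: float
    youden_j: float
    n_malignant: int = 0
    n_benign: int = 0

    @property
    def n_points(self) -> int:
        return len(self.thresholds)


def sample_score(pmap: ProbabilityMap, tissue: Optional[BinaryMask] = None) -> float:
    """Maximum malignancy probability over the sample (optionally tissue-restricted)."""
    if tissue is None:
        return float(pmap.values.max())
    if tissue.shape != pmap.shape:
        raise ValueError(f"tissue shape {tissue.shape} != map shape {pmap.shape}")
    if tissue.count() == 0:
        raise ValueError("tissue mask restricts the map to an empty set")
    return float(pmap.values[tissue.values].max())


def combined_score(s: SampleScore) -> float:
    """Integrated two-algorithm score: max of the per-algorithm scores."""
    return max(s.seg_score, s.det_score)


def _extract(scores: Sequence[SampleScore], which: str) -> tuple[np.ndarray, np.ndarray]:
    if which not in ("seg", "det", "combined"):
        raise ValueError(f"which must be seg|det|combined, got {which!r}")
    if which == "seg":
        vals = np.array([s.seg_score for s in scores])
    elif which == "det":
        vals = np.array([s.det_score for s in scores])
    else:
        vals = np.array([combined_score(s) for s in scores])
    labels = np.array([s.label == "malignant" for s in scores])
    return vals, labels


def roc_curve(scores: Sequence[SampleScore], which: str = "seg") -> ROCResult:
    """Sample-level ROC curve over the observed-score threshold grid.

    The grid is the set of unique observed scores plus the sentinels 0 and
    1, descending; positivity is strict (score > t). AUC is trapezoidal
    over (FPR, TPR), which equals the Mann-Whitney statistic with ties
    weighted 1/2. When some score is exactly 0, the strict sweep stops
    short of (1, 1); the curve is then closed with a final (1, 1) vertex
    at threshold 0 (the sentinel-0 endpoint counts zero scores as
    flagged), preserving both the curve invariant and the Mann-Whitney
    identity.
    """
    vals, labels = _extract(scores, which)
    n_mal = int(labels.sum())
    n_ben = int((~labels).sum())
    if n_mal == 0 or n_ben == 0:
        raise ValueError("ROC requires at least one benign and one malignant sample")

    grid = np.unique(np.concatenate([vals, [0.0, 1.0]]))[::-1]
    # strict ">" sweep: at each grid threshold count scores exceeding it
    tpr = np.array([(vals[labels] > t).mean() for t in grid])
    fpr = np.array([(vals[~labels] > t).mean() for t in grid])
    if tpr[-1] < 1.0 or fpr[-1] < 1.0:  # zero scores present: close the curve
        grid = np.append(grid, 0.0)
        tpr = np.append(tpr, 1.0)
        fpr = np.append(fpr, 1.0)

    auc = float(np.trapezoid(tpr, fpr))
    cutoff, j = _youden(grid, tpr, fpr, n_mal, n_ben)
    return ROCResult(grid, tpr, fpr, auc, cutoff, j, n_malignant=n_mal, n_benign=n_ben)


def _youden(
    thresholds: np.ndarray,
    tpr: np.ndarray,
    fpr: np.ndarray,
    n_mal: int,
    n_ben: int,
) -> tuple[float, float]:
    # maximize J = tp/n_mal + 1 - fp/n_ben in exact integer arithmetic
    # (J * n_mal * n_ben is an integer), so rational ties are honored and
    # broken toward the largest threshold (most specific operating point);
    # thresholds descend, so the first argmax is that largest threshold.
    tp = np.rint(tpr * n_mal).astype(np.int64)
    fp = np.rint(fpr * n_ben).astype(np.int64)
    j_scaled = tp * n_ben - fp * n_mal
    idx = int(np.argmax(j_scaled))
    j = tp[idx] / n_mal + 1.0 - fp[idx] / n_ben
    return float(thresholds[idx]), float(j)


def youden_cutoff(roc: ROCResult) -> tuple[float, float]:
    """Youden-optimal threshold and its J value (ties -> largest threshold)."""
    return _youden(roc.thresholds, roc.tpr, roc.fpr, roc.n_malignant, roc.n_benign)


def candidate_thresholds(roc: ROCResult, n_each_side: int = 2, spacing: float = 0.05) -> list[float]:
    """Candidate operating thresholds around the Youden cut-off.

    Walks the curve to the grid points nearest FPR(cutoff) +/- k*spacing
    for k = 1..n_each_side (spacing in FPR units, clipped at the curve
    ends), adds the cut-off itself, deduplicates, and returns the
    thresholds in descending order.
    """
    if n_each_side < 0:
        raise ValueError("n_each_side must be >= 0")
    if n_each_side > 0 and not spacing > 0:
        raise ValueError("spacing must be > 0")
    cut_idx = int(np.flatnonzero(roc.thresholds == roc.cutoff)[0])
    fpr0 = roc.fpr[cut_idx]
    chosen = {float(roc.cutoff)}
    for k in range(1, n_each_side + 1):
        for target in (fpr0 - k * spacing, fpr0 + k * spacing):
            target = min(max(target, 0.0), 1.0)
            idx = int(np.argmin(np.abs(roc.fpr - target)))
            chosen.add(float(roc.thresholds[idx]))
    return sorted(chosen, reverse=True)


def scores_from_maps(
    items: Iterable[tuple[str, ProbabilityMap, Optional[BinaryMask], float, str]],
) -> list[SampleScore]:
    """Build SampleScores from (sample_id, map, tissue, det_score, label) tuples."""
    return [
        SampleScore(sid, sample_score(pmap, tissue), det, label)
        for sid, pmap, tissue, det, label in items
    ]
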