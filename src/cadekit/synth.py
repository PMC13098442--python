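"""Synthetic biopsy-like cohorts for exercising the CADe pipeline.

No clinical slides or trained networks ship with this package; this
module stands in for both. It fabricates, per tissue fragment: a tissue
mask (an ellipse on the frame), a ground-truth lesion mask for malignant
grades (one or two elliptical blobs whose tissue-area fraction is drawn
from a configurable range and hit exactly by quantile construction), a
mock segmentation probability map (clipped Gaussian noise around a base
level, lifted by ``signal`` inside the lesion), mock detector boxes for
signet-ring-cell samples, and simulated reader calls for the
second-reader workflow with a controllable cluster correlation.

Cohort composition presets mirror the published study arms:

- ``roc_cohort``      211 benign + 324 malignant (threshold optimization)
- ``eval_cohort``     92 G1 + 98 G5 (OVL evaluation, 190 samples)
- ``reader_cohort``   eval_cohort + 7 G3 + 2 G4 (reader study, 199 samples)
- ``training_cohort`` 1105 benign + 820 malignant (1925 samples; the
  per-subtype split of the malignant arm is a synthetic proportional
  allocation, only the totals are anchored)

Seed discipline: one master seed; sample ``i`` draws from the substream
``SeedSequence(seed, spawn_key=(i,))``, so regenerating any subset of a
cohort reproduces the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .metrics import grade_to_binary
from .reader import ReaderCall
from .roc import SampleScore
from .types import BinaryMask, DetectionSet, Box, ProbabilityMap, SampleRecord, SUBTYPES


@dataclass(frozen=True)
class ReaderSpec:
    """Target operating characteristics for simulated readers.

    Rates are marginal per-call probabilities of a correct call;
    ``cluster_rho`` is the exchangeable correlation of correctness among
    calls on the same sample (shared difficulty). Defaults reproduce the
    published reader-study operating points: sensitivity 92% -> 93% and
    specificity 94.7% -> 94.3% from the first to the second review.
    """

    sens_without: float = 0.92
    sens_with: float = 0.93
    spec_without: float = 0.947
    spec_with: float = 0.943
    cluster_rho: float = 0.3

    def __post_init__(self) -> None:
        for name in ("sens_without", "sens_with", "spec_without", "spec_with", "cluster_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``groups`` lists (grade, subtype, count) strata; helper constructors
    build it from benign/malignant totals. ``signal`` is the mean
    probability lift inside lesions over the benign ``base_level``;
    ``noise_sd`` the pixel noise; both chosen so that benign maxima sit
    mostly below the deployed low threshold (0.899) while lesion pixels
    routinely exceed the high one (0.977), giving separable but imperfect
    score distributions.
    """

    groups: tuple[tuple[str, str, int], ...]
    image_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.92
    seed: int = 0
    base_level: float = 0.55
    signal: float = 0.35
    noise_sd: float = 0.08
    lesion_area_fraction_range: tuple[float, float] = (0.05, 0.60)
    detector_hit_rate: float = 0.9
    reader_spec: ReaderSpec = field(default_factory=ReaderSpec)

    def __post_init__(self) -> None:
        lo, hi = self.lesion_area_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("lesion_area_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.detector_hit_rate <= 1.0:
            raise ValueError("detector_hit_rate must lie in [0, 1]")
        for grade, subtype, count in self.groups:
            if subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype {subtype!r}")
            if count < 0:
                raise ValueError("group counts must be >= 0")
        if self.n_total == 0:
            raise ValueError("empty cohort")

    @classmethod
    def from_counts(
        cls,
        n_benign: int,
        subtype_counts: Mapping[str, int],
        **kwargs,
    ) -> "CohortSpec":
        """Benign samples as G1, malignant subtype counts as G5."""
        groups = [("G1", "benign", n_benign)] + [
            ("G5", st, n) for st, n in subtype_counts.items()
        ]
        return cls(groups=tuple(groups), **kwargs)

    @property
    def n_benign(self) -> int:
        return sum(n for g, _, n in self.groups if grade_to_binary(g) == "benign")

    @property
    def n_malignant(self) -> int:
        return sum(n for g, _, n in self.groups if grade_to_binary(g) == "malignant")

    @property
    def n_total(self) -> int:
        return sum(n for _, _, n in self.groups)

    @property
    def subtype_counts(self) -> dict[str, int]:
        """Per-subtype counts over the malignant strata."""
        out: dict[str, int] = {}
        for g, st, n in self.groups:
            if grade_to_binary(g) == "malignant":
                out[st] = out.get(st, 0) + n
        return out


# ---------------------------------------------------------------------------
# Presets mirroring the published cohort compositions

_ROC_G5 = {
    "Tub_well": 40,
    "Tub_mod": 85,
    "Pap": 17,
    "Por_solid": 13,
    "Por_nonsolid": 124,
    "Sig": 15,
    "Muc": 3,
    "MALT": 9,
}  # 306 G5 samples

_ROC_GROUPS = (
    ("G1", "benign", 201),
    ("G2", "adenoma", 2),
    ("G3", "adenoma", 8),
    ("G4", "MALT", 11),
    ("G4", "DLBCL", 5),
    ("G4", "Tub_mod", 1),
    ("G4", "Por_nonsolid", 1),
) + tuple(("G5", st, n) for st, n in _ROC_G5.items())

_EVAL_G5 = {
    "Tub_well": 13,
    "Tub_mod": 23,
    "Pap": 6,
    "Por_solid": 4,
    "Por_nonsolid": 34,
    "Sig": 10,
    "Muc": 3,
    "DLBCL": 5,
}  # 98 G5 samples

_EVAL_GROUPS = (("G1", "benign", 92),) + tuple(("G5", st, n) for st, n in _EVAL_G5.items())

_READER_GROUPS = _EVAL_GROUPS + (
    ("G3", "adenoma", 7),
    ("G4", "Por_nonsolid", 1),
    ("G4", "Tub_mod", 1),
)  # 199 samples


def _largest_remainder(weights: dict[str, int], total: int) -> dict[str, int]:
    wsum = sum(weights.values())
    raw = {k: total * w / wsum for k, w in weights.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(out.values())
    order = sorted(raw, key=lambda k: (raw[k] - out[k], k), reverse=True)
    for k in order[:short]:
        out[k] += 1
    return out


def _training_groups() -> tuple[tuple[str, str, int], ...]:
    # totals anchored at 1105 benign / 820 malignant; the split of the 820
    # across subtypes is a synthetic proportional allocation
    epithelial = _largest_remainder(_ROC_G5, 795)
    epithelial["DLBCL"] = 15
    epithelial["GIST"] = 10
    return (("G1", "benign", 1105),) + tuple(
        ("G5", st, n) for st, n in sorted(epithelial.items())
    )


def get_preset(name: str, image_size: tuple[int, int] = (128, 128), **overrides) -> CohortSpec:
    """Named cohort recipes (see module docstring for what each mirrors)."""
    presets = {
        "roc_cohort": _ROC_GROUPS,
        "eval_cohort": _EVAL_GROUPS,
        "reader_cohort": _READER_GROUPS,
        "training_cohort": _training_groups(),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(presets)}")
    return CohortSpec(groups=presets[name], image_size=image_size, **overrides)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class Cohort:
    """Generated cohort: records, maps, detections and the truth table."""

    spec: CohortSpec
    records: list[SampleRecord]
    maps: dict[str, ProbabilityMap]
    detections: dict[str, DetectionSet]
    truth: pd.DataFrame

    def sample_scores(self) -> list[SampleScore]:
        """Per-sample max segmentation/detector scores with truth labels."""
        out = []
        for rec in self.records:
            pmap = self.maps[rec.sample_id]
            seg = float(pmap.values[rec.tissue_mask.values].max())
            dets = self.detections.get(rec.sample_id)
            det = max((b.score for b in dets), default=0.0) if dets else 0.0
            out.append(SampleScore(rec.sample_id, seg, det, grade_to_binary(rec.grade)))
        return out

    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["sample_id"], self.truth["label"]))


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _tissue_mask(rng: np.random.Generator, shape: tuple[int, int]) -> BinaryMask:
    h, w = shape
    cr = h / 2 + rng.uniform(-0.05, 0.05) * h
    cc = w / 2 + rng.uniform(-0.05, 0.05) * w
    ra = rng.uniform(0.30, 0.42) * h
    rb = rng.uniform(0.30, 0.42) * w
    rr, cc_ = draw_ellipse(cr, cc, ra, rb, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc_] = True
    return BinaryMask(out, role="tissue")


def _lesion_mask(
    rng: np.random.Generator, tissue: BinaryMask, fraction_range: tuple[float, float]
) -> tuple[BinaryMask, float]:
    """Lesion blob(s) inside the tissue hitting an exact area fraction.

    Target fraction f is drawn from the range (with a small margin so the
    one-pixel quantization cannot escape it); the lesion is the f-quantile
    sublevel set of an anisotropic distance field from one or two random
    foci, intersected with tissue — exact fraction by construction.
    """
    lo, hi = fraction_range
    margin = 0.03 * (hi - lo)
    f = rng.uniform(lo + margin, hi - margin) if hi > lo else lo
    rows, cols = np.nonzero(tissue.values)
    n_tissue = len(rows)
    k = int(np.clip(round(f * n_tissue), 1, n_tissue))

    n_foci = rng.choice([1, 2], p=[0.7, 0.3])
    field = np.full(n_tissue, np.inf)
    for _ in range(n_foci):
        j = rng.integers(n_tissue)
        sa, sb = rng.uniform(0.5, 1.5, size=2)
        d = ((rows - rows[j]) * sa) ** 2 + ((cols - cols[j]) * sb) ** 2
        field = np.minimum(field, d)
    order = np.argpartition(field, k - 1)[:k]
    out = np.zeros(tissue.shape, dtype=bool)
    out[rows[order], cols[order]] = True
    return BinaryMask(out, role="ground_truth"), k / n_tissue


def _probability_map(
    rng: np.random.Generator,
    spec: CohortSpec,
    tissue: BinaryMask,
    lesion: Optional[BinaryMask],
    sample_id: str,
) -> ProbabilityMap:
    h, w = spec.image_size
    values = np.clip(0.02 + 0.02 * rng.standard_normal((h, w)), 0.0, 1.0)
    noise = rng.standard_normal((h, w))
    inside = np.clip(spec.base_level + spec.noise_sd * noise, 0.0, 1.0)
    values[tissue.values] = inside[tissue.values]
    if lesion is not None:
        lifted = np.clip(
            spec.base_level + spec.signal + spec.noise_sd * noise, 0.0, 1.0
        )
        values[lesion.values] = lifted[lesion.values]
    return ProbabilityMap(values, pixel_size_um=spec.pixel_size_um, sample_id=sample_id)


def _detections(
    rng: np.random.Generator,
    spec: CohortSpec,
    tissue: BinaryMask,
    lesion: Optional[BinaryMask],
    is_sig: bool,
    sample_id: str,
) -> DetectionSet:
    h, w = spec.image_size
    boxes: list[Box] = []

    def _box_at(r: int, c: int, score: float) -> None:
        size = int(rng.integers(8, 17))
        x = int(np.clip(c - size // 2, 0, w - size))
        y = int(np.clip(r - size // 2, 0, h - size))
        boxes.append(Box(x, y, size, size, float(np.clip(score, 0.0, 1.0))))

    if is_sig and lesion is not None and lesion.count() > 0:
        rows, cols = np.nonzero(lesion.values)
        n_cells = max(int(rng.poisson(8)), 1)
        idx = rng.integers(len(rows), size=n_cells)
        for j in idx:
            if rng.random() < spec.detector_hit_rate:
                _box_at(rows[j], cols[j], rng.uniform(0.82, 1.0))
    # low-score clutter on any tissue (below the deployed 0.8 threshold)
    rows, cols = np.nonzero(tissue.values)
    for _ in range(rng.poisson(0.5)):
        j = rng.integers(len(rows))
        _box_at(rows[j], cols[j], rng.uniform(0.0, 0.6))
    return DetectionSet(boxes, sample_id=sample_id, frame=(h, w))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort, deterministic given ``spec.seed``."""
    strata = [
        (grade, subtype)
        for grade, subtype, count in spec.groups
        for _ in range(count)
    ]
    records: list[SampleRecord] = []
    maps: dict[str, ProbabilityMap] = {}
    detections: dict[str, DetectionSet] = {}
    rows = []
    for i, (grade, subtype) in enumerate(strata):
        rng = _sample_rng(spec.seed, i)
        sid = f"s{i:04d}"
        wsi_id = f"wsi{i // 3:04d}"
        tissue = _tissue_mask(rng, spec.image_size)
        malignant = grade_to_binary(grade) == "malignant"
        lesion = None
        frac = 0.0
        if malignant:
            lesion, frac = _lesion_mask(rng, tissue, spec.lesion_area_fraction_range)
        pmap = _probability_map(rng, spec, tissue, lesion, sid)
        dets = _detections(rng, spec, tissue, lesion, subtype == "Sig", sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                wsi_id=wsi_id,
                grade=grade,
                subtype=subtype,
                tissue_mask=tissue,
                gt_mask=lesion,
            )
        )
        maps[sid] = pmap
        detections[sid] = dets
        seg = float(pmap.values[tissue.values].max())
        det = max((b.score for b in dets), default=0.0)
        rows.append(
            (
                sid,
                wsi_id,
                grade,
                subtype,
                "malignant" if malignant else "benign",
                frac,
                seg,
                det,
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "wsi_id",
            "grade",
            "subtype",
            "label",
            "lesion_area_fraction",
            "seg_score",
            "det_score",
        ],
    )
    return Cohort(spec=spec, records=records, maps=maps, detections=detections, truth=truth)


# ---------------------------------------------------------------------------
# Reader-call simulation


def simulate_reader_calls(
    records: Sequence[SampleRecord],
    reader_spec: ReaderSpec,
    n_readers: int = 5,
    seed: int = 0,
) -> list[ReaderCall]:
    """Simulate the two-phase reader study over a cohort.

    Correctness of each (reader, sample, phase) call is Bernoulli with
    the phase- and class-specific marginal rate from ``reader_spec``; a
    shared per-sample component induces exchangeable within-sample
    correlation equal to ``cluster_rho`` on the binary scale (mixture
    construction: each call copies the sample-level latent call with
    probability sqrt(rho), else draws independently). Grades are derived
    from correctness: detected malignant -> G5, missed -> G1 or G3;
    correctly excluded benign -> G1 (adenoma -> G3), false positive -> G4
    or G5.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xCA11,)))
    gamma = float(np.sqrt(reader_spec.cluster_rho))
    calls: list[ReaderCall] = []
    for rec in records:
        malignant = grade_to_binary(rec.grade) == "malignant"
        rates = {
            "first": reader_spec.sens_without if malignant else reader_spec.spec_without,
            "second": reader_spec.sens_with if malignant else reader_spec.spec_with,
        }
        u = rng.random()  # shared sample difficulty, coupled across phases
        for phase in ("first", "second"):
            rate = rates[phase]
            z = u < rate
            copy = rng.random(n_readers) < gamma
            indep = rng.random(n_readers) < rate
            correct = np.where(copy, z, indep)
            for r in range(n_readers):
                calls.append(
                    ReaderCall(
                        reader_id=f"r{r + 1}",
                        sample_id=rec.sample_id,
                        phase=phase,
                        grade=_grade_for(rec, bool(correct[r]), malignant, rng),
                    )
                )
    return calls


def _grade_for(
    rec: SampleRecord, correct: bool, malignant: bool, rng: np.random.Generator
) -> str:
    if malignant:
        return "G5" if correct else str(rng.choice(["G1", "G3"]))
    if correct:
        return "G3" if rec.subtype == "adenoma" else "G1"
    return str(rng.choice(["G4", "G5"]))
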