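"""Second-reader workflow statistics.

In the second-reader design each pathologist grades every sample twice:
first unaided (phase ``first``), then with the CAD overlays visible
(phase ``second``). This module computes per-reader and pooled
sensitivity/specificity with across-reader t-intervals, and the paired
with-vs-without-CAD comparison as a GEE risk difference with robust
(sandwich) standard errors, clustering all reader-by-phase outcomes of
one sample together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gee import fit_gee, wald_test
from .metrics import EvalMetrics, evaluate, grade_to_binary
from .types import GRADES

PHASES = ("first", "second")


@dataclass(frozen=True)
class ReaderCall:
    """One pathologist's G1-G5 call for one sample in one phase."""

    reader_id: str
    sample_id: str
    phase: str  # "first" (without CAD) | "second" (with CAD)
    grade: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be first|second, got {self.phase!r}")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")


def _validate_design(calls: Sequence[ReaderCall]) -> tuple[list[str], list[str]]:
    """Check the complete two-phase design; returns (readers, sample_ids)."""
    seen: dict[tuple[str, str, str], ReaderCall] = {}
    for c in calls:
        key = (c.reader_id, c.sample_id, c.phase)
        if key in seen:
            raise ValueError(f"duplicate call for reader={c.reader_id} sample={c.sample_id} phase={c.phase}")
        seen[key] = c
    readers = sorted({c.reader_id for c in calls})
    samples = sorted({c.sample_id for c in calls})
    problems = []
    for r in readers:
        missing = [
            (s, ph)
            for s in samples
            for ph in PHASES
            if (r, s, ph) not in seen
        ]
        if missing:
            problems.append(f"reader {r}: {len(missing)} missing (sample, phase) calls, e.g. {missing[:3]}")
    if problems:
        raise ValueError("incomplete two-phase design:\n" + "\n".join(problems))
    return readers, samples


@dataclass
class ReaderStudyMetrics:
    """Per-reader, pooled, and across-reader summary of a reader study."""

    per_reader: dict[tuple[str, str], EvalMetrics]
    pooled: dict[str, EvalMetrics]
    across_readers: pd.DataFrame
    n_readers: int
    flags: list[str] = field(default_factory=list)

    def pooled_difference(self, metric: str) -> float:
        """second - first pooled metric, in percentage points."""
        a = getattr(self.pooled["second"], metric)
        b = getattr(self.pooled["first"], metric)
        return (a - b) * 100.0


def _t_interval(values: np.ndarray) -> tuple[float, Optional[float], Optional[float]]:
    mean = float(values.mean())
    r = len(values)
    if r < 2:
        return mean, None, None
    half = stats.t.ppf(0.975, r - 1) * values.std(ddof=1) / np.sqrt(r)
    return mean, mean - half, mean + half


def reader_metrics(calls: Sequence[ReaderCall], truth: Mapping[str, str]) -> ReaderStudyMetrics:
    """Sensitivity/specificity per (reader, phase), pooled, and across readers.

    ``truth`` maps sample_id to benign|malignant. Pooled metrics treat
    every reader-by-sample decision as one observation; the
    ``across_readers`` table gives the mean of per-reader values with a
    95% t-interval over the R readers (half-width t(0.975, R-1)*sd/sqrt(R)).
    """
    readers, samples = _validate_design(calls)
    missing_truth = [s for s in samples if s not in truth]
    if missing_truth:
        raise ValueError(f"samples without truth label: {missing_truth[:5]}")

    per_reader: dict[tuple[str, str], EvalMetrics] = {}
    for r in readers:
        for ph in PHASES:
            sub = {
                c.sample_id: ("positive" if grade_to_binary(c.grade) == "malignant" else "negative")
                for c in calls
                if c.reader_id == r and c.phase == ph
            }
            per_reader[(r, ph)] = evaluate(sub, {s: truth[s] for s in sub})

    pooled = {}
    for ph in PHASES:
        ms = [per_reader[(r, ph)] for r in readers]
        pooled[ph] = EvalMetrics(
            tp=sum(m.tp for m in ms),
            fp=sum(m.fp for m in ms),
            tn=sum(m.tn for m in ms),
            fn=sum(m.fn for m in ms),
        )

    flags = []
    if len(readers) < 2:
        flags.append("single reader: across-reader intervals are degenerate")
    rows = []
    for ph in PHASES:
        for metric in ("sensitivity", "specificity"):
            vals = np.array(
                [getattr(per_reader[(r, ph)], metric) for r in readers], dtype=float
            )
            mean, lo, hi = _t_interval(vals)
            rows.append((ph, metric, mean, lo, hi))
    across = pd.DataFrame(rows, columns=["phase", "metric", "mean", "ci_low", "ci_high"])

    return ReaderStudyMetrics(
        per_reader=per_reader,
        pooled=pooled,
        across_readers=across,
        n_readers=len(readers),
        flags=flags,
    )


@dataclass
class GEEResult:
    """Paired phase comparison: risk difference in percentage points.

    ``estimate`` is the second-minus-first difference in the proportion of
    correct calls, on the percentage-point scale, with robust (sandwich)
    SE, 95% Wald interval, and two-sided Wald p-value. ``working_correlation``
    is the estimated exchangeable rho of the sample clusters.
    """

    estimate: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_clusters: int
    working_correlation: float
    stratum: str
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"GEE risk difference (second - first), stratum: {self.stratum}",
            f"  estimate      {self.estimate:8.3f} pp",
            f"  robust SE     {self.robust_se:8.3f} pp",
            f"  95% CI        [{self.ci_low:.3f}, {self.ci_high:.3f}] pp",
            f"  p (Wald)      {self.p_value:8.4f}",
            f"  clusters      {self.n_clusters}",
            f"  exch. rho     {self.working_correlation:8.3f}",
        ]
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def gee_difference(
    calls: Sequence[ReaderCall],
    truth: Mapping[str, str],
    stratum: str = "malignant",
    rho: Optional[float] = None,
    reader_effect: bool = False,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> GEEResult:
    """GEE comparison of with- vs without-CAD accuracy.

    The binary outcome per (reader, sample, phase) is "correct call":
    detection of a malignant sample (``stratum='malignant'``, sensitivity)
    or exclusion of a benign one (``stratum='benign'``, specificity). The
    model is an identity-link GEE with binomial working variance and an
    exchangeable working correlation over sample clusters (all
    reader-by-phase outcomes of one sample), a single phase-indicator
    covariate, and optionally reader fixed effects. ``rho=0`` forces the
    independence working model.
    """
    if stratum not in ("malignant", "benign"):
        raise ValueError("stratum must be malignant|benign")
    readers, _ = _validate_design(calls)
    rows = [c for c in calls if truth.get(c.sample_id) == stratum]
    if not rows:
        raise ValueError(f"no calls in stratum {stratum!r}")

    y = np.array(
        [float(grade_to_binary(c.grade) == ("malignant" if stratum == "malignant" else "benign")) for c in rows]
    )
    phase_ind = np.array([1.0 if c.phase == "second" else 0.0 for c in rows])
    cols = [np.ones(len(rows)), phase_ind]
    if reader_effect and len(readers) > 1:
        for r in readers[1:]:
            cols.append(np.array([1.0 if c.reader_id == r else 0.0 for c in rows]))
    X = np.column_stack(cols)
    clusters = np.array([c.sample_id for c in rows])

    fit = fit_gee(y, X, clusters, rho=rho, tol=tol, max_iter=max_iter)
    est = float(fit.beta[1]) * 100.0
    se = float(np.sqrt(max(fit.robust_cov[1, 1], 0.0))) * 100.0
    flags = list(fit.flags)
    if se == 0.0:
        flags.append("degenerate: zero robust SE (separation or identical phases)")
    half = 1.959963984540054 * se
    return GEEResult(
        estimate=est,
        robust_se=se,
        ci_low=est - half,
        ci_high=est + half,
        p_value=wald_test(est, se),
        n_clusters=fit.n_clusters,
        working_correlation=fit.rho,
        stratum=stratum,
        converged=fit.converged,
        flags=flags,
    )
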