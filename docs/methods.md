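# Methods

This note documents the statistical and numerical choices behind
`cadekit`: what each component computes, the conventions where more than
one reading was defensible, what the synthetic-data generator does and
does not emulate, and the problem sizes used by the test suite and the
acceptance script.

## ROI construction and the three overlay modes

A region of interest is the strict superlevel set of the probability map:
pixel `p` is in the ROI iff `map[p] > t`. The inequality is strict
("values greater than a threshold"), so ties at the threshold are
excluded and `t = 1` always yields an empty ROI. Detector boxes are
half-open axis-aligned rectangles `[x, x+w) × [y, y+h)` on a 0-based,
row-major, top-left-origin grid, rasterized as filled rectangles and
clipped to the frame; a box contributes iff its score strictly exceeds
the detector threshold. Integration of the two algorithms is pixel-wise
logical OR.

The three operating modes use two segmentation thresholds and one
detector threshold, all exposed in `OVLConfig` with the deployed values
as defaults: low 0.899 (OVL1/OVL2), high 0.977 (OVL3, the ROC cut-off),
detector 0.8 (OVL2). Because thresholding is anti-monotone in `t` and OR
only adds pixels, the masks nest — OVL3 ⊆ OVL1 ⊆ OVL2 — for any input
under the default configuration; this is asserted as a property test.
No morphological post-processing (hole filling, small-component removal,
minimum-area filtering) is applied: the displayed ROI is exactly the
thresholded set.

Overlay rendering composites `(1 − α)·image + α·color` on ROI pixels,
rounded half-up per channel, and leaves off-ROI pixels bit-exact. "Dark
red" is fixed at RGB (139, 0, 0) and "25% transparent" is read as
α = 0.75 (the overlay hides 75% of the underlying pixel); neither the
color value nor the compositing convention is pinned down by the source
description, so both are configurable.

## Sample-level ROC and threshold optimization

The unit of analysis is the tissue fragment, scored by the maximum of
its probability map over the tissue mask (detector channel: maximum box
score, 0 when no boxes fire). The threshold grid is the set of unique
observed scores plus sentinels 0 and 1, swept descending with the same
strict ">" positivity as ROI extraction; TPR and FPR are the fractions
of malignant and benign fragments exceeding the threshold. AUC is the
trapezoid over (FPR, TPR), which equals the Mann–Whitney statistic with
ties weighted 1/2 — an identity the acceptance suite verifies to 1e-12
against a brute-force pair-counting oracle.

One convention is needed at the bottom of the sweep: with strict ">",
scores exactly equal to 0 (common in the detector channel) are never
flagged, and the curve would stop short of (1, 1). The curve is closed
with a final (1, 1) vertex at the sentinel threshold 0, i.e. the
endpoint counts zero scores as flagged. This preserves both the curve
invariant (runs from (0,0) to (1,1)) and the Mann–Whitney identity.

The Youden cut-off maximizes `J(t) = TPR + 1 − FPR` over the grid. Ties
are broken toward the **largest** threshold (the most specific operating
point, consistent with assigning the cut-off to the confirmation mode).
Because equal-J ties are typically exact in rational arithmetic but not
in floating point, the maximization is done on the integer-scaled
statistic `tp·n_ben − fp·n_mal`, which makes the tie-break exact.
Candidate operating points are the grid points nearest
`FPR(cutoff) ± k·Δ` for `k = 1..K` (Δ in FPR units, clipped at the curve
ends), deduplicated and returned descending; Δ is a free parameter since
"adequate intervals" is not otherwise specified. The deployed thresholds
(0.899/0.977/0.8) are treated as configuration inputs, not recomputed
values: the published selection involved expert review of candidate
overlays, which has no computational counterpart.

The integrated two-algorithm curve scores each fragment by
`max(seg_score, det_score)`. The published description says the two ROC
analyses were "combined" without a formula; the max rule is the reading
consistent with OR-integration of the ROIs (a fragment is flagged iff
either algorithm flags it at the common threshold) and is documented
here as the package's choice. The integrated AUC is *not* guaranteed to
dominate the single-channel AUCs, and no test asserts that it does.

## Evaluation metrics

Group calls map to the dichotomy as G1–G3 → benign, G4–G5 → malignant.
A fragment is called positive when its ROI has at least
`min_positive_pixels` true pixels (default 1: any visible ROI flags the
sample). The wide-field vs zoom distinction is perceptual, not
algorithmic, and is modeled as two values of this knob (zoom = 1;
wide-field = a larger, configurable on-screen-size threshold).
Sensitivity, specificity, PPV and NPV follow the usual confusion-matrix
definitions; a zero-denominator ratio is reported as absent (`None`),
never as 0. Reported percentages round half-up to one decimal, matching
summary-table formatting.

Detectability stratifies malignant fragments by
`|gt ∩ tissue| / |tissue|`: strictly below 0.30 is "likely to be
overlooked", otherwise "easily detectable". The denominator is tissue
pixels, not frame pixels, and the rule is area-based; dispersion of foci
is not separately scored. False-positive burden is
`|ovl ∩ tissue \ gt| / |tissue|`; for benign fragments (no ground-truth
mask) every in-tissue ROI pixel counts as false positive.

## GEE second-reader comparison

The paired comparison of with- vs without-CAD accuracy is a marginal
linear-probability model: outcome = correct call (detection of a
malignant fragment, or exclusion of a benign one), single covariate =
phase indicator, so the coefficient is the risk difference in percentage
points — matching how such study tables report differences, with
symmetric CIs. Configuration: identity link, binomial working variance,
exchangeable working correlation with clusters = samples (all
reader-by-phase outcomes of one fragment form one cluster; readers as an
optional fixed effect). A single-level sample cluster is used because a
crossed reader-by-sample working correlation is not reliably estimable
with five readers; the sandwich variance remains valid under working
-correlation misspecification, which is the point of using it.

Estimation is Fisher scoring with the exchangeable inverse applied in
closed form; rho is re-estimated each iteration by method of moments
from Pearson residuals (pair products over `φ·(Σ nᵢ(nᵢ−1)/2 − p)`),
clipped to the positive-definite range. Convergence is declared when the
maximum absolute coefficient change falls below 1e-12 (max 200
iterations) — tight enough that the degenerate-cluster case reproduces
the closed-form two-proportion estimate and robust SE to 1e-10, at the
cost of a couple of extra cheap iterations. Fitted means are clipped
away from {0, 1} for the working variance only. Degenerate outcomes are
flagged rather than masked: identical phases give estimate 0 with p = 1;
separation (all outcomes identical) gives a zero sandwich SE with an
explicit flag; non-convergence reports the final iterate. Two kinds of
interval are emitted and labeled: GEE Wald CIs for the pooled phase
difference, and across-reader t-intervals
(`mean ± t₀.₉₇₅,R₋₁·sd/√R`) for per-phase reader variability.

The engine is hand-rolled rather than delegated because the degenerate
behavior above and the exact oracle agreement are part of the module's
contract; statsmodels' GEE (binomial family, identity link,
exchangeable) serves as an independent cross-check in the test suite and
agrees with the engine to ~1e-8 on well-behaved data.

## Synthetic-data generator

The generator fabricates the *geometry and score structure* the pipeline
consumes, not histology. Per fragment: the tissue mask is a jittered
ellipse covering roughly a third of the frame; the lesion (malignant
grades only) is the sublevel set of an anisotropic squared-distance
field from one or two random foci inside the tissue, cut at the quantile
that makes the lesion/tissue area fraction *exactly* the drawn target
(uniform over `lesion_area_fraction_range`, default (0.05, 0.60), with a
3%-of-range margin so one-pixel quantization cannot leave the range).
Probability maps are clipped Gaussian noise: background ~0.02, tissue at
`base_level` 0.55 with `noise_sd` 0.08, lesions lifted by `signal` 0.35.
These defaults were set so that benign per-fragment maxima land mostly
below the deployed low threshold 0.899 while lesion pixels routinely
exceed the high threshold 0.977 — separable but imperfect distributions:
OVL1 shows occasional benign false positives, OVL3 is near-perfectly
specific, and the ROC cut-off lands between the bulk of the two score
distributions. Sig fragments receive ~8 Poisson cell centers inside the
lesion, each detected with probability `detector_hit_rate` 0.9 at score
U(0.82, 1); all fragments receive sparse low-score clutter boxes
(score < 0.8). Composition presets carry the published study-arm counts;
the per-subtype split of the 1925-sample training preset's malignant arm
is a proportional allocation (only its benign/malignant totals are
anchored).

Reader calls are simulated with exact marginal correct-call rates and
exchangeable within-sample correlation via a Bernoulli mixture: each
call copies a shared per-sample latent call with probability √ρ and
draws independently otherwise, giving binary-scale correlation exactly ρ
within a phase; the latent calls share one uniform across phases, so
difficulty persists from first to second review. Default rates are the
published reader-study operating points (sensitivity 0.92 → 0.93,
specificity 0.947 → 0.943) with ρ = 0.3 — the correlation is not
published; 0.3 is a typical multi-reader value and is a free parameter.
Grades derive from correctness (detected malignant → G5, missed → G1 or
G3; false-positive benign → G4 or G5).

What the generator does **not** emulate: H&E appearance, spatially
correlated network errors (noise is i.i.d. per pixel), anatomically
shaped lesions or glands, detector localization error structure, reader
drift or learning between phases. Consequently, passing tests establish
that the post-inference statistics are computed correctly and are
calibrated under the stated sampling models — not that any particular
clinical performance level would be attained on real slides.

Seed discipline: one master seed; fragment `i` uses the substream
`SeedSequence(seed, spawn_key=(i,))`, so any subset of a cohort
regenerates identically.

## Problem sizes and runtime

The default test run uses cohorts of 12–190 fragments at 32–96 px
frames, 500 replicates for the GEE recovery study (200 samples × 5
readers, true gain 5 points) and 2000 replicates for the null
calibration (200 sample clusters × 3 readers × 2 phases, ρ = 0.3);
the whole suite runs in well under a minute on one CPU. The acceptance
script generates the full preset compositions (535/190/199 fragments) at
96 px and averages the reader-study simulation over 40 replicates;
frame size mainly scales the per-pixel work and leaves the sample-level
statistics unchanged, which is why the presets default to small frames
rather than the 512 px (0.92 µm/px) frames `CohortSpec` itself defaults
to.

## Known limitations

- The GEE uses a single-level exchangeable cluster on samples; reader-
  level correlation is not modeled as a second clustering dimension.
- The 30% detectability rule is computed on area only; "dispersed foci"
  have no dispersion score.
- Candidate-threshold spacing is a parameter with no principled default.
- The integrated-ROC combination rule (per-sample max) is one defensible
  reading of an underspecified description; alternatives (e.g. averaging
  curves) would differ.
- Free-response (lesion-level) analysis such as JAFROC is out of scope;
  all statistics are sample-level.
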