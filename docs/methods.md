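# Methods

## The sTIL quantification algorithm

The imaging pipeline is a pure function of (tile, configuration, seed).
Its three steps, and the concrete choices made where a step admits more
than one reading:

**Per-channel mixture decomposition.** Each RGB channel's intensity
distribution is fitted with a univariate Gaussian mixture (default 4
components per channel — one per expected tissue compartment:
hematoxylin-dark nuclei, light-purple cytoplasm, eosin-pink stroma,
near-white background). EM runs on the weighted histogram of the 8-bit
values, which is algebraically identical to running it on the raw pixels
but independent of pixel order (so the fit is invariant under image
rotation/mirroring) and fast. EM is initialized at the exact
count-weighted 1-D k-means solution of the histogram (dynamic program
over the sorted values); quantile-based initialization was observed to
get trapped in local optima that merge the nucleus and cytoplasm modes on
stroma-dominated tiles. Variances are floored at 10⁻² intensity² to
prevent singular components; a collapsing component triggers a jittered
restart (bounded at 5), then an error. The log-likelihood trace is
retained and is non-decreasing.

**Threshold derivation and quantization.** All component means, pooled
across channels as scalars tagged with their channel, are partitioned
into K clusters by exact 1-D k-means (dynamic programming, so the
within-cluster sum of squares is globally minimal and the result is
deterministic). Per-channel thresholds are midpoints between consecutive
distinct cluster centers projected onto the channel. A class centroid's
coordinate in a channel is the weight-averaged mean of that cluster's
components from the channel, falling back to the cluster's scalar center
when the cluster holds none; pixels are assigned to the nearest centroid
in RGB space (idempotent by construction). The phrase "clustering of all
mixture components" admits several feature spaces (means as scalars,
(mean, variance) pairs, per-channel vs pooled); the scalar pooled reading
is used because it yields deterministic thresholds and a testable pixel
rule, and it is isolated behind the `derive_thresholds` interface.

**Class-count selection.** K is chosen in a candidate range (default
3–8) by maximizing the Dunn index — minimum inter-cluster point distance
over maximum intra-cluster diameter, Euclidean in raw RGB — computed on a
uniform pixel subsample (default 2,000 pixels; the full image is O(n²))
drawn with the run seed. Ties break toward the smaller K (parsimony).
On four-prototype synthetic tiles the criterion selects K = 4 in 20/20
seeds.

**Semantic annotation.** Each quantization class maps to the semantic
class (nucleus, cytoplasm, stroma, other) whose configured stain
prototype is nearest in RGB. Prototypes are configuration entries with
stated defaults, not hard-coded.

**Lymphocyte identification.** Nucleus-class connected components
(8-connectivity, minimum area 15 px) become candidate nuclei with five
features: relative size (area / median nuclear area on the tile — the
median being robust to a handful of giant segments), roundness 4πA/P²
(perimeter from the boundary contour; digital discs can slightly exceed
1), eccentricity from the central second moments, nucleus-to-cell ratio
(the cell grown from the nucleus by at most 3 simultaneous unit dilations
through cytoplasm-class pixels, stopping at other classes and at pixels
claimed by another cell, conflicts resolved to the lower nucleus index in
centroid order), and staining variation (SD of luminance 0.299R + 0.587G
+ 0.114B over the nucleus pixels; per-channel variance and
stain-deconvolved alternatives would also fit the name — luminance SD is
used and isolated behind the feature interface). A nucleus is a
lymphocyte when all five configurable criteria hold (conjunctive
combination): relative size ≤ 2.0, roundness ≥ 0.8, eccentricity ≤ 0.8,
nucleus-to-cell ratio ≥ 0.5, staining SD ≤ 20. The feature *list* is the
algorithm's substance; the cut-offs are free parameters. Two defaults
deserve justification:

- *relative size ≤ 2.0 (not < 1):* in lymphocyte-rich tiles the
  lymphocytes are the majority nucleus class, so the median nuclear area
  is itself a lymphocyte area and any cut-off below ~1.6 would reject
  true lymphocytes wholesale. The criterion's job is to exclude markedly
  larger nuclei: tumor nuclei run 4–7× the lymphocyte median and remain
  excluded, and in tumor-nucleus-dominated tiles everything small passes
  the size gate and the shape gates discriminate.
- *nucleus-to-cell ratio ≥ 0.5:* a rasterized lymphocyte of radius 3.5 px
  with a 1-px cytoplasm rim has a pixel-count ratio of ≈ 0.54; 0.6 would
  reject it.

With these defaults, classification against ground truth reaches ≥ 0.9
sensitivity and specificity on tiles mixing small round lymphocytes with
large elongated tumor nuclei; discrimination is carried mainly by
eccentricity (tumor nuclei are generated with axis ratios ≥ 1.8, hence
eccentricity ≥ 0.83).

**sTIL scoring.** A lymphocyte is *stromal* iff the substrate under its
nucleus centroid is stroma and the centroid lies in the tumor region.
The substrate map replaces every cell-class pixel (nucleus, cytoplasm)
with the nearest non-cell class via the Euclidean distance transform, so
"the tissue the cell sits on" is well defined even inside dense
infiltrates. The numerator is the whole pixel set (nucleus + attributed
cytoplasm) of the stromal lymphocytes clipped to the tumor mask; the
denominator adds those same pixels to the visible stroma-class pixels in
the mask. This inclusive convention (lymphocyte-covered stroma counts on
both sides) bounds the percentage by 100 and makes adding a stromal
lymphocyte monotone non-decreasing; whether the original denominator
excluded lymphocyte-occupied stroma is not decidable from the method's
description, and the convention is recorded in each result's provenance.
Patient-level sTIL pools tiles by the area-weighted ratio
100·Σnum/Σden.

**Tumor region.** Three sources, recorded in provenance: a provided
expert mask (recommended), the ground-truth mask (tests and recovery
experiments), or a derived heuristic — morphological closing (radius 60)
of the union of discs (radius 35) around non-lymphocyte nucleus
centroids, hole-filled. The derivation is intrinsically coarser than an
expert annotation: on default synthetic tiles it overlaps the true region
at Jaccard ≈ 0.8 and biases sTIL a few points low (sparser tumor-nucleus
layouts degrade it further), which is why the mask-provided mode is the
default recommendation and the recovery experiment uses the ground-truth
mask to isolate the scoring algorithm from region-annotation error.

## Synthetic tiles

Tiles emulate exactly the contrasts the algorithm exploits, not
photorealistic histology: per-pixel RGB = class prototype + independent
Gaussian channel noise (default SD 7; tumor nuclei 15 — more variable
staining; lymphocyte nuclei 4 — darker, even staining), clipped to
[0, 255]. Prototypes (nucleus (60,48,78), cytoplasm (128,112,138),
stroma (205,172,188), background (250,247,252)) are chosen so each
class's three channel levels are mutually closer than to any other
class's levels, making the class structure recoverable by per-channel
mixture decomposition — a property real H&E shares only approximately.
Default geometry: six tumor nests (radius 30–45 px) arranged in a ring
around the tile center; the tumor region is the dilated convex hull of
the nests, so a wide stromal lake sits *inside* the tumor region while
stroma also exists outside it (the "limited to the tumor region"
restriction is genuinely exercised, with out-of-region lymphocytes placed
at density 2 per 10⁴ stromal px). Tumor nuclei are non-overlapping
ellipses (minor semi-axis 5–7 px, axis ratio 1.8–2.4, random
orientation) inside nests; lymphocytes are discs (radius 3.5–5 px) with
a 1-px cytoplasm rim placed on stroma. When a target sTIL percentage is
requested, lymphocytes are added until they cover that fraction of the
in-region stromal substrate: random sequential placement up to 30%
coverage, and above that a hexagonal-lattice packing of same-size cells
whose rims are clipped first-claim where neighbors touch — random
sequential (RSA) placement jams near ~50% coverage, while the lattice
reaches the 60%+ range the recovery grid requires. Nuclei always keep
≥ 2 px separation, so connected components never merge. The emitted
ground truth (semantic mask, tumor region, stromal substrate, lymphocyte
mask) reproduces the stored true sTIL exactly by recounting.

What passing on these tiles does **not** show: robustness to stain
variation between slides, touching/overlapping nuclei (no watershed
splitting is implemented, by design), texture, compression artifacts, or
tissue folds. The pipeline's accuracy on real slides is bounded by those
factors, not by the ones tested here.

## Synthetic cohorts

One explicit seed drives a `numpy` Generator; no global random state.
Defaults mirror the descriptive statistics of the target cohort: n = 969;
age truncated-normal (mean 67, SD 9, range 42–85); 66.6% male; first-line
treatment {surgery 48.3%, combination 22.8%, chemotherapy 12.4%,
radiotherapy 12.1%, untreated 4%}; BMI and grade classes at the reported
frequencies; 32.5% tea drinkers. Genotypes are Hardy–Weinberg draws at
configurable minor-allele frequencies (defaults 0.05–0.38 matching the
six prognosis/sTIL SNPs analyzed). sTIL is truncated-normal on [0, 100]
(mean 28, SD 10) with additive per-minor-allele genotype shifts. DFS
event times are exponential with hazard λ₀·exp(η), λ₀ = 1/900 per day at
the reference covariates, η summing: sTIL −0.043 per point (hazard ratio
0.958 — the reported multivariable estimate), age +0.014/yr, female
−0.28, treatment and BMI and grade class effects at the reported
magnitudes, tea +0.23, and per-SNP dominant effects (|log HR| 0.35–0.40
for the three prognosis SNPs). Censoring is uniform on (180, 2900) days,
independent; times are rounded to whole days (creating ties that
exercise the Efron correction) with a floor of 1. Recurrence vs death is
simulated (35% recurrence) but collapsed into one composite DFS event,
matching the composite endpoint definition. This yields ≈ 60% events and
a median follow-up near 2.5 years.

## Statistical procedures

- **Kruskal–Wallis** with tie correction (scipy); all-identical inputs
  return H = 0, p = 1 (vacuous test). Group summaries report
  mean ± 1.96·SD/√n — the source tables' interval column sometimes looks
  percentile-like, so the column is labeled explicitly. Post-hoc:
  unadjusted pairwise Mann–Whitney (normal approximation, tie-corrected,
  no continuity correction so identical groups give p = 1); Dunn's z
  post-hoc available by option. The per-SNP sweep is complete-case per
  SNP, unadjusted p vs α = 0.05 with **no multiplicity correction by
  default**, replicating the original analysis procedure; a clearly
  labeled Benjamini–Hochberg option exists and is off by default.
- **Cox proportional hazards** is fitted by our own Newton–Raphson on the
  Efron-tied partial likelihood (Breslow by flag): convergence at
  max |score| < 10⁻⁶ or step < 10⁻⁸, step-halving keeps the likelihood
  monotone, proposals capped, covariates standardized internally (mapped
  back), SE from the inverse observed information, constant covariates
  dropped with a warning, diverging coefficients (complete separation)
  raise. The implementation is cross-checked against an independent
  library fit (lifelines) to 10⁻⁴ in the tests; Kaplan–Meier and
  log-rank go through lifelines directly, with a brute-force
  product-limit oracle in the tests. Complete-case analysis per model.
  Significance 0.05 two-sided throughout, as in the replicated procedure.
- **Median follow-up** is reported by both estimators (reverse
  Kaplan–Meier and the raw median among censored patients), since the
  original figure does not state which was used.
- **Prognostic comparison**: 70/30 split (floor rounding to train,
  seeded), Cox risk score = linear predictor, outcome = DFS event by a
  fixed 1,095-day horizon (patients censored earlier are excluded and
  counted; a fixed-horizon binary outcome is the minimal reading
  consistent with a single AUC per model), tie-adjusted AUC, and DeLong's
  structural-components test on the held-out test set only (whether the
  original AUC used the test set or everyone is unstated; test-set-only
  is implemented and labeled).

## Known limitation: DeLong on nested models

DeLong's test assumes the two score vectors are fixed; comparing a
fitted model against a fitted sub-model on the same data violates this,
and under the null (added covariates pure noise) the test over-rejects —
we measure ≈ 0.08–0.10 at nominal 0.05 over 500 nested-model replicates,
consistent with the published analyses of this misuse. The
implementation itself is verified against three oracles (exchangeable-
scores null ≈ nominal, variance = jackknife within 10%, p = paired-
bootstrap p within 0.03). The nested-model comparison is retained
because it is the procedure being replicated; its anti-conservatism is a
property of that procedure and both calibration numbers are reported by
the acceptance run.

## Problem sizes

The recovery and calibration experiments use: 50 tiles of 512×512 px
with true sTIL gridded over [5, 60]% (measured MAE ≈ 0.05 points,
ground-truth mask mode); 20 seeds for class-count selection; 1,000
cohort replicates (n = 969, 5 SNPs) for Kruskal–Wallis null calibration;
2,000 replicates (n = 300) for Cox Wald calibration; 200 replicates
(n = 1,000, true log-HR 0.5) for Cox recovery; 500 nested-model and
1,000 exchangeable-score replicates for DeLong calibration; 100
replicates for the combined-vs-clinical AUC comparison.
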