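# Methods

`woundrepair` quantifies single-cell wound repair in time-lapse fluorescence
movies of the syncytial *Drosophila* embryo — wound-area dynamics, actomyosin
ring geometry and intensity, kymographs and line profiles — and implements the
statistics of the accompanying post-wounding expression analysis. Because raw
wounding movies are rarely redistributable, every measurement is validated
against a synthetic-data generator with exact ground truth. This note records
the model, the defaults, and the numerical choices.

## The simulated wound model

A wound of initial radius `r0` (default 7.9 μm, the equivalent-circle radius
of a ~16×15.5 μm laser ablation target) appears at `t = 0` in a uniform
cortex of intensity `cortex_baseline`. The wound-area trajectory `A(t)`
realizes the phenomenological repair phases — expansion, ring assembly,
inward translocation, closure:

* `A(t < 0) = 0` (one pre-wound frame is always present);
* a half-cosine ramp carries `A` from `π r0²` to
  `expansion_fold · π r0²` at `t_max` (smooth and monotone, two parameters);
* after `t_max`, `A` decays **linearly** at `closure_rate` (μm²/s), clamped
  at zero. Linear decay makes the secant contraction-rate estimator exact on
  the truth. An optional second, shallower linear segment after the area
  halves reproduces the slope change real wounds show after `t_half`.

Each frame is a radially symmetric intensity profile built from logistic
steps of scale `edge_softness` (0.15 μm): ≈0 inside the wound (membrane
plug), a bright ring of width `ring_width` (2 μm) and amplitude
`ring_amplitude` (300) abutting the wound edge, a diffuse outer halo
(3 μm, amplitude 80), and the cortex baseline (100) elsewhere. The ring
travels with the wound edge; treadmilling is not modeled because only
geometry and intensity matter to the metrics. Noise (applied last) is
gaussian with σ = 15 (5% of ring amplitude) by default; Poisson noise and
noise-free rendering are options. Identical parameters + seed give
bit-identical stacks.

The default frame grid mirrors the acquisition protocol: one pre-wound frame
at −30 s, then every 30 s to 900 s, then every 60 s to 2400 s (57 frames).
The default image is 432×432 px at 0.22 μm/px (≈95 μm field, chosen so the
default kymograph ROI fits; the pixel size is typical of a 63×/1.4 NA EMCCD
setup and is configurable).

### Ground truth ("implied" metrics)

`GroundTruth` stores the exact per-frame radius/area and the values the
measurement formulas return when applied to the noiseless trajectory. For
scalar dynamics (expansion fold, `t_max`, `t_half`, contraction rate) that is
a direct scan of the frame-sampled trajectory. For ring width and ring mean
intensity it is the closed-form evaluation of the half-maximum construction
on the analytic radial profile: the half-max annulus of a soft-edged ring is
slightly wider than its nominal support, and its mean sits below
`baseline + amplitude` because edge pixels between half-max and peak are
included by construction (≈8% below, for the default 2 μm ring). Comparing
measurements against this closed-form value separates estimator error from
renderer geometry; both the nominal and implied values are available.

## Measurements

**Segmentation** (replacing manual Fiji outlining): Gaussian blur (σ = 1 px)
→ Otsu threshold (restricted to a dilated neighbourhood of the previous
frame's mask during tracing, or to a hint point) → connected dark components
that do not touch the image border, are ≥5 px, and whose minimum lies below
0.6× the frame median (rejects noise speckles; a membrane plug is genuinely
near-zero) → largest component (or the one containing the hint) → threshold
refinement: the cut is re-set to the midpoint of the interior level and the
adjacent ring peak and applied at full resolution. The refinement pins the
recovered boundary to the edge midpoint; an Otsu cut typically lands between
the cortex and ring intensity classes and would bias the radius by ~0.5 px,
which matters at small radii. Finally morphological closing (3 px) and hole
filling. Areas are pixel counts × pixel area (Fiji-style; no sub-pixel
contour integration). A wound is flagged closed once its area falls below
1 μm² and never recovers. Wounds smaller than ≈6 μm² approach the detection
limit at the default pixel size.

**Ring edges**: the radial mean-intensity profile is computed about the
wound centroid in 1-px bins; the ring peak must exceed the cortex baseline
(frame median) by ≥5% or a "no ring" error is raised. The inner/outer edges
are the first/last half-maximum crossings (linearly interpolated), and the
regions are the filled disks they enclose — the half-max criterion is this
package's construction; the original manual protocol does not state where
the edges were drawn.

**Metrics** (formulas as in the source protocol):

* Feret diameter = max pairwise distance between boundary-pixel centers,
  via convex hull + rotating calipers (exactly equal to the brute-force
  pairwise maximum; a single pixel has Feret 0 — a deliberate deviation from
  Fiji's +1 px convention so the brute-force oracle is exact).
* ring width = (outer Feret − inner Feret)/2, at the frame nearest 120 s
  post-wounding (135 s is the convention for PIP3 reporters; configurable).
* ring mean intensity = (outer − inner integrated intensity)/(outer − inner
  area); relative intensity divides by the UW baseline, the mean of a
  centered 50×50 px window of the pre-wound frame.
* expansion fold = max area / first post-wound area ("initial wound size" is
  read as the first measured frame, not the ablation-target setting).
* `t_max` = time of maximal area (earliest on ties); `t_half` = earliest
  subsequent time with area ≤ fraction·max, fraction ∈ [0.35, 0.5], default
  0.5 (earliest crossing is the most reproducible reading of "50–35%").
* contraction rate = (A(t_max) − A(t_half))/(t_half − t_max), reported as a
  positive magnitude: written with the time difference the other way round
  the quotient would be negative, but the quantity is an average speed.

**Profiles and kymographs**: a 10-px band through the wound center is
averaged per position; the 95% CI is mean ± crit·SD/√width with the band
lines treated as independent. The default critical value is Student-t with
width−1 degrees of freedom — with 10 lines a z-interval (1.96) covers the
true mean only ~92% of the time, and the t-interval is what makes the
empirical coverage test (95% ± 2%) meaningful; `ci_method="z"` gives the
literal 1.96 construction. Dynamic profiles are per-frame profiles
concatenated in time. Kymographs average a 5.3 × 94.9 μm ROI across its
width, one column per frame regardless of the 30 s → 60 s cadence change
(`uniform_time=True` interpolates onto a uniform grid). An optional
moving-average smoothing (window 3) exists but is off everywhere in tests.

## Expression statistics

The generator emulates a 4-replicate wounded-vs-unwounded two-colour array
study: 8000 genes, 80 up- and 173 down-regulated genes planted with |log2FC|
~ U(1.0, 1.4) (the magnitude range of the study's top regulated genes),
i.i.d. replicate noise σ = 0.1. Gene sizes are log-normal (σ_log = 0.6) with
group means 3.7 kb (up), 1.9 kb (down) and 2.5 kb (background), matching the
reported group averages. Genes map to 1169 TADs as contiguous blocks; a
clustering switch packs planted genes into the fewest TADs to exercise the
enrichment test. The spot table plants configurable fractions of spots
violating each quality rule.

* **Spot filter**: remove if foreground ≤ background + 3·SD in a channel,
  background-subtracted signal < 100 in *both* channels, or QC-flagged; the
  removal log names the rule.
* **Per-gene statistic**: mean log2 ratio + two-sided one-sample t-test — a
  deliberately plain stand-in used for synthetic replicates (measured
  studies arrive with per-gene moderated statistics, which `de_filter`
  ingests directly via column mapping). Zero-variance convention: identical
  nonzero replicates → p = 0; identical zeros → p = 1.
* **DE filter**: Benjamini–Hochberg adjustment; call up/down requires both
  adjusted p ≤ 0.05 and |log2FC| ≥ 0.585 (±1.5-fold; 2^0.585 ≈ 1.500).
* **TAD enrichment**: Fisher's exact test of independence on the
  TAD × {regulated, unaffected} table over array-expressed genes (unmapped
  genes excluded and counted). 2×2 exactly; R×2 by Monte-Carlo conditional
  on the margins (≥10⁴ multivariate-hypergeometric draws, fixed seed, MC
  standard error reported) — unbiased and testable where the exact network
  algorithm would be heavy machinery.
* **Gene sizes**: sample median with a percentile bootstrap 95% CI
  (1000 resamples); group means are also emitted since the published figure
  is labeled as an average while the protocol computes a median.
* **ΔΔCq**: technical replicates averaged first; efficiency
  % = (1 − 2^−ΔΔCq)·100; invariant under adding a constant to all Cq.

## What the synthetic data does and does not show

The generator reproduces the measured geometry (soft-edged radially
symmetric rings, realistic cadence, shot-like noise) but not asymmetric or
ragged wounds, drift, photobleaching, z-sectioning, membrane-scoring
artifacts, or spatially correlated array noise; limma's loess normalization
and moderated fit are out of scope (the pipeline consumes per-gene
statistics). Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every real-data
pathology. Recovery experiments (20 stacks spanning folds 1–2, rates
0.1–1 μm²/s, widths 1–4 μm at 5% noise) show median relative errors well
below 1% for expansion and contraction and ring-width errors ≈0.05 px.

## Problem sizes and determinism

Test and acceptance runs use 192×192 px stacks with the cadence truncated at
1560 s (43 frames) for the recovery sweep, and the full default 432×432 px /
57-frame stack for the end-to-end run; the expression experiments use the
full 8000-gene design and 200–500 simulation replicates for the calibration
checks. Every stochastic component draws from `numpy.random.default_rng`
seeded from an explicit parameter; reruns are bit-identical, and the
acceptance script derives all sub-seeds from its single `--seed`.

## Known limitations

* Single wound per frame; no multi-wound tracking or drift correction.
* Ring-edge detection assumes an approximately radially symmetric ring about
  the wound centroid; strongly lobed rings would need per-angle edges
  (gradient-maximum alternatives are noted in the code but not implemented).
* The closure flag depends on the segmentation detection limit (≈6 μm² at
  0.22 μm/px), so closure times carry a one-frame uncertainty.
* The plain t-test stand-in is less powerful than a moderated statistic at
  n = 4; with the default planted effects this costs a few calls
  (e.g. 250/253 recovered at one seed, 253/253 at another).
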