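# woundrepair

Quantification of **single-cell wound repair** from time-lapse fluorescence
stacks, with the accompanying post-wounding **expression statistics**, and a
synthetic-data generator that provides exact ground truth for every
measurement.

When a cell cortex is breached — the laser-wounded syncytial *Drosophila*
embryo is the model here — the wound first expands under cortical tension,
then an actomyosin ring assembles at the wound edge (flanked by a diffuse
actin halo) and translocates inward until closure. This package turns
single-channel movies of that process (T×H×W TIFF stacks with frame times
and pixel size) into the standard repair statistics:

* per-frame wound mask and **area trace** A(t) (μm²), with closure flags;
* **expansion fold** = max A / A(first post-wound frame);
* **t_max** (time of maximal area), **t_half** (first time A falls to a set
  fraction, 0.35–0.5, of the max) and the **contraction rate**
  (A(t_max) − A(t_half)) / (t_half − t_max) in μm²/s;
* actin-**ring geometry** at a reference time (120 s): inner/outer ring
  edges at half-maximum of the radial intensity profile, their Feret
  diameters (max caliper width, rotating calipers), ring width
  (outer − inner Feret)/2, and the annulus mean intensity
  (ΔI/ΔA), normalized by the unwounded baseline (mean of a centered
  50×50 px window of the pre-wound frame);
* averaged **line profiles** (10-px band, 95% CI per position), dynamic
  (concatenated) profiles, and **kymographs** (5.3 × 94.9 μm ROI band).

The expression half implements the array-analysis chain of the wounding
study design (4 replicates, wounded vs unwounded): spot quality filtering,
per-gene statistics, the significance filter |log₂ ratio| ≥ 0.585
(±1.5-fold) at 5% Benjamini–Hochberg FDR, Fisher's exact test of regulated-
gene independence across TADs (exact 2×2, seeded Monte-Carlo for R×2),
bootstrap median gene sizes (1000 resamples, percentile 95% CI), and ΔΔCq
knockdown efficiency.

See `docs/methods.md` for the model, defaults, and numerical conventions.

## Worked example

```python
from woundrepair import WoundSimParams, simulate_wound_stack, summarize_repair

params = WoundSimParams(rng_seed=1)          # defaults: 1.5-fold expansion,
stack, truth = simulate_wound_stack(params)  # 0.2 um^2/s closure, 2 um ring
m = summarize_repair(stack)

print(f"expansion fold   {m.expansion_fold:.3f}  (truth {truth.implied_expansion_fold:.3f})")
print(f"contraction rate {m.contraction_rate:.3f} um^2/s  (truth {truth.implied_contraction_rate:.3f})")
print(f"t_max / t_half   {m.t_max:.0f} s / {m.t_half:.0f} s")
print(f"ring width       {m.ring_width:.2f} um at {m.ring_reference_time:.0f} s")
print(f"relative ring intensity {m.ring_rel_intensity_ref:.2f} x UW baseline")
```

prints

```
expansion fold   1.506  (truth 1.500)
contraction rate 0.202 um^2/s  (truth 0.200)
t_max / t_half   60 s / 810 s
ring width       2.04 um at 120 s
relative ring intensity 3.69 x UW baseline
```

The simulated wound (initial area ≈196 μm², matching a ~16×15.5 μm ablation
target) expands 1.5-fold by 60 s, then closes linearly at 0.2 μm²/s, halving
its maximal area at 810 s; at 5% gaussian noise the pipeline recovers every
truth to well under 1%. `truth` also carries the per-frame radii and the
closed-form values the measurement formulas take on the noiseless movie, so
estimator error can be separated from rendering geometry.

The same flow runs from the shell:

```sh
woundrepair simulate --out sim --seed 1
woundrepair quantify --out quant sim/stack.tif   # trace, metrics, profiles, kymograph CSVs
woundrepair expr --out expr --seed 1             # synthetic expression study end to end
```

and every CSV carries its configuration as `#`-comment provenance lines.

For expression tables, `de_filter` consumes any table with per-gene log-fold
changes and p-values (column-mappable, so externally computed moderated
statistics can be ingested directly):

```python
from woundrepair import ExprSimParams, simulate_expression_study, gene_statistics, de_filter

spots, expr = simulate_expression_study(ExprSimParams(rng_seed=0))
de = de_filter(gene_statistics(expr))
print(de.n_up, de.n_down, de.n_total_called)   # -> 80 173 253
```

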