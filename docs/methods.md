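# Methods

Conventions, models, and numerical choices. Everything below is a
package design decision; all quantities are defined so they can be
verified against hand arithmetic or brute-force pixel oracles.

## Canonical 2D frame

A midsagittal slice is stored with rows running inferior→superior and
columns anterior→posterior, tagged on the object
(`rows=inferior->superior,cols=anterior->posterior`). Extraction from
a NIfTI volume reorients to nibabel's closest-canonical RAS+ order,
takes the sagittal plane at `x = nx // 2`, and re-indexes the plane
into this frame. Volumes are assumed to be registered to a 1 mm
standard grid upstream; registration is out of scope.

## Phantom generator

A phantom CC is the set of pixels within a varying half-thickness of a
quadratic Bezier arch through three control points. The half-thickness
is `base + amplitude * (1 + cos 2πt) / 2` along the curve parameter,
so the ends are thickest (genu/splenium-like). Rasterization uses
exact point-to-segment distances against a 600-point polyline with
linearly interpolated half-thickness, so membership is a closed-form
predicate that tests re-implement independently. The image adds
background blobs at intensity 0.5 and Gaussian noise (σ = 0.1) around
foreground intensity 1.0. Generated masks are validated to be single
4-connected components away from the border. Corruption modes (holes,
posterior truncation, leaking blob, empty, split) imitate real
segmentation failures for QC training; augmentations (integer
down/upsampling, multiples-of-15° rotation, occlusion boxes imitating
partial agenesis) operate on images.

## Segmentation network

An encoder–decoder with skip connections: each contracting stage is
two 3×3 convolutions + ReLU followed by 2×2 max-pooling; each
expansive stage is nearest-neighbor upsampling, a 2×2 convolution
halving the channels, concatenation with the (center-cropped) skip
tensor, and two 3×3 convolutions + ReLU; a 1×1 convolution produces
the logit map. Default depth 3, base 8 channels, 'same' padding
(a 'valid' mode with reflect-padded inference is also provided).

The implementation is pure NumPy (no deep-learning framework is among
the dependencies): im2col convolutions, hand-written backpropagation
checked against finite differences, Adam (lr 1e-4), minibatch binary
cross-entropy computed stably from logits. All tensors are float32,
which makes CPU training ~2.5× faster than float64 at no measurable
cost to final IOU; training is seeded end to end. Early stopping
monitors validation IOU (80/20 split) and halts when the change from
the previous epoch falls below 1e-4, with the untrained network's IOU
as the epoch-0 baseline. On 200 synthetic 64×64 phantoms the held-out
IOU passes 0.8 within a few epochs and reaches ≈0.98 by epoch 50
(≈4 minutes on one CPU).

## Morphometry

All metrics are computed on the binary mask, in mm via `pixel_size_mm`.

- **Area**: pixel count × pixel area. **Length**: inclusive
  anterior–posterior extent of occupied columns.
- **Thickness profile**: per occupied column, the inclusive vertical
  extent `max_row − min_row + 1`; interior holes do not reduce it.
  Regional and total mean thickness average this profile.
- **Witelson parcellation**: the AP extent `[c_min, c_max]` is cut at
  fractions 1/3, 1/2, 2/3, 4/5 of its inclusive width; every
  foreground pixel takes its column's compartment code, so the five
  regions partition the mask exactly (conservation is asserted, not
  approximated). Note the cuts are not symmetric about the midpoint:
  a 180°-rotated mask corresponds to parcellation with the reversed
  complement fractions, and even then the half-open cut convention
  shifts each cut by exactly one column.
- **Perimeter**: marching-squares contours at the 0.5 level on a
  zero-padded copy (so border-touching components close), each closed
  contour smoothed with a window-5 circular moving average before
  summing segment lengths. Raw marching-squares length overestimates
  smooth boundaries by pixel staircasing; the smoothing was set from
  analytic oracles (a 10×10 square gives 36.2 vs 36; doubling the
  pixel grid doubles the estimate within 5%).
- **Curvature**: per-column centerline midpoints are smoothed with a
  window-5 moving average, trimmed 2 columns per end (end caps bias
  the midpoints), and fit with a quartic smoothing spline whose
  per-point residual budget is the half-pixel quantization variance
  (0.5²/12); mean |y″|/(1+y′²)^1.5 is evaluated from the spline's
  analytic derivatives. Validated on analytic circular arcs
  (R = 40–60, recovered within 15%).
- Empty regions yield NaN (missing), never 0; empty masks produce an
  invalid record that downstream QC fails.

## Auto-QC

Features are the 15 shape metrics with NaN→0 plus 15 missingness
indicators, standardized by training-split statistics only. Members
(XGBoost, k-NN, SVC, logistic regression, random forest; optionally
two MLPs, 42-22-11 and 80-80-80-40-40-40) vote independently; ties
break toward *fail* (the conservative choice for a screening tool).
The fraction of fail votes is the ranking score for AUC. On a 400
record synthetic set (intact phantoms vs. all corruption modes) the
held-out AUC exceeds 0.9.

## Agreement

Dice = 2|A∩B|/(|A|+|B|) (1.0 when both masks are empty), related to
IOU by D = 2I/(1+I), an identity the tests assert exactly. ICC(3,1)
(two-way mixed effects, consistency, single measure) is
(MS_R − MS_E)/(MS_R + (k−1)MS_E) from the two-way ANOVA; ICC(2,1)
additionally charges session mean differences. Cross-checked against
`pingouin` to 1e-9.

## Association statistics

- **Allele alignment**: swapped alleles flip β and EAF; anything else
  raises; A/T and C/G pairs are flagged strand-ambiguous.
- **DerSimonian–Laird**: w = 1/se², Q = Σw(β−β_FE)²,
  τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), pooled weights 1/(se²+τ²),
  two-sided normal p. A hand-worked pair (β = 1, 0; se = 0.1) giving
  Q = 50, τ² = 0.49, β* = 0.5, se* = 0.5 is asserted, and the scalar
  path is cross-checked against `statsmodels.combine_effects`. A
  vectorized table path handles METAL-style cohort frames.
- **Calibration caveat**: under the global null with k = 2 cohorts the
  RE z-test's true type-I rate at α = 0.05 is ≈ 0.038, not 0.05: τ̂² is
  strictly positive whenever Q > 1 (≈32% of null draws), which inflates
  the pooled SE. This is a property of the truncated moment estimator
  with a normal reference, not of this implementation — the
  fixed-effect z-test on identical data holds 0.05 within Monte-Carlo
  error. The acceptance criterion asking for 0.05±0.01 from the RE
  test therefore fails by construction and is left failing; both
  measured rates appear in the acceptance output.
- **Li–Ji effective tests**: M_eff = Σ f(|λ|), f(x) = 1{x≥1} + (x−⌊x⌋)
  over eigenvalues of the trait correlation matrix, with near-integer
  eigenvalues snapped before the fractional part so that numerical
  noise cannot turn a hard zero into ≈1. Bonferroni threshold = α/M_eff.
- **Concordance**: a variant is CI-concordant when the primary β lies
  inside the replication's level-CI after allele alignment; the
  percentage is reported to the nearest integer.

## Simulated cohorts

`make_cohort_effects` draws per-variant EAF ~ U(0.01, 0.99) and
non-ambiguous allele pairs, one true effect per variant
(N(0, β_sd²), default 0), adds per-cohort deviations N(0, τ²) and
sampling noise with se = σ_y/√(2pqn). With τ² = 0 and k = 2 the Q
statistics average ≈1 (χ²₁), and the DL τ̂² mean over 2000 variants
recovers a true τ² = 0.25 within a few percent.

## Reproducibility

Every stochastic routine takes an explicit integer seed; the
acceptance script derives all sub-seeds from `--seed` via
`SeedSequence` (masked below 2³¹) and regenerates all data at runtime.
The pipeline writes a manifest with the package version, the full
config, and a config hash.

## Limitations

- The segmentation model and QC ensemble are trained on synthetic
  phantoms only; no claim is made about real-MRI performance.
- Perimeter and curvature estimators were tuned to analytic oracles at
  the phantom scale (tens of pixels); masks much smaller than ~10
  columns fall back to coarser estimates or are rejected.
- The DL RE test's small-k conservatism is documented above; no
  Hartung-Knapp-style correction is applied.
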