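# Methods

## The measurement

The quantity of interest is the fraction of F-actin fiber orientations
within 45° of the applied flow axis — "percent aligned" — computed per
image, compared across a factorial design of confluence (confluent
monolayer vs sparse single cells) and flow condition (static, or laminar
shear stress for 1, 6 or 24 h). Orientations are *axial*: a fiber has no
head or tail, so angles live on [0°, 180°) and all circular statistics use
the angle-doubling transform ψ = 2θ. Under a uniform axial law the aligned
window (−45°, 45°) covers half of the 180° support, so 50% aligned is the
random baseline; the threshold inequality is strict (a deviation of
exactly 45° counts as not aligned), a measure-zero decision made explicit
for reproducibility.

One angle convention binds every module: degrees, axial mod 180°,
counterclockwise from the flow axis, flow along increasing image columns
in a mathematical y-up frame. Image arrays are row-major with the row
index growing downward, so gradient computations negate the row component
before any angle is taken.

## Synthetic data model

No imaging dataset is available, so the generator emulates the statistical
structure the analysis assumes rather than the optics of any particular
microscope:

* **Cells** are ellipses. Confluent layouts tile the field (jittered grid,
  semi-axes slightly above half a tile so the monolayer has no gaps);
  sparse layouts place disjoint elongated ellipses covering 10% of the
  field by bounded rejection sampling (bounding-circle disjointness test,
  1000 retries per cell, failure raises a placement error naming the
  constraint).
* **Fibers** are straight segments with a Gaussian cross-section
  (σ = 1.5 px), length ~ N(28, 7²) px clipped to the cell boundary and the
  image, and orientations drawn from the axial von Mises law: φ ~
  vM(2μ, κ) on the circle, θ = φ/2 mod 180°. κ = 0 reduces exactly to the
  uniform axial law. This is the maximum-entropy axial family with one
  interpretable concentration parameter.
* **Noise** is additive Gaussian (sd 40 DN) on a constant background
  (200 DN); fibers add ≈1800 DN at the ridge. Poisson shot noise is
  deliberately not in the defaults — every downstream operator is
  threshold- or ratio-based, so Gaussian noise exercises the same code
  paths with one fewer parameter.
* **Design**: 256×256 px, 36 cells × 12 fibers per image, three replicates
  per condition (108 simulated cells per condition, matching a design of
  >100 cells per condition). The κ-vs-duration profile for confluent LSS
  is a Hill curve κ(t) = 2.5·t²/(t² + 6²): κ(1 h) ≈ 0.07 (no detectable
  alignment), κ(6 h) = 1.25, κ(24 h) ≈ 2.35. Sparse and static conditions
  get κ = 0. The published time course is graphical, not numerical, so
  this profile is illustrative — chosen once to express "alignment over
  6–24 h, none at 1 h" — and overridable.
* **Determinism**: every image is a pure function of (spec, seed); per-item
  seeds are SHA-256 hashes of (base seed, condition key), so manifests are
  byte-identical across reruns and insertion-order independent.

What the generator does *not* emulate: cell-shape change under flow,
fiber curvature, crossing-fiber bundling, uneven illumination, optical
blur beyond the fiber profile, shot noise, or 3D structure. Passing tests
therefore demonstrate that the estimator and statistics are correct for
images whose orientation content is known — not that the defaults are
tuned for any particular microscope's data.

## Orientation estimation

How fibers are detected and oriented is the genuinely open design choice;
the package uses the structure tensor with coherence weighting, standard
for actin imagery and parameter-light, over per-fiber tracing or
skeletonization. Pixels act as fiber samples; rose-plot "counts" are
weighted pixel counts. Gradients are Gaussian derivatives (σ_g = 1.5 px,
matching fiber widths of 2–4 px); tensor products are smoothed with a
σ_w = 6 px window; boundary handling is reflective, and a border of
3·σ_w is excluded from masks to suppress edge artifacts. The fiber angle
is the half-angle arctangent of (2·Jxy, Jxx − Jyy) — the gradient
direction — plus 90° mod 180°; stating the formula once avoids the classic
perpendicular-axis bug. At isotropic pixels (λ₁ = λ₂) coherence is 0 and
θ is set to 0° — a deterministic tie-break that cannot leak into results
because any positive coherence threshold removes those pixels.

Masking keeps pixels above the 0.75 intensity quantile with coherence
≥ 0.2; weights default to the pixel's coherence. All thresholds are
recorded in the mask's provenance. An empty mask is flagged, not fatal:
batch runs continue and the image is dropped from the tidy table.

Verification: on sinusoidal gratings the median tensor orientation agrees
with an independent FFT-power-peak oracle within 1° at every 15° step;
orientation and coherence are invariant to global intensity scaling; 90°
rotations shift orientations by exactly 90°, interpolated rotations within
2°. On rendered images the extracted axial mean recovers μ within 3°
(aggregated over 20 seeds) for κ ≥ 1. Fitted κ is *systematically larger*
than generating κ — window smoothing averages neighbouring fibers,
shrinking the apparent dispersion — so κ̂ is treated as a monotone index
of alignment, not an unbiased estimate; the recovery criterion is
monotonicity, which holds strongly across κ ∈ {0, 1, 2, 4, 8}.

## Statistics

Percent aligned is the weighted fraction with axial deviation < 45°
(strict). Effective sample sizes use the Kish formula (Σw)²/Σw²; note that
pixel samples are spatially correlated, so the binomial standard error at
the pixel count far understates the true variability — the relevant
effective n is of the order of the fiber count (~430 per default image).
Rose histograms bin the relative angle (θ − flow) mod 180° into half-open
bins [k·w, (k+1)·w) anchored at the flow axis; w must divide 180 (default
15°, 12 bins); totals conserve sample weight exactly. Plots mirror the
histogram onto 360° for the conventional axial display; statistics are
always computed on [0°, 180°). The axial von Mises fit doubles angles,
takes the weighted circular mean and resultant length R, and inverts
A(κ) = I₁(κ)/I₀(κ) = R by Brent's method with scaled Bessel functions
(|A(κ̂) − R| < 1e-8), capping κ̂ at 500 as R → 1 (flagged in the result).

## Inference

The replicate table (one percent-aligned value per image) enters a
classical fixed-effects two-way ANOVA with interaction, computed via an
ordinary least-squares fit with sequential sums of squares — on the
balanced designs the package requires by default, these coincide with the
cell-means decomposition. Unbalanced input raises an error pointing to the
explicit Type-II fallback (`anova_type=2`) rather than silently choosing a
SS type. Post-hoc contrasts compare each LSS level against static within
each density, using the pooled residual mean square and t distribution on
the residual df; Šídák adjustment 1 − (1 − p)^m is applied over the full
family of contrasts across both densities (a per-density family is
available). Correctness is checked three ways: the SS decomposition
identity to 1e-8, agreement with a brute-force design-matrix projection
oracle, and a restricted permutation test of the density main effect
(within-stratum shuffles) agreeing with the F-test p within 0.02.
Calibration: under a null generator (all κ equal) the family-wise rate of
any adjusted p < 0.05 measures ≈ 0.03–0.05 over 500 simulated
experiments, within the ≤ 0.08 control band (Šídák is conservative here
because contrasts share the pooled residual).

Significance stars default to the notation printed in the source figure
legend — `**P<0.005; ***P<0.005` — which uses the same threshold for both
levels and is almost certainly a typo; the notation is reproduced verbatim
in output metadata while the thresholds themselves are configurable.

## Problem sizes

Defaults were chosen so that the full factorial experiment (24 images of
256² px) renders and analyses in a few seconds: parameter recovery uses
20 seeds per κ (100 images), the null calibration 500 distribution-level
simulated experiments (no rendering), and the end-to-end pattern check 20
complete pipeline runs. The acceptance script completes in a few minutes
on one CPU.

## Known limitations

* κ̂ from pixel samples is inflated by window smoothing (see above); use
  it comparatively, not as an estimate of the generating concentration.
* Confluent images are analyzed as one region; per-cell attribution in
  monolayers would require a junction channel the pipeline does not model.
* Whether the original analysis counted fibers, skeleton segments or
  pixels is not documented anywhere; the pixel-sample interpretation is a
  package choice, as is binning relative to the flow axis (configurable).
* Sparse cultures are pooled per image rather than analyzed per cell;
  per-cell labels survive in the segmentation output for anyone who wants
  the alternative.
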