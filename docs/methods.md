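# Methods

`tawssnet` is a self-contained pipeline for studying deep-learning surrogate
prediction of time-averaged wall shear stress (TAWSS) on idealized left
coronary bifurcations.  It covers five stages: morphology sampling, geometry
construction, analytic shear labeling, canonical point ordering, and a
point-cloud U-Net regressor with MRE/NAME evaluation.  This note records the
models, the defaults and why, and the numerical choices.

## Morphology space

A bifurcation is described by five parameters: diameters of the left main
(`d_lm`), left circumflex (`d_lcx`) and left anterior descending (`d_lad`)
arteries, the LM–LAD angle γ (180° = straight continuation), and the LAD–LCx
opening angle α.  Default admissible ranges (mm, degrees):

| parameter | range |
| --- | --- |
| d_lm | 2.18 – 4.18 |
| d_lcx | 1.5 – 3.5 |
| d_lad | 1.5 – 3.5 |
| γ | 112.75 – 172.75 |
| α | 15 – 130 |

Populations are drawn by seeded independent uniform sampling per parameter
(a scrambled Latin hypercube is available for better space filling; neither
is asserted to be "the" design of any external dataset).  Dataset splits
follow a batch-wise protocol: the id list is cut into consecutive batches
(default 300), a fixed quota (default 60) is drawn uniformly without
replacement from each batch into the test set, and a fraction (default 10%,
round-half-to-even) of the remaining pool becomes validation.  For 1800
models this yields 360 test / 144 validation / 1296 training models.

## Geometry

The LM is a straight tube of length `8·d_lm` ending at the origin with
tangent +x; the daughters leave the origin along in-plane (z = 0) circular
arcs of default radius 20 mm and length `10·max(d_lad, d_lcx)`.  The LAD
initial tangent makes an angle 180° − γ with +x (below the x-axis); the LCx
opens a further α from the LAD on the opposite side; the arcs bend away from
each other.  The total arc turn is capped at 60° (the effective radius grows
for long daughters): without the cap, extreme-but-admissible morphologies let
a daughter turn ~100° and hook back over the LM, which is anatomically
implausible for this proximal segment and degenerates every point-ordering
scheme.  A configuration whose LCx initial heading comes within 30° of the
upstream (−x) direction is rejected as folded.

The wall is the zero level set of an exponential smooth-min blend of the
three tube signed-distance fields, with blending length `k = 0.4·d_lm`,
giving a C¹ junction without a CAD kernel.  The surface is sampled on a
structured grid: rows are axial stations (quota 16 LM / 24 LAD / 24 LCx of a
64-row grid, scaled proportionally for smaller grids, stations at arclength
cell centers), columns are equispaced circumferential angles measured from
the bifurcation-plane normal (+z).  Each grid point is found by bisection
along the radial ray from its station center (52 iterations; residuals reach
the 1e-12 mm level, verified against the implicit function).  Points whose
two nearest tube surfaces are within `3k` of each other are labeled
JUNCTION.  Distances to centerlines use exact point-to-polyline projection;
daughter arcs are discretized with 64 segments, whose sagitta error
(< 2e-4 mm at the default radii) is far below all tolerances because the
surface is *defined* by the polyline distance.

## Analytic shear surrogate

A transient CFD solve is deliberately replaced by an analytic pulsatile
field so the full pipeline is testable at desk scale; the network cannot
distinguish label provenance.  Ingredients:

- **Rheology.** Carreau–Yasuda shear-thinning viscosity
  `μ(γ̇) = (μ0−μ∞)[1+(λγ̇)^a]^((m−1)/a) + μ∞` with blood constants
  μ0 = 0.056 Pa·s, μ∞ = 0.0035 Pa·s, λ = 1.902 s, m = 0.22, a = 1.25.
- **Flow.** Mean LM inflow `Q̄ = V̄·π·d_lm²/4` with default mean velocity
  V̄ = 0.8 m/s, modulated by a two-lobe raised-cosine waveform (period
  0.8 s, systolic lobe 35% of the cycle at 0.55 relative amplitude,
  diastolic-dominant, exact cycle mean 1).  Daughter flows follow Murray's
  cube law `Q_v ∝ d_v³`, so flow is conserved at every instant.
- **Base stress.** Per vessel, the Poiseuille wall shear rate
  `γ̇_v(t) = 32·Q_v(t)/(π·D_v³)` and stress `τ_v(t) = μ(γ̇_v)·γ̇_v`
  (viscosity evaluated once at the Newtonian-profile rate; no fixed-point
  iteration — simple, smooth, monotone in Q/D³).
- **Spatial modulators.** (i) Gaussian amplification (amplitude 1.0,
  σ = 0.5·d_lm) centered at the carina — the point one mean daughter radius
  along the bisector of the daughter take-off directions; (ii) Gaussian
  reduction (amplitude 0.4, σ = 1.0·d_lm) at the two lateral wall centers
  perpendicular to that bisector; (iii) circumferential factor
  `1 + A_c·cos(φ)` with `A_c = (π/2)(r−1)/(r+1)` so the front-half mean
  TAWSS exceeds the back-half mean by exactly the configured ratio
  (default r = 1.25); the π/2 factor accounts for the mean of cos over a
  half circumference.  An optional α-proportional apex gain (default off)
  emulates the tendency of wider openings to raise divider shear.
- **Junction blending.** Per-point vessel stresses are mixed with soft
  weights `exp(−|tube distance|/k)`, truncated to exactly one vessel beyond
  `12k`, so fields are continuous across the junction and exactly Poiseuille
  far from it.
- **TAWSS.** Trapezoidal time average of |WSS| over one cycle on a 64-sample
  grid (quadrature error < 1e-3 relative against a 16× finer oracle).

V̄ = 0.8 m/s was fixed by a single calibration sweep (100 models,
{0.4, 0.6, 0.8, 1.0} m/s): it is the value at which the pooled TAWSS 5th–95th
percentile ([3.0, 15.9] Pa) sits inside the physiological 2–20 Pa band and
the per-path magnitudes match the 5–15 Pa range reported for coronary
bifurcation CFD.  Lower velocities leave the large-daughter corner of the
morphology space below 2 Pa.

Each stored model is rotated by a seeded random in-plane angle about the
plane normal.  Independently constructed models share no in-plane
orientation — this is what makes comparing canonical orderings meaningful —
but they do share the bifurcation plane, and the front/back-asymmetric field
makes the plane normal physically meaningful: under arbitrary 3D poses the
front/back orientation of a z-symmetric geometry would be unrecoverable from
coordinates, adding an irreducible error floor to any predictor.

**What the surrogate does and does not emulate.**  It reproduces the
magnitudes, the pulsatility, the divider amplification, the lateral-wall
reduction, the front/back asymmetry, and the diameter/flow scalings of
bifurcation TAWSS.  It does not solve the Navier–Stokes equations: no flow
separation or recirculation, no secondary (Dean) flows, no oscillatory
components, and its spatial detail is smoother than CFD fields.  Passing
tests therefore demonstrate the pipeline and the learnability of
geometry-conditioned smooth shear fields, not CFD-level fidelity.

## Canonical ordering

PCA ordering sorts points by projection on the leading eigenvector of the
coordinate covariance; ties break lexicographically on the second/third
principal projections, then input index.  Sort keys are quantized at
1e-9 mm: exactly mirror-symmetric point pairs otherwise tie at float
precision and the order would depend on summation order.  Eigenvector signs:
the leading axis is oriented by nonnegative dot product with the cloud's
inflow direction (recovered from the stored station structure: displacement
between the first two station-ring centroids); the minor axis by a
front-face reference (cosine-weighted mean radial offset per station ring,
which points along the plane normal); the second axis completes a
right-handed frame.  For frame-free inputs (plain coordinate arrays) the
fallbacks are rotation-invariant moment rules — leading axis toward the end
with larger internal lateral spread, then nonnegative projection skewness —
and finally the nonnegative largest-magnitude-component rule.  Blind moment
conventions alone were measured to agree with the anatomical direction for
only 50–70% of the admissible morphology family, which is why the
structure-derived references are the pipeline default.  Axis orderings (x,
y, z) sort on one raw coordinate with the same tie-breaking.

Ordered features are reshaped row-major to a rows × cols grid (64 clusters
of 64 consecutive sorted points for the default 4096-point budget); the
inverse mapping restores original point order exactly.  When the network
consumes a cloud, coordinates are expressed in the ordering's canonical
frame (centered and rotated onto the principal axes for PCA, centered only
for axis orderings), which makes the PCA pipeline pose-invariant end to end.

## Network

A U-Net regressor on the ordered grid.  Stem: two shared per-point layers
lift each 3-vector to 8 channels (the only reading consistent with a
4096×3 → 4096×8 transform before any reshape).  Encoder: two 3×3
convolutions per level, then 2×2 max pooling, four levels (64→32→16→8→4 for
the default grid); four further 3×3 convolutions at the bottleneck.
Decoder: 2×2 stride-2 transposed convolutions (exact doubling), skip
concatenation, two 3×3 convolutions per level.  Output: 1×1 convolution to
one channel, no normalization or activation.  Batch normalization sits after
every other convolution, before its ReLU.  The default configuration has
16,769 trainable parameters (the exact stem and transposed-convolution
widths that would reproduce a particular historical parameter count are not
recoverable; the count is logged, not asserted).

Training: MSE on targets min-max normalized by the dataset-global TAWSS
extremes, Adam (β = 0.9/0.999), initial learning rate 1e-3 with staircase
exponential decay (×0.9 every 2000 steps), batch size 16, early stopping on
validation NAME (patience 20 by default), best-validation weights restored.
Predictions are de-normalized and clipped to the dataset-global TAWSS range
(values outside the range of every training model are non-physical).  The
implementation is a NumPy layer stack with hand-written backpropagation
(im2col convolutions, float32 compute), verified against central finite
differences to ~1e-7 relative error; it is exactly reproducible for a fixed
seed on a fixed platform.

## Error metrics

Per model over its N points, with ŷ the prediction:

- MRE = mean_i |y_i − ŷ_i| / |y_i| × 100% (the square root of the squared
  ratio in the textbook form is algebraically the absolute value); guarded
  against |y_i| ≤ 1e-12.
- NAME = mean_i |y_i − ŷ_i| / (max{y} − min{y}) × 100%, where the extremes
  are taken over *all* generated models (the dataset-global convention),
  stored in the split manifest and embedded in checkpoints; evaluation
  refuses mismatched normalization constants.

Reported headline figures are the mean ± standard deviation across test
models (the per-point pooled variants are also derivable from the saved
per-model tables).

## Benchmark problem sizes

The repository's own benchmark (test suite and examples) keeps the full
1800-model population with the standard batch-wise splits (360 test / 144
validation / 1296 training) for the headline training run, but samples each
wall at a 16×16-point budget with the U-Net's pooling depth scaled so the
bottleneck stays at 4×4 (two levels), the proportion of the full-size
architecture; training uses batch size 8 for 300 epochs with
best-validation weight restoration and batch-norm recalibration.  These are
the largest sizes a single commodity CPU core handles comfortably.  Fewer
pooling levels at the coarse grid matter: with the full four levels the
bottleneck collapses to 1×1×8 and the network demonstrably underfits.  The
four-arm ordering comparison runs on a separate shared 300-model dataset
with a short matched budget per arm (160 epochs, batch 8).  The full-scale protocol (1800 models,
64×64 grid, four levels) is the package default for `RunConfig` and runs
unchanged on larger hardware.

After training, batch-normalization running statistics are re-estimated by
one sweep over the training inputs (the momentum-averaged statistics
collected during training lag the finally restored weights).

## Known limitations

- The surrogate's smoothness makes the regression task easier than learning
  from real CFD; error magnitudes here should not be read as CFD-level
  performance.
- Geometries are planar and stenosis-free; vessel lengths, arc radii and the
  junction blend are declared defaults, not anatomical reconstructions.
- MRE is dominated by the lowest-shear points (lateral walls), where small
  absolute errors are large relative ones; NAME is the stabler headline
  metric, matching how the results are reported.
- Exact bitwise reproducibility holds per platform/BLAS build; across
  platforms, float summation order may differ at the last ulp.
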