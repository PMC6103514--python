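# Methods

This note records the scientific and numerical choices behind `canopyn`:
what the models assume, which defaults matter and why, what the synthetic
generators emulate (and deliberately do not), and where the design was
genuinely open.

## Color spaces and thresholding

Images are assumed to be ordinary 8-bit sRGB camera output. CIELAB
conversion uses sRGB companding with the D65 reference white and the CIE
1976 L\*a\*b\* formulas (via scikit-image) — the standard assumption for
uncalibrated consumer cameras; no white-balance or color calibration is
attempted, which restricts valid use to images taken under comparable
midday illumination. HSI uses the Gonzalez–Woods arccos hue, normalized to
[0, 1), with S = 1 − 3·min(R,G,B)/(R+G+B) and I = (R+G+B)/(3·255);
achromatic pixels take H = 0 by convention, black takes S = 0.

Otsu thresholding operates on channels affinely quantized to the 8-bit
scale (256 histogram bins), so thresholds are integers on [0, 255] and
interpretable on either scale. The between-class variance is maximized by
exhaustive cumulative-moment scan; ties break toward the smallest
threshold. The low class is "value ≤ t", the high class "value > t", and
binarization polarity decides which class is foreground. A constant
channel has no valid split and is a hard error, which the segmentation
cascade surfaces with the failing step named.

## Segmentation cascade

The cascade exploits two separations that hold for a green target plant
over soil with darker green distractors: vegetation is yellow-shifted in
b relative to soil, and the target is brighter in L than the distractor
plants. Both polarities default to "high" but are configurable, because
which Otsu class is "plant" depends on the scene composition.

Numerical choices:

* "Multiply by the original image" is implemented as masking (background
  → (0,0,0)); re-binarizing the L channel of the masked image uses the
  *original* T_L, and zeroed pixels are explicitly excluded so step 4 can
  only remove pixels, never resurrect them (asserted by tests).
* The 7×7 median filter on a binary mask is a majority filter with edge
  replication; an exact tie (impossible for odd windows, defined anyway)
  resolves to background, keeping the cascade conservative.
* The structuring element is the discrete disk {(dx,dy): dx²+dy² ≤ 25};
  "erode twice then dilate twice" is applied literally in that order
  (not as two openings). Erosion treats out-of-frame as background,
  dilation clips to the frame. Filter and element sizes are exposed in
  `SegmentationConfig`.

## Growth status

Geometry is computed on foreground pixel centers in a 0-based frame
(x = column, y = row). The minimum circumscribed circle comes from
Welzl's randomized incremental algorithm run on the convex hull (the
internal shuffle uses a fixed constant seed — the output is the unique
minimum circle, so determinism is preserved); the minimum-area rectangle
is the hull-edge-aligned rotated rectangle (shapely's oriented envelope),
with an axis-aligned mode behind a flag. MER_p and MCC_p are *rasterized*
pixel counts — lattice points inside the shape, clipped to the frame —
because the indicator is a pixel ratio; continuous areas are reported for
diagnostics. Degenerate masks (single pixel, collinear pixels) define the
enclosing count as max(S_p, rasterized count), so GS ≤ 1 always; ratios
are clamped to (0, 1] by default because boundary pixels can push the raw
ratio marginally above 1.

One connected plant per frame is assumed; there is no per-component GS.
The minimum-area rectangle's *orientation* is not unique for rotationally
symmetric masks, so GS_MER is reproducible only to rasterization
tolerance (~0.01) under translation of such masks; GS_MCC is exact.

## Features

Channel means are computed over foreground pixels only, on each channel's
native scale (L in [0,100], a,b in [−128,127], H,S,I in [0,1], RGB in
[0,255]) — not on the quantized scale, which exists only for Otsu —
because fitted coefficients couple to the scale. The "RLI" mixed system
takes R from RGB, L from Lab, I from HSI, in that order. Total nitrogen
is treated as unit-agnostic throughout (the measurement is a combustion
mass fraction; the package never rescales it). Pearson screening reports
two-tailed p-values with 0.01/0.05 flags and excludes zero-variance
predictors with an explicit flag.

## Model families

All five families share the growth-status intercept a_gs = b₀ (+ b₁·GS).
The reciprocal family is implemented as Σ aᵢ/xᵢ, consistent with its
name; published tables of this model class sometimes typeset it
identically to the linear combination, and this reading is a documented
interpretation. Absolute values guard the power and logarithmic families
exactly as their expressions state. Exponential normalizers
xᵢ′ = xᵢmax − xᵢmin are frozen from the modeling subset at fit time,
stored immutably with the model, and never recomputed at prediction.

Identifiability: the logarithmic family is invariant under a → k·a with
b₀ absorbing a₀·ln k (and under a → −a), so fits are canonicalized to
‖a‖ = 1 with the first nonzero coefficient positive. The exponential
family's raw aᵢ depend on the modeling set through xᵢ′; comparisons
across fits therefore use the effective slopes aᵢ/xᵢ′.

The shipped reference model (exponential/Lab/GS_MCC, a₀ = 237.374,
a = (−4.471, −11.927, −2.782), b₀ = −4.274, b₁ = 26.248) carries *unit*
normalizers because the original calibration's channel ranges were never
published; it is intended for structural checks and API examples, not for
prediction on new imagery.

## Fitting

**Least squares.** Linear and reciprocal families are solved in closed
form (lstsq on the transformed design). Power, logarithmic and
exponential families use trust-region least squares with analytic
Jacobians and multi-start: linearization warm starts (log-regression for
power/exponential; for logarithmic, a profile search over directions with
the inner (a₀,b₀,b₁) solved linearly) plus seeded random perturbations,
five starts by default, best objective wins.

**Errors-in-variables.** The estimator treats every error-laden predictor
column (the channel means, and GS when present) as a noisy reading of a
latent true value and minimizes the weighted orthogonal objective jointly
over coefficients and latents. Implementation: a single nonlinear
least-squares problem over (c, Ξ) with analytic sparse-structured
Jacobian; dense Levenberg–Marquardt when the parameter count is small
(tightest convergence — the Deming agreement of ~1e−7 comes from this
path), trust-region reflective above. Warm start at the least-squares
solution with Ξ = X; additional starts perturb only the coefficients. A
column whose error SD is below 1e−8 of its spread is treated as
error-free and carries no latent, which makes the degenerate limit
(σ_x → 0 ⇒ least squares) exact rather than ill-conditioned. The
trust-region/LM iterations are monotone in the objective by construction,
and tests assert the end-to-end decrease from the warm start.

**Error model.** The default Σ is diagonal: there is no information from
a single segmentation to estimate error correlations. Predictor SDs
follow the segmentation color tolerance, σⱼ = 0.03·|mean of column j|
(the 3% color-error bound the cascade itself is held to), the response SD
is the least-squares root residual variance, and everything is
overridable (`estimate_sigma`, `EivConfig`). Whether the original
calibration knew or estimated its Σ is not stated anywhere; this heuristic
is the package's own documented choice.

## Evaluation

δ² uses the n−1 divisor of its defining formula, and mse = ē² + δ² is
kept exactly as defined; note this "mse" is *not* the mean of squared
residuals. Two conventions are deliberately normalized: R² always squares
both sums (the unsquared variant is not even sign-stable), and the
quantity that validation tables of this model class print as "MSE" is
actually √(ē² + δ²) — the package computes both and calls the
table-compatible value `rmse`. The shipped reference table reproduces all
fourteen tabulated error values to four decimals through this identity.

Ranking uses six criteria — modeling R² and |ē|, validation R², |ē|, δ²
and rmse — each ranked with ties sharing the lower rank, aggregated by
sum of ranks (configurable to mean; the original study's aggregation rule
is not derivable from its text, and sum-of-ranks places the exponential-
Lab model first or second on the published criterion values, which the
tests assert rather than the exact published order).

## Synthetic fixtures

**Scenes** are painted directly in Lab and converted to sRGB, which
guarantees by construction the two separations the cascade exploits:
plant vs soil in b (defaults: plant b ≈ 42 vs soil b ≈ 22), plant vs
distractor in L (L ≈ 58 vs 28 at matching b). Per-pixel Gaussian jitter
(SD 1.5–2 Lab units) emulates texture. Scene geometry (disk, ellipse, or
three-lobed blob) is spec-driven; the seed controls only jitter, so the
ground-truth mask is seed-invariant. What scenes do *not* emulate:
illumination gradients, shadows, specular leaves, occlusion, soft canopy
boundaries, and JPEG artifacts — so passing the 5%/3% segmentation suite
on fixtures demonstrates the mechanism (b/L separation → cascade
recovery), not field-grade robustness.

**Sample tables** follow a latent nutrition gradient t ∈ [0,1]: channel
true values move linearly with t (channels co-vary, as they do across
real fertilization gradients) plus independent per-channel uniform
jitter; the response is the generative model at the *true* predictors
plus Gaussian noise; observed predictors add Gaussian measurement noise.
True values ship alongside observations for oracle checks.

Two condition sets are defined once:

* *Study conditions* (`default_study_spec`): n = 48 modeling samples,
  response noise σ_y = 0.3, predictor noise at the 3% color tolerance,
  and the reference model's coefficients with frozen normalizers
  L′ = 20, a′ = 10, b′ = 20. The channel profiles (L 24→28 ± 2.4,
  a −3.5→−5.0 ± 0.6, b 23→27 ± 2.4, GS 0.35→0.75 ± 0.03) are chosen so
  the reference coefficients produce total nitrogen in the observed
  ~4–40 band; the large |a₂| = 11.927 of the reference model makes the
  response extremely sensitive to the green–red channel, which forces
  these relatively narrow, dark-canopy profiles.
* *Recovery conditions* (`family_recovery_spec`): wider profiles spanning
  typical green-foliage Lab values (L 38→58 ± 3.5, a −12→−22 ± 2.5,
  b 22→40 ± 3.0), with per-family random true coefficients drawn from
  ranges bounded away from zero — a sign of a coefficient whose
  contribution is below the noise floor is not an estimable quantity, so
  the documented ranges guarantee every sign is in principle
  recoverable. Intercept-like terms (b₀) are likewise kept off zero, and
  the power/exponential a₀ is solved from the target response level.
  "Low noise" in the recovery tests means σ_y = 0.1 and 1% predictor
  noise at n = 200 per replicate.

## Problem sizes

The test and acceptance runs use: 20 rendered scenes at 320×240 (the
cascade is resolution-independent; full 1024×768 frames behave
identically at ~10× the cost), 200 random point masks of ≤ 30 points for
the geometry oracles, 100 images for the Otsu oracle, 1000 (tests) /
200 (script) random lines for the Deming limit, 200 (tests) / 50 (script)
Monte-Carlo replicates at n = 48 for the bias comparison, and 20
replicates per family at n = 200 for sign recovery. These sizes were
chosen as the smallest at which the Monte-Carlo statistics are stable.

## Known limitations

* No color calibration: channel means are camera- and
  illumination-specific, so fitted coefficients do not transfer across
  cameras without recalibration.
* The reference model's normalizers are unpublished; its predictions on
  raw channel values are therefore not meaningful, only its structure.
* Single-plant frames only; multiple targets would need connected-
  component handling before GS.
* The EIV estimator assumes independent Gaussian errors with known (or
  heuristically set) diagonal Σ; correlated segmentation errors across
  channels are not modeled.
* The bias advantage of EIV over least squares is demonstrated under the
  study-condition generator with correctly specified Σ; with badly
  misspecified Σ the estimator can be worse than least squares.
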