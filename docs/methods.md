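# Methods

This note documents the models, conventions and design choices behind
`blastoquant`, in the order the pipeline runs. The underlying protocol — a
fixed sequence of classical image-processing steps that turns a bovine
blastocyst micrograph into 36 quantitative variables — leaves several
details open; every place where this implementation had to choose is
marked below.

## 1. Standardization

Input images are 8-bit greyscale or RGB, JPG/BMP/PNG. RGB is collapsed
with ITU-R BT.601 luma weights (0.299, 0.587, 0.114), rounded half-up; the
protocol does not state the weights, and BT.601 matches the default of the
common commercial imaging platforms. Geometry is then forced to aspect
0.75: too-tall images lose rows **from the top** (a 1,280×1,024 capture
loses exactly 64 rows), too-wide images (not part of the original capture
protocol) lose columns symmetrically so the centred embryo stays centred.
Resizing to 640×480 is bicubic with anti-aliasing on downscale. Finally a
linear contrast stretch maps the empirical 1%/99% intensity quantiles to
0/255 and clips outside — "1% saturated per tail" is our reading of the
stated 1% total saturation, matching the default of the reference
platform's histogram-adjustment routine; both tail fractions are
configurable (`stretch_lower_pct`, `stretch_upper_pct`). A constant image
cannot be stretched and passes through with a logged warning. The whole
step is deterministic: identical bytes in, identical pixels out.

Coordinates throughout the package are 0-based, row-major, origin top-left,
x = column, y = row.

## 2. Embryo localization

Edges come from a 3×3 Sobel gradient magnitude rescaled to [0, 255]
(the protocol says only "magnitude of the image gradient"), binarized at
threshold 128 with the convention ≥128 → true (the side convention is
unstated). The circular Hough transform runs twice, radii 100–150 px and
150–250 px, sampled every `radius_step` = 2 px (the recovered radius is
accurate to ±1 px at this sampling, well inside the pipeline's ±2 px
target; step 1 doubles the cost for no benefit). The accumulator "metric"
is the normalized peak height ≈ fraction of the circle perimeter supported
by edge pixels. The published two-stage rule ("metrics are compared and
the largest radius is used") is ambiguous; we implement
*best-metric-wins, ties to the larger radius* and keep both stage
candidates in the result's diagnostics. Detection fails (a structured
error, never a guess) when the best metric is below `embryo_min_metric`
(default 0.05).

Region masks: ER = disc of radius r+5, RR = disc of radius r−40,
TE = ER∖RR. Sub-images are cropped to the ER bounding square of side
2·round(r+5) with an explicit boolean mask channel — background is never
encoded as a sentinel intensity. A square of side 2R cannot contain the
extreme row/column of a radius-R disc, so up to 4 boundary pixels fall
outside the crop; full-frame masks remain exact. At image borders the
square may clip; *Radius ER* is reported as r+5 by definition regardless.
"Total area of the embryo" is the ER mask pixel count (not πr²), which is
exact under clipping.

## 3. GLCM texture (variables 1–8)

The region is quantized to 8 equal-width grey levels between the masked
minimum and maximum (the reference platform's grey-limits default;
`glcm_fixed_range` switches to fixed 0–255 binning). The co-occurrence
matrix counts ordered pairs (p, p+offset) with both pixels in the mask, at
offset d=1, θ=0° (one pixel to the right) — the protocol never states d or
θ; these are the common defaults and both are configurable. The matrix is
not symmetrized; probabilities are counts over the pair total.

Statistics: contrast Σ|i−j|²p, correlation Σ(i−µᵢ)(j−µⱼ)p/σᵢσⱼ,
energy Σp², homogeneity Σp/(1+|i−j|). **Homogeneity denominator:** the
printed formula in the source protocol reads 1+|i+j|, but its own stated
property — homogeneity equals 1 for a diagonal GLCM — holds only for
1+|i−j|; the printed form is treated as a typographical error and |i−j| is
implemented. Degenerate regions (no valid pair) are flagged and yield the
constant-region values (contrast 0, energy 1, homogeneity 1); zero-variance
correlation is undefined and recorded as NaN, written as an empty table
cell, never silently replaced by 0.

Because masked-pixel quantization and masked-pair counting may differ from
the original implementation (which may have included background zeros of
the cropped square), exact reproduction of the deposited per-image texture
values is not guaranteed — a documented limitation.

## 4. Inner dark/light circles (variables 9–16)

Four detections on the ER sub-image: dark and light circles of radius
4–8 px ("sensitivity" 0.935) and 9–15 px (0.94). The reference circle
finder's sensitivity index has no public definition, so its mapping here is
implementation-defined and monotone: normalized accumulator threshold
τ = clip(5·(1−s), 0.05, 0.95), i.e. 0.935 → 0.325 and 0.94 → 0.30.

The detector is an orientation-coded CHT. Canny edges (σ=1) are computed
with hysteresis thresholds tied to `inner_min_gradient` (default 12 grey
levels/px ≈ the Sobel response of a minimally interesting 30-grey-level
blurred step edge); only edges at least that steep vote. Each edge pixel
casts one vote at distance r along its gradient — against the gradient for
dark circles (their gradient points outward), along it for light ones.
Votes are pooled over ±1 px and normalized by perimeter 2πr. Peaks above τ
are validated by a least-squares (Kåsa) circle refit of the
orientation-coherent edge pixels near the candidate, with four checks:
refitted radius inside the class range (±0.5 px) — this is what stops one
physical circle from being counted in both size classes; radially thin
support (MAD ≤ 1.2 px); angular support coverage ≥ 60% of the perimeter
(arcs of the zona, the ICM boundary, or satellite responses subtend well
under half a turn); and a disc-vs-surround intensity contrast of at least
`polarity_margin` (15 grey levels, half the 30-level contrast the detector
is specified to resolve) with the requested sign. Accepted circles are kept
greedily by score with centre separation ≥ min radius and no centre inside
an already-kept disc.

*Mean DC/LC intensity*: a binary mask is built by stamping a disc of the
**mean** detected radius at every detected centre (intersected with the ER
mask); the variable is the mean grey intensity over that union. An empty
circle set contributes count 0 and mean 0 (a number must occupy the cell),
flagged in the quality column.

## 5. First-order intensity statistics (variables 17–31)

Sum ER is the fraction of ER pixels strictly above the Otsu threshold of
the ER histogram, over the ER area; a constant region has no Otsu split and
yields 0 with a flag. Deviation uses the sample (n−1) formula and needs
n ≥ 2 (NaN otherwise). The mode breaks ties toward the smallest intensity.
Dark/bright counts use inclusive boundaries (≤25, ≥230); the near-mean
count uses the **regional** mean ±10, bounds inclusive (whether the
original used the regional or whole-image mean is unstated). All fractions
divide by the ER pixel count, including those computed on RR and TE.

## 6. Watershed and ICM descriptors (variables 32–36)

The watershed treats intensity as topography (dark = low) on the ER region
(configurable to RR), 8-connectivity, no marker control and no minima
suppression — the protocol describes none. Implementation details chosen
here: the working surface is rounded to integer grey levels (8-bit
semantics; sub-grey-level ripples must not seed basins), the background is
raised to a plateau above the embryo maximum so it forms no interior basin,
and basins are seeded from the regional minima of that surface (a fully
flat embryo is then exactly one basin). Optional Gaussian pre-smoothing
(`watershed_smooth_sigma`, default off) and a gradient-surface variant
(`watershed_on_gradient`, default off) are provided because the raw
transform over-segments noisy images — on realistic noisy inputs WSN runs
into the thousands, and deposited WSN values are likely reproducible only
with the original platform's exact implementation.

The ICM proxy is the largest basin (ties → smallest label): area, convex
hull area ("smallest convex polygon"), eccentricity of the
same-second-moments ellipse (focal distance over major axis: 0 = circle,
→1 = line segment) and mean intensity.

## 7. Grades and agreement

The modal grade of three raters on {1, 2, 3} equals the median of the
sorted triple; this also resolves the (1, 2, 3) three-way disagreement to
2, the tie rule adopted here (the protocol never defines it). When a
deposited table carries its own mode column, that column takes precedence.
Inter-rater agreement is Fleiss' kappa (computed via statsmodels); because
the published index does not name its variant, Light's kappa (mean pairwise
Cohen) is computed alongside. Kappa is undefined (NaN) when expected
agreement is 1.

## 8. Synthetic phantoms

The generator renders what the pipeline assumes: a bright field (220), a
circular embryo (standardized-frame radius 100–245 px) rimmed by a dark
zona ring (intensity 110, width 4 px), a textured trophectoderm annulus
(mean 150) inside it, a blastocoel interior (170) with faint large-scale
granularity, a dark elliptical ICM (90), optional dark (100) / light (240)
circular inclusions of radius 4–15 px, then an optics blur (σ=1.2) and
additive Gaussian camera noise (σ=3), clipped to 8 bits. Rendering defaults
to 1,280×1,024 at 2× scale with 64 extra top rows, so standardization's
crop-and-halve path is exercised; a 640×480 option exists. All coordinates
in the spec and ground truth live in the standardized frame. A fixed seed
gives byte-identical images.

Two deliberate identifiability choices: TE granularity uses 1.2 px blobs —
finer than the 4–15 px circle-detector band — so inclusion counts have
unambiguous ground truth; and randomly drawn inclusion radii keep a guard
band around the 8|9 px class boundary (light discs get a wider band because
they saturate in the contrast stretch and bloom ≈1 px outward). Embryos
with radius above ~235 px cannot fit a 480-px-tall frame; up to 12 rows of
vertical clipping are tolerated and the CHT recovers the circle from the
visible arc.

What the phantoms do **not** emulate: real trophectoderm cell boundaries,
zona thickness variation, debris, defocus gradients, or degenerated
embryos. Passing the recovery suite therefore demonstrates the geometry
and statistics of the pipeline, not grading performance on real imagery.

**Recovery protocol.** Embryo radius/centre (±2 px) and inclusion counts
(exact, at ≥30 grey contrast and ≥4 px separation) are validated on noisy
phantoms. ICM shape recovery (eccentricity ±0.05, area ±10%) is validated
on noise-free renders with the gradient-surface watershed: basin
boundaries then sit on the maximum-gradient contour, i.e. the true edge,
whereas the marker-free transform on noisy surfaces fragments — a
documented property of the method, not of the phantom.

## 9. Sizes and numerical conventions

The default test and acceptance runs use 20 random phantoms for parameter
recovery, 6 noise-free phantoms for ICM shape, 10,000 items for the
kappa null check, and 50×50 regions for the analytic GLCM identities —
sizes at which every stochastic check is far from its tolerance. Rounding
is half-up everywhere intensities are quantized; percentiles use numpy's
linear interpolation; all randomness flows from explicit integer seeds.

## 10. Known limitations

* Per-image reproduction of the deposited variable table is out of reach
  where the original platform's internals are unstated (GLCM offset and
  background handling, circle-finder sensitivity semantics, watershed
  implementation details); the package instead guarantees the analytic
  identities and phantom-recovery properties above.
* The embryo detector assumes one approximately centred embryo; multiple
  embryos or empty fields produce a detection error, not a best guess.
* 16-bit inputs are rejected rather than rescaled.
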