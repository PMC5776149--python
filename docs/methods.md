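# Methods

## The model

The package computes the relative distribution of light on the retina that
results from intraocular scatter (disability glare), starting from an exact
array of scene luminances. The optical model is the CIE standard glare
observer: the equivalent veiling luminance per unit glare illuminance at the
eye, as a function of the visual angle θ (degrees) between the glaring and
the receiving point,

    GSF(θ) = [1 − 0.08(A/70)⁴] · [ 9.2·10⁶/(1+(θ/0.046)²)^1.5 + 1.5·10⁵/(1+(θ/0.045)²)^1.5 ]
           + [1 + 1.6(A/70)⁴] · [ 400/(1+(θ/0.1)²) + 3·10⁻⁸θ²
                                  + p·(1300/(1+(θ/0.1)²)^1.5 + 0.8/(1+(θ/0.1)²)^0.5) ]
           + 2.5·10⁻³ p

with observer age `A` (years) and iris/fundus pigmentation factor `p`
(0 very dark eyes … 0.5 brown … 1.2 blue). Every denominator is ≥ 1, so the
function is finite at θ = 0; over the standard's domain 0.01–100° it falls
monotonically from above 10⁶ to about 3·10⁻³ sr⁻¹. Defaults are A = 25,
p = 0.5 (a young brown-eyed observer).

The glare kernel samples this curve on a flat pixel grid: entry at integer
offset (i, j) from the center is GSF(d·√(i²+j²)) where d is the angular
pixel pitch (default 15.5°/600 px ≈ 0.0258°/px, the reference target
geometry). The kernel side is 2r+1 with r = max(width, height), so every
pixel influences every other; it is divided by its own sum so it sums to
exactly one and convolution introduces no DC gain. (A looser prose reading
would make the kernel radius twice the larger image dimension; the explicit
matrix definition r = max(w, h) is what is implemented.) The convolution
uses replicate (edge-extend) padding of half the kernel side on every edge
and is evaluated by FFT; correctness is defined by direct spatial
convolution, with which the FFT path agrees to ~10⁻¹⁵ relative. Output
pixels pushed below the scene minimum by FFT round-off are clamped to that
minimum and counted in the log.

The pipeline output is *relative* retinal contrast: a flat-plane, normalized
photopic-energy array. Pre-retinal absorption, pupil size, the
Stiles–Crawford effect and retinal curvature are deliberately outside the
model; the output is not an absolute retinal luminance.

## Scene input

HDR scenes enter as an 8-bit "paint-by-numbers" map plus a 256-entry
digit → log₁₀ relative-luminance table (the calibration of a physical
transparency target measured with a densitometer). Digit 0 is reserved for
the opaque border/darkroom floor and maps to 10⁻¹⁰⁰ — effectively zero but
strictly positive so logarithms stay defined. Scene luminance is
10^table[map], in double precision throughout. Camera images are not
accepted as luminance input: camera optics add their own veiling glare.

## Energy bookkeeping

A unit-sum kernel redistributes energy; with replicate padding the output
sum equals the input sum only insofar as glare leaking out of the array is
balanced by glare entering from the padded band. The CIE kernel is heavy
tailed (~θ⁻³), so the balance depends on angular sampling:

- at coarse sampling (≳0.5°/px) the discrete kernel mass concentrates in
  the central pixel and a dark-bordered raster conserves its sum to better
  than 0.1% (this is the regime the conservation test asserts);
- at the fine reference pitch (0.0258°/px) roughly 1–7% of the kernel mass
  falls beyond the raster from an interior pixel (more for smaller rasters),
  so a dark-bordered target loses that fraction of its sum — the 375×300
  reference run reports a sum ratio of ~0.982.

The pipeline logs input and output sums so this leak is always visible.
Within the raster, invariants that do hold exactly: constant rasters are
fixed points, the output minimum is ≥ the input minimum, the max/min
dynamic range never increases, and adding light to any pixel never darkens
any output pixel.

## Visualization

For inspection, linear rasters are encoded as 8-bit log-range images:
digit = round(255·(1 + log₁₀(v/v_max)/range)), clipped to [0, 255], with
the analysis range defaulting to 5.4 log₁₀ units so digit 128 encodes
−2.7. Rounding here and in all integer rescaling is half-away-from-zero.
The pseudocolor palette has 64 colors in 8 progressions of 8, linearly
interpolated between the anchors black → dark brown → red → magenta → blue
→ cyan → green → yellow → white (anchor hues are canonical choices; the
original figures' exact hues are not recoverable). Digits are binned four
per color via index = clip(⌈digit/4⌉−1, 0, 63): 64 bins of width 4 do not
tile 0–255 with the mid-range anchor exactly on digit 128, and this
binning resolves the conflict in favor of digit 128 → blue (entry 31,
end of the fourth progression) and digit 255 → white (entry 63).
`rescale_to_output` re-anchors the observed digit span to 0–255 (affine,
idempotent) and shrinks the recorded range to the spanned sub-range, which
makes scene-dependent output compression directly comparable across
targets. Horizontal scan profiles average linear values over a row band
per column and report log₁₀ relative to the raster maximum.

## Synthetic targets

The generator emulates double-transparency HDR displays: 750×600 px
(15.5×19.1°), an 8 px opaque border at digit 0, 20 pairs of gray test
squares, and a background that is uniform white, uniform black, or an
equal-area mosaic of white and black squares with sides from
{1, 2, 4, 8, 16, 32, 64} px. One film spans 2.7 log₁₀ units of optical
density; superimposing two identical films doubles every density
(5.4 log₁₀ units). The conversion table is linear in OD with digit 255 =
clear film (log 0) and digit 1 = full density, which makes the test-square
range exactly 10^2.7 ≈ 501:1 per film and 10^5.4 ≈ 251 189:1 doubled, and
puts the white half of a double-density mosaic background at 50.00% of the
maximum on average. (The physical targets' published range prose of
"2.9/5.8 log units" is inconsistent with those ratios; the ratios are
treated as authoritative.)

Mosaic construction: test squares are placed on a slot grid (pair
locations shuffled by the seed), the remaining interior is tiled greedily
top-left to bottom-right with randomly sized squares, odd counts in a size
class are repaired by splitting one square into four half-size squares, and
colors alternate within each shuffled size class — so white and black areas
balance to within one smallest square. Exact positions, sizes, digits and
roles are recorded in a layout record (JSON sidecar on disk), so region
masks for summaries and for joining observer data are exact. The test-pair
luminances are log-spaced across the film span with a 0.15 OD step inside
each pair; the original display's particular pair values and mosaic
arrangement are not recoverable and are not emulated beyond this structure.
For the all-white background the test-square digits are clamped to ≤ 254 so
every test patch is strictly darker than the surround; the 501:1 range
summary therefore applies to the half- and black-background variants.

What the generator does not emulate: film grain, densitometer noise,
lightbox spectrum and absolute luminance (1,056 cd/m² is metadata only).
Tests passing on these targets show the calculation chain is correct on
exactly calibrated input; they do not show robustness to measurement error
in real calibrations.

## Lightness response (HRF)

Apparent lightness of a test patch is modeled as linear in the log of its
relative retinal contrast,

    L = (26.7 + s)·log₁₀ R + 93,

on a 0–100 scale, with a scene-content factor s: 0 for a black surround
(the white-to-black swing spans 93/26.7 ≈ 3.5 decades), 20 for the
half-white mosaic, 30 for a white surround (93/56.7 ≈ 1.6 decades). Fits
are ordinary least squares with the Pearson correlation reported; the scene
factor is read off as slope − 26.7. The historically fitted slopes for the
white and mosaic surrounds (56.3, 47.0) came from observer data that are
not available here; the package asserts only the model-implied slopes
(56.7, 46.7) and the exactly stated black-surround slope 26.7. A test
square's retinal contrast is sampled as the mean over its interior eroded
by 1 px, so the glare gradient at the patch edge does not bias the mean
(the sampling rule is a package choice; none is prescribed by the model).

## Numerical choices and problem sizes

- All raster arithmetic is float64; kernel agreement with brute force is
  asserted at 1e-12 relative, FFT-vs-spatial at 1e-9 relative (double
  precision FFT round-off), noiseless HRF recovery at 1e-10.
- Angles beyond the standard's 100° domain (corners of wide fields) are
  extrapolated smoothly by the same formula, with a warning; geometries
  whose per-axis field exceeds 200° are rejected.
- Test and acceptance runs use scaled-down rasters (21–31 px oracles, a
  375×300 pipeline target) — the calculation is size-independent, and these
  sizes keep the full suite and the end-to-end run in seconds while
  exercising every code path at full kernel support.
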