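# Methods

This note documents the conventions, parameter choices, and numerical
behavior behind each measure family, the assumptions of the synthetic
generators, and the known limitations. All statistics use population (not
sample) variance/SD, and every random quantity in the package is a pure
function of an integer seed.

## Pre-processing conventions

All inputs are normalized at load time to 8-bit RGB: grayscale is promoted
to three channels, alpha is composited over white, 16-bit values are
rescaled. One color pipeline serves the whole suite: CIELAB assumes sRGB
primaries with a D65 white point; HSV channels live on [0, 1]; the 8-bit
gray conversion uses the legacy luma weights 0.299/0.587/0.114. Published
variants of these measures disagree on exactly these constants, and the
differences propagate into every downstream value — fixing one convention
keeps the suite internally consistent and makes parity checks against other
implementations possible by swapping a single documented constant.

Resizing is bilinear with pixel-center alignment. The named size policies
are: longest-side resize; total-pixel resize (closest product not above the
target, aspect preserved; changes of at most one pixel per side are skipped,
which makes all policies idempotent); a downscale-only pixel cap; fixed
square; centered crop to the largest power-of-two square; and padding to a
square filled with the image mean. Several measures are size-dependent
(gradient-based complexity most of all), so fixed defaults are applied
where a published protocol specifies them: 120,000 pixels for the Gabor
edge measures, 100,000 for the PHOG measures, 1024² inside two of the
slope protocols, 511² for the CNN measures (below).

## Histogram entropies

Lightness entropy and color (hue) entropy are Shannon entropies of
256-bin equal-width histograms over the channel's full declared range (L*
0–100, H 0–1). The bin count is a convention — 8-bit provenance makes the
uniform-occupancy maximum exactly 8 bits. Hue is treated as a plain linear
variable; no circular statistics are applied anywhere, matching the
per-channel scripts these statistics are meant to be comparable with.

## Balance, DCM, mirror symmetry, homogeneity

Perceptual mass is `255 − gray` when dark pixels count as heavy (the
convention for black shapes on white grounds) or `gray` for bright-heavy
material. The Balance score averages the percent mass imbalance
`100·|M1−M2|/(M1+M2)` over eight pairs of equally sized areas: for each of
the four main axes (vertical, horizontal, two diagonals), the two halves,
and the two outer regions cut off by lines parallel to the axis at the
25%/75% positions of the perpendicular extent — placed so the inner band
equals the combined outer area. Region membership is decided by ranking
pixels along the signed perpendicular coordinate; pixels whose rank
interval straddles a region boundary are shared fractionally. This makes
the two areas of every pair *exactly* equal on any image size and keeps all
scores exactly covariant under reflections (verified against brute-force
oracles on all 512 binary 3×3 images).

DCM measures the Euclidean distance between the mass centroid and the
geometric center ((W−1)/2, (H−1)/2) in pixel-center coordinates, as a
percentage of the center-to-corner-pixel distance; a single heavy corner
pixel scores exactly 100. Mirror symmetry averages, per axis, the mean
absolute pixel difference between the image and its reflection
(`100·(1 − mean|I − m(I)|/255)`); square images use all four axes,
rectangular ones only vertical and horizontal (diagonal reflections do not
preserve a rectangle). Homogeneity binarizes with the Otsu threshold
(black strictly below), counts black pixels in a 10×10 grid with integer
boundaries `round(k·H/10)`, and reports Shannon entropies of the cell, row,
and column count distributions, each normalized by its maximum (log₂ 100 ≈
6.64 bits for the cells) and expressed in percent; the headline value is
the mean of the row and column components.

Degenerate inputs (blank under the chosen polarity, constant images where
Otsu is undefined) return NaN with a `DegenerateImageWarning` rather than
an arbitrary number.

## HOG pyramid: complexity, anisotropy, PHOG self-similarity

The combined gradient image takes, per pixel, the largest of the three
CIELAB channel gradient magnitudes ([−1, 0, 1] central differences with
replicated borders — the canonical HOG kernel, which keeps step-edge
responses closed-form), with the orientation of the winning channel (ties
resolved in L\*, a\*, b\* order). Orientations are signed over the full
circle and binned into 16 equal 22.5° bins with bin 0 centered at 0°.

The pyramid holds strength-weighted orientation histograms for 1/4/16/64
sections at levels 0–3 (integer section boundaries `round(k·H/2^ℓ)`);
levels above 3 are rejected because the sections become too small for
stable histograms. Complexity is the mean gradient strength; PHOG
self-similarity is the mean (over levels 1–3, equal weights by default) of
the mean histogram-intersection between each section histogram and the
ground histogram, both normalized to sum 1; anisotropy is the SD of the 16
bin values of the bin-wise sum of all 64 level-3 histograms after
normalization — 0 for isotropic gradient energy, √15/16 ≈ 0.242 for a
single-orientation image.

## Gabor edge measures

The bank covers 24 orientations in 15° steps over the full circle, realized
as 12 quadrature (even/odd) kernel pairs with wavelength 8 px, isotropic
Gaussian envelope σ = 4 px, and exactly zero mean. Quadrature energy is
mathematically identical at θ and θ+180°, so direction within a pair is
assigned by edge polarity — the sign of the odd-filter response. This is
what makes the 360° label set meaningful: the two sides of a dark line on a
white ground land in opposite bins, and patterns with uniformly distributed
line orientations approach the log₂ 24 ≈ 4.585-bit entropy ceiling. The
image is padded with edge replication before filtering so constant images
produce exactly zero response everywhere, and downscaled to at most 120,000
pixels first for comparability.

Edge density sums the quadrature energy over all pixels and all 24
orientations (each pair counted for both directions). First-order EOE is
the entropy of the strength-weighted 24-bin orientation histogram.
Second-order EOE takes the 10,000 strongest edge pixels (stable sort, no
non-maximum suppression), forms every unordered pair at Euclidean distance
≥ 20 px (closer pairs are dominated by trivial collinearity), bins the
label difference modulo 360° into 24 bins, and returns the entropy of that
difference histogram. Enumeration is exact — all ≈ 5·10⁷ pairs — in
chunked vectorized passes; the result matches an all-pairs double loop on
small instances to machine precision.

## Spectral slope, sigma, fractal dimensions

The radially averaged spectrum assigns each Fourier coefficient to the
annulus of its rounded integer radius (cycles/image) and averages amplitude
or power per annulus, DC excluded, radii up to N/2. Three slope protocols
are implemented exactly as published; they differ in pre-processing
(power-of-two crop vs. mean-gray padding + 1024² resize), spectrum (amplitude
vs. power — the power slope is twice the amplitude slope), frequency
selection (Cook's-distance pruning vs. the 10–256 cycles band vs. dropping
the outer frequency quartiles), and binning (the 10–256 band is averaged in
100 equal log-frequency bins before fitting). The Cook's-distance rule uses
the conventional 4/m threshold (m = fitted points, one pruning pass, one
refit); the threshold is a parameter. Fourier sigma is the mean squared
residual about the binned-protocol line, either of all raw annulus points
(the classic definition, which over-weights high frequencies) or of the
binned points themselves.

The 2D fractal dimension crops to the largest central power-of-two square,
binarizes at the mean L* (black strictly below), and counts, for box sides
side/2 … 4, the boxes containing both classes (the black/white boundary);
D is the OLS slope of log₂ N against log₂(1/L) and lies in [1, 2] for
valid fits. The 3D differential variant box-counts the L* surface: for box
size s, each s×s column contributes `floor((max−min)/h) + 1` boxes with
height h = s·255/side; D is the slope of ln N versus ln(1/s), range
[2, 3]. The crop is taken to the largest central power-of-two square so the
box schedule tiles exactly. Out-of-range fits are flagged, never clamped.

Known limitation: differential box counting saturates for very rough
surfaces. On synthetic fractional-Brownian surfaces it recovers
D = 3 − H within ±0.15 for H ≥ 0.5 but reads ≈ 2.55 instead of 2.8 at
H = 0.2, for two verified reasons — the +1 term flattens counts where box
heights exceed typical ranges, and the max–min of s² samples underestimates
the continuum sup of a rough field at small boxes. Rank orderings (which is
what the concordance statistics use) are unaffected.

## CNN first-layer measures

All four measures read the rectified responses of a 96-filter bank of
11×11×3 kernels applied at stride 4 — the geometry of a standard
object-recognition network's first convolutional layer, whose filters are
oriented luminance edges and color-opponent blobs. Pretrained weights can
be loaded from a `.npy` tensor (shape 96×3×11×11, per-channel mean
subtraction as in their training convention); the default is a seeded
surrogate bank (64 oriented Gabor-patch luminance kernels + 32
red-green/blue-yellow center-surround kernels, zero-mean, unit norm,
per-image mean subtraction), which preserves every structural property the
measures depend on and keeps tests self-contained.

Inputs are resized once, bilinearly, to 511×511. With kernel 11 and stride
4 this makes the 126×126 response lattice closed under reflection, and the
symmetric pixel-center resize maps mirror-symmetric inputs of either parity
to exactly mirror-symmetric arrays — so the symmetry scores reach exactly 1
on symmetric images. (Resizing to 512 and trimming one row/column does
*not* have this property: trimming breaks even-parity symmetry.) Symmetry
compares the response stack with the spatially flipped stack of the
axis-flipped kernels via sum(min)/sum(max); the combined left-right-up-down
score takes element-wise min/max over all four stacks and can never exceed
either single-axis score. CNN self-similarity is the median over an 8×8
grid of histogram intersections between per-section and whole-map
per-filter maxima; sparseness is the mean across-filter variance of the
8×8 max-pooled responses, and variability the median across-space variance
per filter. A constant image under the bias-free surrogate bank yields an
all-zero stack; the similarity and symmetry scores are then undefined (NaN
with warning) rather than 1.

## Synthetic generators

Each generator derives its random stream from the seed plus a generator
tag, so outputs never shift when other fixtures are added. Random-phase
images impose an exact radial amplitude law f^(−α) on the unit-magnitude
phase field of white noise (Hermitian symmetry preserved, imaginary residue
at machine precision) and rescale to [0, 255]; values are kept as floats
rather than quantized so the prescribed spectrum holds to the highest
frequencies — steep spectra would otherwise drown in a flat quantization
floor. Fractional-Brownian surfaces use the same synthesis with amplitude
exponent H+1 (power 2H+2). Line patterns draw fixed-length anti-aliased
segments (4× supersampling, box downsampling) with exact orientation
bookkeeping under single/discrete/uniform laws and lattice or random
layouts. Mirrored composites and tiled textures provide exactly symmetric
and exactly self-similar inputs.

What the generators do not emulate: natural-scene phase structure (objects,
occlusion, shading), color gamuts of real photographs or paintings, and
sensor noise. Passing tests therefore establish that the measures compute
their definitions correctly and recover controlled ground truth — not that
any particular aesthetic claim holds on real artwork corpora.

## Batch tool

`qip run` computes selected measures for every image in sorted-path order,
one CSV row per image (46 measure columns in the documented order, plus the
image name and an error column). Per-image failures are isolated: the row
carries NA values and the reason, and the process exit status reflects
partial failure. Execution is single-threaded by design — users parallelize
by sharding input lists — and bit-reproducible for a fixed seed. The full
roster enumerates 46 columns; coarser groupings that count channel
statistics as single properties arrive at smaller totals for the same set.

## Problem sizes used in the checks

The concordance statistics are computed on 200 synthetic random-phase
images at 512×512 with exponents uniform in [0.5, 2.0]; slope-recovery
checks use 20 replicates per exponent at 1024²; Hurst-recovery checks use 5
replicates per H at 1024². These sizes make the whole verification suite
run in a few minutes on one CPU while keeping every estimate's sampling
error well inside the asserted tolerances.
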