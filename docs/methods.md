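# Methods

## Problem setting

H&E-stained sections of the same tissue block look very different when
stained in different laboratories: stain formulation, protocol and scanner
all shift the color distribution while the morphology stays fixed.  Stain
normalization maps a source image's colors onto a reference image's while
preserving tissue structure.  This package implements four classical
normalization methods, the selection procedures that choose the reference
and representative samples, a six-metric evaluation suite, and a synthetic
multi-laboratory slide generator so the entire pipeline can be exercised —
with ground truth — at desk scale.

## Color model

All stain manipulation happens in Beer-Lambert optical density,
`od = -log10(I / i0)` per RGB channel with reference white `i0 = 255`
(configurable for non-8-bit rasters).  Stains absorb independently, so a
pixel's OD is (ideally) a nonnegative combination of two unit *stain
vectors* — the columns of the 3x2 stain matrix `W`, hematoxylin first.
Hematoxylin is identified as the column whose red OD component exceeds its
blue one (hematoxylin absorbs red more than blue, which is why nuclei look
blue-purple); ties break toward the larger red component.

Zero pixels are floored at half an intensity level before the logarithm
(`-log10(max(v, 0.5)/i0)`): the map stays finite, every integer value >= 1
is mapped exactly, and the floored value still rounds back to 0 on
inversion.

Statistical color transfer uses Ruderman's lαβ space: RGB through a cone-
response matrix to LMS, `log10`, then a fixed orthogonal-scaling rotation
onto a luminance axis and two chroma axes.  The published coupling matrix
rows sum to 0.9996/0.9993/0.9973; we rescale each row to unit sum (a <0.3%
perturbation) so achromatic pixels map to exactly `α = β = 0`.  LMS
responses are floored at 1e-6 before the logarithm.

## Normalization methods

All four methods run on the whole image at once, never patchwise, so
whole-slide statistics drive the fit and no tiling seams appear.

**Histogram matching.**  Per-RGB-channel monotone quantile mapping.  Each
distinct source value sits at the *mid-rank* (averaged-rank) quantile of
its tie block and is sent to the first reference gray level whose
empirical CDF reaches that quantile.  Mapping directly onto the
reference's own levels avoids the interpolate-and-round variant's level
collisions; mid-ranks center each tie block, which halves its CDF
displacement.  A reference channel with fewer than two distinct values is
rejected.  Note a hard limit of 8-bit data: a tie block of mass `p` must
move wholesale (splitting it would violate the constant-channel contract),
so the vertical KS distance between output and reference CDFs is bounded
below by roughly `p/2`.  On images whose channels are compressed onto few
gray levels (heavy under-staining, chroma-collapsed stains) this floor can
reach 1-2% regardless of implementation.

**Reinhard.**  Per-channel moment matching in lαβ:
`out = (src - mean_src)/std_src * std_ref + mean_ref`, then back to RGB
with clamping.  Pre-clamp channel means and stds equal the reference's to
floating-point precision and are recorded in the result diagnostics.  A
zero-variance source channel raises by default; an opt-in flag substitutes
`std = 1e-6`.

**Macenko.**  Background pixels (all OD channels < 0.15) are discarded;
the remaining OD cloud is projected onto the plane of its top-2 right
singular vectors; the stain vectors are the directions at the 1st and 99th
percentiles of the projected angle.  Source concentrations (least-squares
per pixel, negatives clamped) are rescaled per stain so their 99th
percentile (computed over tissue pixels) matches the reference's, then
reconstructed through the reference stain matrix.  Defaults
(`od_threshold = 0.15`, `angle_percentile = 1`, `scale_percentile = 99`)
follow the original method's published values.

**Vahadane.**  Stain basis and density from sparse NMF:
`min ||V - WH||_F^2 + λ Σ H` over tissue-pixel OD with `H >= 0` and
`W >= 0`, unit columns, `λ = 0.1`.  Solved by HALS (hierarchical
alternating least squares): each block update — an L1-soft-thresholded
projection for an H row, a normalized positive part for a W column — is
the exact minimizer of its subproblem, so the objective is non-increasing
by construction (we chose HALS over multiplicative updates precisely
because the unit-norm constraint breaks the monotonicity proof for the
latter).  Initialization is the Macenko fit; the procedure is
deterministic.  Normalization rescales the source density per stain to the
reference's 99th-percentile scale and recombines with the reference basis.

A known behavior, visible in our self-normalization measurements: the L1
term biases the fitted eosin vector ~1-3° *inside* the OD cone (sparsity
strengthens the bias; with `λ = 0` the fit agrees with an unpenalized NMF
oracle to <1°).  Pixels outside the narrowed cone get clamped
concentrations, so the brightest pure-eosin pixels reconstruct several
levels off.  This mirrors the well-documented tendency of this method to
distort extreme colors (e.g. tinting white backgrounds).

## Selection procedures

**Reference selection.**  For each panel image the ratio of red to blue
channel mean intensities is computed; the image with the ratio closest to
1 (balanced H&E expression) is the reference.  Ties break to the lowest
index.  The full ratio list is kept for the convergence plot.

**Representative selection.**  Per-channel lαβ histograms (64 bins over
panel-global channel ranges) are concatenated as features, centered and
projected onto the first two principal components (no variance scaling),
clustered with seeded k-means (k = 8 by default, 10 restarts, best
inertia), and the member nearest each centroid represents its cluster.  A
within-cluster-sum-of-squares curve for k = 1..min(12, n) is attached as
an elbow diagnostic; k stays at its default even when the elbow suggests
otherwise, so the protocol is reproducible and the diagnostic is surfaced
rather than acted on.

## Evaluation suite

Color-transfer quality: per-channel lαβ histograms (256 bins over
panel-global ranges; background included by default, an OD-threshold
tissue mask is available) compared by histogram intersection, Pearson
correlation, Euclidean distance and Jensen-Shannon divergence (base-2,
bounded in [0, 1]); the three channel scores are averaged, unweighted,
into one scalar per metric.  An undefined correlation (zero-variance
histogram) is reported as missing, never as 0.

Structural preservation: SSIM of the normalized image against the
*original* (Gaussian-weighted 11-pixel windows, sigma 1.5, stabilizers
`C1 = (0.01·255)^2`, `C2 = (0.03·255)^2`, per-RGB-channel then averaged).

Style-plus-structure: Fréchet distance between Gaussian fits of tile-level
feature clouds, `||μ₁-μ₂||² + Tr(Σ₁+Σ₂-2(Σ₁Σ₂)^½)` with a symmetric
matrix square root and `1e-6·I` shrinkage.  The default extractor is
deterministic and self-contained (eight seeded 5x5x3 convolution kernels;
mean/std of each response plus per-channel means/stds, D = 22); a plug-in
interface accepts pretrained-network features when literal comparability
with published FID magnitudes is needed.  Our FID values are comparable
within a run, not across extractors.

## Synthetic study design

The generator emulates the multi-center design: one `TissueField` (shared
morphology) rendered by N virtual laboratories.

*Morphology*: a wobbly elliptical tissue region filling most of the frame
(a 3-pixel margin stays exactly white), lumen holes, elliptical nuclei
with a minimum center spacing so they stay individually countable,
nucleus hematoxylin density >= 0.8, strongly suppressed nuclear eosin.
Eosin-binding texture is composed at four scales (bands σ=16, structure
σ=4, fine σ=1.2, per-pixel grain), the base structure is blurred with a
σ=0.7 point-spread kernel (as scanner optics do) before the grain is
applied, and a faint stain-residue film covers the background — together
these give each channel the quasi-continuous intensity histogram real
scans have instead of a few isolated gray levels.  Cytoplasm carries
faint basophilia.  The canonical stain vectors are a widely used
real-slide calibration, H = (0.5626, 0.7201, 0.4062),
E = (0.2159, 0.8012, 0.5581); real eosin's appreciable red/blue
absorption is what gives H&E its broad dynamic range.

*Per-lab variation* (`PanelVariation`): stain vectors jittered by a random
rotation with angular σ = 0.2 rad (re-drawn if a draw would swap the
hematoxylin/eosin identities — labs vary their stains, they do not
exchange them); log-normal over-/under-staining scales (σ = 0.25), so
extremes occur but are rare; a smooth multiplicative unevenness field of
amplitude 0.15; a background OD tint up to 0.02 per channel.  Lab 0 always
renders with the canonical balanced profile so the panel contains a
meaningful reference candidate.  Rendering is Beer-Lambert:
`od = W (h_scale·h, e_scale·e)ᵀ · unevenness + tint`, inverted to RGB.

*What it does and does not emulate.*  The generator reproduces the color
statistics that drive stain normalization (stain-vector spread from
blue-dominant to pink-dominant, intensity scaling, unevenness, shared
morphology across labs, quasi-continuous histograms).  It does not attempt
histologically realistic textures, organ-specific morphology, sectioning
artifacts, or scanner ICC differences.  Passing tests therefore show the
methods behave correctly under the Beer-Lambert two-stain model with
realistic variation breadth; they do not certify performance on effects
outside that model (e.g. out-of-plane chromatic shifts, which the
deconvolution methods necessarily discard — visible as a few levels of
self-normalization error on tinted or unevenly stained references).

## Benchmark orchestration

`run_benchmark` selects the reference by the R/B rule, normalizes every
other image with every requested method (failures become error records,
not crashes), evaluates each result (histogram metrics and Fréchet
distance against the reference, SSIM against the original; whole images
for histogram metrics and SSIM, tiles only for the feature clouds), and
aggregates mean/std per method and metric.  The reference is excluded
from aggregates by default (a flag includes it for self-normalization
checks; the flag is logged in the run metadata).  Tiling is a row-major
non-overlapping grid with right/bottom remainders dropped — padding would
distort histogram and feature statistics.  The default FID tile is 128 px
so that a 512x512 slide still yields a 16-tile cloud (two tiles is the
covariance minimum).  Reports are deterministic: rerunning with the same
seed produces byte-identical CSVs.

## Problem sizes and numerical choices

Defaults were chosen so the full pipeline runs on one CPU in minutes: the
standard panel is 20 labs at 512x512 with 400 nuclei; stain-recovery
studies use 20 slides at 256x256; pairwise studies 10 pairs at 256x256.
Tolerances: stain-matrix validation at 1e-9 on norms; NMF objective
monotonicity asserted to 1e-10 relative (floating-point plateau wiggle);
Fréchet shrinkage 1e-6; concentration clamp at 0.  Degenerate inputs
(blank images, constant channels, rank-deficient OD clouds, singular
stain matrices) raise typed errors rather than producing silent nonsense.
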