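# Methods

This note records the models, defaults and numerical choices behind
srhkit, and what its synthetic tests do and do not demonstrate about real
microscope data.

## Imaging model and conventions

A dataset is exactly two co-registered channels: lipid (CH₂, 2850 cm⁻¹)
and protein (CH₃, 2930 cm⁻¹). All in-memory arrays are float64 in
`(channel, row, col)` order with channel 0 = lipid; readers reorder
on-disk planes into this canonical order using the manifest's declared
channel order. Pixel indices are 0-based and row-major with y downward;
stage coordinates are micrometres and refer to the centre of a tile's
top-left pixel, which makes tile placement a single rounding of
`(stage − origin)/pixel_size`. Tiles are stored as 16-bit unsigned TIFF
with a per-file floating scale factor in the image description (preserving
the dynamic range of lock-in detection without exotic formats), mosaics as
float32 TIFF, renderings as lossless PNG/TIFF. Round trips are bit-exact
for 8-bit renderings and within one quantization step (max/65535) for
tiles.

## Flat-field normalization

SRS signal scales multiplicatively with delivered and collected power, so
the illumination model is a per-channel positive gain field, removed by
division (never an additive offset). The gain is estimated from the tile
stack itself: pixelwise median across tiles (suppressing specimen
structure), Gaussian smoothing at `smoothing_scale` (default 8 px), and
normalization to unit mean. Because a Gaussian filter attenuates the
curvature of a smooth gain field, the median/smooth step is iterated
(default 3 passes), each pass estimating the residual of the last; this
converges to a fixed point, cancels the smoother's bias, and makes
estimate-then-apply idempotent to well under 0.1 % RMS. Any non-positive
gain (e.g. a channel that is zero in every tile) is a hard
`DegenerateFieldError`.

Two caveats the tests make explicit. First, the absolute intensity scale
is unrecoverable: the estimated gain is unit-mean, so a vignette with mean
0.9 leaves a global 10 % scale factor behind; comparisons after
normalization are therefore made shape-wise. Second, the median needs
enough tiles for structure suppression — with 9 structure-free tiles the
injected 30 % radial vignette is recovered to ≈0.2 % RMS, whereas heavily
structured tiles require a larger stack (≈25 tiles brings a cellular
phantom to <1 % reconstruction error).

## Stitching

Tiles are placed at their stage-derived pixel positions on a canvas sized
from the grid geometry. With `registration="phase_refine"` (default),
each tile after the first is registered against the already-composited
canvas by masked phase correlation over its nominal footprint; the
integer correction is capped at `max_shift` (default half the overlap
width), and an over-cap or unusable correlation falls back to the stage
position with a warning. One placement offset is computed per tile and
applied to both channels, so chemistry can never de-register. Overlaps
are blended either by last-writer ("overwrite", bit-exact on synthetic
cut-and-reassemble round trips) or by linear distance-to-edge feathering
("feather", seam-free on real data with residual tile-to-tile intensity
differences). Default tile overlap is 0.10; real acquisitions should set
whatever the stage script used.

## Lipid-corrected protein

The 2930 cm⁻¹ channel contains lipid bleed-through, removed as
`P_corr = P − αL`, clipped at zero by default (negative abundance is
unphysical; clipping can be disabled for diagnostics). On channels
flat-field normalized to a shared scale, α defaults to 1.0.
`calibrate_alpha` estimates α as the median protein/lipid ratio over a
region asserted to be pure lipid — lipid-laden macrophages are the
natural choice — which by construction drives the median corrected
protein in that region to zero. Zero-lipid pixels are excluded; an ROI
with none left is a `CalibrationError`. The median (rather than a
least-squares slope) makes the estimate robust to the minority of ROI
pixels that are not actually pure lipid.

## Color renderings

**Pseudo-H&E.** Each input image is scaled by its 99th percentile over
nonzero (tissue) pixels — robust to hot pixels — and mapped through
Beer–Lambert attenuation:

    RGB = 255 · exp(−(P̂ · OD_H + L̂ · OD_E))

with OD_H = (0.65, 0.70, 0.29) (hematoxylin, applied to corrected
protein) and OD_E = (0.07, 0.99, 0.11) (eosin, applied to lipid) — the
conventional published H&E absorbance directions, exposed in
configuration. The exponential form is linear in optical density,
guarantees a white background at zero signal, monotone darkening in each
input, and outputs always inside [0, 255] with no clipping logic. Floats
are quantized with round-half-even. Gamma (default 1.0, off) applies to
the normalized intensities before the OD product. An all-zero map renders
white with a warning rather than erroring.

**Two-color.** Lipid maps linearly to green and protein to red+blue
(magenta) between the 1st and 99th percentile of each channel, clipped to
[0, 1]; a degenerate percentile range renders that channel constant with
a warning. This view preserves the chemistry the virtual stain collapses:
a protein-rich, lipid-poor matrix is unmistakably magenta.

**Nuclear contrast score.** Mean Rec. 709 luminance over a cytoplasm mask
minus that over a nucleus mask, divided by 255. Positive = nuclei darker,
as in well-stained H&E. It quantifies the known chondroid failure mode:
with scant lipid around nuclei the virtual stain has no contrast to draw,
and chondroid phantoms score several-fold lower than lipid-rich ones.

## Synthetic phantoms

The generator emulates, at the level of two-channel chemistry and
geometry, the tissue motifs relevant to the pipeline: protein-rich nuclei
placed by a hard-core (dart-throwing) point process with minimum
separation 1.5× the mean nuclear radius; cytoplasm annuli (outer radius
2.2× nuclear); lipid-laden macrophages replacing a fraction of cells;
protein-only collagen either ringed around k-means lobules of cells
(meningioma-like, with a mild sinusoidal wobble for a curvilinear look)
or threaded between nearest-neighbour cells (schwannoma-like); a
protein-rich lipid-free matrix for the chondroid archetype; and psammoma
bodies as concentric low-signal whorls. Masks are derived from a single
label image painted in a fixed precedence order, so they are disjoint and
covering by construction.

Default study conditions: 1 µm pixels, 1500 nuclei/mm² (600 for the
less-cellular chondroid preset), nuclear radius 3.0 ± 0.5 µm, intensity
means in acquisition units of order 1–12 with macrophages at
protein/lipid = 3/12 = 0.25, read noise σ = 0.1 (≈1–2 % of signal), and
shot noise as scaled Poisson counts at 200 counts per intensity unit —
the standard two-term noise model for a laser-scanning microscope.
Archetype presets are ordinal (who is lipid-richer than whom, where
collagen sits), not calibrated absolute chemistry. Vignetting is
tile-relative — every cut tile sees the same radial profile,
`g = 1 − s·r²/2` with s = 0.3 by default — because it is a property of
the optics, not the specimen; this is what makes flat-field estimation
from the stack well-posed. Generation is deterministic given the seed
(NumPy PCG64), including the k-means initialization.

What passing phantom-based tests does **not** show: real tissue has
continuous chemistry rather than piecewise-constant compartments,
sub-resolution texture, correlated (non-Poisson) noise from the lock-in,
stage drift beyond rigid offsets, and axial structure; results on
phantoms bound algorithmic correctness, not clinical image quality.

## Concordance statistics

Percent agreement is reported as the exact fraction and as a
nearest-integer percent (half-up), the granularity of published survey
tables. Cohen's κ uses chance agreement from the product of marginal
frequencies and returns exactly 1 whenever observed agreement is perfect
(including the degenerate constant-label case). Fleiss' κ follows the
standard formulation (per-case agreement, pooled category proportions);
a panel that only ever uses one category leaves it undefined (NaN with a
warning). Under simulated rater independence both statistics are checked
to average within ±0.02 of zero over 500 replicates of 200 cases — kappa
has O(1/n) finite-sample bias, so small panels sit visibly below zero
even under the null.

Relative accuracy converts each percent agreement back to an integer
agreeing-case count out of n (16 in the motivating survey design),
divides the counts, and rounds half-up; the unrounded count ratio is also
reported. Count arithmetic, not percentage arithmetic, is what reproduces
the way such tables are tabulated: (75 %, 81 %) of 16 cases is 12/13 =
92 %, not 93 %. One published final-diagnosis cell (75 % vs 81 % printed
as 85 %) is not reproducible from its own percent agreements under any
rounding convention we tried; the report computes from counts and
documents the value rather than matching it.

Differential diagnoses are `;`-separated lists scored by set membership
(the reference diagnosis appearing anywhere in the list counts as
agreement), with exact-match scoring available; for kappa, a matching
differential is mapped onto the reference label and a miss keeps the full
list as its own category, keeping κ consistent with the percent
agreement. Missing responses are excluded pairwise per cell with the
cell's effective n reported; Fleiss' κ uses only cases answered by every
rater. No confidence intervals or multiple-testing corrections are
computed — the report is descriptive.

## Pipeline and determinism

`run_pipeline` executes read → flat-field → stitch → lipid-correct →
render (both modes) in that fixed order, writes the stitched two-channel
TIFF, both renderings, and a JSON summary with parameters, SHA-256
checksums and per-stage timings. Configuration is validated before any
computation; stage failures abort with a stage-labelled error and the
partial summary flagged. All computation is deterministic — randomness
exists only in phantom generation, governed by the spec seed — so
repeated runs with the same inputs produce byte-identical images.

## Problem sizes used in the test suite

Synthetic checks run on 220–520 px phantoms, 3×3 to 5×5 tile grids,
20-seed sign tests for orderings, 500-replicate null simulations and
1000-table kappa fuzzing; these sizes give the statistical resolution the
assertions need (e.g. a one-sided sign test at 16/20 has p < 10⁻³) while
keeping the suite quick.

## Known limitations

No global bundle-adjustment stitching (refinement is greedy,
row-major against already-placed neighbours); no subpixel registration;
no multi-wavenumber unmixing beyond the two acquired channels; no attempt
to reproduce any particular instrument's recoloring lookup table
byte-for-byte; archetype chemistry is ordinal, not calibrated to measured
lipid/protein ratios, which are not available per tumor type.
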