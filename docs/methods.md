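# Methods

This note records the model choices, conventions, parameters and known
limitations behind `callomap`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself reproduce.

## Geometry: parcellation and template

**Coordinate conventions.** Arrays are `[row, column]` with columns along
the antero-posterior (AP) axis (anterior at column 0 by default) and rows
dorsoventral (row 0 dorsal). Pixel `(r, c)` occupies the half-open cell
`[r, r+1) × [c, c+1)`; its centre is `(r+0.5, c+0.5)`. All extents are
half-open and all indices 0-based, except ROI indices, which are 1–92.

**Witelson parcellation.** The AP extent is the mask's bounding box, not
a PCA axis: the template is meant to follow the image axes of a
midsagittally oriented section or slice. Each pixel is assigned by the
normalised AP coordinate of its *centre*, `u = (c − lo + 0.5) / extent`,
against five boundary fractions; intervals are half-open and
anterior-closed, so a centre exactly on a fraction goes to the posterior
region. On a 100-px-wide rectangle with the default fractions the six
regions therefore begin at columns 0, 17, 33, 50, 67 and 80. The default
fractions are Witelson's geometric cuts (1/3, 1/2, 2/3, 4/5) plus a
conventional 1/6 split separating the rostrum/genu from the rostral body
inside the anterior third; they are fully configurable, and the rostrum
is not separated from the genu. A mask must be a single 4-connected
component with AP extent ≥ 6 px, and all six regions must be non-empty.

**92-ROI template.** The default grid is 46 AP columns × 2 dorsoventral
rows; any `columns × rows = 92` layout is accepted and the constructor
validates the product. Column width is `extent / 46` px. The local
dorsoventral extent of each column is measured at the column's *central
pixel column* and split into equal rows; measuring it as the union over
the whole column would, on the steep limbs of an arch, include rows
present only at one edge and push circle centres outside the mask. Each
square's inscribed circle has radius `0.8 × min(square side) / 2`
(configurable); radii below 1 px are rejected as unresolvable. ROIs are
ordered anterior→posterior, dorsal before ventral, and labelled by the
Witelson region of the circle centre. On a solid rectangle the centres
reduce to the closed form `cx = (i + 0.5)/46 × width`, rows at 1/4 and
3/4 of the height, which the tests verify, as well as invariance of all
ROI labels and column assignments under 2× upsampling.

## Histology optical density

RGB sections are converted to a single 256-level grey image with
Rec. 709 luminance weights (0.2126, 0.7152, 0.0722), rounded
half-to-even; a plain channel mean is available. The myelin-density
proxy is the *linear* inversion `d = 255 − grey`, mapped onto the
arbitrary 1–7 scale as `density = 1 + 6 d / 255`, so grey 255 → 1 and
grey 0 → 7 exactly. The divisor is 255 (the 256-level range read as
[0, 255]) so that both endpoints are attainable. The default uses this
fixed global range rather than per-image min–max, which is the right
choice when all sections share one light calibration and keeps densities
comparable across sections; explicit calibration bounds, and a
`−log10((grey+1)/256)` transmittance-OD variant, are available options.
The seven-bin purple→dark-red rendering (bin edges `1 + 6k/7`) is for
display only; statistics always use the continuous densities, because
correlations over 92 ROIs computed on 7 quantised levels would discard
most of the information.

## Volumetric sampling

Volumes are reduced to 2-D by averaging the two parasagittal slices at
`midline ± round(offset_mm / sagittal spacing)` voxels (default 4 mm);
a warning is logged when the rounding error exceeds 25% of the spacing.
Averaging the two slices voxelwise before ROI sampling and averaging the
two ROI means afterwards are identical for the mean statistic; the
voxelwise order is implemented. ROI sampling takes the mean (median
optional) over pixels whose centres lie strictly inside the circle,
intersected with the mask foreground; NaN pixels are excluded, and an
empty circle raises an error naming the ROI. Maps are assumed
co-registered to the mask the template was built on; registration is out
of scope.

**1–7 rescale.** Each modality's ROI values are min–max rescaled to
[1, 7] with *one* affine map per modality over all of its samples
jointly. A per-sample rescale would look the same on single-sample data
but is not affine-compatible with the sample averaging that precedes
correlation, and would therefore (slightly) change correlations; the
joint map keeps every downstream Pearson correlation invariant to below
1e-10, which the tests assert. Constant vectors (zero range) are
rejected rather than silently mapped.

## Statistics

Pearson r is the standard product-moment estimate; two-sided p-values
come from `t = r √((n−2)/(1−r²))` with `n−2` degrees of freedom (a
seeded permutation alternative with 10,000 shuffles is available).
Multi-sample modalities are averaged across samples before correlating,
mirroring how replicate histology sections are combined before
comparison with single averaged MRI maps. Missing ROI values propagate
as pairwise-complete deletion with a logged warning and a correspondingly
reduced n. Signed r, r² and p are all reported, since r² alone is
ambiguous about direction.

The variance decomposition uses the unbiased (n−1) SD estimator for both
the across-region SD (mean over samples of each sample's SD over ROIs)
and the across-sample SD (mean over ROIs of each ROI's SD over samples).
It accepts tables in raw units as well as 1–7 units and records which
was used: raw units are required when comparing the across-sample SD
against a known perturbation SD, because the 1–7 rescale changes scale.

## Synthetic phantom

The phantom emulates the *structure* of a cross-modal callosal study —
an arch-shaped mask, AP-organised intensity patterns, replicate samples,
pixel noise — with known ground truth; it makes no claim to anatomical
or MR-physical realism.

**Mask.** A half annulus opening downward, anterior tip at the left. The
inner boundary is a fixed circle; the thickness profile, including
Gaussian end bulbs (genu-like anterior, larger splenium-like posterior),
grows outward only, which guarantees every AP column's cross-section is
a single vertical interval and the mask a single 4-connected component.
Defaults: arch length 320 px (minimum 200 px, so the 46 columns keep
≥ 4 px each), base thickness 36 px, bulb factors 0.55/0.85, bulb width
0.45 rad. The rasterised bounding box matches the requested arch length
within ±2 px.

**Modalities.** Each modality has a strictly positive piecewise-linear
AP profile over the normalised coordinate u ∈ [0, 1] and is rendered
either as an RGB "stained section" (profile values are myelin fractions;
grey `g = 255 − round(f·255)` tinted with a fixed blue-dominant hue whose
luminance remains linear in g; background white) or as a 3-slice
sagittal volume (slice order −offset/midline/+offset, default 4 mm
sagittal spacing so ±4 mm is ±1 slice; all three slices share the truth
field; background 0). Noise is additive Gaussian per pixel (independent
per slice), truncated to the valid range ([0, 1] for sections, ≥ 0 for
volumes).

**Per-sample variability.** Sample i's profile is the shared profile
plus a smooth random AP perturbation, implemented as a
random-Fourier-feature draw from a squared-exponential Gaussian process
(12 cosines, length scale 0.25): `σ √(2/K) Σ cos(ω_k u + φ_k)`. This
construction has *exactly* marginal SD σ at every AP position, so the
across-sample SD of the sampled raw table is an unbiased target for
calibration; a spline-through-control-points perturbation would have
position-dependent marginal variance below σ² between knots. Noise and
jitter SDs accept a scalar or a per-modality mapping, in the absolute
units of each modality's profile (modality scales differ by two orders
of magnitude, so a single absolute scalar is rarely appropriate for
multi-modality specs).

**Default profiles.** `paper_pattern_profiles()` encodes the qualitative
AP patterns reported for the three modalities — LFB low anteriorly (with
a small uptick in the most anterior genu) rising to a high splenium;
T1w/T2w high rostrum/genu, low posterior midbody, partly recovering in
the splenium; MWF high anterior genu, dipping in the anterior body, high
from the posterior midbody through the splenium. The knots were chosen
once from those published descriptions; the resulting noise-free truth
correlations carry the expected sign structure (T1w/T2w vs LFB negative,
MWF vs LFB strongly positive, T1w/T2w vs MWF weakly negative), which the
seeded end-to-end tests confirm is robust to the default noise (5% of
each profile's range) and per-sample jitter (10% of range, 3 samples).

**Known correlation structure.** `make_correlated_profiles(rho, seed)`
draws two smooth random profiles whose values at the 46 AP column
centres have sample correlation exactly ρ (the second function is
orthonormalised against the first and mixed as
`ρ z₁ + √(1−ρ²) w`). Both template rows of a column share an AP
coordinate, so the 92-ROI truth correlation equals ρ up to rasterisation
error (< 0.01 in practice); the tests verify recovery of ρ ∈
{−0.8, 0, +0.8} within ±0.1 by the full pipeline under 5% noise,
averaged over 50 seeds.

**What the phantom does not model** — and hence what passing tests do
not show about real data: partial-volume effects at the callosal
boundary, registration error between modalities, staining artefacts and
uneven illumination, MR physics (no signal equations; volumes are
profile + noise), spatially correlated noise, true 3-D callosal
geometry, and spatial autocorrelation between neighbouring ROIs (the
Pearson inference treats the 92 ROIs as independent, as is standard for
this analysis).

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng(seed)` carried in
the phantom spec; identical specs produce byte-identical outputs, and
the pipeline stamps every output with a config hash and the seed. The
statistical test conditions are: 50 seeds for the correlation-recovery
and sign-structure checks (the number over which the stochastic claims
are averaged), 200 samples for the jitter-SD calibration, 1,000 random
vector pairs for the Pearson-oracle equivalence at 1e-12. With the
default 320-px arch these all run in seconds.
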