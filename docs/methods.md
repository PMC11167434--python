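# Methods

This note documents the models, numerical choices, and limitations behind
`emomap`. Everything described here is exercised by the test suite and the
acceptance script; no empirical claim is made beyond what those compute.

## The GLM

First-level analysis is ordinary least squares per voxel. Each condition
with at least one block contributes one regressor: a boxcar on a microtime
grid of TR/16 seconds convolved with the canonical double-gamma HRF
(gamma-density response peaking at 6 s minus a 16 s undershoot at ratio 6,
32 s support, normalised to unit peak so a planted block amplitude of beta
produces a regressor plateau near beta). The HRF parameters are config
fields (`emomap.hrf.HRFParams`); the generator and the design builder share
the same regressor code, which is what makes noiseless beta recovery exact
(verified to 1e-8, measured ~6e-16) — a deliberate property: the tests that
need an analytic truth use it, while oracle tests of the regressor itself
compare against an independent direct convolution at 0.01 s resolution.

Drift is removed by a discrete cosine basis: `floor(2T / cutoff)` unit-norm
cosine columns for a run of length T at the default 128 s cutoff, plus an
intercept. Cutoffs at or below twice the TR are rejected. Global signal is
removed by proportional scaling — every frame is multiplied so that its
in-mask mean equals 100; the default brain mask keeps voxels whose
time-averaged intensity exceeds one eighth of the global mean, the usual
EPI heuristic, and is exposed as an argument since the choice is not
otherwise determined. Gaussian smoothing (per-axis FWHM in mm, sigma =
FWHM / 2sqrt(2 ln 2) in voxel units, constant-zero boundary) is available
but off by default in the pipeline: the synthetic signal is planted at ROI
scale and unsmoothed maps keep the planted-count recovery checks exact.
Residual variances within rounding error of an exact fit are clamped to
zero and such voxels are flagged `degenerate` with t = 0 rather than
carrying infinite statistics; the same guard applies to zero
between-subject variance at the second level and to constant pixels in
silhouette group maps.

## Group inference and cluster correction

Second-level inference is a one-sample t across subjects' contrast images
(random effects, df = n - 1, at least 3 subjects). Statistical maps are
thresholded voxelwise (one-sided by default, since all the contrasts of
interest are directional; a two-sided mode exists) and cluster-corrected by
a sign-flipping max-cluster-size permutation scheme: subject images are
multiplied by random +-1 vectors, the permuted t-map is rebuilt, and the
maximal suprathreshold cluster size (26-connectivity by default,
configurable to 6) forms the null distribution; observed clusters survive
if they exceed its (1 - cluster_p) quantile. The identity permutation is
always included, so familywise p-values cannot undercut 1/n_permutations,
and at least 100 permutations are required when cluster_p <= 0.05. Sign
flips leave per-voxel second moments unchanged, so all permuted t-maps are
computed with a single matrix product per contrast. Measured familywise
error over 200 pure-noise replicates (n = 15, 500 permutations) is 0.06 at
a nominal 0.05, within Monte-Carlo error. Parametric random-field cluster
correction is intentionally not implemented: the permutation scheme is
exact under exchangeability and reproducible given a seed, and the method
name is recorded in each map's `threshold_meta`.

The whole-body map is the minimum-statistic conjunction over all eight
segment x modality contrasts — the conjunction-null reading, i.e. evidence
in *every* contrast, which is the stricter of the two standard readings;
the permutation null for the conjunction applies the same sign flips to all
contrasts and takes the per-permutation minimum. Segment-specific maps test
(target motor + target tactile)/2 minus the mean of the six other contrast
images. Where two segments' maps claim the same voxel (possible at lenient
thresholds), the voxel is assigned to the segment with the larger t, making
the coloured maps disjoint by construction. The motor/tactile partition
thresholds the (motor - tactile) difference both ways inside the whole-body
map; the two one-sided results are necessarily disjoint.

## Convergence and hotspots

Convergence of a binary emotion map with a binary mask is
`100 x |emotion AND mask| / |mask|` by default: the denominator ambiguity
(mask vs emotion) is real, and the mask-relative reading is the default
because it normalises per segment, allowing comparison across segments of
very different sizes; the emotion-relative mode is kept for sensitivity
analysis. An empty denominator yields a missing value rendered as "–" in
formatted tables, never a zero. Voxel counts (not mm^3) are used
throughout, with the voxel volume recorded in the provenance manifest.
Hotspots are the segments within tau of an emotion's row maximum
(tau = 0, the strict argmax set with ties included, by default); hotspot
agreement between the pixel and voxel matrices is reported as +/- flags per
emotion and segment.

## Silhouette digitization

The body template is generated programmatically: a stylised figure of
7,845 pixels on a 220 x 100 raster whose four districts (face, hands/arms,
trunk, legs/feet) tile the silhouette exactly, so per-segment counts sum to
the body total. Real emBODY-style templates have different pixel counts;
none is asserted anywhere.

Scanned pages are registered to the template by maximising Mattes mutual
information (50 histogram bins, 50% regular sampling, multi-resolution
4/2/1 with smoothing 2/1/0, regular-step gradient descent) under a 2-D
*similarity* transform — rotation, translation, isotropic scale but no
shear, which would distort segment areas; near-rigid scans make this
family sufficient. The fitted transform is returned for audit as
translation/rotation/scale about the template centre; planted transforms
up to 10 px and 5 degrees are recovered within 0.06 px / 0.06 deg on the
packaged template (the guaranteed bound in the tests is 0.5 px / 0.5 deg).
Blank or foreground-free pages raise an error carrying the final metric
value. Resampling into template space uses nearest-neighbour interpolation
so colours stay crisp for the coding step.

Pixel coding is an HSV rule: red (activation) is hue < 20 or > 340 degrees,
blue (deactivation) hue 200-260 degrees, both requiring saturation >= 0.3
and value >= 0.2; anything else, and every pixel outside the body boundary,
codes 0. Scanner colour thresholds are never standardised, so the windows
are config-exposed (`ColorRules`). The red and blue windows are disjoint,
so no pixel can be both. Percentages are `100 x coloured / segment_count`
per segment; the reported channel is `activation` by default, with a
`subtraction` mode (activation-minus-deactivation positive part) available
because percentage analyses can reasonably be defined on either.
Pixelwise group t-maps of the subtraction rasters and the pre/post
reliability (Pearson r over all subject x emotion x segment entries) follow.

## RSA and Bayes factors

Each subject's 5 x 4 pixel and voxel matrices are correlated (Pearson by
default, Spearman optional) either directly on the flattened matrices
("direct", the default) or after building 5 x 5 emotion-dissimilarity
matrices per modality and correlating lower triangles ("rdm") — both modes
exist because the two descriptions are genuinely different analyses and the
choice matters. Coefficients are Fisher-z transformed before the group
one-sample t-test (variance stabilisation); a raw-r mode reproduces the
untransformed variant, and the two always agree in sign. Constant matrices
are excluded with a warning; fewer than 3 usable subjects is an error.
Under independence the group test rejects at the nominal 5% (measured 4.6%
over 500 replicates of 26 subjects), and additive noise of half the signal
sd attenuates the mean coefficient to 1/sqrt(1.25) as predicted.

The Bayes factor for a one-sample t is the JZS form: Cauchy prior
(scale sqrt(2)/2, the common software default, config-exposed) on the
standardised effect, computed by adaptive quadrature of the equivalent
inverse-gamma(1/2, 1/2) mixture integral. It is validated against an
independent oracle that integrates the noncentral-t density over the Cauchy
prior directly, agreeing within 0.5% over n in {10, 26, 50} and t in
{0, 1, 2, 3, 5}; BF10(t=0) < 1 for all n. Ratings contrasts are paired
emotional-minus-neutral subject means per emotion, fed to the same test.

## The synthetic-data generator

The generator reproduces the study conditions: TR 2 s; localizer blocks of
20 s stimulation / 20 s rest cycling hands, feet, face, trunk (4 repeats);
recall episodes of 14 s, three per emotion, each followed by a matched
neutral episode with a rating gap; integer 1-5 intensity/vividness ratings.
Signal is planted as beta x (boxcar * HRF) inside spherical ROIs — four
segments x two modalities, pairwise disjoint, radius 2 voxels on the
default 32 x 32 x 24 grid of 2 mm isotropic voxels — on a baseline of 100
(so unit amplitudes are ~1% signal changes), plus two low-order cosine
drift terms and i.i.d. Gaussian noise (sd 1 by default). No per-condition
effect sizes or noise levels are reported for studies of this design, so
these defaults are calibration choices held fixed across all tests.

Two generator choices deserve explanation. First, a *whole-body common
region* (a ninth sphere responding to every localizer condition) emulates
areas with body-wide receptive fields such as SII and the insula; without
it, the conjunction over eight disjoint ROIs would be empty by construction
and the whole-body analyses untestable. Second, that region responds
asymmetrically to the two modalities (amplitudes 1 +- 0.3 in its anterior
and posterior halves), so the motor/tactile partition is non-degenerate
while both halves still survive the conjunction.

Emotion activation is planted in one of two modes. Option A (default for
unit tests and the pipeline demo) plants binary suprathreshold maps
directly: for each emotion and mask, a compact blob of exactly
`round(fraction x |mask|)` voxels — rounding is half-away-from-zero
everywhere in the package, and a positive fraction that rounds to zero
voxels warns — plus a configurable number of voxels outside all masks.
Option B plants the same blobs as beta carriers in the recall run, so the
full first+second-level GLM chain recovers them; measured recovery of
planted fractions {0, 0.25, 0.5, 1.0} at n = 20 is exact to the rounding
rule. Silhouettes get `round(fraction x segment_count)` coloured pixels as
bands growing from the segment's top (activation) and bottom
(deactivation), disjoint whenever the fractions sum to at most 1. Each
synthetic subject carries a stable felt-body profile (group fractions plus
subject-level jitter, sd 0.08) that drives the pre- and post-scan
silhouettes (phase jitter sd 0.03) and the fMRI emotion fractions (jitter
sd 0.03) — so pre/post reliability and pixel-voxel congruence are high by
construction in the demo pipeline, which is a feature of the bench, not a
scientific finding. Planted emotion-overlap magnitudes follow broad
felt-body patterns (face/trunk-weighted positive emotions and sadness,
limb-weighted fear, feet weakest), chosen once as realistic values.

What the generator does **not** emulate: physiological noise and its
spatial autocorrelation, head motion, susceptibility distortion,
between-subject anatomical variability (all subjects share one grid and
one ROI layout), surface geometry, drawing-style idiosyncrasies in
silhouettes (planted bands rather than free-hand strokes) and intensity-
graded colouring. Passing tests therefore demonstrate the correctness and
calibration of the *procedures* under known truth, not that real data
would yield any particular result.

## Pipeline scale and determinism

The packaged demo (`emomap all --simulate`) runs 12 subjects with 4
localizer repeats and 200 permutations, completing in well under a minute
on one CPU; the acceptance checks use the sizes their statements call for
(n = 15 for FWER calibration, n = 20 for GLM-backed convergence recovery,
26 subjects for RSA calibration). Every random draw descends from the
single run seed through `numpy.random.SeedSequence` spawning, and repeated
runs with the same config and seed produce byte-identical CSV tables; the
provenance manifest records the package version, config, seed, and every
output file. NIfTI outputs carry a JSON sidecar with map kind, df and
threshold metadata.

## Known limitations

- The permutation null assumes symmetric exchangeable subject effects;
  skewed between-subject distributions would need a different scheme.
- The minimum-statistic conjunction tests the conjunction null only; the
  global-null variant (weaker, more sensitive) is not the default reading.
- Registration is similarity-only; genuinely sheared or locally distorted
  scans would register imperfectly and the error is not modelled.
- AR(1) prewhitening is not implemented; with the default white-noise
  generator this is exact, but real BOLD autocorrelation would make
  first-level variance estimates optimistic.
- Option-A emotion maps bypass the single-subject GLM; conclusions about
  single-subject threshold behaviour should use option B (`emotion_mode:
  glm`).
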