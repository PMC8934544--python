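# Methods

This note documents the models, parameter choices and numerical decisions
behind `danioeye`, and what the synthetic validation does and does not
establish about real data.

## OCT biometry

### Optical-path model

The depth axis of an SD-OCT volume is optical path length: a compartment of
geometric thickness *t* and refractive index *n* occupies *n·t* of raw
depth. The generator therefore multiplies by *n* when rendering and the
analysis divides by *n* after segmentation; refractive-index correction is
an exact linear operation on the 2 µm z-pitch under this reading, which is
the only reading that makes it one. Default indices are cornea 1.33,
anterior chamber and vitreous 1.34, lens 1.40 (a single effective value for
the gradient-index fish lens), retina 1.38. No separate RPE index is
established for zebrafish, so the RPE inherits the retinal 1.38; because the
RPE is ~12 µm thick, a ±0.04 error in its index moves its thickness by
~0.3 µm, well under the measurement floor.

### Segmentation

The central axis is the lateral position maximizing anterior-to-posterior
signal extent, found as the argmax of the depth-mean projection (the column
mean grows with the chord length through the globe; a 3×3 smoothing keeps
speckle from deciding the argmax, and plateau ties resolve to the plateau
centroid). The working A-scan is the per-depth *median* over a ±10-column
band around the axis — the median suppresses speckle without the axial
blurring a mean would add. Interfaces are `scipy.signal.find_peaks` maxima
with prominence ≥ 15% of the profile's dynamic range and ≥ 3 px separation;
exactly seven are expected (cornea outer/inner, lens anterior/posterior,
retina inner, retina/RPE, RPE outer), surplus peaks are dropped by
prominence rank, and a deficit raises a QC error naming the count. Each
peak is refined by three-point parabolic interpolation. At 2 µm pixels
integer peaks would quantize a 5 µm corneal effect to 2–3 levels; sub-pixel
refinement is what makes that endpoint resolvable (noiseless round-trip
error is ≈0.05 µm, speckled ≈0.1 µm per boundary).

Anterior chamber depth may legitimately approach zero in wild-type fish
(the lens can rest against the cornea); the analysis reports a small ACD
with an `acd_at_floor` QC flag rather than failing. Axial length is defined
as the sum of all six compartments, RPE included, and is additive by
construction. Eye volume is the ellipsoid (4/3)π·a·b·c: the axial semi-axis
from axial length and two equatorial semi-axes measured by image moments on
an en-face slice taken at mid depth but nudged ≥ 12 µm away from any
segmented interface (a slice through an interface cap would otherwise
dominate the threshold). The slice is Gaussian-smoothed (σ = 2 px) and
thresholded halfway between its border (background) and central
(intraocular) levels; a bimodal Otsu split fails here because the bright
interface pixels form a third mode.

### Rendering

Synthetic volumes cover a 1.7 × 1.7 × 2.2 mm field at 2 µm z-pitch. The
lateral pitch is 12 µm (142 × 142 columns): fine enough that the ±10-column
median band spans only ±120 µm, coarse enough to keep a volume at ~44 MB
and ~1 s to render. Interfaces are Gaussian bands (σ = 2.5 µm) with
sub-pixel centres; all interfaces share one spherical sag (curvature radius
4 mm), so curvature is cosmetic — it cancels exactly in every thickness —
and biases absolute boundary positions by < 1 µm within the median band.
The globe interior is a dim ellipsoid over background (200 vs 100 a.u.,
interface amplitude 4000 a.u.) and speckle is additive Gaussian noise with
SD 150 a.u. Rendering is the inverse of the analysis by design; the
round-trip tests close the loop against the generator's ground truth.

## Genotype presets and the noise model

Preset geometries encode the study conditions. Wild-type retinal thickness
is pinned to the known developmental series (152/137/126 µm at 2/4/6 months
post-fertilization). The remaining wild-type baselines are not established
quantities; they are plausible adult-zebrafish constants (e.g. 6 mpf:
cornea 30, ACD 30, lens 720, VCD 550, RPE 12 µm, axial 1468 µm) and only
*differences* between genotypes should be compared against published
numbers. The wild-type ACD default is 30 µm rather than the near-contact
value so that the cornea-inner and lens-anterior peaks remain separable at
the 2 µm pitch; the near-zero case is still handled by the analysis (QC
flag). Mutant presets add the published per-component effect sizes, with
non-significant components at zero. For the *prss56* presets the
per-component sums differ from the published axial effects by −3/+4/+1 µm
at 2/4/6 mpf; these residuals are absorbed into the VCD delta so the preset
axial difference equals the published axial effect — axial length is the
headline endpoint and VCD its dominant component.

Between-fish and between-eye variability are modeled as shared ocular-scale
factors: each fish draws one relative size factor, each eye a second, and
all axial components of that eye are multiplied by (1 + fish + eye). The
factor SDs are calibrated so axial length varies with SD 10 µm between fish
and 4 µm between eyes. This choice (rather than independent additive noise
per component) reflects what residual variation in deliberately
size-matched cohorts looks like — overall eye size — and gives each
component an SD proportional to its magnitude, which keeps small endpoints
(cornea, RPE) measurable at n = 10 fish per group just as the large ones
are. The genotype-effect estimator then has SD ≈ 4.7 µm for axial length
and ≈ 0.1–2.3 µm for individual components at 20 eyes per genotype. Body
lengths are drawn around a common age-specific mean and recentered per
genotype, so cohorts satisfy the 1% size-matching rule by construction, as
deliberate selection against the reference mean would.

What the synthetic data do *not* emulate: real speckle is multiplicative
and spatially correlated; real eyes tilt, decenter and deform away from
concentric caps; real retinas have internal lamination that can distract a
peak detector; motion and blink artifacts are absent. Passing round trips
therefore validate the geometry→signal→geometry chain and the statistics,
not robustness to acquisition pathology.

## Photorefraction

The pupil is the largest near-circular (circularity ≥ 0.8) connected region
above a background-based threshold (median + max(3 × MAD, 10% of dynamic
range)); a bimodal threshold is unusable here because a strong refractive
ramp can push part of the pupil to background levels and split it. The
brightness slope is an ordinary least-squares fit of intensity against
vertical position normalized to pupil radius, over the central vertical
chord (column half-width 15% of the radius) with a 10% rim excluded;
saturation of > 20% of pupil pixels raises a QC flag. Slope→diopter
conversion is a linear calibration persisted as JSON. The synthetic forward
model uses gain 60 D per unit slope, offset 0 — with a mean pupil
brightness of 0.5 and background 0.08 this keeps every preset's ramp inside
the frame's dynamic range (the usable range is about ±22 D, analogous to a
real instrument's working range). Per-eye refraction averages 100 frames.
The wild-type preset is +5 D, a plausible hyperopic bias from the small-eye
retinoscopic artifact: absolute diopters are not meaningful in small eyes,
so genotype differences are the readout, and the acceptance surface.

The relative refractive error uses the linear focal-length model
*f* = 2.182·*r*₍lens₎ + 11.699 (µm), with the retinal radius taken as lens
radius + VCD (lens centre to inner retina) from the biometry record. The
intercept's units are taken as µm, matching the lens radius.

## Optokinetic response

Eye angles come from second-order image moments of the two largest dark
components in dorsal-view frames, assigned left/right by lateral position
and unwrapped over time (180° period); orientation from binary moments is
accurate to ~0.5° for the rendered ellipse sizes. Saccades are samples
where the Savitzky–Golay-smoothed derivative (window 0.2 s, order 2)
exceeds 100 deg/s *against* the stimulus direction, merged within 0.1 s.
Slow phases are the inter-saccade intervals trimmed by 0.15 s (the
smoothing spill-over of a saccade), kept if ≥ 0.3 s; each gets a
least-squares slope and R². The per-fish velocity is the median of
qualifying slopes (R² ≥ 0.8); a fish with no qualifying segment is a
non-responder (gains undefined, ETMs 0). Gain is |eye velocity| / |drum
velocity| at the standard 20 deg/s drum and 0.15 cycles/deg grating; ETMs
are saccade-delimited cycles counted per 15 s bin, trailing partial bin
dropped, so the bin total equals the saccade count in retained bins. None
of the segmentation constants (threshold, windows, R² cut) are established
values; they are chosen so a 20 deg/s slow phase can never be misclassified
as a saccade, and all are exposed in the config. With the 100 deg/s
threshold a reset must be ≳15° to register, so sweeps across slow-phase
velocities use a fixed 20° saccade amplitude (reset interval 20/v s) rather
than the balanced-sawtooth default amplitude v·interval, which at 5 deg/s
would produce undetectably small resets.

## IOP

Readings are validity-filtered (finite, positive) and averaged, nominally
six per eye; deviations from six are flagged, and no outlier rejection is
applied beyond validity — the protocol is plain averaging.

## Statistics

Two eyes of one fish are exchangeable repeated measures: a random intercept
per fish induces exactly the compound-symmetry covariance (equal variances,
equal within-fish covariance). For balanced two-eye tables the REML
variance components have the classical closed form — σ²₍eye₎ from
within-fish eye differences, the fish-mean variance from the genotype-means
residual — and the GLS genotype effect reduces to OLS on per-fish eye
means; this exact path is used whenever possible and `statsmodels` MixedLM
(REML) otherwise. The fixed-effect p value uses a t reference with
between-fish degrees of freedom (n₍fish₎ − n₍genotypes₎): conservative,
exact under the balanced model (the fit then *equals* the pooled t-test on
fish means, which is the oracle in the tests, and holds 5% type-I error
exactly). Negative variance estimates are truncated at zero. The ICC is
σ²₍fish₎/(σ²₍fish₎+σ²₍eye₎). Welch's heteroscedastic ANOVA (Welch's F with
Welch–Satterthwaite df) covers per-fish metrics; no multiple-testing
correction is applied — per-metric p values carry the conventional star
thresholds (0.05/0.01/0.001). Power for the two-eye design is Monte Carlo:
simulate CS cohorts, fit the closed form, report the rejection fraction
with its binomial MC error. Power depends on the user-supplied variance
components; none are established quantities, so no particular power value
is asserted.

## Problem sizes used in validation

The round-trip validation uses 10 fish (20 eyes) per genotype — the
design's intended cohort size — with full-size volumes for the effect
recoveries, 100 pupil frames per eye for refraction, 2000 null replicates
for type-I calibration, and reduced ~0.35 mm model eyes for the unit tests
where only correctness, not the study geometry, is at stake.

## Known limitations

- Segmentation is purely axial; tilted or decentered eyes, B-scan motion
  and en-face curvature correction are out of scope.
- The lens diameter is its axial extent under a spherical-lens assumption;
  an ellipsoidal lens would need the equatorial extent too.
- Absolute diopters from photorefraction are not calibrated against a
  physical instrument; only differences are interpreted, and the small-eye
  artifact is represented as a constant bias, not modeled optically.
- The OKR direction labels (temporal→nasal vs nasal→temporal) follow a
  documented convention from slope sign against drum direction; with a
  unidirectional drum only one direction is measured and the other gain is
  reported as the same value (NaN when no opposite-sign segments exist).
- Whether published ETM counts are saccades or full cycles is ambiguous;
  saccade-delimited cycles are counted here, which coincide except at trace
  edges.
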