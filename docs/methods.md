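# Methods

`striascope` quantifies the *shape* of striatal tracer uptake in
DAT-SPECT-like volumes alongside the conventional semi-quantitative
striatum binding ratios (SBR), and measures how well each feature family —
and their combination — separates normal-control (NC) from Parkinson-like
(PD) uptake. Because real DAT-SPECT cohorts are access-restricted, the
package ships a digital striatal phantom with known ground truth, and every
claim the package makes is a parameter-recovery statement on that phantom.

## The imaging model

In a healthy striatum the dopamine-transporter distribution forms a
bilateral "comma": a roundish caudate head joined to an elongated putamen
at similar tracer concentration. Parkinsonian degeneration removes putaminal
uptake first, leaving an "egg" or "dot" dominated by the caudate head.
Shape descriptors of the uptake region on an axial summed image therefore
carry diagnostic signal: the uptake region gets smaller, shorter and —
headline feature — *rounder*. Circularity

    c = 4 * pi * S / L**2

(S area, L perimeter) is 1 for a circle and decreases with elongation, so c
rises with putaminal loss.

## Phantom construction

A phantom volume (default 91 x 109 x 91 voxels at 2 mm, the grid of
preprocessed PPMI SPECT) is assembled in units of the occipital reference
level:

* a brain ellipsoid of uniform nonspecific uptake (level 1.0); the
  occipital reference mask is a posterior slab of it at striatal height;
* per side, a caudate ellipsoid (radii ~6 x 9 x 9 mm, anterior-medial) and
  an elongated, axially rotated putamen ellipsoid (radii ~6.5 x 15 x 8 mm,
  posterior-lateral) whose union is the comma. Caudate voxels take
  `uptake_contrast` x reference (default 3.0, i.e. true caudate SBR 2.0);
  putamen voxels take the same scaled by `putamen_intensity_fraction`
  (1.0 = NC comma, low = PD egg/dot);
* a bright parotid-like ellipsoid pair (default level 4.0) on a low axial
  slice, so that slice searches must genuinely restrict themselves to
  "above the parotid";
* Gaussian resolution blur of 6.0 mm FWHM, then Poisson-like count noise
  (Gaussian with sd = `noise_scale` * sqrt(intensity), default scale 0.1,
  about 6% at striatal levels). Blur before noise follows the
  emission-imaging ordering: resolution loss happens in the imaging chain,
  counting statistics on top.

Truth masks (caudate/putamen per side, occipital) are kept pixel-exact and
disjoint (caudate wins overlaps), and the construction SBR
`(region level / reference level) - 1` is stored as ground truth: with blur
and noise off the measured SBR recovers it to machine precision, which the
tests assert.

Cohorts draw per-subject parameters from Gaussians:
`putamen_intensity_fraction` NC ~ N(0.95, 0.03), PD ~ N(0.30, 0.10);
`uptake_contrast` NC ~ N(3.0, 0.25), PD ~ N(2.4, 0.25) (caudate uptake also
declines moderately in PD, so caudate SBR separates but less than putamen
SBR); overall striatal size jitter ~ N(1.0, 0.05). Fractions are clipped to
[0.02, 1] and contrasts floored at 1.3, so no burst-striatum-like subject
(near-total bilateral loss) is emitted — such images are excluded from this
kind of analysis. All randomness flows from one integer seed through
spawned child streams (one per subject), making cohorts bit-reproducible.

What the phantom does *not* emulate: tomographic reconstruction artifacts,
attenuation/scatter, anatomical variability beyond isotropic size jitter,
spatial-normalization residuals, and observer variability in ROI placement.
Passing recovery tests therefore demonstrate that the *feature and
evaluation machinery* behaves correctly and that the comma-to-egg
morphology is sufficient to reproduce the published qualitative structure —
not that real-cohort AUCs are reproduced.

## Summed image and slice logic

The striatal peak slice is the axial index (strictly above a configured
parotid boundary; for phantoms, parotid slice + 8) maximizing the per-slice
maximum intensity, ties toward the inferior slice. The summed image adds
the peak slice and its two neighbours on each side (5 slices = 1 cm at 2-mm
spacing; the 5-slice rule is kept and a warning is emitted when spacing
makes that not 1 cm). For SBRs, the single-slice image is instead the mean
of the 8 hottest striatal slices in a contiguous window grown around the
peak (neighbour with the higher per-slice maximum joins first, ties toward
inferior).

## ROI surrogate

Manual tracing ("the region where radioactivity is visually accumulated")
is replaced by a reproducible surrogate: per hemifield, threshold at

    level = bg + f * (peak - bg),      f = 0.5 by default,

where `bg` is the median of the strictly positive hemifield pixels (a
robust estimate of nonspecific background) and `peak` the hemifield
maximum; keep the largest 8-connected component; fill interior holes.
Anchoring to the background rather than using a plain fraction-of-maximum
cut matters: once the striatal peak falls below twice the background (the
low-count PD regime), a 0.5 x max threshold floods into the background and
the "largest component" becomes the hemifield itself. On a zero background
the rule reduces to fraction-of-maximum. The threshold fraction, and the
left/right reduction (mean of both sides by default, "worst side"
optionally), are config knobs, because the manual protocol they replace is
not reproducible.

## Shape features and the perimeter convention

Area is pixel count x pixel area; the equivalent diameter `sqrt(4S/pi)`
and circularity are exact functions of area and perimeter; major/minor
axis lengths come from the ellipse with the same normalized second central
moments (4 x sqrt of the covariance eigenvalues, via
`skimage.regionprops`), reported in mm.

The perimeter is the length of the 0.5 iso-contour polygon (marching
squares on the zero-padded mask) after **two midpoint corner-cutting
passes**. The raw marching-squares polygon overestimates smooth perimeters
by ~6% (staircase effect), which biases circularity down ~12% and would
make even a radius-30 disk report c ≈ 0.88. Two corner-cutting passes give
disks c = 0.96 at radius 30 (converging monotonically toward 1 with
radius) while keeping c <= 1 for convex shapes; a third pass overshoots 1
on small disks and is therefore not used. The convention is frozen because
circularity is the headline feature; all circularity values produced by
this package are comparable only under this convention.

Circularity is *not* pixel-for-pixel monotone in the putaminal fraction:
as the putamen dims through the segmentation level its tail first thins
(the ROI becomes more elongated, c dips from ~0.52 to ~0.45) before the
tail disappears (c ≈ 0.95). The regimes separate cleanly — every
noise-free phantom with fraction <= 0.6 is rounder than every phantom with
fraction >= 0.8 — and that is the property the tests assert.

## SBR

`SBR = target/reference - 1` on the 8-hottest-slice mean image. In the
pipeline the four regional means use the phantom's truth masks restricted
to the selected slices (a 3D mask is averaged voxelwise there rather than
projected, so a region whose footprint varies across slices is not diluted
by out-of-region voxels); the occipital slab is the reference. SBRs are
exactly scale-invariant and exactly recover the construction value when
blur and noise are off; recovery error decreases monotonically as blur
shrinks.

## Statistics

* Feature ranking: two-sided Welch t-test per feature (NC vs PD),
  ascending p, ties broken by name. No multiplicity correction, matching
  the analysis style this mirrors (raw p ranking at alpha = 0.05).
* ROC: trapezoidal AUC, equal to the tie-corrected Mann-Whitney
  proportion (asserted against an O(n^2) oracle); orientation
  auto-detected unless supplied; optimal cutoff by Youden's J with ties
  toward higher specificity; sensitivity/specificity/PPV/NPV at that
  cutoff; 95% CI as a normal interval on the DeLong variance, clipped to
  [0, 1].
* DeLong test for correlated AUCs: structural components via midranks
  (O(n log n)), covariance from the paired components,
  z = delta / sqrt(var), two-sided normal p. Identical score vectors give
  p = 1 by definition. The midrank components are asserted equal to the
  brute-force O(n^2) definition, and the p-value is cross-checked against
  a stratified paired bootstrap near p = 0.05.
* Classifier: linear SVM, C = 1.0 (kernel and C are config; with 1-3
  features and n = 200 a linear margin is the defensible default),
  evaluated by leave-one-out cross-validation with the standardizer refit
  inside every fold on the training rows only (the leakage-free reading of
  "standardized before learning"; a global-standardization variant exists
  behind a flag for sensitivity analysis). ROC for the classifier uses the
  pooled continuous decision scores; accuracy-style numbers are taken at
  the Youden cutoff of that pooled-score ROC.

A caveat the test suite documents: pooled leave-one-out decision scores of
a margin classifier are *pessimistic* under the null (mean AUC ≈ 0.33 for
a single pure-noise feature at n = 60, reproduced identically by sklearn's
own pipeline) because the near-zero weight vector's sign flips between
folds anti-correlate each held-out score with its own class. Null AUC near
0.5 should not be expected from pooled LOOCV scores in low dimension;
optimism (AUC well above 0.5) remains the signature of leakage.

## Reference experiment and problem sizes

The reference recovery experiment uses cohorts of 100 NC + 100 PD phantoms
on the full 91 x 109 x 91 grid with the population parameters above. The
acceptance test suite evaluates 20 seeded cohorts; `scripts/acceptance.py`
reports means over 3 seeded cohorts (600 subjects), a size chosen to keep
a from-scratch rerun comfortably interactive while leaving the per-cohort
conditions untouched. Expected structure, computed fresh on every run: PD
mean circularity > NC mean circularity; circularity and putamen SBR
outrank minor axis length and minimum count; the combined
SBRs + circularity classifier is never meaningfully worse than the best
single family, with all three LOOCV AUCs near 1 under these well-separated
phantom conditions (the published cohorts, with real anatomical and
observer variability, sit at 0.97–0.995).

## Known limitations

* Phantom geometry is a stylized stand-in: two ellipsoids per side, no
  claim of anatomical fidelity to PPMI templates.
* The ROI surrogate replaces an irreproducible manual protocol; its
  threshold is a knob, not an estimate of observer behaviour.
* Noise is Gaussian-on-sqrt-intensity (Poisson-like), adequate for the
  rank-based statistics used downstream, not a reconstruction noise model.
* Left/right reduction to one value per subject (mean by default) is a
  documented choice; published reports do not state theirs.
* Phantom cohorts are far better separated than clinical ones; absolute
  AUCs here are ceiling-level and only orderings/directions are meaningful.
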