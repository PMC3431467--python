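# Methods

This note documents the models, conventions and numerical choices behind
`lungqct`, in the order the pipeline runs them: phantom generation,
reconstruction-noise rendering, lung segmentation, densitometry, airway
morphometry, agreement statistics.

## Thoracic phantom

Each synthetic subject is a pair of clean (noise-free) inspiratory and
expiratory attenuation volumes plus ground truth. Geometry is defined in
physical millimetres on an anisotropic grid, by default 128³ voxels at
0.7 × 0.7 × 1.0 mm — thin-slice chest-CT-like anisotropy at desk scale.

* **Thorax / lung.** A soft-tissue ellipsoid (+40 HU) in background air
  (−1000 HU) contains a single smooth ellipsoidal "lung". Normal
  parenchyma is −880 HU at inspiration and −790 HU at expiration;
  all tissue classes carry per-voxel Gaussian texture (σ = 20 HU) so lung
  histograms are realistic unimodal curves rather than delta spikes.
* **Pathology.** Emphysema (−1000 HU, both phases) and air trapping
  (−880 HU at expiration, i.e. retaining inspiratory density while the
  surrounding lung rises) are carved from thresholded smooth Gaussian
  random fields (correlation scale 3 mm), which yields spatially coherent
  clusters; selecting exactly k voxels by field value makes the achieved
  fraction exact to one voxel. Emphysema sits below the −950 HU density
  mask, normal inspiratory lung above it, so the mask is genuinely
  exercised.
* **Airway.** One straight tube parallel to the z axis (lumen −1000 HU,
  wall 0 HU; default inner radius 1.8 mm, outer 3.8 mm) runs through the
  lung and continues superiorly into the mediastinal soft tissue, with an
  open top and a capped bottom. The lumen is therefore an air column
  enclosed by wall everywhere except its superior opening — which is what
  lets the segmenter find and remove it the way a trachea is removed. The
  analytic truths LA = πr_i², WA = π(r_o² − r_i²), Pi = 2πr_i follow from
  the radii.
* **Cohort.** Per-subject parameters are drawn uniformly from configurable
  ranges; the defaults emulate a heavy-smoker screening population: mild
  emphysema (2–15 % of lung voxels), broad air trapping (5–30 %),
  inspiratory parenchyma −900…−860 HU, expiratory −810…−770 HU, lumen
  radius 1.4–2.4 mm with 1.6–2.4 mm walls (segmental-bronchus calibre;
  the resulting LA/WA/Pi medians fall where segmental airways measure).
  Per-subject seeds come from independent substreams of one master seed,
  so runs are bit-reproducible and subject k does not depend on cohort
  size.

Deliberately not modelled: respiratory motion or volume change between
phases (the expiratory volume shifts attenuation only), lobar anatomy,
vessels, beam hardening, projection-domain physics. Passing tests
therefore demonstrate correctness of the measurement battery and the
direction of noise-driven effects, not performance on anatomically
faithful scans.

## Reconstruction noise model

A reconstruction rendering adds independent zero-mean Gaussian noise with
standard deviation σ·(1 − ρ), where σ is the full "FBP" image noise and ρ
the fractional noise reduction of the iterative algorithm (default
ρ = 0.45, the vendor-stated theoretical reduction of the hybrid IR level
modelled). IR is modelled purely as noise scaling — no additional
smoothing or texture change — consistent with a denoiser that preserves
image characteristics. No absolute noise magnitudes are published for
either algorithm at these scan settings, so σ is an artifact choice:
σ = 80 HU by default, picked inside the range where expiratory low-dose
chest CT noise plausibly lies and where the threshold indices visibly
separate between renderings.

Within the cohort pipeline the two renderings of one phase share the
underlying standard-normal field (the IR volume is the same noise scaled
by 0.55), emulating two reconstructions of a single raw acquisition;
independent fields can be had by calling `apply_reconstruction` with
different seeds.

## Lung segmentation

Threshold/region method: Gaussian pre-smooth (σ = 1 voxel); air mask at
< −320 HU; connected components at 26-connectivity; components touching
the grid border (outside air) discarded; components above 0.5 % of the
field of view kept as lung; internal holes filled.

Two details matter numerically:

* **Boundary margin.** The final surface is taken at −470 HU
  (threshold − 150 HU margin) on the smoothed volume, near the midpoint of
  the parenchyma/chest-wall edge profile. The iso-contour of a noisy
  smoothed field drifts systematically with noise level wherever the edge
  profile is curved (a second-order effect), so a surface taken at −320 HU
  admits more chest-wall partial-volume voxels at higher noise, which
  couples mean lung density — and hence E/I-ratio₍MLD₎ — to the
  reconstruction algorithm. At the profile midpoint the curvature term
  vanishes to leading order and the bias disappears, while Dice overlap
  against the phantom truth improves (the midpoint surface is closer to
  the true boundary than the −320 HU surface).
* **Airway removal.** The strict-air (< −950 HU) component with the most
  superior extent — the trachea-like opening above the lung apex — is
  removed after dilation by 2 voxels. This step thresholds the *raw*
  volume: pre-smoothing a 1–2 mm lumen against its high-attenuation wall
  pulls it above −950 HU and makes it undetectable, whereas in the raw
  volume the lumen stays a connected air column that the wall ring
  isolates from parenchymal noise. Growth is capped at 2 % of the field
  of view against leakage into emphysematous clusters.

Implausible outcomes raise a typed `SegmentationFailure` (no lung-like
component, or lung volume outside 2–60 % of the field of view — bounds
expressed as fractions so the same defaults serve phantom and human
scale). The pipeline converts failures into logged exclusions, mirroring
how visually failed segmentations are excluded from cohort studies;
`check_segmentation` provides an automated QC surrogate (volume bounds,
border contact) since no visual check exists here.

## Densitometry conventions

Stated explicitly because conventions differ between tools: "below"
thresholds are strict (<); the RVC band −860…−950 HU is inclusive at both
ends and voxels below −950 HU are outside it; percentiles (Perc15, and
all medians/IQRs in the statistics module) interpolate linearly between
closest order statistics at position (n−1)·p. HU values stay real-valued
throughout; nothing is quantised to integers before statistics.
Inspiratory and expiratory masks are segmented independently, each on its
own series. Depth-of-inspiration normalisation and emphysema cluster-size
analysis are out of scope.

## Airway morphometry (FWHM)

From a manual seed, the centre is refined to the centroid of the
8-connected lumen region (< −700 HU) — a fixed point for a symmetric
lumen. 128 rays (0.1 mm steps, 10 mm reach, bilinear interpolation) give
radial profiles. Per ray, the wall is the *first* sustained excursion
above the mid-level between the profile extremes; taking a global maximum
instead would latch onto the chest wall or an adjacent vessel on rays
that leave the parenchyma within the sampling radius. The inner boundary
is the first crossing of (lumen minimum + wall peak)/2, the outer
boundary the first crossing of (wall peak + parenchymal minimum)/2 beyond
the peak, both sub-step by linear interpolation — which makes the radii
exactly invariant to affine rescaling of the profile. Monotone or
peakless profiles are flagged invalid.

Rays whose radii sit more than 3 median-absolute-deviations from the
angular median are rejected (the MAD is floored at the sampling step so a
near-perfect circle does not reject its own rays); invalid and rejected
rays are refilled by periodic linear interpolation over angle. If fewer
than 75 % of rays survive, the measurement fails rather than returning a
contaminated contour. A 5-ray circular moving average is applied to the
angular radius profiles before contour assembly: uncorrelated per-ray
jitter from pixelation or noise inflates a polygon's perimeter even when
its area is unbiased, and the average suppresses exactly that. LA and the
outer area are shoelace polygon areas, WA their difference, Pi the inner
polygon perimeter; WA% = 100·WA/(WA+LA) holds to numerical precision by
construction. Measurement is in the axial plane at the seed's slice; the
ray count, step and outlier policy are artifact choices (the validated
tools in this field do not publish theirs at this granularity).

## Agreement statistics

Lin's concordance correlation coefficient uses moment estimators with
denominator n (Lin's original form; n−1 shifts pc slightly at small n),
classified as poor (< 0.90), moderate (0.90 ≤ pc ≤ 0.95), substantial
(0.95 < pc ≤ 0.99) or almost perfect (> 0.99). The Wilcoxon signed-rank
test discards zero differences, uses midranks for ties, and computes the
exact two-sided p (dynamic programming over doubled midranks, exact also
under ties) for up to 25 non-zero differences, switching to the normal
approximation with tie and continuity corrections above. Significance is
read at 0.05 with no multiplicity correction, matching common practice in
paired-agreement studies of this kind. Bland–Altman limits and
mixed-effects models are out of scope.

## Problem sizes

The default study is 30 subjects at 128³; one full run (simulate, render
×4, segment ×4, measure, compare) takes about a minute and a half on one
CPU. Unit tests use 64³ phantoms, which preserve every geometric
relationship of the default grid.

## Known limitations

* The phantom's lung is a single ellipsoid; segmentation is not tested
  against real chest anatomy (fissures, hila, diaphragm contact).
* IR is a global noise scale; real iterative algorithms are spatially
  adaptive and slightly nonlinear, so real-data concordance values will
  differ from the phantom's.
* Expiration does not shrink the lung, so expiratory lung volume equals
  inspiratory volume; E/I-ratio₍MLD₎ variation across subjects comes from
  attenuation, not volume change.
* The airway is measured on one perpendicular cross-section; oblique
  branches would require reformatting that is not implemented.
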