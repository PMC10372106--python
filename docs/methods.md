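# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `lvpet`, and what the synthetic phantom does and
does not establish about real data.

## Data model and units

Images are activity-concentration volumes (Bq/mL) on regular orthonormal
grids; world coordinates are RAS millimetres. NIfTI-1 is the interchange
format, with frame timing and gating in a JSON sidecar
(`FrameTimesStart`/`FrameDuration` or `FrameSchedule` for dynamic series;
`NumberOfGates` + `GateWindow` for gated series) since the NIfTI header has
no usable timing fields. No decay correction is applied anywhere — input is
assumed reconstruction-corrected. The default dynamic framing is 22 frames
(1×10, 8×5, 4×10, 2×15, 3×20, 2×30, 2×60 s; 360 s total); the default
gating is 8 bins over the 10–50 s first-pass window.

## Kinetic model

A voxel follows the single-tissue-compartment model for freely diffusible
water with arterial and venous blood spill-over:

    C_PET(t) = (1 − V_A − V_V) · MBF · [C_A ⊗ e^(−k2 t)](t)
               + V_A·C_A(t) + V_V·C_V(t),        k2 = MBF / V_T

with MBF in mL·min⁻¹·mL⁻¹, the water partition volume V_T in mL·mL⁻¹, and
unitless spill-over fractions bounded by 0 ≤ V_A, V_V, V_A+V_V ≤ 1. Model
frame values are time-averages over each frame interval.

**Fitting** is the basis-function linearisation: for each k2 on a fixed
grid the model is linear in (α, V_A, V_V) with α = (1−V_A−V_V)·MBF. Per k2
the bound-constrained least-squares problem is solved *exactly* by
enumerating every active set of the constraints {α≥0, V_A≥0, V_V≥0,
V_A+V_V≤1}, including the V_A+V_V=1 boundary — pure blood-pool voxels sit
on that boundary and omitting it misattributes their signal to spurious
tissue mixtures. MBF is recovered as α/(1−V_A−V_V) with the denominator
floored at 0.05. The default grid is 64 log-spaced k2 values in
[0.01, 8] min⁻¹, wide enough to cover high-flow/low-V_T combinations
(k2 = MBF/V_T up to 6 min⁻¹ for MBF 3, V_T 0.5). On noiseless synthetic
TACs this recovers V_A/V_V to better than ±0.01 and MBF to within ~5%
(grid-resolution limited) across MBF∈[0.3,3], V_T∈[0.5,1.1], V_A∈[0,0.6],
V_V∈[0,0.4].

**Numerics.** Input curves are resampled to a uniform 0.25 s grid (zero
before the first sample, last value held after the end); the convolution is
a trapezoid-corrected discrete convolution (second-order accurate, needed
to track the sharp bolus rise); frame averages use the cumulative
trapezoid. No delay or dispersion correction is applied to the input
functions — a documented limitation.

**Input functions** are extracted by k-means (fixed seed, k=4 by default)
on L2-normalised TACs of voxels above the 95th percentile of early-frame
activity. Among high-amplitude clusters peaking inside the first pass, the
earliest-peaking is the venous (right-heart) curve and the latest-peaking
the arterial; same-frame peak ties go to the higher-amplitude cluster
(purer blood). Each cluster's curve is the mean TAC of its top-decile
amplitude members so partial-volume edge voxels do not depress the scale.

A caveat that matters downstream: in *single voxels* under noise, a blood
TAC and a fast-clearing tissue response are nearly degenerate explanations.
The fitted V_A/V_V values are therefore noisy voxelwise even though they
are unbiased regionally. Since chamber evidence is regional, the pipeline
smooths internally fitted V_A/V_V maps with the segmentation kernel before
sampling them at seed maxima; maps supplied by the caller are used as
given.

## Seeding and chamber assignment

Foreground is `value ≥ background_fraction · max` (default 0.10 — a low
threshold, consistent with count-based volumetrics). Each foreground voxel
points to the 26-neighbour maximising (neighbour − centre)/distance in mm
(anisotropy-safe); ties break to the lowest linear voxel index; maxima
plateaus (mutually adjacent no-higher-neighbour voxels, necessarily
equal-valued) collapse to the component's lowest-linear-index voxel.
Pointer-jumping resolves every voxel to its basin root. Seeds smaller than
`min_seed_voxels` (default 8) merge into the neighbour sharing the largest
boundary. The implementation is validated voxel-for-voxel against a
brute-force path-tracing oracle on random grids.

A seed is LEFT if V_A at its maximum exceeds both V_V and `min_fraction`
(default 0.25, a package choice — the evidence threshold is not a published
value), RIGHT symmetrically, NONE otherwise including exact ties.

Seeding is recomputed per gate bin by default (`seed_per_bin=False` reuses
the time-averaged segmentation), since chamber shape changes over the
cycle.

**Presmoothing.** Gated first-pass bins are count-starved; at realistic
count levels voxelwise Poisson noise creates hundreds of spurious local
maxima that small-seed merging cannot repair. The pipeline therefore
applies a matched Gaussian filter (default 6 mm FWHM, the scanner PSF
scale) to the images used for *segmentation and plane search only*. Volume
sums use the raw counts (see below).

## Valve-plane detection

The LV long axis is the activity-weighted principal axis of the LEFT pool.
Base→apex orientation uses mass asymmetry: the centroid (weighted by
activity) lies on the ventricular side of the pool's extent midpoint, and
the apex is the extreme on that side. (A cross-section-based rule fails
here: with the atrium attached, the mid-atrium cross-section is smaller
than the mid-ventricle one.) Pools smaller than 20 voxels or with principal
anisotropy below 1.2 raise an error asking for a manual axis.

For each of 36 rotations about the axis, the image is resampled on a thin
slab (2-voxel thickness) containing the axis; positions below
`0.5 × median(LEFT-pool activity)` form the low-activity mask (the median
reference is insensitive to hot-spot noise); at each long-axis position the
width of the contiguous high-activity run around the axis is measured.
Local width minima with prominence ≥ 2 mm become indentation candidates at
the run midpoint. Candidate triples are searched exhaustively (sampled with
a fixed seed above 20 000 triples); the plane with most candidates within
2 mm wins, ties going to the most basal mean long-axis position (the mitral
waist is the basal-most consistent ring); planes tilted more than 45° from
transverse are rejected as implausible valve orientations. The winner is
refit by total least squares on its inliers, the normal oriented toward the
apex; an inlier fraction below 0.5 flags the plane low-confidence (the CLI
downgrades its exit status accordingly). User adjustment translates the
plane along its normal and/or tilts the normal about a fixed horizontal
axis at a chosen azimuth (a fixed axis makes equal-and-opposite tilts
cancel exactly); tilts beyond 45° are rejected.

The plane is detected once on the time-averaged gated image, not tracked
per bin — atrioventricular-plane motion over the cycle is a known
limitation, particularly under stress.

## Count-based volumes

Per bin, the LV region is the union of LEFT seeds whose activity-weighted
centroid lies apical (positive side) of the plane — whole seeds flip in or
out with plane adjustments, which mirrors the interactive behaviour of the
analysis and is the main source of observer variability. The volume is

    C_ref = mean of region voxels ≥ 75th percentile (pure-blood estimate)
    V = v_vox · Σ_{C_i ≥ 0.10·C_ref} C_i / C_ref

Fractional counting makes V insensitive to the blur that moves counts out
of the cavity (they are still summed) and exactly reduces to voxel counting
for uniform regions; global intensity rescaling cancels. With noisy counts
the top-quartile rule would preferentially select upward noise excursions
and bias C_ref high, so C_ref and the counting threshold are evaluated on
the smoothed copy while the sum uses raw counts. ED/ES are the volume
extremes over bins (first bin wins ties); EF is reported in percent.

## Synthetic phantom

The gated phantom is a prolate-ellipsoid LV cavity (semi-axis ratio 1:1.8)
whose volume follows `V(φ) = ESV + (EDV−ESV)(1+cos 2πφ)/2`, base fixed at
a known valve plane (the atrioventricular plane moves in reality; fixing
the base keeps the truth analytic); a 40 mL left atrium joined across the
plane by a 5 mm-radius neck (the activity waist the detector must find); a
140 mL right-ventricular pool separated by a 12 mm septal gap; and a 9 mm
myocardial shell at 8% of blood activity — the first-pass window is chosen
clinically precisely because myocardial uptake is still small, and 8%
keeps the unblurred wall below the 10% counting threshold, as the method
assumes. Blood activity is 30 kBq/mL (a 400 MBq bolus scale), voxels 2 mm
isotropic on a 96³ grid, PSF 6 mm FWHM, and Poisson noise on expected
counts (activity × voxel volume × bin duration × sensitivity 0.05, i.e.
tens of counts per voxel per gate — gated bins are genuinely
count-starved). Structures are voxelised with 4× supersampling so analytic
truth volumes carry <0.5% voxelisation error. The whole geometry can be
rigidly rotated for equivariance tests.

Gate bins are *phase-window averages* of the volume curve: bin b averages
the window of width 1/B centred on φ=b/B, giving
`V_b = ESV + (EDV−ESV)/2·(1 + cos(2πb/B)·sinc(1/B))`. The sinc factor is
the gating attenuation — fewer bins wash the extremes toward the mean,
which reproduces the clinically observed ESV overestimation with few gates
and is why per-bin truth extremes sit ~1% inside the continuous EDV/ESV at
B=8.

The dynamic phantom uses the cycle-averaged geometry with gamma-variate
venous (peak ~15 s) and arterial (peak ~25 s) blood curves plus a small
recirculation tail; myocardial voxels follow the kinetic model (MBF 0.9,
V_T 0.91). Truth V_A/V_V maps are the PSF-blurred blood occupancies.

**What the phantom does not emulate:** anthropomorphic anatomy, papillary
muscles and trabeculation, atrioventricular plane motion, respiratory and
patient motion, attenuation/scatter, correlated reconstruction noise (the
phantom's Poisson noise is voxel-independent post-blur), arrhythmic gating
errors, and pathology (regional wall-motion abnormalities, severely dilated
or low-EF ventricles). Passing phantom tests therefore demonstrates
correctness of the algorithmic chain under controlled geometry and noise,
not clinical accuracy; the latter requires patient validation against a
reference modality.

## Agreement statistics

Bland–Altman bias and limits of agreement with the repeatability
coefficient RPC = 1.96·SD of paired differences; percent bias relative to
the reference (second) series; Pearson r; paired Wilcoxon signed-rank
(zero differences dropped, mid-ranks for ties, exact null for n ≤ 25
without ties, normal approximation with continuity correction otherwise;
verified against exhaustive sign enumeration). The ICC is fixed to the
two-way random-effects, absolute-agreement, single-measurement form
ICC(2,1), with a McGraw–Wong F-based 95% CI, and is cross-checked against
an independent implementation. The choice matters: consistency-type ICCs
ignore systematic bias between methods and read higher whenever one method
is offset.

## Problem sizes and determinism

Default analyses run on 96³ × 8-bin images in a few seconds; the test
suite uses 48³ phantoms where full resolution adds nothing. All stochastic
steps (phantom noise, k-means, triple sampling) draw from seeds recorded in
the run configuration; identical configuration and seed reproduce outputs
bit-for-bit.
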