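# Methods

This note records the models, conventions, parameter choices and known
limitations behind `synq`'s measurements, in the spirit of a methods section
a maintainer can audit.

## Image model and conventions

All analyses operate on `ImageStack` objects normalized to axis order
(T, Z, C, Y, X) with intensities as non-negative floats (integer camera data
is promoted on load so projections and ratios cannot overflow). Pixel
indices are 0-based; the physical position of a pixel is
(index + 0.5) × pixel size (pixel-center convention), y increasing downward;
all landmark coordinates are (x, y) pairs in μm. Rasterized regions (cell
disk, bead, centrosome circle, center ellipse) contain a pixel iff the pixel
*center* lies inside the analytic shape, so rasterized-area errors are
bounded by roughly perimeter × pixel size and shrink linearly with sampling.
Loading requires an explicit pixel size when neither TIFF metadata (with a
real unit) nor a sidecar YAML provides one — defaulting silently would
corrupt every μm-denominated quantity. Axis layouts that cannot be inferred
unambiguously (bare 3-D TIFFs) require an explicit `axes` override rather
than a guess, to prevent silent Z/C swaps.

## Synthetic scenes as ground truth

The generator emulates the inputs the measurements were designed for: an
IIA1.6 B cell as a ~20-μm disk sampled at 0.1 μm/px (the scale at which a
1-μm-radius circle spans ~314 pixels, making circle-based densities
well-resolved), a tangent 3-μm antigen-coated bead, a Gaussian centrosome
punctum, a cortical actin band, diffusing sub-resolution spots (per-axis
step variance 2DΔt), a single-exponential FRAP recovery on a residual
post-bleach floor of 0.2 with 5 pre-bleach frames, and a flow edge
translating at constant speed. Rendering is noise-free field → Gaussian PSF
(default σ 0.2 μm, disabled where analytic equality is asserted) → optional
Poisson shot noise → additive Gaussian read noise, a standard camera model.
Everything is driven by one `numpy` Generator per call, so a fixed seed
reproduces pixels bit-identically.

What the generator does **not** emulate: real actin mechanics or
centrosome-translocation dynamics, 3-D PSFs, uneven illumination, photophysics
beyond a step bleach, or segmentation-adversarial morphologies. Passing
tests therefore demonstrate correctness of the *measurements* given
reasonable images, not robustness to every pathology of real microscopy.

Default kinetic/scale parameters (spreading intercept 80 μm² and slope
6 μm²/min over 10-s frames, FRAP plateau 0.8 and k 0.2 s⁻¹ sampled at 0.5 s,
flow edge 0.05 μm/s over 1-s frames, diffusion 0.074 μm²/s at Δt 0.75 s with
50-frame tracks) were chosen once as realistic magnitudes for B-cell synapse
imaging and are the conditions under which parameter recovery is validated.

## Segmentation and landmarks

Cell masks come from classical thresholding (Otsu by default, fixed
threshold optionally), hole filling and largest-connected-component
selection, matching single-cell fields where the cell of interest dominates;
multi-cell fields should supply label masks instead. A
machine-learning segmentation refinement is deliberately out of scope: no
trained classifier could be distributed, so classical thresholding is used
and the substitution is visible in this note. The centrosome is the
brightest punctum after PSF-scale smoothing (raw argmax is noise-sensitive),
refined to the intensity-weighted centroid of the above-half-max
neighbourhood, with 3×3 integrated intensity breaking exact ties. Spot
detection is scale-matched Laplacian-of-Gaussian (σ = r/√2 for the nominal
1-μm² spot area, r ≈ 0.564 μm); "quality" is the LoG response at the
detected scale — a monotone analogue of interactive tracking tools' quality
index with identical thresholding semantics, not a reimplementation of any
specific plugin. The central ellipse takes its orientation and axis ratio
from the mask's second central moments and is scaled by bisection until its
*rasterized* area matches one third of the mask area as closely as the grid
allows, which keeps the all-center recruitment extreme within ±0.05 of its
algebraic value 2.

## Index definitions and edge policies

The polarity index uses the *signed* scalar projection: the stated −1…+1
range is only achievable with sign, and the sign is what distinguishes
polarized from anti-polarized cells. Indices beyond ±1 (centrosome
projecting past BMC or its mirror) are reported raw with an `out_of_range`
flag rather than clamped. The bead-recruitment denominator is the union of
cell mask and bead region, because the contact region can extend past the
segmented cell edge; with all fluorescence inside the bead region the value
is exactly 100. Antigen extraction is floored at 0% when the "after"
fluorescence exceeds "before" (staining variability), and the flooring is
flagged. Z profiles normalize plane index from the coverslip (fraction 1) to
the upper cell limit — auto-detected as the last plane above 5% of the peak
plane mean, or supplied explicitly when the label itself is axially
confined — and call a profile synaptic when the peak lies in fractions 1–2.
The number of fractions defaults to 10 and must not exceed the plane count.

## Dynamics

Spreading velocity is the OLS slope of area versus time (reported in
μm²/min with a 95% CI from the slope standard error); frames where
segmentation fails are excluded, never interpolated. Aspect ratio uses the
moment-equivalent ellipse, making it rotation-invariant, unlike a bounding
box. Kymographs sample the reslice line at 1-px spacing with bilinear
interpolation, averaging across the line width; the tan formula for flow
velocity is defined on the physically scaled kymograph (angle from the time
axis), and an explicit converter handles angles measured in pixel units —
the only reading under which tan of an angle yields μm/s. FRAP fitting
pins Y₀ = 0 (the curve is shifted to the bleach event), initializes the
plateau at the curve maximum and k at 1/t_half, and bounds the plateau in
(0, 2×max]; the fit is `scipy.optimize.curve_fit` least squares. Noiseless
curves are recovered to <10⁻⁶ relative error; at Gaussian noise σ = 0.02
with 60 points, k̂ falls within 10% of truth in ≥95% of 200 seeded
replicates.

## Tracking

Linking is greedy nearest-neighbour: per frame transition, candidate pairs
within the displacement gate are taken in ascending distance (ties broken by
track id, then spot position, making the result invariant to spot input
order), with optional gap closing off by default. Against exhaustive
minimal-total-distance assignment on small instances, greedy agrees exactly
under the sparse conditions tested; its known failure mode (a closer pair
stealing a spot needed for a globally better matching) is accepted as the
standard trade-off of this linker class. Track duration is
(n_frames − 1) × Δt — an interval, not a point count. Diffusion uses the
time-averaged MSD with the planar convention MSD = 4Dτ, fit through the
origin over the first quarter of lags (≥2); negative slopes are truncated to
0 and flagged. At 500 tracks × 50 steps the median D̂ lands within 15% of
truth across D ∈ {0.01, 0.074, 0.5} μm²/s; single-track estimates scatter
far more, which is why medians are the validated statistic.

## Colocalization and radial profiles

The rotation control rotates one channel about the mask centroid (the pivot
is otherwise undefined and the centroid keeps the cell in frame) with
bilinear resampling, computing the control coefficient over the mask pixels
whose rotated source stays in the image. Spot–channel correlation
normalizes each channel's circle mean by that frame's whole-cell total, so
per-frame gain changes cancel exactly; spots are binned into 5 equal-count
groups by default (the group count is configurable) and Spearman's rho
summarizes the monotone association. Normalized radii are computed by ray
marching from the mask centroid at 0.25-px steps with sub-pixel (bilinear)
interpolation of the 0.5-crossing; pixels whose ray leaves and re-enters the
mask (non-star-shaped geometry) are clipped to radius 1 and counted in a
`non_star_fraction` flag. The IQR filter fixes the Tukey factor at 1.5 and
linear-interpolation quantiles — both pinned explicitly because different
quantile conventions change which cells are rejected.

## Problem sizes and numerical tolerances

Validation suites run at desk scale chosen for statistical sufficiency:
288²-px scenes for index extremes, 128²-px scenes (20 random replicates) for
brute-force oracle equivalence at relative tolerance 10⁻⁹ (independent
summation orders), 500×50-step track ensembles per diffusion level, 200 FRAP
replicates, and 20 random star masks for the ray-cast binning oracle, where
pixels falling exactly on a quartile edge are excluded from the comparison
(either bin is correct there). Rasterization tolerances asserted in tests —
density index 1 ± 0.02 at 0.1 μm/px, center recruitment 2 ± 0.05 — follow
from the perimeter-bounded area error above.

## Known limitations

Single-channel Otsu segmentation fails on low-contrast or multi-cell fields;
bead regions require a bead channel or a supplied mask (bead borders are not
inferred from fluorescence-free images); the FRAP model is reaction-limited
single-exponential (no diffusion-coupled recovery, no mobile-fraction
normalization to the pre-bleach level — the plateau is reported on the
y-shifted scale only); kymograph lines are user-supplied, as in manual
reslicing practice; the greedy linker is not a globally optimal LAP tracker;
and the diffusion estimator assumes free planar Brownian motion over the
fitted lags.
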