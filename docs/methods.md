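# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know.

## Biaxial kinematics and J-curve metrics

The deformation gradient is the 2×2 linear part of the affine map
minimizing squared marker misfit: with centered coordinates X̃ (reference)
and Ỹ (deformed), F = (ỸᵀX̃)(X̃ᵀX̃)⁻¹. Centering makes the translation
drop out, and the four-marker grid (3 mm square) keeps X̃ᵀX̃ well
conditioned; collinear references are rejected. Stretches are reported
along the device axes (√C₁₁, √C₂₂) rather than as eigen-stretches because
the specimen axes are mounted aligned to the device axes; principal
stretches remain available through C.

Membrane tension is force over the deformed orthogonal rake-to-rake
length; mN/mm is numerically N/m. The 10 mN slack-removal preload is
subtracted in force space before division, so the generator's constitutive
law inverts exactly; corrected tensions are clipped at zero and
zero-tension frames are excluded from toe fitting.

Loading cycles are segmented by prominence-filtered force extrema
(minimum prominence 10 % of range) on the controlled axis; the final
downstroke runs from the last peak to the following trough.

Toe and calf stiffness are OLS slopes of tension on stretch over tension
windows. Two window policies exist:

- fixed windows, default toe ∈ [0.5, 4] N/m, calf ∈ [16, 20] N/m —
  symmetric margins around the 20 N/m evaluation tension and above
  preload noise;
- `"auto"`: an exhaustive two-segment least-squares change-point fit
  locates the bilinear breakpoint, and the windows become
  (0, break − 10 %) and (break + 10 %, max). The pipeline uses auto
  because it recovers bilinear truths exactly wherever the transition
  sits; the fixed windows remain for curves whose transition tension is
  known to sit below the toe window.

The transition stretch is the curve point nearest (Euclidean, after
scaling both axes to unit curve range — "nearest" is otherwise
unit-dependent) to the toe/calf line intersection; parallel lines flag the
transition undefined. The anisotropy index interpolates each curve's
stretch at 20 N/m (monotone interpolation on sorted tension) and divides
circumferential by radial.

## Thickness profiling

Contours are parametric smoothing splines (`splprep`) reparameterized by
arc length through a 2000-point lookup table. Thickness is the distance
from each of N = 100 equally spaced atrialis stations (configurable) to
the first intersection of the station's normal ray with the ventricularis
curve; the normal is oriented by which side the ventricularis midpoint
lies on, and the ray length is 4× the longer contour so end stations
cannot silently miss. Stations whose rays miss are dropped and counted;
more than 20 % dropped raises a flag. Region means are taken over
arc-fraction thirds (near-annulus, belly, free edge); exclusion intervals
are input masks, not automated detection.

Leaflet area uses the shoelace formula (via shapely) on the calibrated
outline; width is the commissure-to-commissure distance. Height is
implemented as the maximal outline extent perpendicular to the commissure
chord — the published construction is shown only graphically, so this is
a recorded interpretation, configurable against the alternative
(annulus-midpoint to free edge).

## Regional IHC quantification

The 3×10 grid blends matched arc-length stations linearly:
P(s, t) = (1 − t)A(s) + tV(s), 3 equal arc-length segments × 10
transmural layers. Pixels are assigned to regions by polygon
rasterization with first-come resolution on shared boundaries, so the
partition conserves pixel totals exactly. Positivity is pluggable: a
label channel for synthetic rasters; for real RGB images, stain
separation with the standard hematoxylin/DAB vectors followed by an Otsu
or fixed threshold on the DAB channel (the original rule is unpublished,
hence the pluggable seam). Group summaries inside a cell are means by
default (median by config) and the fold-change map is
summary(TIC)/summary(CTL) with log₂; cells with zero control are flagged
undefined, never zeroed.

## Fiber orientation and nuclei

Orientation histograms come from the local structure tensor with
**Gaussian-derivative gradients** (σ_d = 1 px): finite differences are
anisotropic on thin fibers and bias orientations toward the diagonals by
several degrees, which Gaussian derivatives remove. The tensor is
window-averaged at σ = 2 px, the histogram is coherency-weighted, and
intensity is first percentile-clipped (0.35 % tails) and rescaled —
emulating saturation-based histogram normalization. A constant image
yields the uniform density with a zero-coherency flag.

Axial von Mises fitting doubles the angles onto the full circle, takes
the trigonometric moments of the (histogram-weighted) doubled angles, and
inverts the Bessel ratio A(κ) = I₁/I₀ = R̄ by bracketed root finding;
below the resolvable floor A(κ) ≈ κ/2 is used, and a single-bin histogram
caps κ at 500 with a flag. μ maps back to [0°, 180°); a resultant below
10⁻³ flags μ undefined. At 1° bins the grouping attenuation of R̄ is
≈ 5·10⁻⁵, negligible against the 10 % recovery tolerance. Depth thirds
D1/D2/D3 use lower-inclusive boundaries at exactly 1/3 and 2/3 of
normalized depth, averaging κ unweighted (coherency weighting available).

Nuclei are segmented by Otsu threshold (fixed threshold for synthetic
label images) and connected components; orientation and NAR come from the
second central moments with the 1/12 unit-pixel point-spread term, and
circularity = 4πA/P² with the Crofton perimeter, which keeps discretized
circles within a few percent of 1. Components with NAR > 6 are flagged as
possible unsplit merges but still reported.

## Collagen assay

Absorbance = slope·mass + intercept by OLS over ≥ 3 standards. The
default dilution chain matches the bench protocol: 10 µL water per mg wet
tissue for homogenization, 100 µL homogenate diluted 3× through
hydrolysis/neutralization, 10 µL plated — so content (µg/mg) = 3 × well
mass (µg). Absorbances outside the standard range flag extrapolation;
negative interpolated masses floor at zero with a flag. Triplicates are
averaged with their CV reported; no outlier rejection by default
(median-of-three available).

## Proteomics DE filter

Steps run strictly in order: (1) ≥ 2 non-missing replicates in every
group, (2) per-sample total normalization, (3) fold change as the ratio
of group means (median by config) of normalized intensities, (4) Wilcoxon
rank-sum per protein (exact for pooled n ≤ 20 without ties), (5) DE iff
|log₂FC| ≥ 1 and the test criterion. Because a two-sided exact rank-sum
test at n = 3 per group cannot fall below p = 0.1, the test criterion is
explicit: `two_sided_exact` (default), `one_sided`, or
`fold_change_only`; the chosen mode travels with the result. Missing
intensities are treated as absent — the replicate filter implies
presence/absence semantics — so no imputation.

## Statistics dispatcher

Shapiro–Wilk per sample, gate at p ≥ 0.05 (configurable); both normal →
two-sided variance-ratio F-test at 0.05 → Student's (equal) or Welch's
(unequal) t; any normality failure (including undefined normality for
constant samples, flagged) → Wilcoxon rank-sum, exact for pooled n ≤ 20
without ties, otherwise normal approximation with tie/continuity
correction. Samples are summarized by mean iff they passed normality,
median otherwise. Two-tailed is the default; one-sided tests require
explicit declaration per comparison. Correlations: Spearman when either
variable is ordinal (e.g. regurgitation grades 0–4) or non-normal, else
Pearson. No multiple-testing correction is applied across the pipeline's
comparisons, matching the upstream analysis practice; the comparison
table exposes raw p-values so a user can apply one.

## Synthetic generators: what they emulate, and what not

Defaults are the study-like conditions: a 7×7 mm specimen with a 3 mm
four-marker grid sampled at 5 Hz; piecewise-linear tension–stretch laws
(circ toe 25, calf 300 N/m per unit stretch, transition 1.10; rad 12/150
at 1.25) giving a J-curve that reaches ~20 N/m at the prescribed final
stretches diag(1.16, 1.37) and an anisotropy index ≈ 0.85; thickness
falling linearly 1.2 → 0.6 mm from annulus to free edge; mean fiber angle
90° (circumferential) with κ(z) = 5 − 3z through depth; nuclei NAR
~ N(1.8, 0.2); 100-protein log-normal intensity matrices with 10 planted
|log₂FC| = 2 proteins, 5 samples per group, 10 % CV. Cohorts apply
independent log-normal between-subject factors (10 % CV) to area,
thickness, and the κ profile. The piecewise-linear law was chosen over a
smooth hyperelastic form so metric recovery has an exact analytic truth.

Not emulated: second-harmonic speckle and imaging physics, chromogen
color (synthetic positivity is a label channel; the color-deconvolution
path is tested separately), rake friction, hemodynamics, raw mass
spectra. Passing tests therefore demonstrate correctness of the
quantification chain on idealized signal content, not robustness to
acquisition artifacts of real microscopes or devices.

At zero planted effect and zero noise the generators satisfy exact
identities (fold change exactly 1 or 4, markers exactly affine) used as
trivial oracles; sampled recoveries are tested at their statistical error
scale (κ within 10 % at n = 10⁴, NAR mean within 0.05 at n = 500).

## Problem sizes

The default test and acceptance runs use: 1,000 random marker sets for
the deformation oracle; a 5×5×5 grid of 200-point bilinear curves;
100-station thickness profiles; a 120×900 px IHC band; 10⁴ fiber samples
per slice; 500-nucleus fields at 2048²; 2,000 null replicates for
dispatcher calibration; and 200 effect + 100 null cohort replicates at
n = 10/10 with 12 depth slices × 1,500 fibers per subject. These sizes
put every sampled check well inside its tolerance while keeping a full
run to a few minutes on one CPU.

## Known limitations

- The change-point window finder assumes one dominant stiffness
  transition; multi-phase curves would need the fixed-window path.
- Normal-ray thickness can drop end stations on strongly curved sections;
  the drop counter and 20 % warning make this visible rather than silent.
- Region polygons assume the atrialis and ventricularis contours are
  ordered consistently and do not cross; crossing contours are rejected,
  not repaired.
- The nuclei generator places non-overlapping ellipses; touching-nuclei
  splitting (watershed) is out of scope, and merged components are only
  flagged.
- `dispatch_compare` inherits the known behavior of pretest-gated
  pipelines: the Shapiro–Wilk gate makes the overall procedure slightly
  conservative at small n (measured type-I ≈ 0.04 at n = 15/15).
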