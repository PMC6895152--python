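# Methods

## Physical model

A collagen fibril is modelled as a cylindrically symmetric (C∞)
second-order scatterer with non-chiral susceptibility components χ33,
χ31, χ15. For incident linear polarization at angle θ (from the
laboratory Z axis, counter-clockwise, radians internally and degrees at
every user interface) and a fibril axis at in-plane angle ϕ, the total
SHG intensity is

    I(θ) = a0 + a2·cos 2(θ−ϕ) + a4·cos 4(θ−ϕ)
    a0 = K/2·[1 + ((ρ−1)/2)² + 2((ρ+1)/2)²]
    a2 = K(ρ²−1)/2
    a4 = K/8·(ρ−3)(ρ+1)

with ρ the effective anisotropy and K an overall scale. Out-of-plane
tilt δ enters only through ρ = ρ0·cos²δ + 3·sin²δ; the pipeline never
inverts δ separately. The component form
IZ ∝ |χ15 cosδ (A sin²u + B cos²u)|², IY ∝ |χ15 A cosδ sin 2u|²
(u = θ−ϕ) is kept with the degeneracy factor 2 on the sin 2u term so
that at A = 1, B = ρ the component sum reproduces the harmonic
coefficients above exactly; `tests` enforce this consistency on a 1°
grid. Chiral tensor terms, wavelength dependence and focal-field
modelling of emission directionality are out of scope; F/B is treated
empirically.

ρ = −1 (no modulation) and ρ = 3 (vanishing 4th harmonic) are degenerate
points of the law; simulation defaults draw ρ0 from [1.3, 2.0], inside
the physically typical and numerically well-conditioned band.

## Orientation inversion

With Nθ angles θ_k = k·180°/Nθ (default 18 × 10°, the half-turn period
of the signal), the harmonic cos 2(θ−ϕ) lives in DFT bin 1 and
cos 4(θ−ϕ) in bin 2: F_m = Σ_k I_k e^(−2πimk/Nθ), α0 = F0/Nθ,
c_m = 2F_m/Nθ. The phase estimates are ϕ2 = −Arg(c1)/2 (two-argument
arctangent: unique on the axial half-turn) and
ϕ4 = −arctan(tan(Arg(c2)))/4 (single-argument arctangent so the unknown
sign of a4 cannot fold it out of (−π/8, π/8]). The final orientation is
the variance-weighted blend ϕ = β·ϕ2 + (1−β)(ϕ4 + mπ/4) with
β = α2²/(α2²+4α4²) and m ∈ {−2…2} minimizing the circular (period-π)
distance between the two estimates; the blend is evaluated on the branch
of ϕ4+mπ/4 nearest ϕ2, then wrapped, so it never averages across the
±90° seam. Ties between m = ±2 (π apart, hence equivalent) resolve to
the smaller |m|. Sign conventions were fixed by exact-recovery tests on
rendered truth, not assumed.

ρ is recovered in closed form: projecting the complex harmonics at the
known ϕ gives signed amplitudes a2 = Re(c1·e^(2iϕ)),
a4 = Re(c2·e^(4iϕ)); with r = a4/a2, ρ = (4r−3)/(4r−1). Guards:
|a2| ≤ 1e−12·max(α0,1) and |4r−1| ≤ 1e−6 mark the pixel undefined
rather than clipping — the estimate is reported on the branch the closed
form returns so estimator pathologies stay visible; clipping to a
physical display range is a rendering choice, not an estimation one.
For ρ < 1, a2 < 0 shifts ϕ2 by 90°; the default simulation band avoids
this regime and the limitation is accepted.

### Kleinman-relaxed fit and validity filter

The per-pixel fit relaxing Kleinman symmetry uses

    I(θ) = K[(A sin²u + B cos²u)² + sin² 2u]

i.e. the χ15-normalized total intensity. The variant carrying A² on the
sin²2u term admits the exact gauge (A,B) → (sA,sB), K → K/s² that leaves
the whole θ-curve invariant, making A unidentifiable in principle; the
normalized form above (identical at A = 1, where it coincides with the
harmonic law) breaks that gauge, which is precisely what lets the
validity filter |A| < 1.1 discriminate. A sign ambiguity
(A,B) → (−A,−B) remains and is irrelevant to the |A| filter.

The fit is a batched Levenberg–Marquardt (4 parameters × Nθ residuals
per pixel, analytic Jacobian, damping 10×/0.3×, budget 200 iterations,
convergence at relative residual change < 1e−10), initialized from the
DFT inversion at A = 1. A per-pixel `scipy.optimize.least_squares` on
the same residual serves as the independent cross-check in tests; it is
far too slow to run per pixel at image scale. A pixel is valid when the
fit converged, the harmonic modulation exceeds 1e−6 of the mean (ϕ is
unidentifiable on a constant pixel) and |A| < 1.1.

The general validity mask requires α0 ≥ intensity floor (default 2
counts = 2× the default read-noise σ) and a relative RMS residual of the
two-harmonic reconstruction ≤ 0.3 — structureless noise has no harmonic
shape and fails this gate. Both thresholds are configurable.

## F/B directionality

Repeat frames (3 per channel by default) are mean-averaged before any
ratio. The corrected ratio is (F/B)/c with c the forward/backward
detection-efficiency ratio from an isotropic emitter (default 0.4), so
an isotropic source maps to 1 exactly. Pixels whose averaged backward
signal is below the noise floor (default 2 counts) are excluded from all
medians rather than regularized — an epsilon denominator would fabricate
the largest ratios exactly where the backward channel is empty.
Aggregation below the per-sample level is by median (robust to the
heavy ratio tail); across samples, means with SEM.

Thick fibers are segmented as pixels strictly above the Yen
maximum-correlation threshold (256-bin histogram over the channel's
min–max range, bright = fiber); the inter-fibrillar fraction is the
complement. A known behavior of Yen's criterion, measured here against
an exhaustive-search oracle: on a two-Gaussian 90/10 mixture it cuts at
roughly the 1.9σ quantile of the dominant mode at any σ, leaking ≈2.5%
of background into the foreground. The guarantee "recovered fraction
within 0.02 of truth" therefore holds for quasi-discrete histograms,
small foreground weights, and the skewed, high-contrast backward images
this pipeline segments (measured error < 0.01 on rendered adult
fields) — not for arbitrary Gaussian mixtures. A constant backward image
has no threshold; segmentation then reports the whole field as
inter-fibrillar with a warning.

## Circular statistics

Fibril orientation is axial (period π): statistics double the angles,
compute the resultant R = |mean e^(2iϕ)|, and halve the results:
mean = Arg/2, std = ½√(−2 ln R), reported in degrees. R < 1e−12 returns
+∞ for the std (uniform axial data) and an error for the mean
(undefined). Polar histograms duplicate every orientation by central
symmetry, so counts are exactly centrosymmetric and total 2n; the bin
width (default 5°) must divide 180 so the duplicate lands a whole number
of bins away. Statistics run over valid-mask pixels, unweighted by
intensity (weighting is available but off by default).

## Cohort statistics

One row per imaged sample; groups are compared per metric with the
two-sided Wilcoxon-Mann-Whitney test — exact enumeration when
n1+n2 ≤ 12 with no ties (attainable minimum 2/C(n1+n2,n1), e.g. 0.0043
for 5 vs 6), otherwise the normal approximation with midrank tie
correction. Shapiro-Wilk p-values are reported per group but gate
nothing: the comparison is always nonparametric. SEM uses the n−1
standard deviation. No multiple-testing correction is applied across
the four metrics; reports say so in their footer. The exact test at
nominal α = 0.05 is conservative at these sizes (discreteness), which
the suite verifies by simulation.

## Synthetic tissue fields

The generator emulates three architectures on a pixel grid (default
256×256 at 2 µm/pixel; full scan sizes are an option, not a test
default): homogeneous foetal fields (one base orientation, default
horizontal, plus wrapped-normal jitter), random foetal fields (Voronoi
orientation patches, expected cell area 40×40 px, patch axes uniform on
a solved arc plus 5° jitter), and adult fields (Voronoi fascicles with
per-cluster orientations, 4° jitter, separated by a thick-fiber skeleton
along the cell boundaries whose axis follows the boundary tangent —
computed from the smoothed boundary-distance gradient). The fiber area
(2% foetal, 10% adult) is set by a distance-transform quantile, so the
label fraction is exact by construction. The Voronoi cell scale is a
free parameter of the emulation, recorded in every manifest.

Dispersion defaults are calibrated to the tissue-class circular stds
(26° homogeneous foetal, 37° random foetal, 32° adult): writing the
target as a resultant R_t = e^(−2s²), the generator solves
|f·R_j·C_f + (1−f)·R_j·R_c| = R_t for the unknown non-fiber dispersion,
where f is the fiber fraction and C_f the realized fiber-tangent
resultant. Cluster orientations are assigned by area-weighted stratified
inverse-CDF sampling, so even ~40 clusters represent the nominal law;
measured field stds land within ~0.5° of target across seeds.
Wrapped-normal dispersion has circular std exactly σ, which makes the
solve closed-form.

Rendering: the polarization series scales each pixel's harmonic law to a
mean of `photons`·K counts per frame (K ≈ 1 inter-fibrillar with
lognormal texture σ = 0.15, 1.8 on fibers), adds Poisson shot noise and
Gaussian read noise (σ = 1 count) over 3 repeat frames, and quantizes to
integer counts; `photons=inf` renders the analytic model exactly with no
noise or quantization. F/B frames are Poisson draws around
backward = 200·K (fibers boosted 3× — they dominate the backward
channel) and forward = backward·fb_ratio·c, with fb_ratio 4.5
(foetal inter-fibrillar), 28 (adult inter-fibrillar) and 5 (fibers, both
ages — fiber F/B does not mature). All randomness flows from one integer
seed through named generators; fixtures regenerate bit-identically from
their manifest.

What the simulator does **not** emulate: realistic fibril packing or
diameter distributions, collagen-type chemistry, optical sectioning and
PSF blur (fiber boundaries are crisp, which flatters segmentation
accuracy relative to real images), stage drift between polarization
frames, or absolute instrument photon budgets. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not performance on real tissue.

## Problem sizes and numerical choices

Tests run on 64–256 px fields with the 18-angle grid and 3 repeats —
large enough for ±0.5° dispersion statistics and exact-fraction
segmentation, small enough for a routine desk run. The acceptance script
uses the full default 256×256 fixtures. Degenerate inputs are handled
explicitly rather than by epsilon: constant polarization pixels, zero
backward signal, constant backward images, zero-resultant axial samples
and tied rank-sum inputs each take a documented branch (invalid pixel,
excluded pixel, warned full-field fraction, ±∞/error, asymptotic
fallback).
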