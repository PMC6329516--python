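# Methods

## Problem and model

Multislice helical CT measures line integrals of the attenuation map
`x` (mm⁻¹) along rays from an X-ray source that rotates while the table
translates, so the focal spot traces a helix. Reconstruction is posed as

    min_x  ½ ‖A x − y‖₂² + λ ‖W x‖₁,

where `A` is the system matrix of the helical cone-beam geometry, `y` the
measured sinogram, and `W` the tensor framelet transform. With λ = 0 the
problem reduces to unregularized least squares; the TV special case is
described below.

## Scan geometry

The source sits at radius `R` from the rotation axis; at view `v` its angle
is `start_angle + 2πv / views_per_rotation` and its axial position advances
by `pitch · collimation / views_per_rotation` per view, where collimation =
`n_rows · row_height · R / SDD` is the total beam width at the isocenter
and pitch is the dimensionless table feed per rotation divided by
collimation. The detector is a flat equispaced panel rigidly attached to
the gantry at source-to-detector distance `SDD`, centered on the nominal
central ray. A clinical scanner's panel is cylindrical; flat is simpler
and irrelevant to the algorithmic questions at desk scale.

A flying focal spot is modeled as a deterministic per-view source offset
table (radial and z columns, mm); a helper builds the common alternating
±δz schedule. The panel stays on the nominal gantry while the source is
deflected, which is how the deflection is realized physically. Offsets
default to zero and no particular magnitude is assumed.

Conventions: 0-based indices, voxel-center sampling, right-handed frame,
z along the rotation axis, angles counter-clockwise from +x, mm
everywhere.

## Projector pair

`forward_project` is Joseph's method: for each detector cell a single
infinitely-narrow ray from the (possibly deflected) source to the cell
center; the driving axis is the one the ray crosses fastest in index
units; at each voxel slab the two transverse coordinates are interpolated
bilinearly and the sample is weighted by the path length per slab,
`spacing · ‖d‖ / |d_axis|`. Joseph interpolation is preferred over exact
Siddon intersection because its smooth footprint yields a better-behaved
adjoint for iterative solvers. `back_project` scatters with the identical
weights, making the pair an exact numerical transpose — the dot-product
identity holds at rounding level (~1e-16 relative), comfortably inside the
1e-6 the solver analysis assumes. Rays that miss the grid contribute zero
rather than raising.

## Tensor framelet transform

The 1D piecewise-linear tight frame uses the refinement masks

    ω₀ = ¼[1 2 1]   (average),
    ω₁ = √2/4[1 0 −1] (first difference),
    ω₂ = ¼[−1 2 −1]  (second difference),

whose transfer functions satisfy |ŵ₀|² + |ŵ₁|² + |ŵ₂|² = 1. Level-l masks
insert 2^(l−1) − 1 zeros between taps (à trous), so every sub-volume stays
grid-sized (undecimated). The 3D transform applies the 1D frame along each
axis unfolding with weight 1/√3; each axis carries its own lowpass chain
x_a^l = ω₀^l ∗_a x_a^(l−1). Convolutions are circular, so per axis and
level Σ_j ω_jᵀω_j = I exactly, the cascades telescope, and WᵀW = I holds
to machine precision (verified to 1e-10 in the tests; observed ~1e-15).
Symmetric padding is available in principle but the identity then holds
only away from the boundary, so periodic is the default and only tested
mode.

Design choice on the multilevel lowpass: the coefficient object keeps the
*per-axis* lowpass triple (scaled 1/√3) rather than a single merged
volume. Merging the three chains would break the exact identity (the
cross terms do not cancel); for L = 1 the triple is precisely the M₀ band
of the uni-level transform. The total coefficient count is therefore
(6L + 3) x voxel count: 2 bands x 3 axis components per level plus the
3-component lowpass.

The weighted TF norm combines the three axis components isotropically per
voxel and band, Σ_{l,j} λ_{l,j} Σ_vox √(c_x² + c_y² + c_z²), plus an
optional component-wise ℓ₁ on the lowpass (weight λ_{L,0}, default 0 —
penalizing the lowpass is unusual and disabled unless requested). Its
proximal map is the isotropic shrinkage c · max(m − λ/μ, 0)/m on the
band magnitude m, with a scalar soft-threshold on the lowpass.

**TV special case.** With L = 1 and weights (λ₀ = 0, λ₁ = λ, λ₂ = 0) the
penalty equals the central-difference isotropic TV norm times √6/6
(= (1/√3)(√2/4)·2, the axis weight times the mask scale times the
half-difference convention), so TV reconstruction is just a weight
configuration of the same solver.

## Solver

ADMM / split Bregman with auxiliaries d ~ Wx and multiplier v:

1. x-update: (AᵀA + μI) x = Aᵀy + μWᵀ(dⁿ − vⁿ), by conjugate gradients
   (WᵀW = I collapses the framelet quadratic to μI — the efficiency edge
   of the tight frame over TV, where the identity does not hold).
2. d-update: isotropic shrinkage of Wxⁿ⁺¹ + vⁿ with thresholds λ_{l,j}/μ.
3. v-update: vⁿ⁺¹ = vⁿ + Wxⁿ⁺¹ − dⁿ⁺¹.

Defaults (ours; quoted on data normalized so max|y| = 1): μ = 1, a single
scalar λ broadcast to all bands (1e-3), L = 2, 30 outer iterations, 20 CG
iterations at tolerance 1e-6, CG warm-started from the previous outer
iterate, x⁰ = 0 (FDK warm start optional), fixed iteration count (a
relative-change early stop at a configurable tolerance exists but is off
for reproducibility). The split-Bregman objective is not strictly
monotone; with coupling μ of the order of λ or larger the trace is
non-increasing after a few iterations, and μ should be scaled up with λ
when strong regularization is requested. The solver is deterministic:
identical config and seed give bit-identical traces.

## FDK baseline

A simplified helical Feldkamp reconstruction: cosine weighting
`SDD/√(SDD² + u² + v²)`, row-wise ramp filtering with the band-limited
Ram–Lak kernel in isocenter-plane units under a smooth cosine rolloff
(Hann or none selectable), then voxel-driven backprojection weighted by
the squared magnification (R/l)². Angular redundancy is handled by
averaging over the views whose detector z-window covers the voxel and
scaling by π (for a full circular scan this reduces to the classic
(1/2)∫ R²/U² q dβ). No Parker/Tam weighting is applied — the baseline
needs to be a credible FDK, not a vendor-grade one; it recovers the
center of a uniform sphere within 5% at dense sampling and is expected to
streak under sparse views, which is the phenomenon the regularized
methods are compared against. Slices never covered by any view's z-window
raise a validation error listing them.

## Synthetic data

Phantoms are sums of rotated ellipsoids with additive attenuation,
rasterized at voxel centers with 2x supersampling per axis by default;
an accreditation-style template (water cylinder, three insert rods, air
pocket, high-contrast edge block for MTF) is provided. The desk-scale
preset — 64 x 64 x 32 voxels at 2 mm, 16 rows x 96 channels of 4 mm
cells, R = 300 mm, SDD = 600 mm, 96 views/rotation, pitch 1, two turns —
is a scaled replica of a 64-row clinical acquisition (512 x 512 x 88,
2304 views/rotation) chosen so a full iterative solve runs in minutes on
one CPU; the methods' relative behavior, not absolute clinical quality,
is what the scale preserves.

Dose enters as the incident photon count I₀ per detector cell:
N ~ Poisson(I₀ e^(−p)) plus optional Gaussian electronic noise, clamped at
one count (standard guard against log of zero; a warning is logged when
clamping touches > 1% of cells), then p̂ = ln(I₀/N). Four I₀ presets
(2e4 … 2e5) stand in for 80–140 kV tube settings; first-order
var(p̂) ≈ e^p/I₀. The sparse-view protocol keeps every step-th view and
rescales views-per-rotation and the angular/table steps — equivalent to a
step-times-faster rotation and table feed.

What the simulator does **not** emulate: polychromatic spectra and beam
hardening, scatter, detector cross-talk and afterglow, bowtie filtration,
a cylindrical detector, or anatomical structure. Tests passing on this
generator therefore demonstrate algorithmic correctness and the relative
ordering of methods under ideal physics, not clinical image quality.
The noiseless simulation path uses the same projector as the solvers
(an "inverse crime"), which is intentional for the exact-recovery checks;
the noisy sparse-view comparisons add Poisson noise so the data no longer
lie in the projector's range.

## Metrics

All ROI statistics use population (divisor-n) standard deviations. UQI is
the product form 4 Cov(a,b)/(σ_a²+σ_b²) · m_a m_b/(m_a²+m_b²); it equals
1 exactly for identical non-constant ROIs and is undefined (signaled, not
zeroed) when both ROIs are constant. The general form ranges [−1, 1]
(negative for anti-correlated inputs) even though typical CT use sees
[0, 1]. SNR = mean/std over an ROI; CNR = |mean difference| / root of
summed variances. Volumes can be normalized by their robust maximum
(99.9th percentile) first; SNR/UQI are scale-invariant and CNR
shift-invariant regardless.

MTF: the edge-spread function is sampled along a line profile by linear
interpolation, optionally smoothed by a 3-tap moving average (off by
default), differentiated with the two-point mid-sample difference, and
the magnitude of the DFT of the resulting line-spread function is
normalized so MTF(0) = 1. The two-point difference maps a one-sample step
to an exact impulse (flat MTF) but attenuates smooth edges by sinc(f·Δs);
with ≥ 4 profile samples per blur σ the attenuation is within 2% down to
the MTF = 0.1 point, which is the documented sampling requirement for
quantitative use. At 2 samples per σ the attenuation reaches ~5% near
MTF = 0.1, so profiles should oversample the edge.

## Numerical choices and degenerate inputs

- float64 throughout the computations; containers store float32.
- Sinograms are rescaled to max|y| = 1 inside the solver and the result
  scaled back, so μ and λ are quoted on a common scale.
- CG reports whether tolerance or the iteration budget ended the solve;
  a non-positive-definite operator raises.
- Non-finite volumes/sinograms are rejected at the boundaries; a
  non-finite ADMM iterate raises naming the outer iteration.
- Shrinkage at zero magnitude returns zero (no 0/0); zero thresholds are
  an exact identity.
- Rays that miss the grid contribute zero; views whose z-window misses a
  voxel simply do not contribute to its FDK sum.

## Known limitations

- The FDK baseline's helical weighting is approximate (view-window
  averaging); its edge slices degrade when the helix barely covers them.
- Periodic convolution wraps framelet coefficients across the volume
  boundary; fields of view should keep the object away from the edge.
- The regularization parameters are not auto-tuned; reported defaults
  were chosen on the desk-scale phantom and are not claimed optimal for
  other geometries.
- Exact (Katsevich-type) helical reconstruction, ordered-subset
  acceleration and GPU execution are out of scope.
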