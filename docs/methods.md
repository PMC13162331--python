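# Methods

## Overview

`ctialps` computes perivascular-transport indices from two complementary MR
contrasts on one co-registered grid:

1. **High-frequency conductivity (σ_H)** is reconstructed from the
   multi-echo transceive phase φ^tr of the RF field. Under the assumption
   that conduction dominates displacement currents at the Larmor frequency,
   the phase-only relation is

       ∇φ^tr · ∇(1/σ_H) + ∇²φ^tr · (1/σ_H) = 2ωμ₀,

   a convection–reaction equation in u = 1/σ_H, stabilized by an
   artificial-diffusion term −c∇²u and solved slice-by-slice with 2-D
   central finite differences (Dirichlet boundary ring).

2. **Microstructure** comes from two-shell diffusion MRI via the
   multi-compartment spherical-mean decomposition: per voxel, the
   direction-averaged signal ē_b per shell is fit by a stick (intra-neurite,
   fraction ν_int, axial diffusivity D_int, zero radial) plus a zeppelin
   (extra-neurite, axial D_int, radial (1−ν_int)·D_int by the tortuosity
   constraint). The extra-neurite mean diffusivity follows as
   D_ext = (λ∥ + 2λ⊥)/3. Spherical-mean kernels:

       h_stick(b, λ)        = √(π/(4bλ)) · erf(√(bλ))
       h_zeppelin(b, λ∥, λ⊥) = exp(−bλ⊥) · h_stick(b, λ∥ − λ⊥)

3. **Low-frequency conductivity.** Because sub-kHz currents are confined to
   the extra-neurite space,

       σ_L = (1−ν)·D_ext·σ_H / (ν·β·D_int + (1−ν)·D_ext),

   with β the apparent intra/extra ion-concentration ratio. Anisotropy is
   inherited from the water-tensor eigen-frame S_D with extra-neurite
   eigenvalues d₁ = d₂ = (1−ν)·D_int and d₃ = 3·D_ext − 2·(1−ν)·D_int
   (their mean is exactly D_ext), giving the conductivity tensor
   C_L = prefactor · S_D diag(d₁, d₂, d₃) S_Dᵀ with
   prefactor = (1−ν)·σ_H / (ν·β·D_int + (1−ν)·D_ext).

4. **ALPS indices.** With 5-mm spherical ROIs at fixed template
   coordinates on the projection-fiber sites (±24/−28, −12, 24 mm) and
   association-fiber sites (±36/−40, −12, 24 mm), the water-diffusion index
   is ALPS = (Dxxᵖ + Dxxᵃ)/(Dyyᵖ + Dzzᵃ) per hemisphere, and the
   conductivity index substitutes C_L components (the canonical
   component-ratio form). Two cross-check forms are provided: a
   coordinate-free expression over per-ROI direction cosines, and a closed
   form in the ROI-mean compartment parameters,

       [(1−ν_ia)D_ia + (1−ν_ip)D_ip] / [(1−ν_ip)D_ip + 3D_ea − 2(1−ν_ia)D_ia].

   The closed form presumes a scalar prefactor common to both ROIs (it
   contains no β or σ_H) and a specific axis alignment; when the
   component-ratio and closed-form values disagree beyond a tolerance the
   package warns that the prefactors are ROI-specific.

## Axis convention of the closed form

The closed form assigns the projection ROI's x- and y-components the radial
eigenvalue (1−ν_ip)D_ip and the association ROI's z-component the axial
eigenvalue 3D_ea − 2(1−ν_ia)D_ia. Algebraically this is self-consistent
only when the fibers of *both* ROIs run along z (projection x/y transverse,
association z axial). The synthetic ALPS subject therefore uses z-oriented
fibers in both zones so the component-ratio and closed-form indices agree
exactly at ground truth; with other orientations the coordinate-free form
is the appropriate cross-check. Conventional ALPS anatomy instead treats
association fibers as y-oriented (anterior–posterior); under that geometry
the closed form does not reduce to the component ratio, which is why the
component ratio is the canonical reported value here.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| ω | 2π·127.74×10⁶ | rad/s | proton Larmor frequency at 3 T; the phantom round trip is invariant to the choice |
| μ₀ | 4π×10⁻⁷ | N/A² | physical constant, enforced exactly |
| c | 0.03 | SI (metre-scaled) | stabilizer weight; at this scale it balances the convection and reaction couplings of the operator (≈7.5×10³ vs 1–2×10³ per m² on a 2-mm grid). A voxel-lattice interpretation is exposed for sensitivity checks but makes the term numerically negligible |
| phase pre-smoothing | FWHM 1 voxel | in-plane voxels | raw phase Laplacians amplify noise; disabled for analytic phantoms |
| boundary σ | Helmholtz-seeded | S/m | each boundary-ring voxel takes the nearest interior Laplacian estimate, Gaussian-smoothed (σ = 1 voxel); self-contained, no manual input. Tests may inject the true value |
| u ≤ 0 failure threshold | 5% | of interior voxels | above this the reconstruction is considered failed rather than silently masked |
| β | 1.0 | – | never observable from these data; it cancels in the index whenever the ROI prefactors are common. Surfaced in every output and sweepable |
| shell rounding | nearest 50 | s/mm² | b < 50 is treated as b = 0 |
| MC-SMT bounds | ν ∈ [0,1], D ≤ 3.0×10⁻³ | mm²/s | free-water ceiling |
| multi-start grid | 5×5 over (ν, D_int) | – | deterministic; best grid point seeds a bounded trust-region refinement |
| ROI set | 5-mm spheres, 4 template centers | mm | shipped default; alternative diameters/centers are plain configuration |

DTI tensors are fitted per shell (b = 800 and b = 2000 separately, each with
the b = 0 volumes) by weighted log-linear least squares, because the index
is reported per b-value; pooling both shells remains available. MC-SMT
always uses both shells jointly. No Rician bias correction is applied by
default.

## What the phantoms emulate — and what they do not

The phase phantom solves the *exact* divergence-form forward relation
∇·((1/σ)∇φ) = 2ωμ₀ with a flux-conservative finite-volume scheme and
harmonic-mean face conductances — deliberately a different discretization
from the reconstruction stencil, so round-trip errors measure genuine
inverse accuracy rather than an inverse crime. Echoes share one transceive
phase (spin-echo assumption) with T2-decaying magnitudes and optional
Gaussian phase noise. The DWI phantom draws stick+zeppelin signals with
optional Rician noise (complex Gaussian of SD S₀/SNR on both channels).

The default acquisition mirrors the targeted protocol: 6 echoes at 12-ms
spacing; 6 b = 0 volumes plus 16 directions at b = 800 and 32 at
b = 2000 s/mm². Direction tables are generated by deterministic, seedless
electrostatic repulsion of antipodal point pairs initialized from a
Fibonacci lattice (1000 fixed iterations), yielding ≥ 24° minimum axis
separation and < 0.3% spherical-mean quadrature error.

The ALPS phantom places 10-mm cubic fiber zones at the four template ROI
centers on a 2-mm grid whose voxel centers coincide with those centers
exactly. Default zone parameters (projection ν = 0.6, D_int = 1.7×10⁻³;
association ν = 0.5, D_int ≈ 2.14×10⁻³ mm²/s, both tortuosity-consistent)
are chosen so the C_L scalar prefactor is common to both zones — the regime
in which the closed-form ground truth is exact.

Not emulated: head anatomy, coil/B1 profiles, k-space or EPI artifacts,
susceptibility distortion, partial volume from thick MREPT slices, motion.
Passing phantom tests therefore demonstrates correctness of the estimators
and index algebra under the stated signal models, not robustness to
acquisition artifacts that upstream preprocessing must remove.

## Numerical choices

- MREPT inverse: 5-point Laplacian and central first differences in
  physical (metre) spacing; per-slice sparse direct factorization
  (SuperLU); relative residual above 10⁻⁸ raises. Voxels with u ≤ 0 are
  masked and counted. The boundary ring keeps its Dirichlet value.
- The homogeneous-phantom solve is exact to machine precision for any
  c ∈ {0, 0.03, 0.3}: with u constant both the diffusion and convection
  terms vanish identically on the discrete stencil.
- Reconstruction under a rescaled ω is invariant except for the fixed
  stabilizer (the rest of the operator scales linearly with ω); measured
  footprint < 1% on the two-region phantom.
- MC-SMT: kernels evaluated with a series guard for bλ < 10⁻⁹;
  least-squares refinement is accepted only if it does not worsen the grid
  seed, otherwise the grid value is kept and the voxel flagged.
- Tensor eigen-systems by `numpy.linalg.eigh`, eigenvalues sorted
  descending, negative eigenvalues clamped at zero with a count. Within the
  degenerate radial plane (d₁ = d₂) the eigenvector assignment is
  arbitrary; equality is asserted only up to the subspace.
- σ_L is computed ratio-first, sigma_H · (num/den), so the ν = 0 limit
  returns σ_H bit-exactly.
- ROI membership: voxel-center Euclidean distance ≤ diameter/2 in world mm.
  Fields are required to be in axis-aligned RAS template orientation; other
  orientations are rejected, never silently flipped. ROI component means
  are taken first, then the ratio is formed (matching the printed structure
  of the index); the closed form likewise consumes ROI means of the
  parameter maps.
- ROC: empirical curve over observed thresholds (predicted positive when
  score ≥ cutoff), trapezoidal AUC (equals the Mann–Whitney statistic with
  ties counted ½), Youden-optimal cutoff with ties broken toward higher
  specificity. Age adjustment, where requested, is ROC on residuals after a
  pooled linear age regression — one of several possible adjustments, so
  the unadjusted ROC is always reported alongside.
- Group summaries use the sample SD (n−1).

## Problem sizes used in the shipped verification

Round trips use a 64×64 slice (2-mm in-plane); parameter recovery uses 500
voxels; the end-to-end phantom is a 54×14×10 grid with 7-voxel ROIs,
repeated over 20 seeds for the noisy condition; the fits are restricted to
a 2-voxel dilation of the ROI spheres, since only ROI voxels enter the
index.

## Known limitations

- **Noise floor of the two-shell spherical-mean inversion.** With 16+32
  directions and Rician SNR 30, the median per-voxel errors measured on the
  500-voxel grid are |Δν| ≈ 0.06 and |ΔD_int| ≈ 0.16×10⁻³ mm²/s. This is
  variance-dominated (Gaussian noise of the same SD reproduces it, and
  oracle-style Rician correction changes it little): with two shells and
  two free parameters the fit interpolates the observed means, so mean
  noise propagates directly into the parameters. Tighter per-voxel accuracy
  at this SNR requires more directions/averages; ROI averaging (7+ voxels)
  is what makes the index itself stable (mean index error < 4% at SNR 30).
- The 2-D slice-wise reconstruction ignores through-slice phase curvature;
  near-interface voxels are unreliable, hence region-interior validation
  with 2-voxel erosion.
- β, ion concentrations and hence absolute σ_L calibration are not
  identifiable from these data; c̄_ext is reported in arbitrary units.
- The mask-boundary Dirichlet seeding assumes locally smooth conductivity
  at the mask edge; a mask whose border crosses a sharp σ interface will
  bias adjacent voxels.
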