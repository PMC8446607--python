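# Methods

## The model

`cinestrain` estimates left-ventricular myocardial deformation from
short-axis cine-MRI as a Lagrangian displacement field **u**ₜ defined on the
end-diastolic (ED) reference frame: for every ED voxel v, V₀(v) and
Vₜ(v + **u**ₜ(v)) image the same piece of tissue.  Finite-deformation strain
is the Green-Lagrange tensor

    E(t) = (∇u + ∇uᵀ + ∇uᵀ∇u) / 2,

which is exactly zero under rigid motion (the quadratic term cancels the
rotation contribution).  Radial and circumferential strain are the diagonal
components of E in a per-voxel cylindrical frame about the LV long axis
(taken as the grid z axis); global strain averages E over the ED myocardium
mask, regional strain over each of the 16 AHA segments.  Strain rate is the
time derivative of the millisecond-interpolated global curve.

Displacement fields are stored in voxel units of the grid they live on; the
conversion to physical mm (multiplication by the spacing dr) happens inside
the strain engine and the smoothness loss only.  Arrays are indexed
(x, y, z), x/y in-plane.

## Networks and losses

Three task networks share one U-shaped backbone of convolution, batch
normalisation, and PReLU with residual connections, kernels 3 × 3 × kz with
kz ∈ {1, 3}, and in-plane-only 2 × 2 max-pooling and linear upsampling
(linear rather than nearest-neighbour, so upsampled feature maps carry no
half-voxel phase shift; the slice direction is thick and variable, so it
is never pooled, and with the default kz = 1 no operation mixes slices at
all).

* Centering: workspace volume → single-channel heatmap, trained with MSE
  against a Gaussian (σ = 10 mm, peak 1) centred on the myocardium centre
  of mass.  The crop centre is the heatmap argmax (ties resolved to the
  lowest linear index).
* Segmentation: 2D per-slice → 4-channel softmax, trained with the
  multi-class Dice (MDC) loss by default (categorical cross-entropy is
  available as a switch).
* Motion: 2-channel frame pair → 3-channel field, trained with
  λᵢ·intensity + λₐ·anatomical + λₛ·smoothness and λ = (0.01, 0.5, 0.1).
  Training uses only the (ED, ED) and (ED, ES) pairs: the identity pair
  anchors the identity transform, the ED–ES pair the full contraction.

Loss conventions worth noting:

* MDC divides by K = 4 classes, so perfect agreement scores −1.  Warped
  masks are soft, and the Dice relaxation uses sums of products for
  intersections and sums of values for sizes; a class absent from both
  masks contributes 1 (no penalty for correctly absent tissue), implemented
  with a 1e-7 smoothing term.
* Cross-entropy probabilities are clipped at 1e-7.
* The smoothness (diffusion) term multiplies each directional voxel
  difference by the matching spacing entry before squaring, so through-plane
  gradients are weighted by the true anisotropy.  It is returned as a
  *mean* over voxels by default (a sum is available via `reduction="sum"`):
  the mean keeps λₛ = 0.1 interpretable across grid sizes.
* The warping operator is trilinear with clamp-to-edge sampling;
  its gradient with respect to the field is zero where a coordinate is
  clamped.  Trilinear interpolation reproduces affine images exactly, which
  the tests exploit as an oracle.

All of this runs on a small reverse-mode autodiff engine over numpy
(im2col convolutions via BLAS, fused batch-norm/PReLU primitives, analytic
warp gradients).  Networks default to float32; float64 is available for
gradient verification, and every loss gradient is checked against central
finite differences in the test suite.

## Training protocol

Adam with learning rate 1e-4, betas (0.9, 0.999), batch size 80 (5 for the
motion network), 300 epochs — these are the full-scale defaults in
`TrainConfig`.  A single master seed drives weight initialisation, data
order, and augmentation, and single-threaded runs reproduce loss
trajectories bit-exactly.  Augmentation (off by default at desk scale) is
strictly in-plane: rotation ±15°, translation ±10 voxels, x/y mirroring,
gamma contrast in [0.7, 1.4]; ground-truth displacement vectors are rotated
and sign-flipped consistently with the grid.

**Desk scale.**  The repository's tests and the acceptance script run
everything on one CPU, so they use reduced problem sizes chosen once:
phantoms on 64 × 64 × 8 grids at 1.25 × 1.25 × 8 mm with a proportionally
smaller heart (endo 12 mm, epi 18 mm), networks with base width 4 and
depth 3 (depth 2 for centering), 20 motion-training pairs from 10 phantoms
with 200 motion-training epochs in the test suite (100 in the acceptance
script), the segmentation network trained 50 epochs on the 160 ED/ES
slices, the centering network 300 epochs on 5 phantom volumes, and desk
learning rates of 3e-3 (1e-2 for centering).  The higher rates compensate
for the small number of optimisation steps (hundreds rather than the tens
of thousands of a full-scale run); the full-scale default remains 1e-4.
The anatomical-weight ablation is evaluated as a matched-epoch comparison
(both arms at 100 epochs; the ablated loss converges within a few epochs,
so longer training does not change its outcome).

## The phantom

The synthetic substrate is an annular LV myocardium (ED endocardial radius
r₀, epicardial r₁) around a bright blood pool, with an adjacent RV disk
fixing the septal direction.  A sin² activation s(t) (time-warped so its
peak lands at the end-systolic fraction of the cycle) drives

* endocardial contraction r_endo(t) = r₀(1 − a·s(t)) with peak fraction
  a = 0.2 by default;
* per-slice 2D incompressibility across the wall,
  r′² = r_endo(t)² + r² − r₀², giving closed-form strains
  E_cc = ((r′/r)² − 1)/2 and E_rr = ((r/r′)² − 1)/2 that satisfy
  (1 + 2E_rr)(1 + 2E_cc) = 1 exactly;
* a per-slice twist θ′ = θ + (twist/slice)·z·s(t), which adds only shear in
  the aligned cylindrical frame.

The incompressible form is extended a 4 mm margin past both wall surfaces
before blending into a linear cavity core and an exponentially decaying
far field, so the motion is smooth across the finite-difference stencil of
every myocardium voxel; the map stays monotone in radius and therefore
invertible, and frames are rendered as Vₜ(x) = V₀(φₜ⁻¹(x)) with exact
analytic label classification (no mask interpolation).  Intensities are
piecewise-constant tissue classes plus a smooth advected texture (std 0.1,
the trackable feature inside otherwise homogeneous tissue) and per-frame
Gaussian noise (sd 0.02).  An optional dark-stripe banding overlay exists
for robustness experiments and is off by default.

What the phantom does *not* emulate: MR physics (coils, k-space),
papillary muscles, through-plane motion, respiratory drift, and the
population variability of real cardiac shapes.  Passing the recovery tests
therefore demonstrates that the estimation machinery is correct and that
the loss design behaves as intended on idealised data — not clinical-grade
accuracy on patient images, which requires full-scale training on real
cine-MRI.

## Numerical choices

* Resampling: trilinear for intensities, nearest-neighbour for labels
  (never invents labels); the workspace is laid symmetrically around the
  input's physical centre.
* Crop padding: 0 for intensities, background for labels; the crop window
  records its inverse so outputs can be pasted back into the original
  geometry.
* Gradients: central differences, one-sided at array borders (both in the
  strain engine and the smoothness loss).
* Strain reference: u₀ is forced to zero so curves start at exactly 0;
  strain is averaged over the *ED* myocardium mask (the field lives on ED
  coordinates).
* Curve interpolation to 1 ms is linear; strain rate uses central
  differences on the millisecond grid, unit s⁻¹.
* ESS is the strain value at end-systole; SRs/SRe are the largest
  |strain rate| in the systolic/diastolic window, reported with the sign
  of the value at that peak (radial SRs positive, circumferential SRs
  negative for normal motion).
* End-systole, when not supplied, is the frame of minimum LV-cavity volume
  (ties → earliest frame).
* AHA map: 16 segments (no apical cap — no long-axis data); myocardial
  slices split into basal/mid/apical thirds along z with remainder slices
  assigned to basal then mid; angular sectors measured from the anterior RV
  insertion, taken as the septal (RV-centroid) direction rotated +90°;
  six 60° sectors on basal/mid rings, four 90° sectors apically.
* ICC is the single-rating absolute-agreement two-way form ICC(A,1) with
  the F-based 95 % confidence interval; Bland-Altman precision uses the
  n−1 denominator; LV mass uses the 1.05 g/mL myocardial density
  convention; the Hausdorff distance is the exact boundary-voxel maximum in
  mm (no percentile variant).
* Landmarks are deformed by sampling the field trilinearly at the
  landmark's slice; end-point error is in-plane by definition.

## Known limitations

* At desk resolution (wall ≈ 5 voxels, peak displacement ≈ 2 voxels) the
  soft Dice of trilinearly warped masks tolerates sub-voxel boundary
  misregistration, so desk-trained motion estimates underestimate strain
  magnitudes by a few strain points even though end-point error and the
  anatomical-weight ablation behave as designed; the acceptance script
  reports this bias explicitly.  The effect shrinks with resolution and is
  a property of the loss weighting, not of the strain engine (which matches
  the closed-form oracle to well under one strain point).
* Layer counts and filter widths of the backbone are configurable defaults,
  not a faithful reproduction of any published architecture at the layer
  level.
* The anatomical loss warps masks on the native grid; no finer through-plane
  resampling is applied before the loss.
* Longitudinal strain is out of scope (short-axis data only), as are
  principal-strain analysis and torsion reporting.
* Full DICOM handling covers spacing and trigger times only.
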