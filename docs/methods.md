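# Methods

`kvtrack` implements marker-less tracking of an abdominal (pancreatic)
target on orthogonal kilovoltage projection pairs, and quantifies the
dosimetric cost of the residual tracking error. Because real robotic-
radiotherapy image archives cannot be redistributed, every computation
runs against a synthetic digital phantom whose ground-truth motion is
known exactly; validation is parameter recovery, not comparison with a
clinical dataset.

## Imaging model

The two views are parallel-ray projections at ±45° from vertical in the
axial plane, with the image vertical axis along the patient
superior–inferior (SI) direction. A rigid target displacement
(x, y, z) — x toward patient left, y anterior, z superior — appears as

    x = R (I_A + I_B),   y = R (I_B − I_A),   z = −J_AB,   R = √2/2,

where `I_A`, `I_B` are the lateral (column) shifts of the two views and
`J_AB` the shared row shift. Rows increase toward inferior, which makes
`z = −J_AB` literal; this row-direction convention is a dialect choice
documented here because detectors could be mounted either way. Cone-beam
divergence and imager flex are not modelled: the back-projection
relation itself is a parallel-geometry statement, and all quantities are
referred to the target plane through the configurable pixel spacing
(default 1.0 mm at 320 px; the pipeline default is 2.5 mm at 128 px,
covering the same 320 mm field of view at reduced cost).

DRRs are attenuation-style line integrals `μ ∫ ρ dl` with
μ = 0.0171 mm⁻¹ (a water-equivalent value at 120 kV), sampled by
trilinear interpolation at one volume-voxel step along each ray.
Densities above 1.869 g cm⁻³ are reset to 1.0 before tracing, which is
how the reference DRRs hide metal fiducials. Simulated treatment images
skip the clipping (markers must appear so their removal can be
exercised), then apply a smooth multiplicative gain field (a random
quadratic, amplitude ±10% by default) and additive Gaussian noise.
Treatment images use the same attenuation-style polarity as the DRRs
rather than a transmitted exponential, so bright-marker removal by
intensity ranking remains meaningful.

## The phantom

A parametric abdomen on a 128³ grid at 2.5 mm (all dimensions
configurable): an elliptical water-equivalent body (semi-axes
140 × 95 mm), a static spine cylinder (r = 14 mm, ρ = 1.55), lung
(ρ = 0.28) above a paraboloid diaphragm dome, three bowel-gas pockets
(r = 10 mm, ρ = 0.05) ringing a 15 mm-radius target of ρ = 1.05, four
gold-surrogate fiducials (ρ = 8) inside the target, and stomach /
duodenum / bowel surrogate ellipsoids used only as dose structures. The
PTV is the target dilated by a 3–5 mm margin (default 5 mm).

Rigid motion moves a *soft-tissue block* — everything below the
diaphragm except the spine — by the full 3-vector displacement; the
diaphragm dome follows the SI component only; body outline and spine
stay fixed. Uniform tissue translates invisibly in projection, so the
block carries a smooth zero-mean density texture (Gaussian-filtered
noise, 10 mm correlation length, 0.07 g cm⁻³ amplitude) that is
resampled rigidly with the block. The texture is the phantom's stand-in
for real soft-tissue detail; its amplitude sets how well lateral motion
can be seen and was fixed once at a level giving projected contrast
clearly above the default image noise.

Respiration follows a cos⁴-shaped waveform (end-exhale dwell, period
4 s, pure cosine available), with per-patient half peak-to-peak
amplitudes drawn uniformly from 3–8 mm (left–right), 3–8 mm
(antero-posterior) and 6–12 mm (SI) — the mid-range of published
per-patient fiducial excursions for this site, capped so the diaphragm
stays on the grid. Per-fraction baselines are i.i.d. Gaussian with
σ = 5 mm per axis; image sample times are uniform over a 300 s fraction,
so respiratory phases are well covered. What the generator does *not*
emulate: organ deformation, bowel peristalsis and gas appearance /
disappearance, scatter and beam hardening, detector artefacts, and
day-to-day anatomy change beyond a small per-patient jitter of target
position (±5 mm) and body size (±5%). Passing tests therefore
demonstrate correctness of the algorithms under rigid-motion conditions,
not clinical performance.

## Preprocessing

1. **Bandpass sharpening** in the 2D DFT domain with radial gain
   `1 + g f` up to half the Nyquist bin and a mirrored ramp
   `1 + g (f_max − f)` above it, g = 0.02, f in bin-index units
   (f_max = n/2, peak gain 2.6 at n = 320). Frequency is measured in bin
   indices because in cycles/pixel the same gradient would leave the
   filter inert (peak gain 1.005). The descending branch is implemented
   continuously; the discontinuous variant `1 + g (f − f_max)`, which
   dips below unity, is available behind a flag as a diagnostic.
2. **Fiducial removal**: the brightest 0.5% of pixels of the central
   region (0.25–0.75 of each dimension; count = ⌈fraction × region
   pixels⌉, ties broken in raster order) and their 8-neighbourhoods are
   replaced by the mean of the four pixels 10 px away in the four
   cardinal directions (offsets clamped at the frame, means taken from
   the unmodified input).
3. **Equalisation**: 25th/75th percentiles of DRR and treatment image
   are taken in the four corner regions of a 5×5 partition, interpolated
   bilinearly between the corner-region centres (constant beyond them),
   and each DRR pixel is mapped by
   `(D − d_min)·s + t_min`, `s = (t_max − t_min)/(d_max − d_min)`.
   Percentiles interpolate linearly between order statistics. A corner
   region with zero DRR interquartile range raises an error naming the
   corner. With clamped extension, exact corner-quartile matching holds
   when the two images differ by smooth gain/offset fields; it cannot
   hold for images with unrelated strong spatial trends, and the
   property tests are built accordingly.

## Registration

Candidate shifts are scored by γ = NMS × NMI on the shifted overlap:

* NMS = 1 − MSD/N with N = [max(D_max − T_min, T_max − D_min)]², the
  largest mean square the block pair could produce, computed at the
  evaluated shift. Equal constant blocks score 1.
* NMI = (Ψ(D)+Ψ(T))/Ψ(M) from a 128-bin joint histogram (0·ln 0 := 0).
  Bin edges are fixed per region from the union intensity range at zero
  shift and held constant during that region's search, so the optimiser
  cannot move its own binning. A single-cell joint histogram (both
  blocks constant) is treated as a perfect match, NMI = 2.

Search stages, all exhaustive over integer shifts with deterministic
tie-breaking (highest γ, then smallest shift norm, then raster order):

1. whole-image coupled search, shared J_AB, independent I_A/I_B inside
   the J loop; passes ±20 px step 4, then ±2 px step 1;
2. per-image 2D refinement in a 5×5 grid of subregions (width
   ⌊2n/6⌋, 50% overlap, edge-clamped), passes ±10/2 then ±1/1, seeded at
   the whole-image optimum;
3. one coupled search on the PTV beam's-eye-view bounding box + 20 mm
   margin (taken at the target plane), subregion pass schedule.

Treatment pixels shifted outside the frame are excluded and the pixel
count reduced (no padding); candidates with no overlap score −∞. The
coupled score is γ_A + γ_B (the additive reading of the coupled
objective). Finest step is 1 px; no subpixel interpolation, so every
reported shift is quantised to the pixel grid. At the default 2.5 mm
pixels, noise-free recovery is within ~1 px per axis (up to 1.5 px
including the 0.5 px quantisation of a non-integer true shift).

The output per image pair is a 104-vector: per view, 25 grid (I, J)
pairs in raster order followed by the PTV pair (I_view, J_AB), converted
to mm. The motion model depends on this ordering.

## Motion model

Observations split into per-fraction means and residuals,
`v_mn = v_m + v′_mn`, `r_mn = r_m + r′_mn`, with means taken as
arithmetic averages over each fraction. Two affine maps are fitted by
SVD of the design matrix [V, 1] (intercept column of ones):
`x = V W⁻¹ Uᵀ b`, zeroing reciprocals of singular values below
`w_max/R`. The truncation convention follows standard regularised SVD:
small singular values carry negligible signal and are removed. (The
alternative literal reading — discarding the *largest* singular values —
contradicts the purpose of the regularisation and is available only as
a flag.) R = 1.2 for the inter-fraction model (aggressive: predicting
the daily baseline from images is genuinely hard, and a near-unity
cutoff keeps only the strongest mode), R = 7.0 for the intra-fraction
model. Columns are not standardised — all components are mm, so scales
are commensurate; the intra intercept is fitted although residual
centring makes it ≈ 0.

Scenarios evaluated under leave-one-patient-out cross validation
(models fitted on the other patients, both R values fixed):

* **no DVI**: `r̂_mn = f_inter(v_m) + f_intra(v_mn − v_m)` with v_m the
  test patient's own per-fraction image mean;
* **DVI**: `r̂_mn = r_m + f_intra(v_mn − v_m)` with the true fraction
  mean supplied, the idealisation of daily volumetric imaging.

Error tables report min / quartiles / median / max (linear-interpolation
quartiles) of per-axis absolute and 3D Euclidean errors; pooled rows
aggregate per-image errors across held-out patients rather than
averaging medians. The fitting-set table reuses the no-DVI path on the
training patients.

## Dosimetry

The synthetic plan is 60 beams from a golden-angle azimuthal sweep with
alternating ±15° elevation; each beam is a cylinder conformal to the
PTV with Gaussian lateral penumbra (σ = 4 mm) and shallow longitudinal
falloff (σ = 30 mm). The sum is normalised so D95%(PTV) equals the
35 Gy prescription. This is a geometric surrogate for a clinical dose
engine: the reproducible computation here is the *accumulation logic*,
not beam physics.

Residual errors (predicted − reference per image) perturb the dose by
rigid trilinear resampling of the grid (2 mm isotropic, zero fill; the
grid is a ±60 mm cube about the target so realistic shifts never drag
the fill value into a structure). Stochastic accumulation draws one
residual index per (repeat, fraction, beam) uniformly and independently,
shifts that beam's per-fraction dose (total/5) and sums; 10 repeats give
a DVH band. The expectation dose applies every residual to the whole
plan and averages — the infinite-repeat limit. D95% is the 5th
percentile of structure voxel doses; D0.5cc interpolates the sorted
cumulative-volume curve of the exact voxel list; DVH curves use 0.1 Gy
bins while D-metrics use the unbinned voxel list.

## Problem sizes and numerical choices

The default study is 4 patients × 3 fractions × 6 images at 128 px
(2.5 mm pixels), 60 beams, 10 repeats — the scale at which the whole
pipeline, including simulation and cross-validation, completes in a few
minutes on one core while leaving enough images per fraction for the
inter/intra decomposition to be meaningful. Larger runs at the full
imaging resolution (320 px, hundreds of images per patient) use the
same code paths via the configuration file. All randomness derives from a single master seed
through named SeedSequence streams (per patient, per image, per dose
scenario), so any run is bit-reproducible; derived seeds stay below
2³¹.

Known limitations: rigid motion only (no deformation), parallel-beam
rendering, a geometric dose surrogate, idealised DVI (the measured
fraction mean is exact), and 1 px shift quantisation that bounds
achievable tracking accuracy at coarse pixel spacings.
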