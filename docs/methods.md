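# Methods

This note records the model, the numerical choices, and the limits of the
bundled synthetic data. Everything quantitative stated here is computed by the
test suite (`tests/`) or the acceptance script (`scripts/acceptance.py`); the
note itself makes no empirical claims beyond those.

## Problem setting

MRI-only particle-therapy workflows need a CT-like Hounsfield-unit (HU) volume
— a synthetic CT (sCT) — because dose calculation for carbon-ion beams depends
on HU-derived stopping power. The package translates abdominal MRI into sCT
with a conditional GAN and evaluates the result at three levels: image
similarity, structure geometry, and dose (DVH metrics, equivalence testing,
gamma analysis, beam range shift).

## Data representation

Volumes are `(nz, ny, nx)` float arrays with spacing `(dz, dy, dx)` in mm and
an explicit background mask (`mrisct.volume.ImageVolume`), read and written as
NIfTI.

### Channel decomposition

A conditioned CT slice is decomposed into three channels by HU range:

| channel | HU interval |
|---|---|
| air | [−1000, −800) |
| soft tissue | [−800, 150) |
| bone | [150, 1047] |

The printed clinical ranges share their endpoints; to make mask-based
reassembly exact the partition is made half-open, assigning each boundary to
the upper class (−800 → soft, 150 → bone). Each channel is affinely scaled to
[−1, 1] over its own HU interval; pixels outside the channel mask are filled
with −1. The decomposition is exactly invertible on body voxels: composition
of `segment_channels → scale_channels → reassemble_slice` reproduces the
conditioned CT to ≤ 1e−3 HU (acceptance criterion 1; the observed error is at
the float64 rounding level).

MRI slices are decomposed through *CT-derived* tissue masks when a paired CT
exists (training and the `ct_masks` evaluation scenario) or through label-map
derived masks in the `mri_only` scenario; all three MRI channels share the
[0, in-body max] scaling interval.

## Preprocessing

- CT: resample onto the MRI grid (linear interpolation), clip to
  [−1000, +1047] HU, force background to −1000 HU.
- MRI: N4 bias-field correction (SimpleITK), per-slice bilateral denoising,
  99th-percentile intensity clipping over body voxels, background forced to 0,
  and optional histogram matching to a reference volume (the first training
  volume in the pipeline).
- Network input: per-slice triplets resized to the network size (linear for
  intensities, nearest for masks).

### Augmentation

Eight transforms per training pair — horizontal flip, vertical flip, Gaussian
noise (MRI only, SD 2 % of the [−1, 1] dynamic range), shear 8°, rotation
±10°, central crop to 90 % with resize back, flip+noise, rotation+crop.
Geometric transforms are applied identically to the MRI and CT triplets of a
pair. The expansion is exactly 8×: 2014 slice pairs become 16 112 (acceptance
criterion 7).

## Model

Pix2Pix-style conditional GAN, batch size 1:

- **Generator**: U-net on 3-channel inputs/outputs. At the clinical size
  (256×256) it has 8 encoder and 7 decoder blocks (depth = log2(size)); the
  tiny CPU configuration uses 64×64 with a quarter of the filters. Encoder
  blocks are stride-2 4×4 convolutions with leaky ReLU (0.2) and per-channel
  normalization (batch normalization at batch 1, i.e. instance statistics);
  decoder blocks are stride-2 transposed convolutions with ReLU, skip
  concatenation, and dropout 0.5 in the first three blocks. Output is tanh.
  Dropout stays active at inference, acting as the noise source z.
- **Discriminator**: PatchGAN over the concatenated (MRI, candidate CT)
  6-channel stack — three stride-2 blocks, one stride-1 block, and a final
  1-channel convolution, giving a 70×70-pixel receptive field (30×30 logit map
  at 256; the tiny configuration uses two stride-2 blocks, receptive field
  34).
- **Losses**: `L_tot = L_cGAN + λ·L1` with λ = 100. `L_cGAN` is the
  non-saturating adversarial cross-entropy on patch logits; `L1` is the mean
  absolute HU difference between *reassembled* slices, so the generator is
  penalized in HU units after channel merging. The logged decomposition is
  exact at every step (acceptance criterion 5).
- **Optimization**: Adam with β₁ = 0.5, β₂ = 0.999; discriminator learning
  rate 2e−7, generator 2e−4; 20 epochs; one discriminator and one generator
  step per slice pair in a seeded shuffled order.

The networks are implemented in numpy (forward and analytic backward passes
for convolution, transposed convolution, instance normalization, dropout and
the composite U-net/PatchGAN graphs), verified against centred finite
differences in `tests/test_nn.py`. Training and inference are single-threaded
deterministic given the master seed.

## Synthetic phantom

An analytic abdominal phantom supplies co-registered CT/MRI/label triples:
a soft-tissue body cylinder containing a vertebra, two ribs, two kidneys, two
air pockets (stomach, colon) and a tumor, each an ellipsoid or cylinder with
organ-specific HU/MRI mean and standard deviation. The MRI gets a smooth
multiplicative polynomial bias field. Organ centers can be jittered per
subject (with deterministic retries so organs never overlap). Inter-
acquisition mismatch — mobile air pockets — is emulated by displacing or
rescaling one labelled structure on the MRI side (`apply_mismatch`).

Realism limits: the phantom has piecewise-constant tissue statistics, no
partial-volume effect at boundaries beyond grid rasterization, no motion
artifacts, a polynomial rather than coil-physics bias field, and exact
CT–MRI registration. It exists to exercise every pipeline contract, not to
imitate patient anatomy; the phantom defaults are study conditions and were
not tuned to any evaluation outcome.

## Toy dose engine

Axis-aligned pencil-like carbon beam: HU → relative stopping power via a
piecewise-linear lookup (−1000 → 0.001, 0 → 1.0, 1047 → 1.6); cumulative
water-equivalent path length (WEPL) to each voxel center along its grid
column; an analytic Bragg-like depth-dose (plateau 0.3 with a broad proximal
Gaussian shoulder, σ 7 mm, and a sharp distal Gaussian falloff, σ 1.5 mm);
lateral Gaussian profile, σ 9 mm. Dose is prescription × depth-dose ×
lateral factor, with no renormalization, so upstream HU perturbations move
the distal falloff by exactly the WEPL change — the property the range-shift
analysis measures (acceptance criterion 4).

## Evaluation

- **Similarity** (per region: body, air, bone, soft): MAE, RMSE, Pearson
  correlation, PSNR and SSIM over a 2047-HU data range; SSIM uses 11×11
  Gaussian windows (σ 1.5) whose centers are restricted to the region mask.
- **Geometry**: Dice coefficient, symmetric 95th-percentile Hausdorff
  distance (6-connectivity surfaces, distance transform with physical
  spacing), and centroid distance, all in mm.
- **DVH**: cumulative histogram by sort-and-count; D_x by inverse linear
  interpolation of the curve (100 voxels dosed 1..100 give D2 = 99 exactly).
- **TOST-P**: two one-sided paired t-tests at α = 0.05 with margin ±0.5 % of
  the prescription dose; zero-variance differences degrade to an exact
  comparison against the margin.
- **Gamma** (global): dose tolerance as % of prescription, voxels below the
  reference-dose threshold excluded, minimization over a sphere of radius
  3×DTA. Default sub-voxel search uses a DTA/10 lattice with trilinear
  interpolation; `subvoxel=False` restricts to whole-voxel displacements,
  the definition shared with the brute-force oracle (acceptance criteria 2
  and 3). Offsets are visited in increasing distance with early termination
  once no voxel's gamma can improve.
- **Range shift**: distal R80 (80 % of each profile's own peak, linearly
  interpolated) on beam-parallel profiles at 10 transversal slices through
  the target's axial extent; RS = R80(sCT) − R80(CT), RRS = RS/R80(CT),
  |RS| > 5 mm flagged. Profiles without a distal crossing are excluded from
  the median/IQR summary.

## Numerical and reproducibility choices

- All randomness flows from one master seed through `numpy.random.SeedSequence`
  child seeds; network math is float32, metrics float64.
- Report CSVs are written with `%.10g` formatting and contain no timestamps
  (timing goes to a separate run log), so a repeated run is byte-identical
  (acceptance criterion 8).
- Cross-validation folds keep multiple acquisitions of one subject in the
  same fold (greedy balanced assignment after a seeded shuffle).

## Limitations

- The GAN runs at desk scale (tiny configuration, small phantom datasets);
  quantitative results on the synthetic phantom say nothing about clinical
  image quality.
- The dose engine is a 1D-WEPL toy: no scattering, no heterogeneity-driven
  lateral effects, no fragmentation tail, single axis-aligned beam.
- The phantom's manual-segmentation surrogate is its own label map, so the
  `mri_only` scenario's mask quality is idealized.
- N4 and bilateral filtering operate with fixed, small iteration counts
  chosen for CPU runtime, not for optimal MRI restoration.
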