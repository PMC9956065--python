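# Methods

## Model

The registration model is a symmetric 3D U-Net that maps the
channel-concatenated (fixed, moving) volume to a three-channel dense
displacement field in the backward (pull) convention: the field gives,
for every voxel of the fixed grid, the offset at which the moving image
is sampled.  Contraction blocks are a 3×3×3 convolution + LeakyReLU
(slope 0.2) followed by stride-2 max pooling; the deepest block is the
bottleneck and is not pooled, so an encoder of B blocks needs input
dimensions divisible by 2^(B−1) (32 for the default six blocks of
32–1024 filters, which a 128³ input satisfies).  The decoder mirrors
the encoder with nearest-neighbour upsampling and skip connections by
channel concatenation; a head of two 16-filter convolutions precedes
the 3-filter output convolution.  The output convolution is
zero-initialised so the untrained model predicts the identity field —
early training then starts from the unregistered state instead of a
random warp.

All tensor operations run on `voxreg.autodiff`, a compact reverse-mode
automatic-differentiation engine over NumPy float64 arrays.  It
implements exactly the operators the model needs (convolution, pooling,
upsampling, windowed box sums, differentiable trilinear warping,
softmax, elementwise algebra) and every operator's gradient is checked
against central differences in the test-suite.  Warping clamps
out-of-bounds sample positions to the volume edge; the gradient with
respect to the field vanishes where a position is clamped.

## Synthetic pair generation

Training pairs are manufactured on the fly, in memory.  A rigid motion
is sampled first — per-axis rotation uniform in ±10°, translation
direction uniform on the sphere with magnitude uniform in [0, 30] mm —
and converted to a dense backward field about the volume centre
(rotation composed as R₀R₁R₂ about the array axes, translation
converted mm→voxels per axis).  A non-rigid component is drawn as
per-axis-uniform control displacements on a regular 8×8×8 lattice
spanning the full extent (vector norms clipped to the 6 mm cap),
interpolated by a 3D thin-plate spline with kernel U(r) = r plus an
affine part — the triharmonic-consistent choice in three dimensions.
Because the spline can overshoot between control points, the dense
field is globally rescaled whenever its maximum voxelwise magnitude
exceeds the cap, so the printed bound holds exactly.  The two fields
are composed (rigid applied first) into a single map; the moving image
is the warped fixed image with gamma (exponent uniform in [0.5, 2])
then brightness (uniform ±20 % of the unit range) augmentation applied
to the moving side only, clipped back to [0, 1]; labels follow by
nearest-neighbour sampling, so no new labels can appear.  The generator
performs no disk writes.

For experiments on small volumes the package ships a reduced preset
(`desk_augmentation`): 3 mm translation, 4° rotation, 2 mm non-rigid
displacement on a 4³ grid, and mild intensity jitter (gamma 0.9–1.1,
±5 % brightness).  These values scale the full-size caps to a 32³
field of view so that the sampled motion remains mostly within the
volume; they are a deliberate scaled-down analogue, not a tuning knob —
the full-scale caps remain the `AugmentationConfig` defaults.

## Phantoms

The phantom generator supplies study material where real scans are
unavailable: a low-frequency background, n ellipsoidal "organs" of
distinct intensity with non-overlapping centres, and one sinusoidally
curved tube, with matching labels 1..n+1 over background 0, intensities
in [0, 1], reproducible under a seed.  Phantoms emulate the structural
properties the method relies on — smooth intensity, multiple labelled
structures, organ-scale geometry — but not CT/MR noise statistics,
intensity inhomogeneity, partial-volume effects or anatomical
variability.  Passing tests on phantoms therefore demonstrate the
mechanics of the pipeline (caps, losses, optimisation, recovery of
synthetic motion), not clinical-grade accuracy on real data.

## Losses and adaptive weighting

- **Local NCC** (training): 1 − mean of squared windowed correlation
  over 9³ windows, averaged over voxels whose window lies fully inside
  the volume; valid-window averaging keeps the loss exactly zero for
  identical inputs and exactly invariant under affine intensity maps.
  The variance product is floored at 1e-9 to guard constant windows.
  The evaluation metric is the global zero-mean NCC over all voxels.
- **SSIM**: standard luminance/contrast/structure form over uniform 7³
  windows (k₁ = 0.01, k₂ = 0.03, unit data range), averaged over
  interior windows; loss form 1 − SSIM.
- **Soft Dice**: 1 − mean over foreground classes of
  (2Σpq + ε)/(Σp + Σq + ε), ε = 1e-5, on warped one-hot probabilities
  against the fixed one-hot truth; background excluded.
- **Hausdorff surrogate**: mean over foreground classes of
  Σ[(p−q)²(d_q² + d_p²)] / (Σ(p−q)² + ε), with d the Euclidean distance
  transforms of the binarised truth and prediction; the distance maps
  are treated as constants so gradients flow through the disagreement
  term.  Empty truth classes are skipped with a warning.
- **Regulariser**: diffusion penalty — mean over the nine
  (component, axis) pairs of the mean squared forward difference of the
  field; zero for constant (pure-translation) fields.

The combination layer holds the loss weights ω as a softmax over free
logits, so ω ≥ 0 and Σω = 1 at every read by construction, with the
uniform initialisation at zero logits.  The regulariser weight is a
positive free parameter exp(ρ) initialised to 5e-3.  A sum-to-one
constraint on a single regulariser weight would pin it to 1 and
contradict that initial value, so λ is deliberately left unnormalised.
In the UW variants both parameter vectors are appended to the optimiser
and learn by backpropagation; their per-epoch trajectories are logged
in the training history so weight-evolution curves can be plotted.
The validation loss used for scheduling and checkpointing reads the
current (not initial) weights.

## Training

Batch size is one, with gradients accumulated over `accum_steps`
(default 8) generated pairs and averaged before each Adam update
(β = 0.9/0.999), so the learning-rate semantics match a true batch of
that size.  The learning rate starts at 1e-3 and is divided by 10
whenever the validation loss fails to improve by a relative 1e-4 for
`patience` (default 10) consecutive epochs; the improvement threshold
is a package choice, as is regenerating the validation pairs once per
run from a fixed seed and reusing them across epochs.  The parameters
with the lowest validation loss are returned.  A non-finite loss
aborts with a diagnostic dump rather than silently continuing.
Transfer learning runs at 1e-4, either over all parameters (`direct`)
or in two stages (`two_step`): decoder and head with the encoder
frozen, then the full model; histories carry a stage tag.

## Evaluation

Metrics are computed per pre-generated pair so the identical pair set
can be reused across model variants: global NCC, interior-window SSIM,
hard Dice (mean over classes present in either volume, a class missing
from one side scoring 0), symmetric surface-distance HD and HD95 in mm
(6-connectivity boundary voxels, both directions pooled, per-class
values averaged with equal weight), and centroid TRE in mm over classes
present in both volumes.  Inference timing covers field prediction and
warping only.  Displacement fields can be resampled to a different
grid by piecewise-linear interpolation with per-axis unit rescaling
(old_spacing/new_spacing) before metrics are taken; since resizing a
volume changes its effective spacing, all mm-denominated metrics use
the post-resize spacing recorded on the volume.  The Mann-Whitney U
test uses midranks, an exact enumeration for samples of at most 8
apiece, and otherwise the normal approximation with tie and continuity
corrections; Benjamini-Hochberg is the standard step-up rule, monotone
and clipped at 1.  Plain displacement fields are not guaranteed
invertible; a Jacobian-determinant sign count is available as a
diagnostic only.

## Problem sizes

The shipped experiments are sized for a single CPU: gradient checks on
4³ tensors, oracle comparisons on ≤12³ grids, CLI smoke runs on 16³
phantoms, and the registration-recovery experiment on 32³ phantoms with
an (8, 16, 32)-filter network, 250 accumulated updates (500 generated
pairs) and 20 held-out evaluation pairs.  The full-scale protocol —
128³ volumes, the 32–1024-filter encoder, up to 1e5 epochs — is
expressible with the same configuration objects but is not exercised by
the tests.

## Known limitations

No diffeomorphism guarantee (no velocity-field integration or
inverse-consistency), mono-modal losses only (no mutual information),
no orientation-matrix handling (array axes map to physical axes through
spacing alone), no DICOM ingestion, and float64-only computation sized
for desk-scale problems rather than GPU throughput.
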