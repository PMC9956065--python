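# voxreg

Weakly-supervised deformable 3D image registration with on-the-fly
synthetic training-pair generation and adaptive multi-term loss
weighting.

`voxreg` is aimed at medical-image registration research where paired,
annotated training data is scarce (e.g. abdominal CT or brain MR): it
trains a displacement-predicting 3D U-Net entirely from *fixed* images
with segmentations, manufacturing the *moving* counterparts during
training by sampling rigid and thin-plate-spline (TPS) deformations
with configurable, clinically motivated magnitude caps.  Nothing is
written to disk during augmentation.

## Method

Given a fixed image $I_f$ and a generated moving image $I_m$, the
network predicts a dense backward displacement field $\Phi$
(three channels, voxel units); the predicted image is the spatial
re-sampling $I_p(x) = I_m(x + \Phi(x))$ by trilinear interpolation, and
moving segmentations $S_m$ are warped with the same field.  Training is
weakly supervised: the field itself is never scored, only the warped
results, by the combined objective

$$\mathcal{L}(y_t, y_p) = \sum_{i=1}^{N} \omega_i L_i(y_t, y_p)
  + \sum_{j=1}^{M} \lambda_j R_j ,$$

where the $L_i$ are drawn from {local NCC, SSIM, soft Dice, a
distance-transform Hausdorff surrogate}, $R$ is a diffusion (squared
spatial gradient) penalty on $\Phi$, $\sum_i \omega_i = 1$ by
construction, and $\lambda$ is initialised to $5\times10^{-3}$.  In the
uncertainty-weighting (UW) variants the $\omega_i$ and $\lambda_j$ are
trainable parameters updated by backpropagation alongside the network.
Six loss designs form the ablation matrix: `bl-n`, `bl-ns` (intensity
baselines), `sg-nd`, `sg-nsd` (segmentation-guided), `uw-nsd`,
`uw-nsdh` (uncertainty-weighted).

The synthetic-pair generator composes a rigid motion (rotation ≤ 10°
per axis, translation ≤ 30 mm) with a TPS field on an 8×8×8 control
grid whose voxelwise magnitude is capped at 6 mm exactly, then applies
gamma (0.5–2) and ±20 % brightness augmentation to the moving image.
Registration quality is evaluated with global NCC, SSIM, Dice,
Hausdorff distance (HD and HD95, mm) and a centroid-based target
registration error (TRE, mm); variant contrasts use one-sided
Mann-Whitney U tests with Benjamini-Hochberg correction.

The network, losses and training loop run on a small NumPy
reverse-mode autodiff engine (`voxreg.autodiff`) whose operators are
verified against numerical gradients in the test-suite.

## Worked example

Train the segmentation-guided variant on generated 32³ phantoms and
compare registered against unregistered metrics on 20 held-out pairs
(≈4 minutes on one CPU):

```python
import numpy as np
import voxreg as vr
from voxreg.evaluation import evaluate_pairs
from voxreg.losses import make_variant
from voxreg.synthesis import desk_augmentation, generate_phantom, make_eval_pairs
from voxreg.training import TrainConfig, train

rng = np.random.default_rng(100)
train_ds = [generate_phantom((32, 32, 32), 3, rng) for _ in range(4)]
held_ds = [generate_phantom((32, 32, 32), 3, np.random.default_rng(200))
           for _ in range(4)]

aug = desk_augmentation(0)                    # reduced caps for 32^3 volumes
net = vr.build_model(vr.UNetConfig(encoder_filters=(8, 16, 32), seed=0))
cfg = TrainConfig(lr=1e-3, accum_steps=2, steps_per_epoch=50, max_epochs=5,
                  n_val_pairs=4, seed=0)
best, history = train(net, train_ds, cfg, make_variant("sg-nd"), aug)
net.load_state_dict(best["net_state"])

pairs = make_eval_pairs(held_ds, aug, 20, seed=300)
unreg = evaluate_pairs(None, pairs)
reg = evaluate_pairs(net, pairs)
print(f"median TRE: {unreg.tre_mm.median():.2f} -> {reg.tre_mm.median():.2f} mm")
print(f"median DSC: {unreg.dsc.median():.2f} -> {reg.dsc.median():.2f}")
```

Output:

```
median TRE: 1.86 -> 0.95 mm
median DSC: 0.57 -> 0.76
```

The median centroid error of the held-out pairs roughly halves after
250 optimiser updates, and the segmentation overlap improves
accordingly — the desk-scale analogue of the registered-versus-
unregistered contrast the method is designed to win.

The same workflow is available from the shell:

```bash
voxreg phantom data/ --n 4 --size 32 --seed 0
voxreg train --data data/ --variant sg-nd --out model.npz
voxreg pairs --data data/ --out-dir pairs/ --n 20 --seed 3
voxreg evaluate --model model.npz --pairs pairs/ --out report.csv
voxreg register fixed.nii.gz moving.nii.gz --checkpoint model.npz --out-dir out/
```

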