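"""Training losses, the smoothness regulariser, and the adaptively
weighted multi-term combination layer.

The combined training objective is a weighted sum of N similarity losses
and M regularisers,

    L_total = sum_i omega_i * L_i  +  sum_j lambda_j * R_j,

where the omega_i are normalised (sum to one at every read) and, in the
uncertainty-weighting variants, both omega and lambda are trainable
parameters updated by backpropagation alongside the network weights.
The regulariser weight is initialised to 5e-3.

All loss functions accept either ``autodiff.Tensor`` (differentiable,
used in training) or plain arrays / :class:`~voxreg.volumes.Volume`
(returns a Tensor whose ``.item()`` is the value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .volumes import DisplacementField, Volume

EPS_CORR = 1e-9   # correlation denominators
EPS_DICE = 1e-5   # Dice smoothing


def _coerce(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, Volume):
        return Tensor(x.data)
    return Tensor(np.asarray(x, dtype=np.float64))


# -- intensity losses ----------------------------------------------------

def local_ncc_loss(a, b, window: int = 9) -> Tensor:
    """Local (windowed) squared normalised cross-correlation loss.

    1 - mean of cc^2 where cc is the correlation of the two images inside
    a centred ``window``^3 box, averaged over voxels whose window lies
    fully inside the volume (valid windows only, so no padding enters the
    statistics).  Zero for identical non-constant inputs and invariant
    under affine intensity maps b = s*a + t with s != 0.
    """
    a, b = _coerce(a), _coerce(b)
    if a.shape != b.shape:
        raise ValueError("inputs must share a shape")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if any(s < window for s in a.shape):
        raise ValueError(f"volume {a.shape} smaller than NCC window {window}")
    n = float(window**3)
    sa = ad.box_sum(a, window)
    sb = ad.box_sum(b, window)
    saa = ad.box_sum(a * a, window)
    sbb = ad.box_sum(b * b, window)
    sab = ad.box_sum(a * b, window)
    cross = sab - sa * sb * (1.0 / n)
    va = saa - sa * sa * (1.0 / n)
    vb = sbb - sb * sb * (1.0 / n)
    cc = cross * cross / ad.maximum_const(va * vb, EPS_CORR)
    m = window // 2
    interior = cc[m:cc.shape[0] - m, m:cc.shape[1] - m, m:cc.shape[2] - m]
    return 1.0 - ad.tmean(interior)


def global_ncc(a, b) -> float:
    """Whole-volume zero-mean normalised cross-correlation in [-1, 1]."""
    x = (a.data if isinstance(a, Volume) else np.asarray(a)).ravel().astype(np.float64)
    y = (b.data if isinstance(b, Volume) else np.asarray(b)).ravel().astype(np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must share a shape")
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("global NCC is undefined for a constant input")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def ssim3d(a, b, window: int = 7, k1: float = 0.01, k2: float = 0.03,
           data_range: float = 1.0) -> Tensor:
    """Mean structural similarity over interior windows of a 3D pair.

    The standard luminance/contrast/structure form with a uniform
    ``window``^3 box; the SSIM map is averaged over voxels whose window
    lies fully inside the volume.  Returns the similarity value; the
    training loss is ``1 - ssim3d(...)``.
    """
    a, b = _coerce(a), _coerce(b)
    if a.shape != b.shape:
        raise ValueError("inputs must share a shape")
    if any(s < window for s in a.shape):
        raise ValueError(f"volume {a.shape} smaller than SSIM window {window}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    n = float(window**3)
    mu_a = ad.box_sum(a, window) * (1.0 / n)
    mu_b = ad.box_sum(b, window) * (1.0 / n)
    var_a = ad.box_sum(a * a, window) * (1.0 / n) - mu_a * mu_a
    var_b = ad.box_sum(b * b, window) * (1.0 / n) - mu_b * mu_b
    cov = ad.box_sum(a * b, window) * (1.0 / n) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    ssim_map = num / den
    m = window // 2
    interior = ssim_map[m:ssim_map.shape[0] - m,
                        m:ssim_map.shape[1] - m,
                        m:ssim_map.shape[2] - m]
    return ad.tmean(interior)


def ssim_loss(a, b, window: int = 7) -> Tensor:
    return 1.0 - ssim3d(a, b, window=window)


# -- segmentation losses -------------------------------------------------

def soft_dice_loss(pred, truth, exclude_background: bool = True) -> Tensor:
    """1 - mean soft Dice over (foreground) classes.

    ``pred`` are per-class probability grids, ``truth`` one-hot grids,
    both shaped (C, D, H, W).  Per class: (2*sum(pq) + eps) /
    (sum(p) + sum(q) + eps) with eps = 1e-5.
    """
    pred, truth = _coerce(pred), _coerce(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a (C, D, H, W) shape")
    start = 1 if exclude_background else 0
    if pred.shape[0] <= start:
        raise ValueError("no foreground classes to score")
    p = pred[start:]
    q = truth[start:]
    inter = ad.tsum(p * q, axis=(1, 2, 3))
    sizes = ad.tsum(p, axis=(1, 2, 3)) + ad.tsum(q, axis=(1, 2, 3))
    dice = (2.0 * inter + EPS_DICE) / (sizes + EPS_DICE)
    return 1.0 - ad.tmean(dice)


def hd_surrogate_loss(pred, truth, exclude_background: bool = True) -> Tensor:
    """Distance-transform surrogate for the Hausdorff distance.

    Per foreground class: sum((p - q)^2 * (d_q^2 + d_p^2)) /
    (sum((p - q)^2) + eps), where d_q and d_p are Euclidean distance
    transforms to the binarised truth and prediction masks.  The distance
    maps are treated as constants, so gradients flow through the
    disagreement term only.  Empty truth classes are skipped with a
    warning.
    """
    pred, truth = _coerce(pred), _coerce(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a (C, D, H, W) shape")
    start = 1 if exclude_background else 0
    terms = []
    for c in range(start, pred.shape[0]):
        qb = truth.data[c] > 0.5
        if not qb.any():
            warnings.warn(f"class {c}: empty truth mask, skipped in HD surrogate")
            continue
        pb = pred.data[c] > 0.5
        dq = ndimage.distance_transform_edt(~qb)
        dp = ndimage.distance_transform_edt(~pb) if pb.any() else np.zeros_like(dq)
        w = Tensor(dq**2 + dp**2)
        diff2 = ad.square(pred[c] - truth[c])
        terms.append(ad.tsum(diff2 * w) / (ad.tsum(diff2) + EPS_DICE))
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def smoothness_reg(fld) -> Tensor:
    """Diffusion penalty on a displacement field (3, D, H, W).

    Mean over the nine (component, axis) combinations of the mean squared
    forward difference; zero for any constant field.
    """
    if isinstance(fld, Tensor):
        x = fld
    elif isinstance(fld, DisplacementField):
        x = Tensor(fld.data)
    else:
        x = Tensor(np.asarray(fld, dtype=np.float64))
    if x.ndim != 4 or x.shape[0] != 3:
        raise ValueError("expected a (3, D, H, W) field")
    terms = []
    for axis in range(1, 4):
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        diff = x[tuple(sl_hi)] - x[tuple(sl_lo)]
        terms.append(ad.tmean(ad.square(diff)))
    total = terms[0] + terms[1] + terms[2]
    return total * (1.0 / 3.0)


# -- adaptive combination layer -----------------------------------------

class AdaptiveLossWeights:
    """Trainable weights of the multi-term objective.

    omega is produced from unconstrained logits through a softmax, so it
    is non-negative and sums to one at every read, by construction.
    lambda is a positive free parameter (exp of a log-parameter),
    initialised to 5e-3; it is not normalised (with a single regulariser
    a sum-to-one constraint would pin it to 1, contradicting the
    initial value).
    """

    def __init__(self, loss_names, reg_names=("smooth",), trainable: bool = False,
                 init_omega=None, init_lambda: float = 5e-3):
        self.loss_names = list(loss_names)
        self.reg_names = list(reg_names)
        self.trainable = bool(trainable)
        n = len(self.loss_names)
        if init_omega is None:
            logits = np.zeros(n)
        else:
            w = np.asarray(init_omega, dtype=np.float64)
            if w.shape != (n,) or np.any(w <= 0):
                raise ValueError("init_omega must be positive with one entry per loss")
            logits = np.log(w / w.sum())
        if init_lambda <= 0:
            raise ValueError("init_lambda must be positive")
        self.logits = Tensor(logits, requires_grad=self.trainable)
        self.log_lambda = Tensor(
            np.full(len(self.reg_names), np.log(init_lambda)), requires_grad=self.trainable
        )

    @property
    def omega(self) -> np.ndarray:
        z = self.logits.data - self.logits.data.max()
        e = np.exp(z)
        return e / e.sum()

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.log_lambda.data)

    def parameters(self) -> list[Tensor]:
        return [self.logits, self.log_lambda] if self.trainable else []

    def state_dict(self) -> dict:
        return {
            "loss_names": list(self.loss_names),
            "reg_names": list(self.reg_names),
            "trainable": self.trainable,
            "logits": self.logits.data.copy(),
            "log_lambda": self.log_lambda.data.copy(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.logits.data = np.array(state["logits"], dtype=np.float64)
        self.log_lambda.data = np.array(state["log_lambda"], dtype=np.float64)

    def combine(self, losses, regs) -> "LossBundle":
        """Weighted total; gradients flow into the weight parameters when
        the layer is trainable."""
        if len(losses) != len(self.loss_names):
            raise ValueError(
                f"expected {len(self.loss_names)} losses, got {len(losses)}"
            )
        if len(regs) != len(self.reg_names):
            raise ValueError(f"expected {len(self.reg_names)} regularisers, got {len(regs)}")
        losses = [_coerce(l) for l in losses]
        regs = [_coerce(r) for r in regs]
        w = ad.softmax(self.logits)
        lam = ad.exp(self.log_lambda)
        total = ad.tsum(w * ad.stack(losses)) + ad.tsum(lam * ad.stack(regs))
        return LossBundle(
            loss_values={n: float(l.data) for n, l in zip(self.loss_names, losses)},
            reg_values={n: float(r.data) for n, r in zip(self.reg_names, regs)},
            omega=self.omega.copy(),
            lam=self.lam.copy(),
            total=total,
        )


@dataclass
class LossBundle:
    """Per-term scalar values plus the combined total (a Tensor)."""

    loss_values: dict[str, float]
    reg_values: dict[str, float]
    omega: np.ndarray
    lam: np.ndarray
    total: Tensor

    def check(self, tol: float = 1e-6) -> None:
        expect = float(
            np.dot(self.omega, list(self.loss_values.values()))
            + np.dot(self.lam, list(self.reg_values.values()))
        )
        if abs(expect - float(self.total.data)) > tol:
            raise AssertionError("total does not match the weighted sum of its parts")


# -- design-matrix variants ---------------------------------------------

#: The six loss-design variants of the ablation study: intensity-only
#: baselines (BL), segmentation-guided (SG) and uncertainty-weighted (UW).
VARIANTS: dict[str, tuple[tuple[str, ...], bool]] = {
    "bl-n": (("ncc",), False),
    "bl-ns": (("ncc", "ssim"), False),
    "sg-nd": (("ncc", "dice"), False),
    "sg-nsd": (("ncc", "ssim", "dice"), False),
    "uw-nsd": (("ncc", "ssim", "dice"), True),
    "uw-nsdh": (("ncc", "ssim", "dice", "hd"), True),
}


@dataclass
class LossVariant:
    """A named loss design: which terms are active and whether the
    combination weights are trainable."""

    name: str
    loss_names: tuple[str, ...]
    weights: AdaptiveLossWeights
    ncc_window: int = 9
    ssim_window: int = 7

    @property
    def uses_labels(self) -> bool:
        return any(n in ("dice", "hd") for n in self.loss_names)

    def compute_losses(self, fixed: Tensor, warped: Tensor,
                       truth_onehot: Tensor | None = None,
                       warped_onehot: Tensor | None = None) -> list[Tensor]:
        """Evaluate the active loss terms in declaration order."""
        out = []
        for name in self.loss_names:
            if name == "ncc":
                out.append(local_ncc_loss(fixed, warped, window=self.ncc_window))
            elif name == "ssim":
                out.append(ssim_loss(fixed, warped, window=self.ssim_window))
            elif name == "dice":
                out.append(soft_dice_loss(warped_onehot, truth_onehot))
            elif name == "hd":
                out.append(hd_surrogate_loss(warped_onehot, truth_onehot))
            else:
                raise ValueError(f"unknown loss term {name!r}")
        return out


def make_variant(name: str, init_lambda: float = 5e-3, *,
                 ncc_window: int = 9, ssim_window: int = 7) -> LossVariant:
    """Build one of the six design-matrix loss variants by name."""
    key = name.lower()
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    loss_names, trainable = VARIANTS[key]
    weights = AdaptiveLossWeights(loss_names, trainable=trainable, init_lambda=init_lambda)
    return LossVariant(key, loss_names, weights,
                       ncc_window=ncc_window, ssim_window=ssim_window)
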