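"""Weakly-supervised training loop and transfer-learning schedules.

Training never sees a ground-truth displacement field: each step draws a
synthetic moving image from a fixed image on the fly, predicts a field,
warps the moving image (and, for segmentation-guided variants, its
one-hot labels) back, and scores only the warped results against the
fixed image and labels.  Gradients are accumulated over several
mini-batches (batch size one) and averaged before each Adam update, so
the learning-rate semantics match a true batch of that size.  The
learning rate starts at 1e-3 and is divided by 10 whenever the
validation loss plateaus (no relative improvement > 1e-4 for `patience`
epochs); the parameters with the lowest validation loss are kept.

Transfer learning runs at 1e-4, either finetuning the whole model
directly or in two steps: decoder-only with a frozen encoder, then the
full model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .losses import LossVariant, make_variant, smoothness_reg
from .network import RegistrationNetwork, UNetConfig, build_model
from .synthesis import AugmentationConfig, generate_pair
from .volumes import LabelVolume, Volume, one_hot


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters.

    lr: initial learning rate; finetune_lr is used by transfer learning.
    accum_steps: mini-batch gradients averaged per optimiser update.
    plateau_factor/patience: learning-rate schedule on validation loss.
    max_epochs caps the run (the full-scale protocol allows up to 1e5;
    desk-scale runs use far fewer).
    """

    lr: float = 1e-3
    accum_steps: int = 8
    batch: int = 1
    plateau_factor: float = 10.0
    patience: int = 10
    max_epochs: int = 10
    steps_per_epoch: int = 25
    n_val_pairs: int = 4
    seed: int = 0
    finetune_lr: float = 1e-4
    rel_improvement: float = 1e-4

    def __post_init__(self):
        if self.accum_steps < 1:
            raise ValueError("accum_steps must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


class TrainingDiverged(RuntimeError):
    """Raised when a non-finite loss appears; carries a diagnostic dump."""

    def __init__(self, message: str, dump: dict):
        super().__init__(message)
        self.dump = dump


def accumulate_and_step(optimizer: Adam, loss_fn: Callable[[int], Tensor],
                        n_micro: int) -> list[float]:
    """Average ``n_micro`` mini-batch gradients, then apply one update.

    Each call to ``loss_fn(i)`` must build a fresh graph for mini-batch
    i.  Scaling every loss by 1/n before backprop makes the accumulated
    gradient the mean of the per-batch gradients, so one accumulated
    update is equivalent to a single update on the concatenated batch.
    """
    optimizer.zero_grad()
    values = []
    for i in range(n_micro):
        loss = loss_fn(i)
        (loss * (1.0 / n_micro)).backward()
        values.append(float(loss.data))
    optimizer.step()
    return values


def _pair_loss(net: RegistrationNetwork, variant: LossVariant,
               fixed: Volume, fixed_onehot: np.ndarray,
               moving: Volume, moving_onehot: np.ndarray):
    """Build the weighted loss graph for one fixed/moving pair."""
    x = np.stack([fixed.data, moving.data])
    phi = net.forward(x)
    warped = ad.grid_sample(Tensor(moving.data[None]), phi)[0]
    fixed_t = Tensor(fixed.data)
    truth_t = warped_seg = None
    if variant.uses_labels:
        truth_t = Tensor(fixed_onehot)
        warped_seg = ad.grid_sample(Tensor(moving_onehot), phi)
    losses = variant.compute_losses(fixed_t, warped, truth_t, warped_seg)
    reg = smoothness_reg(phi)
    return variant.weights.combine(losses, [reg])


def _prepare(dataset: Sequence[tuple[Volume, LabelVolume]]):
    n_classes = 1 + max(int(lbl.data.max()) for _, lbl in dataset)
    onehots = [one_hot(lbl, n_classes) for _, lbl in dataset]
    return n_classes, onehots


def make_validation_pairs(dataset, aug_cfg: AugmentationConfig, n_pairs: int,
                          seed: int, n_classes: int):
    """Pre-generate validation pairs once; reused across every epoch."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        fixed, labels = dataset[i % len(dataset)]
        moving, moving_labels, _ = generate_pair(fixed, labels, aug_cfg, rng)
        pairs.append((fixed, one_hot(labels, n_classes),
                      moving, one_hot(moving_labels, n_classes)))
    return pairs


def _validation_loss(net, variant, val_pairs) -> float:
    with ad.no_grad():
        totals = [
            float(_pair_loss(net, variant, f, fo, m, mo).total.data)
            for f, fo, m, mo in val_pairs
        ]
    return float(np.mean(totals))


def _snapshot(net, variant, epoch, val_loss) -> dict:
    return {
        "net_state": net.state_dict(),
        "weights_state": variant.weights.state_dict(),
        "epoch": epoch,
        "val_loss": val_loss,
    }


def train(net: RegistrationNetwork, dataset, cfg: TrainConfig,
          variant: LossVariant | str, aug_cfg: AugmentationConfig | None = None,
          val_dataset=None, stage: str = "train") -> tuple[dict, list[dict]]:
    """Run the weakly-supervised loop; returns (best checkpoint, history).

    ``dataset`` is a sequence of (Volume, LabelVolume) fixed images; the
    moving counterparts are generated on the fly.  History is a list of
    per-epoch records (losses, learning rate, adaptive-weight values) so
    the weight trajectories can be plotted afterwards.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    if isinstance(variant, str):
        variant = make_variant(variant)
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    n_classes, onehots = _prepare(dataset)
    val_source = val_dataset if val_dataset is not None else dataset
    val_pairs = make_validation_pairs(
        val_source, aug_cfg, cfg.n_val_pairs, cfg.seed + 1_000_003, n_classes
    )
    rng = np.random.default_rng(cfg.seed)
    params = net.parameters() + variant.weights.parameters()
    optimizer = Adam(params, lr=cfg.lr)
    history: list[dict] = []
    best: dict | None = None
    wait = 0
    updates_per_epoch = max(1, cfg.steps_per_epoch // cfg.accum_steps)
    for epoch in range(cfg.max_epochs):
        epoch_losses: list[float] = []
        term_sums: dict[str, float] = {}
        for _ in range(updates_per_epoch):
            bundles: list = []

            def micro(_i) -> Tensor:
                idx = int(rng.integers(len(dataset)))
                fixed, labels = dataset[idx]
                moving, moving_labels, _ = generate_pair(fixed, labels, aug_cfg, rng)
                bundle = _pair_loss(
                    net, variant, fixed, onehots[idx],
                    moving, one_hot(moving_labels, n_classes),
                )
                bundles.append(bundle)
                return bundle.total

            values = accumulate_and_step(optimizer, micro, cfg.accum_steps)
            if not np.all(np.isfinite(values)):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}",
                    dump={"epoch": epoch, "losses": values,
                          "state": _snapshot(net, variant, epoch, float("nan"))},
                )
            epoch_losses.extend(values)
            for b in bundles:
                for k, v in {**b.loss_values, **b.reg_values}.items():
                    term_sums[k] = term_sums.get(k, 0.0) + v
        val_loss = _validation_loss(net, variant, val_pairs)
        record = {
            "stage": stage,
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr": optimizer.lr,
            "omega": variant.weights.omega.tolist(),
            "lam": variant.weights.lam.tolist(),
        }
        n_terms = max(1, len(epoch_losses))
        record.update({f"loss_{k}": v / n_terms for k, v in term_sums.items()})
        history.append(record)
        if best is None or val_loss < best["val_loss"] * (1.0 - cfg.rel_improvement):
            best = _snapshot(net, variant, epoch, val_loss)
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                optimizer.lr /= cfg.plateau_factor
                wait = 0
    assert best is not None
    return best, history


def freeze_encoder(net: RegistrationNetwork) -> RegistrationNetwork:
    """Exclude encoder parameters from updates (decoder/head stay live)."""
    net.freeze_encoder()
    return net


def unfreeze_encoder(net: RegistrationNetwork) -> RegistrationNetwork:
    net.unfreeze_encoder()
    return net


def finetune(net: RegistrationNetwork, dataset, cfg: TrainConfig,
             mode: str, variant: LossVariant | str,
             aug_cfg: AugmentationConfig | None = None) -> tuple[dict, list[dict]]:
    """Transfer-learn a pretrained network at the finetuning rate.

    mode='direct' updates all parameters; mode='two_step' first trains
    decoder and head with a frozen encoder, then the full model.  Both
    stages run at ``cfg.finetune_lr``; histories are concatenated with a
    stage tag.
    """
    if isinstance(variant, str):
        variant = make_variant(variant)
    ft_cfg = replace(cfg, lr=cfg.finetune_lr)
    if mode == "direct":
        best, history = train(net, dataset, ft_cfg, variant, aug_cfg, stage="direct")
        return best, history
    if mode != "two_step":
        raise ValueError("mode must be 'direct' or 'two_step'")
    freeze_encoder(net)
    best1, h1 = train(net, dataset, ft_cfg, variant, aug_cfg, stage="stage1")
    unfreeze_encoder(net)
    cfg2 = replace(ft_cfg, seed=ft_cfg.seed + 1)
    best2, h2 = train(net, dataset, cfg2, variant, aug_cfg, stage="stage2")
    best = best1 if best1["val_loss"] <= best2["val_loss"] else best2
    return best, h1 + h2


# -- checkpoint files ----------------------------------------------------

def save_checkpoint(path, net: RegistrationNetwork, variant: LossVariant,
                    extra: dict | None = None) -> None:
    """Persist weights + architecture + adaptive-weight state as one file."""
    meta = {
        "unet": asdict(net.cfg),
        "variant": variant.name,
        "weights": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in variant.weights.state_dict().items()
        },
        "extra": extra or {},
    }
    arrays = net.state_dict()
    np.savez(str(path), meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[RegistrationNetwork, LossVariant, dict]:
    """Rebuild (network, loss variant, metadata) from a checkpoint file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(str(path)) as f:
        meta = json.loads(str(f["meta"][()]))
        state = {k: f[k] for k in f.files if k != "meta"}
    unet = meta["unet"]
    cfg = UNetConfig(
        encoder_filters=tuple(unet["encoder_filters"]),
        head_filters=tuple(unet["head_filters"]),
        kernel=unet["kernel"],
        leaky_slope=unet["leaky_slope"],
        in_channels=unet["in_channels"],
        out_channels=unet["out_channels"],
        seed=unet["seed"],
    )
    net = build_model(cfg)
    net.load_state_dict(state)
    variant = make_variant(meta["variant"])
    ws = meta["weights"]
    variant.weights.load_state_dict(
        {"logits": np.asarray(ws["logits"]), "log_lambda": np.asarray(ws["log_lambda"])}
    )
    return net, variant, meta.get("extra", {})
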