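"""The displacement-predicting 3D U-Net.

The fixed and moving images are concatenated into a two-channel volume;
the network returns a three-channel displacement map of the same spatial
size.  The encoder consists of contraction blocks (3x3x3 convolution +
LeakyReLU, followed by stride-2 max pooling); the deepest block acts as
the bottleneck and is not pooled, so an encoder with B blocks requires
input dimensions divisible by 2^(B-1).  The decoder mirrors the encoder
with nearest-neighbour upsampling and skip connections by channel
concatenation.  A head of two 16-filter convolutions precedes the
3-filter output convolution, which is zero-initialised so the initial
prediction is the identity field.

Sizes are configurable so the same code runs both at the full scale
(32..1024 filters on 128^3 volumes) and at desk scale for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .volumes import DisplacementField, Volume


@dataclass
class UNetConfig:
    """Architecture hyper-parameters.

    Default encoder widths are 32, 64, 128, 256, 512, 1024; the head has
    two 16-filter convolutions; all kernels are 3^3 with LeakyReLU
    (slope 0.2) activations and nearest-neighbour upsampling.
    """

    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 512, 1024)
    head_filters: tuple[int, int] = (16, 16)
    kernel: int = 3
    leaky_slope: float = 0.2
    in_channels: int = 2
    out_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        self.head_filters = tuple(int(f) for f in self.head_filters)
        if len(self.encoder_filters) < 2:
            raise ValueError("need at least two encoder blocks")
        if self.out_channels != 3:
            raise ValueError("the displacement head must emit 3 channels")

    @property
    def divisibility(self) -> int:
        """Required divisor of every input spatial dimension."""
        return 2 ** (len(self.encoder_filters) - 1)


class _Conv:
    """A 3D convolution layer with bias and optional LeakyReLU."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 slope: float | None = 0.2, zero_init: bool = False):
        if zero_init:
            w = np.zeros((cout, cin, k, k, k))
        else:
            std = np.sqrt(2.0 / (cin * k**3))
            w = rng.normal(0.0, std, size=(cout, cin, k, k, k))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv3d(x, self.w, self.b)
        if self.slope is not None:
            y = ad.leaky_relu(y, self.slope)
        return y

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class RegistrationNetwork:
    """U-Net mapping a (2, D, H, W) input to a (3, D, H, W) field."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k, s = cfg.kernel, cfg.leaky_slope
        filt = cfg.encoder_filters
        self.enc: list[_Conv] = []
        cin = cfg.in_channels
        for f in filt:
            self.enc.append(_Conv(cin, f, k, rng, slope=s))
            cin = f
        self.dec: list[_Conv] = []
        prev = filt[-1]
        for f in reversed(filt[:-1]):
            self.dec.append(_Conv(prev + f, f, k, rng, slope=s))
            prev = f
        h1, h2 = cfg.head_filters
        self.head = [
            _Conv(prev, h1, k, rng, slope=s),
            _Conv(h1, h2, k, rng, slope=s),
        ]
        self.out = _Conv(h2, cfg.out_channels, k, rng, slope=None, zero_init=True)

    # -- parameter bookkeeping ------------------------------------------
    def encoder_parameters(self) -> list[Tensor]:
        return [p for c in self.enc for p in c.params()]

    def decoder_parameters(self) -> list[Tensor]:
        layers = self.dec + self.head + [self.out]
        return [p for c in layers for p in c.params()]

    def parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.decoder_parameters()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def freeze_encoder(self) -> None:
        for p in self.encoder_parameters():
            p.requires_grad = False

    def unfreeze_encoder(self) -> None:
        for p in self.encoder_parameters():
            p.requires_grad = True

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match this architecture")
            p.data = arr.copy()

    # -- forward ---------------------------------------------------------
    def _check_shape(self, spatial: tuple[int, ...]) -> None:
        d = self.cfg.divisibility
        if any(n % d for n in spatial):
            raise ValueError(
                f"input spatial dims {spatial} must be divisible by {d} "
                f"for {len(self.cfg.encoder_filters)} encoder blocks"
            )

    def forward(self, x) -> Tensor:
        """x: (in_channels, D, H, W) array or Tensor -> (3, D, H, W) Tensor."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}"
            )
        self._check_shape(x.shape[1:])
        skips = []
        for conv in self.enc[:-1]:
            x = conv(x)
            skips.append(x)
            x = ad.maxpool2(x)
        x = self.enc[-1](x)
        for conv, skip in zip(self.dec, reversed(skips)):
            x = ad.upsample_nearest2(x)
            x = ad.concat([x, skip], axis=0)
            x = conv(x)
        for conv in self.head:
            x = conv(x)
        return self.out(x)

    __call__ = forward


def build_model(cfg: UNetConfig) -> RegistrationNetwork:
    """Construct the registration U-Net for a given configuration."""
    return RegistrationNetwork(cfg)


def predict_displacement(net: RegistrationNetwork, fixed: Volume,
                         moving: Volume) -> DisplacementField:
    """Predict the dense displacement field for one fixed/moving pair.

    Deterministic given frozen weights; runs without recording a
    gradient graph.
    """
    if fixed.data.shape != moving.data.shape:
        raise ValueError("fixed and moving volumes must share a shape")
    with ad.no_grad():
        out = net.forward(np.stack([fixed.data, moving.data]))
    return DisplacementField(out.data, fixed.spacing)
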