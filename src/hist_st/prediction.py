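"""The prediction network: a modified U-Net over spot-grid feature maps.

Architecture
------------
* Encoder: five convolutional levels (channels 64, 128, 256, 512, 1024 by
  default), each level two conv blocks ``ReLU(BN(Conv3x3)))``, with 2x2 max
  pooling between levels.  On an 80 x 64 input the bottleneck is 1024 x 5 x 4.
* Bottleneck: a ConvMixer of seven repeated depthwise (7x7, pad 3) +
  pointwise convolution pairs.
* Decoder: symmetric, upsampling by bilinear 2x followed by a conv block
  (a transposed-convolution mode is available); skip connections pass through
  a multi-scale attention gate (MSAG) — parallel pointwise, 3x3, and dilated
  3x3 (pad 2, dilation 2) convolutions, each batch-normalized, concatenated,
  ReLU, then a batch-normalized pointwise convolution with sigmoid producing
  an attention field that multiplicatively filters the skip features.
* Head: 1x1 convolution to 1 channel (tumor mask, sigmoid) or G channels
  (gene expression map, linear).

Training uses Adam (weight decay 1e-4), an initial learning rate of 1e-3
with cosine annealing, up to 200 epochs at batch size 5; BCE loss for
segmentation, MSE for expression regression, computed over the full padded
grid (blank cells carry blank targets).  Slide-level generalization is
assessed by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import nn
from .grid import ExpressionGrid, GeometryError, LabelGrid
from .images import FeatureMap
from .nn.tensor import Tensor, concat, conv_transpose2x2

__all__ = ["NetworkSpec", "TrainingConfig", "PredictionNet",
           "train", "predict", "loocv"]


@dataclass
class NetworkSpec:
    """Channel/kernel/depth configuration of the prediction network."""

    in_channels: int = 768
    level_channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    mixer_repeats: int = 7
    mixer_kernel: int = 7
    out_channels: int = 1
    head: Literal["sigmoid_mask", "linear_grid"] = "sigmoid_mask"
    upsample: Literal["bilinear", "transposed"] = "bilinear"
    msag_per_channel: bool = False

    def __post_init__(self):
        if len(self.level_channels) < 2:
            raise ValueError("need at least two convolutional levels")
        if any(b <= a for a, b in zip(self.level_channels, self.level_channels[1:])):
            raise ValueError("level channels must be strictly increasing")
        if self.mixer_repeats < 1:
            raise ValueError("mixer_repeats must be >= 1")
        if self.mixer_kernel % 2 != 1:
            raise ValueError("mixer_kernel must be odd")

    @property
    def n_levels(self) -> int:
        return len(self.level_channels)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.n_levels - 1)


@dataclass
class TrainingConfig:
    loss: Literal["mse", "bce"] = "mse"
    lr0: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 5
    seed: int = 0
    masked_loss: bool = False  # restrict the loss to valid (spot) cells

    def __post_init__(self):
        if min(self.lr0, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("hyperparameters must be positive")


class ConvBlock(nn.Module):
    """ReLU(BatchNorm(Conv 3x3, stride 1, pad 1))."""

    def __init__(self, c_in: int, c_out: int, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class MSAG(nn.Module):
    """Multi-scale attention gate filtering a skip connection.

    Three parallel convolutions of the (skip + gating) sum — pointwise, 3x3
    (pad 1), dilated 3x3 (pad 2, dilation 2), each batch-normalized — are
    concatenated, passed through ReLU and a batch-normalized pointwise
    convolution with sigmoid to give attention alpha in (0, 1); the gated
    skip is skip * alpha.  Default attention is per-location (broadcast over
    channels); per-channel gating is available.
    """

    def __init__(self, channels: int, per_channel: bool = False, *, rng):
        super().__init__()
        self.point = nn.Conv2d(channels, channels, 1, rng=rng)
        self.point_bn = nn.BatchNorm2d(channels)
        self.local = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.local_bn = nn.BatchNorm2d(channels)
        self.dilated = nn.Conv2d(channels, channels, 3, padding=2, dilation=2, rng=rng)
        self.dilated_bn = nn.BatchNorm2d(channels)
        att_out = channels if per_channel else 1
        self.gate = nn.Conv2d(3 * channels, att_out, 1, rng=rng)
        self.gate_bn = nn.BatchNorm2d(att_out)

    def forward(self, skip, gating):
        if skip.shape != gating.shape:
            raise GeometryError(f"skip {skip.shape} vs gating {gating.shape}")
        x = skip + gating
        branches = concat([
            self.point_bn(self.point(x)),
            self.local_bn(self.local(x)),
            self.dilated_bn(self.dilated(x)),
        ], axis=1).relu()
        alpha = self.gate_bn(self.gate(branches)).sigmoid()
        return skip * alpha


class ConvMixer(nn.Module):
    """Repeated depthwise (kxk, groups=C, residual) + pointwise conv pairs."""

    def __init__(self, channels: int, repeats: int, kernel: int, *, rng):
        super().__init__()
        self.blocks = nn.ModuleList()
        pad = kernel // 2
        for _ in range(repeats):
            self.blocks.append(nn.ModuleList([
                nn.Conv2d(channels, channels, kernel, padding=pad,
                          groups=channels, rng=rng),
                nn.BatchNorm2d(channels),
                nn.Conv2d(channels, channels, 1, rng=rng),
                nn.BatchNorm2d(channels),
            ]))

    def forward(self, x):
        for dw, dw_bn, pw, pw_bn in self.blocks:
            x = dw_bn(dw(x)).relu() + x       # spatial mixing, residual
            x = pw_bn(pw(x)).relu()           # channel mixing
        return x


class _UpConv(nn.Module):
    """2x spatial upsampling then a conv block halving the channel count."""

    def __init__(self, c_in: int, c_out: int, mode: str, *, rng):
        super().__init__()
        self.mode = mode
        if mode == "transposed":
            self.tweight = nn.Parameter(
                rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, c_in, 2, 2)))
        self.block = ConvBlock(c_in, c_out, rng=rng)

    def forward(self, x):
        if self.mode == "transposed":
            x = conv_transpose2x2(x, self.tweight)
        else:
            _, _, h, w = x.shape
            x = x.resize_bilinear(2 * h, 2 * w)
        return self.block(x)


class PredictionNet(nn.Module):
    """Attention-gated U-Net with a ConvMixer bottleneck."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.level_channels
        self.enc = nn.ModuleList()
        c_prev = spec.in_channels
        for c in ch:
            self.enc.append(nn.Sequential(ConvBlock(c_prev, c, rng=rng),
                                          ConvBlock(c, c, rng=rng)))
            c_prev = c
        self.mixer = ConvMixer(ch[-1], spec.mixer_repeats, spec.mixer_kernel, rng=rng)
        self.up = nn.ModuleList()
        self.gates = nn.ModuleList()
        self.dec = nn.ModuleList()
        for deep, shallow in zip(ch[::-1], ch[-2::-1]):
            self.up.append(_UpConv(deep, shallow, spec.upsample, rng=rng))
            self.gates.append(MSAG(shallow, spec.msag_per_channel, rng=rng))
            self.dec.append(nn.Sequential(ConvBlock(2 * shallow, shallow, rng=rng),
                                          ConvBlock(shallow, shallow, rng=rng)))
        self.head = nn.Conv2d(ch[0], spec.out_channels, 1, rng=rng)

    def _check_geometry(self, x: Tensor):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, spec expects {self.spec.in_channels}")
        f = self.spec.downsample_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise GeometryError(
                f"spatial dims {x.shape[2]}x{x.shape[3]} must divide by {f} "
                f"({self.spec.n_levels - 1} halvings); pad the grid first")

    def encode(self, x: Tensor):
        """Bottleneck features plus per-level skips (shallow to deep)."""
        self._check_geometry(x)
        skips = []
        for i, level in enumerate(self.enc):
            if i > 0:
                x = x.maxpool2x2()
            x = level(x)
            if i < len(self.enc) - 1:
                skips.append(x)
        return x, skips

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Logits (segmentation) or expression values, (N, out, H, W)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape((1,) + tuple(x.shape))
        bottleneck, skips = self.encode(x)
        y = self.mixer(bottleneck)
        for up, gate, dec, skip in zip(self.up, self.gates, self.dec, skips[::-1]):
            y = up(y)
            gated = gate(skip, y)
            y = dec(concat([gated, y], axis=1))
        return self.head(y)

    def predict_probs(self, x) -> np.ndarray:
        """Numpy forward in eval mode; sigmoid applied for the mask head."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(x)
            out = out.sigmoid() if self.spec.head == "sigmoid_mask" else out
            return out.data
        finally:
            self.train(was_training)


def _as_input(fmap) -> np.ndarray:
    if isinstance(fmap, FeatureMap):
        return fmap.values
    return np.asarray(fmap, dtype=np.float32)


def _as_target(target) -> np.ndarray:
    if isinstance(target, ExpressionGrid):
        return target.values
    if isinstance(target, LabelGrid):
        return target.values[None]
    arr = np.asarray(target, dtype=np.float32)
    return arr[None] if arr.ndim == 2 else arr


def _target_validity(target) -> np.ndarray | None:
    if isinstance(target, (ExpressionGrid, LabelGrid)):
        return target.validity
    return None


def train(slides: Sequence[tuple], cfg: TrainingConfig,
          spec: NetworkSpec | None = None,
          model: PredictionNet | None = None) -> tuple[PredictionNet, list[float]]:
    """Train on (feature map, target grid) pairs; returns model + loss trace.

    ``slides`` pairs a :class:`FeatureMap` (or raw C x H x W array) with an
    :class:`ExpressionGrid`, :class:`LabelGrid` or raw array target.
    """
    if not slides:
        raise ValueError("need at least one training slide")
    xs = np.stack([_as_input(s[0]) for s in slides]).astype(np.float32)
    ys = np.stack([_as_target(s[1]) for s in slides]).astype(np.float32)
    if model is None:
        if spec is None:
            head = "sigmoid_mask" if cfg.loss == "bce" else "linear_grid"
            spec = NetworkSpec(in_channels=xs.shape[1], out_channels=ys.shape[1],
                               head=head)
        model = PredictionNet(spec, seed=cfg.seed)
        if spec.head == "linear_grid":
            # start the head at the per-gene target mean: expression targets
            # have a large positive offset that is wasteful to learn by SGD
            model.head.bias.data = ys.mean(axis=(0, 2, 3)).astype(np.float32)
    if cfg.masked_loss:
        masks = np.stack([
            (_target_validity(s[1]) if _target_validity(s[1]) is not None
             else np.ones(ys.shape[2:], dtype=bool)) for s in slides])
        mask_arr = masks[:, None].astype(np.float32)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    sched = nn.CosineAnnealingLR(opt, t_max=cfg.max_epochs)
    n = len(slides)
    losses: list[float] = []
    model.train()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(xs[idx])
            out = model(xb)
            if cfg.masked_loss:
                m = Tensor(mask_arr[idx])
                frac = max(float(mask_arr[idx].mean()), 1e-12)
                if cfg.loss == "bce":
                    # per-cell BCE from logits, masked mean
                    t = Tensor(ys[idx])
                    per = _bce_map(out, t)
                    loss = (per * m).mean() * (1.0 / frac)
                else:
                    diff = (out - Tensor(ys[idx])) * m
                    loss = (diff * diff).mean() * (1.0 / frac)
            else:
                loss = (nn.bce_with_logits(out, ys[idx]) if cfg.loss == "bce"
                        else nn.mse_loss(out, ys[idx]))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()} "
                    f"(lr={opt.lr:.2e}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        sched.step()
        losses.append(epoch_loss / n_batches)
    return model, losses


def _bce_map(logits: Tensor, targets: Tensor) -> Tensor:
    """Elementwise binary cross-entropy from logits (stable composition)."""
    # softplus(z) - t z  =  relu(z) - t z + log(1 + exp(-|z|))
    z = logits
    absz = z.relu() + (-z).relu()
    softplus = z.relu() + ((-absz).exp() + 1.0).log()
    return softplus - targets * z


def predict(model: PredictionNet, fmap, gene_names: Sequence[str] | None = None,
            validity: np.ndarray | None = None):
    """Predict one slide; wraps regression output as an ExpressionGrid."""
    x = _as_input(fmap)
    out = model.predict_probs(x)[0]
    if validity is None and isinstance(fmap, FeatureMap):
        validity = fmap.validity
    if model.spec.head == "sigmoid_mask":
        return out  # (1, H, W) probabilities
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(out.shape[0])]
    if validity is None:
        validity = np.ones(out.shape[1:], dtype=bool)
    vals = out.copy()
    vals[:, ~validity] = 0.0
    return ExpressionGrid(values=vals, gene_names=list(gene_names), validity=validity)


def loocv(slides: Sequence[tuple], cfg: TrainingConfig,
          spec: NetworkSpec | None = None):
    """Leave-one-out cross-validation over slides.

    For each slide, trains on the remaining slides and predicts the held-out
    one.  Returns (predictions, manifests): raw output arrays in slide order
    and per-fold manifests recording train/test membership.
    """
    if len(slides) < 2:
        raise ValueError("LOOCV needs at least two slides")
    predictions, manifests = [], []
    for fold in range(len(slides)):
        train_idx = [i for i in range(len(slides)) if i != fold]
        model, losses = train([slides[i] for i in train_idx], cfg, spec=spec)
        out = model.predict_probs(_as_input(slides[fold][0]))[0]
        predictions.append(out)
        manifests.append({"fold": fold, "train_indices": train_idx,
                          "test_index": fold, "final_loss": losses[-1]})
    return predictions, manifests
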