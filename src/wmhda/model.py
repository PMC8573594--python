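"""Triplanar U-Net ensemble: depth-trimmed planar 2D U-Nets taking FLAIR+T1
slices, a combined weighted-CE + Dice loss, and triplanar probability
averaging with per-plane assembly back into subject space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .preproc import (
    PLANES,
    PreprocConfig,
    assemble_probability_volume,
    crop_fov,
    extract_plane_slices,
    gaussian_normalise,
)
from .synthgen import Subject

__all__ = [
    "PlanarUNetConfig",
    "LossWeights",
    "PlanarUNet",
    "TriplanarEnsemble",
    "build_planar_unet",
    "build_triplanar_ensemble",
    "weighted_cross_entropy",
    "soft_dice_loss",
    "combined_loss",
    "voxel_weights",
    "predict_volume",
    "binarize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class PlanarUNetConfig:
    """Architecture of one planar network.

    Channels double per resolution level, capped at `bottleneck_channels`;
    the defaults (base 128, depth 3) give a 128/256/512 channel ladder with
    the 512-channel bottleneck after the maximum levels of pooling.
    """

    in_channels: int = 2
    n_classes: int = 2
    depth: int = 3
    base_channels: int = 128
    bottleneck_channels: int = 512

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")

    def level_channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.bottleneck_channels)
                for i in range(self.depth)]


@dataclass(frozen=True)
class LossWeights:
    lambda_ce: float = 1.0
    lambda_dice: float = 1.0
    voxel_weight_mode: str = "inverse_frequency"

    def __post_init__(self):
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise ValueError("loss weights must be >= 0")
        if self.lambda_ce == 0 and self.lambda_dice == 0:
            raise ValueError("at least one loss weight must be positive")


class ConvBlock(nn.Module):
    """Two 3x3 conv + batch-norm + ReLU stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class PlanarUNet(nn.Module):
    """Depth-trimmed 2D U-Net with softmax output and named feature taps.

    After a forward pass, ``taps["bottleneck"]`` holds the coarsest encoder
    output and ``taps["pre_label_predictor"]`` the skip-concatenated input
    to the final decoder block (the features the label predictor consumes).
    """

    def __init__(self, config: PlanarUNetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        chans = config.level_channels()
        d = config.depth
        self.encoders = nn.ModuleList(
            [ConvBlock(config.in_channels if i == 0 else chans[i - 1], chans[i], rng)
             for i in range(d - 1)]
        )
        self.bottleneck = ConvBlock(chans[d - 2], chans[d - 1], rng)
        self.up = nn.UpsampleBilinear(2)
        # decoder level i (from coarse to fine): upsample-conv then conv block
        self.upconvs = nn.ModuleList(
            [nn.Conv2d(chans[i + 1], chans[i], 3, rng=rng) for i in reversed(range(d - 1))]
        )
        self.decoders = nn.ModuleList(
            [ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(d - 1))]
        )
        self.outc = nn.Conv2d(chans[0], config.n_classes, 1, rng=rng)
        self.taps: dict[str, Tensor] = {}

    def forward(self, x: Tensor, return_logits: bool = False) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = nn.maxpool2d(x, 2)
        x = self.bottleneck(x)
        self.taps = {"bottleneck": x}
        for i, (upconv, dec) in enumerate(zip(self.upconvs, self.decoders)):
            skip = skips[-(i + 1)]
            x = upconv(self.up(x, target_hw=(skip.shape[2], skip.shape[3]))).relu()
            x = nn.concat([x, skip], axis=1)
            if i == len(self.decoders) - 1:
                self.taps["pre_label_predictor"] = x
            x = dec(x)
        logits = self.outc(x)
        if return_logits:
            return logits
        return nn.softmax(logits, axis=1)


def build_planar_unet(config: PlanarUNetConfig, seed: int = 0) -> PlanarUNet:
    return PlanarUNet(config, seed=seed)


class TriplanarEnsemble(nn.Module):
    """Three architecturally identical planar networks, one per plane."""

    def __init__(self, config: PlanarUNetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.axial = PlanarUNet(config, seed=seed)
        self.sagittal = PlanarUNet(config, seed=seed + 1)
        self.coronal = PlanarUNet(config, seed=seed + 2)

    def net(self, plane: str) -> PlanarUNet:
        if plane not in PLANES:
            raise ValueError(f"unknown plane {plane!r}")
        return getattr(self, plane)

    def planes(self):
        return {plane: self.net(plane) for plane in PLANES}


def build_triplanar_ensemble(config: PlanarUNetConfig | None = None,
                             seed: int = 0) -> TriplanarEnsemble:
    return TriplanarEnsemble(config or PlanarUNetConfig(), seed=seed)


# -- losses ------------------------------------------------------------------

_EPS = 1e-12


def voxel_weights(labels: np.ndarray, mode: str = "inverse_frequency") -> np.ndarray:
    """Per-voxel CE weights. 'inverse_frequency' balances classes per batch."""
    labels = np.asarray(labels)
    if mode == "uniform":
        return np.ones(labels.shape)
    if mode == "inverse_frequency":
        w = np.ones(labels.shape)
        total = labels.size
        for cls in (0, 1):
            n = int((labels == cls).sum())
            if n:
                w[labels == cls] = total / (2.0 * n)
        return w
    raise ValueError(f"unknown voxel weight mode {mode!r}")


def weighted_cross_entropy(probabilities: Tensor, labels: np.ndarray,
                           weights: np.ndarray | None = None) -> Tensor:
    """Mean over pixels of weight * -log p(true class)."""
    labels = np.asarray(labels)
    if probabilities.shape[0] != labels.shape[0] or probabilities.shape[2:] != labels.shape[1:]:
        raise ValueError("probability/label shape mismatch")
    if weights is None:
        weights = np.ones(labels.shape)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != labels.shape:
        raise ValueError("weight/label shape mismatch")
    if np.any(weights < 0):
        raise ValueError("voxel weights must be >= 0")
    p_true = nn.gather_channel(probabilities, labels.astype(np.int64))
    nll = -(p_true.clamp_min(_EPS).log())
    return (nll * Tensor(weights)).mean()


def soft_dice_loss(probabilities: Tensor, labels: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - (2 sum(p*y) + eps) / (sum p + sum y + eps) on the lesion channel."""
    labels = np.asarray(labels)
    if probabilities.shape[0] != labels.shape[0] or probabilities.shape[2:] != labels.shape[1:]:
        raise ValueError("probability/label shape mismatch")
    p = nn.gather_channel(probabilities, np.ones(labels.shape, dtype=np.int64))
    y = Tensor(labels.astype(float))
    inter = (p * y).sum()
    denom = p.sum() + y.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def combined_loss(probabilities: Tensor, labels: np.ndarray,
                  weights: LossWeights = LossWeights(),
                  voxel_w: np.ndarray | None = None) -> Tensor:
    if voxel_w is None:
        voxel_w = voxel_weights(labels, weights.voxel_weight_mode)
    loss = Tensor(np.zeros(()))
    if weights.lambda_ce:
        loss = loss + weights.lambda_ce * weighted_cross_entropy(probabilities, labels, voxel_w)
    if weights.lambda_dice:
        loss = loss + weights.lambda_dice * soft_dice_loss(probabilities, labels)
    return loss


# -- inference ---------------------------------------------------------------

def subject_image(subject: Subject) -> np.ndarray:
    """Normalised 2-channel (FLAIR, T1) image volume for a subject."""
    flair = gaussian_normalise(subject.flair, subject.brain_mask)
    t1 = gaussian_normalise(subject.t1, subject.brain_mask)
    return np.stack([flair, t1])


def predict_volume(ensemble: TriplanarEnsemble, subject: Subject,
                   config: PreprocConfig | None = None,
                   batch_size: int = 8,
                   planes: tuple[str, ...] = PLANES) -> np.ndarray:
    """Mean of the per-plane assembled 3D probability volumes."""
    config = config or PreprocConfig()
    image = subject_image(subject)
    _, crop_box = crop_fov(subject.flair, subject.brain_mask, config.crop_margin)
    sl = tuple(slice(lo, hi) for lo, hi in crop_box)
    cropped = image[(slice(None),) + sl]

    volumes = []
    for plane in planes:
        net = ensemble.net(plane)
        was_training = net.training
        net.eval()
        stack = extract_plane_slices(cropped, plane, resize_dims=config.resize[plane],
                                     original_shape=subject.flair.shape, crop_box=crop_box)
        slices = stack.slices.astype(np.float32)
        probs = np.empty((slices.shape[0], 1) + tuple(stack.resize_dims), dtype=np.float64)
        for start in range(0, slices.shape[0], batch_size):
            batch = Tensor(slices[start:start + batch_size])
            out = net(batch)
            probs[start:start + batch_size, 0] = out.numpy()[:, 1]
        stack.slices = probs
        volumes.append(assemble_probability_volume(stack))
        net.train(was_training)
    return np.mean(volumes, axis=0)


def binarize(probability: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(probability) >= threshold


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(ensemble: TriplanarEnsemble, path, extra: dict | None = None) -> None:
    """Single-file .npz with weights, config and optional metadata."""
    state = {f"state/{k}": v for k, v in ensemble.state_dict().items()}
    meta = {"config": asdict(ensemble.config), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> TriplanarEnsemble:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = PlanarUNetConfig(**meta["config"])
        ensemble = TriplanarEnsemble(config)
        ensemble.load_state_dict(
            {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")})
    return ensemble
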