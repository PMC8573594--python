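"""Baseline training loop: Adam with a stepped learning-rate schedule,
online augmentation, subject-level validation split and patience-based
early stopping. Each planar network is trained independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .model import LossWeights, TriplanarEnsemble, combined_loss, subject_image
from .nn import Tensor
from .preproc import PLANES, PreprocConfig, crop_fov, extract_plane_slices
from .synthgen import Subject

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "augment_sample",
    "expand_dataset",
    "lr_schedule",
    "build_plane_dataset",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr_init: float = 1e-3
    lr_factor: float = 0.1
    lr_step_epochs: int = 2
    lr_floor: float = 1e-5
    adam_eps: float = 1e-4
    pretrain_epochs: int = 50
    patience: int = 25
    max_epochs: int = 200
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_floor <= self.lr_init:
            raise ValueError("require 0 < lr_floor <= lr_init")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation; one transform family is drawn per call."""

    translate_range: tuple[float, float] = (-10.0, 10.0)
    rotate_range: tuple[float, float] = (-10.0, 10.0)
    noise_var_range: tuple[float, float] = (0.01, 0.09)
    blur_sigma_range: tuple[float, float] = (0.1, 0.3)
    factor_axial: int = 10
    factor_sag_cor: int = 6

    def __post_init__(self):
        for rng_ in (self.translate_range, self.rotate_range,
                     self.noise_var_range, self.blur_sigma_range):
            if rng_[0] > rng_[1]:
                raise ValueError("augmentation intervals must be ordered")
        if self.factor_axial < 1 or self.factor_sag_cor < 1:
            raise ValueError("expansion factors must be >= 1")

    def factor_for(self, plane: str) -> int:
        if plane == "axial":
            return self.factor_axial
        if plane in ("sagittal", "coronal"):
            return self.factor_sag_cor
        raise ValueError(f"unknown plane {plane!r}")


def augment_sample(image: np.ndarray, label: np.ndarray | None,
                   config: AugmentConfig, rng: np.random.Generator):
    """Apply one randomly drawn transform to a (C, H, W) slice.

    Translation/rotation act identically on image and label (label with
    nearest-neighbour interpolation, re-binarised); noise and blur touch
    the image channels only.
    """
    image = np.asarray(image, dtype=np.float64)
    out_label = None if label is None else np.asarray(label)
    kind = rng.integers(4)
    if kind == 0:  # translation
        dx = rng.uniform(*config.translate_range)
        dy = rng.uniform(*config.translate_range)
        image = np.stack([ndimage.shift(c, (dx, dy), order=1, mode="constant") for c in image])
        if out_label is not None:
            out_label = ndimage.shift(out_label.astype(float), (dx, dy),
                                      order=0, mode="constant") > 0.5
    elif kind == 1:  # rotation
        angle = rng.uniform(*config.rotate_range)
        image = np.stack([ndimage.rotate(c, angle, reshape=False, order=1,
                                         mode="constant") for c in image])
        if out_label is not None:
            out_label = ndimage.rotate(out_label.astype(float), angle, reshape=False,
                                       order=0, mode="constant") > 0.5
    elif kind == 2:  # additive Gaussian noise
        var = rng.uniform(*config.noise_var_range)
        if var > 0:
            image = image + rng.normal(0.0, np.sqrt(var), image.shape)
    else:  # Gaussian blur
        sigma = rng.uniform(*config.blur_sigma_range)
        if sigma > 0:
            image = np.stack([ndimage.gaussian_filter(c, sigma) for c in image])
    if out_label is not None:
        out_label = out_label.astype(np.int8)
    return image.astype(np.float32), out_label


def expand_dataset(samples: list, plane: str, config: AugmentConfig, seed: int = 0) -> list:
    """Original samples plus (factor - 1) augmented copies of each.

    The plane selects the expansion factor (10x axial, 6x sagittal/coronal),
    counting the original sample in the total.
    """
    if not samples:
        raise ValueError("sample list is empty")
    factor = config.factor_for(plane)
    rng = np.random.default_rng(np.random.SeedSequence([zlib.crc32(plane.encode()), seed]))
    out = []
    for image, label in samples:
        out.append((image, label))
        for _ in range(factor - 1):
            out.append(augment_sample(image, label, config, rng))
    return out


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """max(lr_floor, lr_init * lr_factor^floor(epoch / lr_step_epochs))."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    lr = config.lr_init * config.lr_factor ** (epoch // config.lr_step_epochs)
    return max(config.lr_floor, lr)


# -- dataset assembly --------------------------------------------------------

def build_plane_dataset(subjects: list[Subject], plane: str,
                        config: PreprocConfig,
                        with_labels: bool = True,
                        min_brain_fraction: float = 0.02) -> list:
    """(image, label) slice pairs for one plane across subjects.

    Volumes are normalised, cropped around the brain and sliced; slices with
    almost no brain coverage are dropped. `with_labels=False` yields
    (image, None) pairs (unlabelled target data never touches its masks).
    """
    samples = []
    for subject in subjects:
        image = subject_image(subject)
        _, box = crop_fov(subject.flair, subject.brain_mask, config.crop_margin)
        sl = tuple(slice(lo, hi) for lo, hi in box)
        cropped = image[(slice(None),) + sl]
        stack = extract_plane_slices(cropped, plane, resize_dims=config.resize[plane],
                                     original_shape=subject.flair.shape, crop_box=box)
        brain = subject.brain_mask[sl].astype(float)
        brain_stack = extract_plane_slices(brain, plane, resize_dims=config.resize[plane],
                                           interpolation="nearest")
        if with_labels:
            mask = subject.lesion_mask[sl].astype(float)
            mask_stack = extract_plane_slices(mask, plane, resize_dims=config.resize[plane],
                                              interpolation="nearest")
        for i in range(stack.slices.shape[0]):
            if brain_stack.slices[i, 0].mean() < min_brain_fraction:
                continue
            label = (mask_stack.slices[i, 0] > 0.5).astype(np.int8) if with_labels else None
            samples.append((stack.slices[i].astype(np.float32), label))
    return samples


def split_subjects(subjects: list[Subject], val_fraction: float, seed: int):
    """Subject-level train/validation split (avoids slice leakage)."""
    n = len(subjects)
    if n == 1:
        # degenerate single-subject cohort: validate on the training subject
        # so the patience criterion still has a signal
        return list(subjects), list(subjects)
    n_val = max(1, int(round(val_fraction * n)))
    if n - n_val < 1:
        raise ValueError("cohort too small for a nonempty train/validation split")
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(subjects) if i not in val_idx]
    val = [s for i, s in enumerate(subjects) if i in val_idx]
    return train, val


def _batches(samples, batch_size, rng):
    order = rng.permutation(len(samples))
    for start in range(0, len(samples), batch_size):
        idx = order[start:start + batch_size]
        images = np.stack([samples[i][0] for i in idx])
        labels = np.stack([samples[i][1] for i in idx])
        yield images, labels


def _epoch_loss(net, samples, batch_size, loss_weights):
    net.eval()
    total, count = 0.0, 0
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        images = np.stack([c[0] for c in chunk])
        labels = np.stack([c[1] for c in chunk])
        probs = net(Tensor(images))
        total += combined_loss(probs, labels, loss_weights).item() * len(chunk)
        count += len(chunk)
    net.train()
    return total / max(count, 1)


def train_plane(net, train_samples, val_samples, config: TrainConfig,
                augment: AugmentConfig | None, plane: str,
                loss_weights: LossWeights = LossWeights(),
                optimiser=None, lr_fn=None, log_rows=None,
                param_filter=None) -> dict:
    """Early-stopped training of one planar network; returns the best state."""
    params = param_filter(net) if param_filter else net.parameters()
    opt = optimiser or nn.Adam(params, lr=config.lr_init, eps=config.adam_eps)
    lr_fn = lr_fn or (lambda epoch: lr_schedule(epoch, config))
    rng = np.random.default_rng(np.random.SeedSequence(
        [zlib.crc32(plane.encode()), config.seed]))
    best_val = np.inf
    best_state = net.state_dict()
    wait = 0
    net.train()
    for epoch in range(config.max_epochs):
        opt.lr = lr_fn(epoch)
        samples = (expand_dataset(train_samples, plane, augment,
                                  seed=config.seed * 10007 + epoch)
                   if augment is not None else train_samples)
        running, nb = 0.0, 0
        for images, labels in _batches(samples, config.batch_size, rng):
            opt.zero_grad()
            probs = net(Tensor(images))
            loss = combined_loss(probs, labels, loss_weights)
            loss.backward()
            opt.step()
            running += loss.item()
            nb += 1
        val_loss = _epoch_loss(net, val_samples, config.batch_size, loss_weights)
        if log_rows is not None:
            log_rows.append({"plane": plane, "epoch": epoch, "lr": opt.lr,
                             "train_loss": running / max(nb, 1), "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = net.state_dict()
            wait = 0
        elif epoch >= config.pretrain_epochs:
            wait += 1
            if wait >= config.patience:
                break
    net.load_state_dict(best_state)
    return {"best_val_loss": best_val}


def train_model(ensemble: TriplanarEnsemble, cohort: list[Subject],
                config: TrainConfig = TrainConfig(),
                augment: AugmentConfig | None = AugmentConfig(),
                preproc: PreprocConfig | None = None,
                loss_weights: LossWeights = LossWeights(),
                planes: tuple[str, ...] = PLANES):
    """Train each planar network independently; returns (ensemble, log)."""
    if not cohort:
        raise ValueError("cohort is empty")
    preproc = preproc or PreprocConfig()
    train_subj, val_subj = split_subjects(cohort, config.val_fraction, config.seed)
    rows: list[dict] = []
    for plane in planes:
        train_samples = build_plane_dataset(train_subj, plane, preproc)
        val_samples = build_plane_dataset(val_subj, plane, preproc)
        if not train_samples or not val_samples:
            raise ValueError(f"no usable {plane} slices for training/validation")
        train_plane(ensemble.net(plane), train_samples, val_samples, config,
                    augment, plane, loss_weights, log_rows=rows)
    return ensemble, pd.DataFrame(rows)
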