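"""Domain-adversarial adaptation (DANN / semi-DANN).

A domain-predictor head is attached to the bottleneck tap through a
gradient-reversal layer; the segmentation path trains on labelled samples
(source, plus an optional labelled fraction of target subjects) with Adam
while the domain head trains on all samples with momentum SGD. The reversed
domain gradient drives the shared features toward domain invariance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .model import LossWeights, PlanarUNet, TriplanarEnsemble, combined_loss
from .nn import Tensor, grad_reverse
from .preproc import PLANES, PreprocConfig
from .synthgen import Subject
from .training import TrainConfig, build_plane_dataset, lr_schedule, split_subjects

__all__ = [
    "DannConfig",
    "DomainHead",
    "grad_reverse",
    "build_domain_head",
    "select_semi_subset",
    "train_dann",
    "extract_features",
]


@dataclass(frozen=True)
class DannConfig:
    grl_lambda: float = 1.0
    projection_channels: tuple[int, int] = (128, 64)
    fc_widths: tuple[int, int, int] = (1024, 512, 32)
    dropout: float = 0.2
    domain_lr: float = 1e-3
    domain_momentum: float = 0.9
    main_lr: float = 1e-3
    semi_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.semi_fraction <= 1.0:
            raise ValueError("semi_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.grl_lambda < 0:
            raise ValueError("grl_lambda must be >= 0")


class DomainHead(nn.Module):
    """2x2 max-pool, 1x1 projections, then FC layers to a 2-domain softmax."""

    def __init__(self, in_channels: int, spatial: tuple[int, int],
                 config: DannConfig = DannConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        p1, p2 = config.projection_channels
        self.pool = nn.MaxPool2d(2)
        self.proj1 = nn.Conv2d(in_channels, p1, 1, rng=rng)
        self.proj2 = nn.Conv2d(p1, p2, 1, rng=rng)
        h, w = spatial[0] // 2, spatial[1] // 2
        if h < 1 or w < 1:
            raise ValueError(f"bottleneck tap {spatial} too small for 2x2 pooling")
        flat = p2 * h * w
        f1, f2, f3 = config.fc_widths
        self.fc1 = nn.Linear(flat, f1, rng=rng)
        self.drop1 = nn.Dropout(config.dropout, rng=np.random.default_rng(seed + 1))
        self.fc2 = nn.Linear(f1, f2, rng=rng)
        self.drop2 = nn.Dropout(config.dropout, rng=np.random.default_rng(seed + 2))
        self.fc3 = nn.Linear(f2, f3, rng=rng)
        self.out = nn.Linear(f3, 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.proj2(self.proj1(self.pool(x)).relu()).relu()
        x = x.flatten_batch()
        x = self.drop1(self.fc1(x).relu())
        x = self.drop2(self.fc2(x).relu())
        x = self.fc3(x).relu()
        return nn.softmax(self.out(x), axis=1)


def build_domain_head(bottleneck_channels: int, spatial: tuple[int, int],
                      config: DannConfig = DannConfig(), seed: int = 0) -> DomainHead:
    return DomainHead(bottleneck_channels, spatial, config, seed)


def select_semi_subset(subjects: list[Subject], fraction: float, seed: int = 0) -> list[Subject]:
    """floor(fraction * n) subjects chosen uniformly without replacement."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    k = int(np.floor(fraction * len(subjects)))
    if k == 0:
        return []
    idx = np.random.default_rng(seed).choice(len(subjects), size=k, replace=False)
    return [subjects[i] for i in sorted(idx)]


def domain_cross_entropy(probs: Tensor, domains: np.ndarray) -> Tensor:
    """Mean -log p(true domain) over a (N, 2) row-stochastic tensor."""
    p_true = nn.gather_channel(
        probs.reshape(probs.shape[0], 2, 1, 1),
        domains.reshape(-1, 1, 1).astype(np.int64),
    )
    return -(p_true.clamp_min(1e-12).log()).mean()


def _mixed_batches(src, tgt, batch_size, rng):
    """Yield 50/50 source/target batches of (images, labels, domains, has_label)."""
    half = max(1, batch_size // 2)
    n_steps = max(min(len(src), len(tgt)) // half, 1)
    src_order = rng.permutation(len(src))
    tgt_order = rng.permutation(len(tgt))
    for step in range(n_steps):
        s_idx = src_order[(step * half) % len(src):][:half]
        t_idx = tgt_order[(step * half) % len(tgt):][:half]
        picks = [src[i] + (0,) for i in s_idx] + [tgt[i] + (1,) for i in t_idx]
        images = np.stack([p[0] for p in picks])
        labels = [p[1] for p in picks]
        domains = np.array([p[2] for p in picks], dtype=np.int64)
        has_label = np.array([lab is not None for lab in labels], dtype=bool)
        yield images, labels, domains, has_label


def train_dann(ensemble: TriplanarEnsemble,
               source_cohort: list[Subject],
               target_cohort: list[Subject],
               dann: DannConfig = DannConfig(),
               config: TrainConfig = TrainConfig(),
               preproc: PreprocConfig | None = None,
               loss_weights: LossWeights = LossWeights(),
               planes: tuple[str, ...] = PLANES):
    """Adversarial training of the ensemble; returns (ensemble, heads, log).

    Source samples always carry lesion labels; target samples are unlabelled
    except for the semi-supervised subject subset (``dann.semi_fraction``).
    The domain loss is computed per-slice on every sample and backpropagated
    through the gradient-reversal layer into the shared trunk.
    """
    if not source_cohort or not target_cohort:
        raise ValueError("both cohorts must be nonempty")
    preproc = preproc or PreprocConfig()
    src_train, src_val = split_subjects(source_cohort, config.val_fraction, config.seed)
    tgt_train, tgt_val = split_subjects(target_cohort, config.val_fraction, config.seed + 1)
    semi_subjects = select_semi_subset(tgt_train, dann.semi_fraction, seed=config.seed)
    semi_ids = {s.subject_id for s in semi_subjects}

    rows: list[dict] = []
    heads: dict[str, DomainHead] = {}
    for plane in planes:
        net = ensemble.net(plane)
        src_samples = build_plane_dataset(src_train, plane, preproc)
        tgt_labelled = build_plane_dataset(
            [s for s in tgt_train if s.subject_id in semi_ids], plane, preproc,
            with_labels=True) if semi_ids else []
        tgt_unlabelled = build_plane_dataset(
            [s for s in tgt_train if s.subject_id not in semi_ids], plane, preproc,
            with_labels=False)
        tgt_samples = tgt_labelled + tgt_unlabelled
        if not src_samples or not tgt_samples:
            raise ValueError(f"no usable {plane} slices")
        val_samples = build_plane_dataset(src_val, plane, preproc)

        # shape the head from a probe forward pass
        probe = Tensor(src_samples[0][0][None])
        net.eval()
        net(probe)
        net.train()
        c, h, w = net.taps["bottleneck"].shape[1:]
        head = build_domain_head(c, (h, w), dann,
                                 seed=config.seed + zlib.crc32(plane.encode()) % 1000)
        heads[plane] = head

        opt_main = nn.Adam(net.parameters(), lr=dann.main_lr, eps=config.adam_eps)
        opt_dom = nn.SGD(head.parameters(), lr=dann.domain_lr,
                         momentum=dann.domain_momentum)
        rng = np.random.default_rng(np.random.SeedSequence(
            [zlib.crc32(plane.encode()), config.seed, 7]))

        best_val, best_state, wait = np.inf, None, 0
        for epoch in range(config.max_epochs):
            opt_main.lr = min(lr_schedule(epoch, config), dann.main_lr)
            seg_sum = dom_sum = 0.0
            dom_correct = dom_total = 0
            n_steps = 0
            for images, labels, domains, has_label in _mixed_batches(
                    src_samples, tgt_samples, config.batch_size, rng):
                if not has_label.any():
                    raise ValueError("no label-available samples in batch")
                opt_main.zero_grad()
                opt_dom.zero_grad()
                # segmentation pass on labelled samples only
                lab_imgs = images[has_label]
                lab_arr = np.stack([lab for lab in labels if lab is not None])
                probs = net(Tensor(lab_imgs))
                seg_loss = combined_loss(probs, lab_arr, loss_weights)
                seg_loss.backward()
                # adversarial domain pass on the full mixed batch
                net(Tensor(images))
                tap = net.taps["bottleneck"]
                dom_probs = head(grad_reverse(tap, dann.grl_lambda))
                dom_loss = domain_cross_entropy(dom_probs, domains)
                dom_loss.backward()
                opt_main.step()
                opt_dom.step()
                seg_sum += seg_loss.item()
                dom_sum += dom_loss.item()
                dom_correct += int((dom_probs.numpy().argmax(1) == domains).sum())
                dom_total += len(domains)
                n_steps += 1
            val_loss = _validation_loss(net, val_samples, config.batch_size, loss_weights)
            rows.append({"plane": plane, "epoch": epoch,
                         "seg_loss": seg_sum / n_steps, "domain_loss": dom_sum / n_steps,
                         "domain_accuracy": dom_correct / dom_total,
                         "val_loss": val_loss})
            if val_loss < best_val - 1e-9:
                best_val, wait = val_loss, 0
                best_state = (net.state_dict(), head.state_dict())
            elif epoch >= config.pretrain_epochs:
                wait += 1
                if wait >= config.patience:
                    break
        if best_state is not None:
            net.load_state_dict(best_state[0])
            head.load_state_dict(best_state[1])
    return ensemble, heads, pd.DataFrame(rows)


def _validation_loss(net, samples, batch_size, loss_weights):
    if not samples:
        return np.nan
    net.eval()
    total, count = 0.0, 0
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        images = np.stack([c[0] for c in chunk])
        labels = np.stack([c[1] for c in chunk])
        total += combined_loss(net(Tensor(images)), labels, loss_weights).item() * len(chunk)
        count += len(chunk)
    net.train()
    return total / count


def extract_features(ensemble: TriplanarEnsemble, subjects: list[Subject],
                     tap: str = "bottleneck",
                     preproc: PreprocConfig | None = None,
                     plane: str = "axial",
                     batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Spatially pooled per-slice feature vectors with 0/1 domain labels.

    `tap` is ``"bottleneck"`` or ``"pre_label_predictor"`` (the layer before
    the label predictor, as used for neighbour-embedding diagnostics).
    """
    if tap not in ("bottleneck", "pre_label_predictor"):
        raise ValueError(f"unknown tap {tap!r}")
    preproc = preproc or PreprocConfig()
    net = ensemble.net(plane)
    was_training = net.training
    net.eval()
    domains = sorted({s.domain for s in subjects})
    feats, labels = [], []
    for subject in subjects:
        samples = build_plane_dataset([subject], plane, preproc, with_labels=False)
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            images = np.stack([c[0] for c in chunk])
            net(Tensor(images))
            f = net.taps[tap].numpy().mean(axis=(2, 3))
            feats.append(f)
            labels.extend([domains.index(subject.domain)] * len(chunk))
    net.train(was_training)
    return np.concatenate(feats, axis=0), np.array(labels)
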