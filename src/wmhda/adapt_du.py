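"""Iterative domain unlearning (DU).

Each iteration runs three sequential updates on a mixed-domain batch:
(1) feature extractor + label predictor on the segmentation loss,
(2) the domain-predictor head alone on the domain cross-entropy with the
features fixed, and (3) the feature extractor alone on a beta-weighted
confusion loss (cross-entropy toward the uniform domain posterior) with the
head fixed. The head attaches at the pre-label-predictor decoder tap through
repeated 2x2 max-pooling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .adapt_dann import _mixed_batches, _validation_loss, domain_cross_entropy
from .model import LossWeights, PlanarUNet, TriplanarEnsemble, combined_loss
from .nn import Tensor
from .preproc import PLANES, PreprocConfig
from .synthgen import Subject
from .training import TrainConfig, build_plane_dataset, lr_schedule, split_subjects

__all__ = [
    "DuConfig",
    "DuDomainHead",
    "build_du_domain_head",
    "confusion_loss",
    "du_iteration",
    "du_step_segmentation",
    "du_step_domain",
    "du_step_confusion",
    "train_du",
    "tune_beta",
    "label_predictor_parameters",
    "feature_extractor_parameters",
]


@dataclass(frozen=True)
class DuConfig:
    beta: float = 50.0
    fc_widths: tuple[int, int, int] = (468, 96, 32)
    dropout: float = 0.2
    #: learning rate of the domain predictor (step 2, Adam)
    lr: float = 1e-4
    #: learning rate of the confusion update (step 3); not pinned anywhere,
    #: defaults to the baseline feature-learning rate
    confusion_lr: float = 1e-3
    #: learning rate of the segmentation update (step 1), as in baseline training
    main_lr: float = 1e-3
    beta_grid: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0, 60.0)

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not self.beta_grid:
            raise ValueError("beta grid must be nonempty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class DuDomainHead(nn.Module):
    """Repeated 2x2 max-pooling down to the first FC width, then FC stack."""

    def __init__(self, in_channels: int, spatial: tuple[int, int],
                 config: DuConfig = DuConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        f1, f2, f3 = config.fc_widths
        h, w = spatial
        n_pools = 0
        while in_channels * h * w > f1 and (h >= 2 and w >= 2):
            h, w = h // 2, w // 2
            n_pools += 1
        flat = in_channels * h * w
        if flat > f1:
            raise ValueError(
                f"cannot pool {in_channels}x{spatial[0]}x{spatial[1]} down to <= {f1}; "
                f"achievable flattened size is {flat}")
        self.n_pools = n_pools
        self.fc1 = nn.Linear(flat, f1, rng=rng)
        self.drop1 = nn.Dropout(config.dropout, rng=np.random.default_rng(seed + 1))
        self.fc2 = nn.Linear(f1, f2, rng=rng)
        self.drop2 = nn.Dropout(config.dropout, rng=np.random.default_rng(seed + 2))
        self.fc3 = nn.Linear(f2, f3, rng=rng)
        self.out = nn.Linear(f3, 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for _ in range(self.n_pools):
            x = nn.maxpool2d(x, 2)
        x = x.flatten_batch()
        x = self.drop1(self.fc1(x).relu())
        x = self.drop2(self.fc2(x).relu())
        x = self.fc3(x).relu()
        return nn.softmax(self.out(x), axis=1)


def build_du_domain_head(tap_shape: tuple[int, int, int],
                         config: DuConfig = DuConfig(), seed: int = 0) -> DuDomainHead:
    """Head for a (channels, height, width) pre-label-predictor tap."""
    c, h, w = tap_shape
    return DuDomainHead(c, (h, w), config, seed)


def confusion_loss(domain_probs: Tensor, beta: float) -> Tensor:
    """beta x mean cross-entropy between predictions and the uniform posterior.

    Minimal (= beta ln 2 for two domains) exactly when every row is uniform.
    """
    p = domain_probs
    sums = p.numpy().sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("domain probabilities must be row-normalised")
    k = p.shape[1]
    return -beta * (p.clamp_min(1e-12).log().sum(axis=1) / k).mean()


def label_predictor_parameters(net: PlanarUNet) -> list:
    """Final decoder conv block + output projection (+ softmax)."""
    names = {n for n, _ in net.named_parameters()
             if n.startswith(f"decoders.{len(net.decoders) - 1}.") or n.startswith("outc.")}
    return [p for n, p in net.named_parameters() if n in names]


def feature_extractor_parameters(net: PlanarUNet) -> list:
    label_ids = {id(p) for p in label_predictor_parameters(net)}
    return [p for p in net.parameters() if id(p) not in label_ids]


def du_step_segmentation(net: PlanarUNet, images, labels, has_label,
                         opt_main, loss_weights: LossWeights = LossWeights()) -> float:
    """Step 1: update feature extractor + label predictor on the seg loss."""
    opt_main.zero_grad()
    lab_imgs = images[has_label]
    lab_arr = np.stack([lab for lab in labels if lab is not None])
    probs = net(Tensor(lab_imgs))
    seg_loss = combined_loss(probs, lab_arr, loss_weights)
    seg_loss.backward()
    opt_main.step()
    return seg_loss.item()


def du_step_domain(net: PlanarUNet, head: DuDomainHead, images, domains,
                   opt_head) -> tuple[float, float]:
    """Step 2: update the head alone (trunk in eval mode, tap detached)."""
    opt_head.zero_grad()
    net.eval()
    net(Tensor(images))
    tap = net.taps["pre_label_predictor"].detach()
    net.train()
    dom_probs = head(tap)
    dom_loss = domain_cross_entropy(dom_probs, domains)
    dom_loss.backward()
    opt_head.step()
    acc = float((dom_probs.numpy().argmax(1) == domains).mean())
    return dom_loss.item(), acc


def du_step_confusion(net: PlanarUNet, head: DuDomainHead, images,
                      config: DuConfig, opt_feat) -> float:
    """Step 3: update the feature extractor alone on the confusion loss."""
    opt_feat.zero_grad()
    for p in head.parameters():
        p.requires_grad = False
    head.eval()
    net(Tensor(images))
    conf_probs = head(net.taps["pre_label_predictor"])
    conf_loss = confusion_loss(conf_probs, config.beta)
    conf_loss.backward()
    opt_feat.step()
    head.train()
    for p in head.parameters():
        p.requires_grad = True
    return conf_loss.item()


def du_iteration(net: PlanarUNet, head: DuDomainHead,
                 images: np.ndarray, labels: list, domains: np.ndarray,
                 has_label: np.ndarray,
                 config: DuConfig,
                 opt_main, opt_head, opt_feat,
                 loss_weights: LossWeights = LossWeights()) -> dict:
    """One three-step DU update on a mixed batch; returns the step losses."""
    if len(np.unique(domains)) < 2:
        raise ValueError("DU batches must contain both domains")
    if not has_label.any():
        raise ValueError("DU batches need labelled (source) samples")
    seg = du_step_segmentation(net, images, labels, has_label, opt_main, loss_weights)
    dom, acc = du_step_domain(net, head, images, domains, opt_head)
    conf = du_step_confusion(net, head, images, config, opt_feat)
    return {"seg_loss": seg, "domain_loss": dom,
            "confusion_loss": conf, "domain_accuracy": acc}


def train_du(ensemble: TriplanarEnsemble,
             source_cohort: list[Subject],
             target_cohort: list[Subject],
             du: DuConfig = DuConfig(),
             config: TrainConfig = TrainConfig(),
             preproc: PreprocConfig | None = None,
             loss_weights: LossWeights = LossWeights(),
             planes: tuple[str, ...] = PLANES):
    """Iterative unlearning over mixed batches; returns (ensemble, heads, log)."""
    if not source_cohort or not target_cohort:
        raise ValueError("both cohorts must be nonempty")
    preproc = preproc or PreprocConfig()
    src_train, src_val = split_subjects(source_cohort, config.val_fraction, config.seed)
    tgt_train, _ = split_subjects(target_cohort, config.val_fraction, config.seed + 1)

    rows: list[dict] = []
    heads: dict[str, DuDomainHead] = {}
    for plane in planes:
        net = ensemble.net(plane)
        src_samples = build_plane_dataset(src_train, plane, preproc)
        tgt_samples = build_plane_dataset(tgt_train, plane, preproc, with_labels=False)
        val_samples = build_plane_dataset(src_val, plane, preproc)
        if not src_samples or not tgt_samples:
            raise ValueError(f"no usable {plane} slices")

        probe = Tensor(src_samples[0][0][None])
        net.eval()
        net(probe)
        net.train()
        head = build_du_domain_head(tuple(net.taps["pre_label_predictor"].shape[1:]),
                                    du, seed=config.seed + zlib.crc32(plane.encode()) % 1000)
        heads[plane] = head

        opt_main = nn.Adam(net.parameters(), lr=du.main_lr, eps=config.adam_eps)
        opt_head = nn.Adam(head.parameters(), lr=du.lr, eps=config.adam_eps)
        opt_feat = nn.Adam(feature_extractor_parameters(net), lr=du.confusion_lr,
                           eps=config.adam_eps)
        rng = np.random.default_rng(np.random.SeedSequence(
            [zlib.crc32(plane.encode()), config.seed, 13]))

        best_val, best_state, wait = np.inf, None, 0
        for epoch in range(config.max_epochs):
            opt_main.lr = min(lr_schedule(epoch, config), du.main_lr)
            opt_feat.lr = du.confusion_lr
            sums = {"seg_loss": 0.0, "domain_loss": 0.0, "confusion_loss": 0.0,
                    "domain_accuracy": 0.0}
            n_steps = 0
            for images, labels, domains, has_label in _mixed_batches(
                    src_samples, tgt_samples, config.batch_size, rng):
                step = du_iteration(net, head, images, labels, domains, has_label,
                                    du, opt_main, opt_head, opt_feat, loss_weights)
                for k in sums:
                    sums[k] += step[k]
                n_steps += 1
            val_loss = _validation_loss(net, val_samples, config.batch_size, loss_weights)
            rows.append({"plane": plane, "epoch": epoch,
                         **{k: v / n_steps for k, v in sums.items()},
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


def tune_beta(candidates, accuracies) -> float:
    """argmin |validation domain accuracy - 0.5|; ties -> smaller beta."""
    candidates = list(candidates)
    accuracies = list(accuracies)
    if not candidates:
        raise ValueError("empty beta grid")
    if len(candidates) != len(accuracies):
        raise ValueError("one accuracy per candidate required")
    order = sorted(zip(candidates, accuracies), key=lambda t: (abs(t[1] - 0.5), t[0]))
    return order[0][0]
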