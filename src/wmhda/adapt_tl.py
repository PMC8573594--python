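"""Transfer-learning adaptation: freeze all but the last i layer-blocks of a
source-trained ensemble and fine-tune on target subjects with a reduced
learning-rate schedule; includes the subjects x layers sweep.

Blocks are numbered from the decoder end: 1 = output projection, 2 = final
decoder conv block (with its up-convolution), 3 = bottleneck plus the
remaining decoder path ("end of the encoder"), then one block per encoder
level back to the input. Frozen blocks keep their batch-norm statistics
frozen as well.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import evaluate_subject
from .model import (
    PlanarUNet,
    TriplanarEnsemble,
    binarize,
    load_checkpoint,
    predict_volume,
    save_checkpoint,
)
from .nn import BatchNorm2d
from .preproc import PLANES, PreprocConfig
from .synthgen import Subject
from .training import AugmentConfig, TrainConfig, train_model

__all__ = [
    "LayerIndexMap",
    "TL_SCHEDULE",
    "layer_blocks",
    "freeze_for_finetune",
    "unfreeze_all",
    "finetune",
    "sweep",
    "frozen_parameter_hash",
]

#: fine-tuning schedule: initial 1e-4, /10 every 2 epochs, floor 1e-6
TL_SCHEDULE = dict(lr_init=1e-4, lr_factor=0.1, lr_step_epochs=2, lr_floor=1e-6)


@dataclass
class LayerIndexMap:
    """Ordered blocks 1..L from the decoder end partitioning all parameters."""

    blocks: dict[int, list[str]]          # block index -> parameter names
    parameter_counts: dict[int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _block_of(param_name: str, depth: int) -> int:
    """Map a planar-network parameter name to its block index."""
    parts = param_name.split(".")
    head = parts[0]
    n_enc = depth - 1
    if head == "outc":
        return 1
    if head in ("decoders", "upconvs"):
        level = int(parts[1])  # 0 = coarsest decoder level
        if level == n_enc - 1:  # finest (final) decoder block
            return 2
        return 3  # intermediate decoder path rides with the bottleneck
    if head == "bottleneck":
        return 3
    if head == "encoders":
        level = int(parts[1])  # 0 = finest encoder level
        return 3 + (n_enc - level)
    raise ValueError(f"unrecognised parameter {param_name!r}")


def layer_blocks(net: PlanarUNet) -> LayerIndexMap:
    """Partition a planar network's parameters into decoder-end-first blocks."""
    depth = net.config.depth
    blocks: dict[int, list[str]] = {}
    counts: dict[int, int] = {}
    for name, param in net.named_parameters():
        b = _block_of(name, depth)
        blocks.setdefault(b, []).append(name)
        counts[b] = counts.get(b, 0) + param.data.size
    missing = set(range(1, max(blocks) + 1)) - set(blocks)
    if missing:
        raise ValueError(f"unassigned blocks {missing}; unknown architecture")
    return LayerIndexMap(blocks={k: sorted(v) for k, v in sorted(blocks.items())},
                         parameter_counts=dict(sorted(counts.items())))


def _set_block_trainable(net: PlanarUNet, index_map: LayerIndexMap,
                         trainable_blocks: set[int]) -> None:
    name_to_block = {name: b for b, names in index_map.blocks.items() for name in names}
    for name, param in net.named_parameters():
        param.requires_grad = name_to_block[name] in trainable_blocks
    # freeze batch-norm statistics inside frozen blocks
    def visit(module, prefix=""):
        for attr, child in module._children():
            full = f"{prefix}{attr}"
            if isinstance(child, BatchNorm2d):
                block = name_to_block[f"{full}.weight"]
                child.frozen = block not in trainable_blocks
            visit(child, f"{full}.")
    visit(net)


def freeze_for_finetune(ensemble: TriplanarEnsemble, i: int) -> TriplanarEnsemble:
    """Keep blocks 1..i trainable, freeze blocks i+1..L, in every plane."""
    index_map = layer_blocks(ensemble.net("axial"))
    if not 1 <= i <= index_map.n_blocks:
        raise ValueError(f"layers-to-tune must be in [1, {index_map.n_blocks}]")
    for plane in PLANES:
        net = ensemble.net(plane)
        _set_block_trainable(net, layer_blocks(net), set(range(1, i + 1)))
    return ensemble


def unfreeze_all(ensemble: TriplanarEnsemble) -> TriplanarEnsemble:
    for plane in PLANES:
        net = ensemble.net(plane)
        for _, p in net.named_parameters():
            p.requires_grad = True
        _set_block_trainable(net, layer_blocks(net),
                             set(layer_blocks(net).blocks))
    return ensemble


def frozen_parameter_hash(ensemble: TriplanarEnsemble) -> str:
    """SHA-256 over the bytes of all non-trainable parameters."""
    h = hashlib.sha256()
    for plane in PLANES:
        for name, p in sorted(ensemble.net(plane).named_parameters()):
            if not p.requires_grad:
                h.update(name.encode())
                h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def finetune(ensemble: TriplanarEnsemble, target_cohort: list[Subject],
             i: int, n_subjects: int | None = None,
             config: TrainConfig | None = None,
             augment: AugmentConfig | None = None,
             preproc: PreprocConfig | None = None,
             planes: tuple[str, ...] = PLANES,
             seed: int = 0) -> TriplanarEnsemble:
    """Fine-tune blocks 1..i of a source-pretrained ensemble on target data."""
    if n_subjects is not None:
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if n_subjects > len(target_cohort):
            raise ValueError("n_subjects exceeds cohort size")
        target_cohort = target_cohort[:n_subjects]
    base = config or TrainConfig()
    tl_config = replace(base, **TL_SCHEDULE, seed=seed)
    freeze_for_finetune(ensemble, i)
    train_model(ensemble, target_cohort, tl_config, augment=augment,
                preproc=preproc, planes=planes)
    return ensemble


def sweep(source_ckpt_path, target_train: list[Subject], target_test: list[Subject],
          subject_counts: list[int], layer_counts: list[int],
          config: TrainConfig | None = None,
          preproc: PreprocConfig | None = None,
          augment: AugmentConfig | None = None,
          planes: tuple[str, ...] = PLANES,
          threshold: float = 0.5,
          seed: int = 0) -> dict[str, pd.DataFrame]:
    """Mean test metrics over the (n_subjects x layers) fine-tuning grid.

    Returns one DataFrame per metric with rows indexed by subject count and
    columns by layer count. Each cell retrains from the source checkpoint.
    """
    if not subject_counts or not layer_counts:
        raise ValueError("subject_counts and layer_counts must be nonempty")
    if max(subject_counts) > len(target_train):
        raise ValueError("subject_counts exceed available target subjects")
    metric_names = ["si", "voxel_tpr", "voxel_fpr", "cluster_tpr",
                    "cluster_precision", "cluster_f1", "lavd"]
    grids = {m: pd.DataFrame(index=subject_counts, columns=layer_counts, dtype=float)
             for m in metric_names}
    for n in subject_counts:
        for i in layer_counts:
            ens = load_checkpoint(source_ckpt_path)
            finetune(ens, target_train, i=i, n_subjects=n, config=config,
                     augment=augment, preproc=preproc, planes=planes, seed=seed)
            reports = []
            for subject in target_test:
                prob = predict_volume(ens, subject, preproc, planes=planes)
                pred = binarize(prob, threshold)
                reports.append(evaluate_subject(pred, subject.lesion_mask,
                                                subject.voxel_dims))
            for m in metric_names:
                grids[m].loc[n, i] = float(np.mean([getattr(r, m) for r in reports]))
    return grids
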