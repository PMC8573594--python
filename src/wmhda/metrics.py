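"""Voxel- and cluster-wise segmentation metrics, a paired sign-flip
permutation test, and a feature-space domain-accuracy probe.

Cluster-wise quantities use 26-connected components: a true cluster counts
as detected if it overlaps at least one predicted voxel, and a predicted
cluster counts as a true positive if it overlaps at least one true voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import product

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

__all__ = [
    "MetricsReport",
    "dice_si",
    "voxel_rates",
    "label_clusters_26",
    "cluster_metrics",
    "lavd",
    "evaluate_subject",
    "paired_permutation_test",
    "max_t_correction",
    "domain_accuracy_probe",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MetricsReport:
    """Per-subject evaluation summary."""

    si: float
    voxel_tpr: float
    voxel_fpr: float
    cluster_tpr: float
    cluster_precision: float
    cluster_f1: float
    lavd: float
    n_true_clusters: int
    n_pred_clusters: int
    n_tp_clusters: int

    def as_dict(self) -> dict:
        return asdict(self)


def _check_masks(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    return pred.astype(bool), true.astype(bool)


def dice_si(pred: np.ndarray, true: np.ndarray) -> float:
    """Dice similarity index 2*TP / (|true| + |pred|); 1.0 if both empty."""
    pred, true = _check_masks(pred, true)
    denom = int(true.sum()) + int(pred.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & true).sum()) / denom


def voxel_rates(pred: np.ndarray, true: np.ndarray,
                region: np.ndarray | None = None) -> tuple[float, float]:
    """(TPR, FPR). TPR = TP/|true|; FPR = FP / #non-true voxels.

    If `region` (e.g. a brain mask) is given, the FPR denominator is
    restricted to non-true voxels inside it. An empty true mask makes TPR
    undefined and raises.
    """
    pred, true = _check_masks(pred, true)
    n_true = int(true.sum())
    if n_true == 0:
        raise ValueError("voxel TPR is undefined for an empty true mask")
    tp = int((pred & true).sum())
    if region is not None:
        region = np.asarray(region).astype(bool)
        neg = region & ~true
        fp = int((pred & neg).sum())
    else:
        neg = ~true
        fp = int((pred & neg).sum())
    n_neg = int(neg.sum())
    fpr = fp / n_neg if n_neg else 0.0
    return tp / n_true, fpr


def label_clusters_26(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected component labelling of a binary 3D mask."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("cluster labelling requires a 3D mask")
    return ndimage.label(mask.astype(bool), structure=_STRUCT_26)


def cluster_metrics(pred: np.ndarray, true: np.ndarray) -> tuple[float, float, float]:
    """(cluster TPR, cluster precision, cluster F1) under any-overlap matching."""
    pred, true = _check_masks(pred, true)
    true_lab, n_true = label_clusters_26(true)
    pred_lab, n_pred = label_clusters_26(pred)

    if n_true:
        hit_true = np.unique(true_lab[pred & true])
        tp_true = int((hit_true > 0).sum())
        tpr = tp_true / n_true
    else:
        tpr = 0.0
    if n_pred:
        hit_pred = np.unique(pred_lab[pred & true])
        tp_pred = int((hit_pred > 0).sum())
        precision = tp_pred / n_pred
    else:
        precision = 0.0
    f1 = 0.0 if (tpr + precision) == 0 else 2 * tpr * precision / (tpr + precision)
    return tpr, precision, f1


def lavd(pred_volume: float, true_volume: float) -> float:
    """|ln(pred_volume / true_volume)| of lesion volumes (natural log)."""
    if pred_volume <= 0 or true_volume <= 0:
        raise ValueError("lAVD requires strictly positive volumes "
                         "(empty segmentation is a degenerate case)")
    return abs(float(np.log(pred_volume / true_volume)))


def evaluate_subject(pred: np.ndarray, true: np.ndarray,
                     voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     region: np.ndarray | None = None) -> MetricsReport:
    """All metrics for one subject. Volumes are in mm^3 via `voxel_dims`."""
    pred_b, true_b = _check_masks(pred, true)
    si = dice_si(pred_b, true_b)
    tpr, fpr = voxel_rates(pred_b, true_b, region=region)
    ctpr, cprec, cf1 = cluster_metrics(pred_b, true_b)
    vox = float(np.prod(voxel_dims))
    vol_metric = lavd(pred_b.sum() * vox, true_b.sum() * vox) if pred_b.any() and true_b.any() else (
        0.0 if not pred_b.any() and not true_b.any() else float("inf"))
    _, n_true = label_clusters_26(true_b)
    _, n_pred = label_clusters_26(pred_b)
    n_tp = round(ctpr * n_true)
    return MetricsReport(si, tpr, fpr, ctpr, cprec, cf1, vol_metric, n_true, n_pred, n_tp)


def paired_permutation_test(a: np.ndarray, b: np.ndarray,
                            n_permutations: int = 10000,
                            seed: int = 0) -> float:
    """Two-sided sign-flip permutation p-value for paired samples.

    The statistic is the mean paired difference. All 2^n sign patterns are
    enumerated when 2^n <= n_permutations (exact test); otherwise
    `n_permutations` random flips are drawn (the identity flip is always
    included, so p >= 1/(n_permutations+1)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    observed = abs(d.mean())
    if 2 ** n <= n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        stats = np.abs(signs @ d) / n
        return float((stats >= observed - 1e-15).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    stats = np.abs(signs @ d) / n
    count = int((stats >= observed - 1e-15).sum()) + 1  # include identity
    return count / (n_permutations + 1)


def max_t_correction(diff_matrix: np.ndarray, n_permutations: int = 10000,
                     seed: int = 0) -> np.ndarray:
    """Family-wise corrected p-values via the max-statistic over columns.

    `diff_matrix` is (n_subjects, n_tests) of paired differences; sign flips
    are shared across tests (subjects are the exchangeable units).
    """
    d = np.asarray(diff_matrix, dtype=float)
    if d.ndim != 2:
        raise ValueError("expected a (subjects, tests) matrix of differences")
    n, m = d.shape
    observed = np.abs(d.mean(axis=0))
    if 2 ** n <= n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
        signs[0] = 1.0
    stats = np.abs(signs @ d) / n          # (perms, tests)
    max_stats = stats.max(axis=1)          # (perms,)
    return np.array([
        (max_stats >= observed[j] - 1e-15).mean() for j in range(m)
    ])


def domain_accuracy_probe(features: np.ndarray, domains: np.ndarray,
                          seed: int = 0, test_fraction: float = 0.5) -> float:
    """Held-out accuracy of a linear probe predicting domain from features.

    ~0.5 indicates domain-confused features; high values indicate a
    remaining domain signal.
    """
    features = np.asarray(features, dtype=float)
    domains = np.asarray(domains)
    classes = np.unique(domains)
    if classes.size < 2:
        raise ValueError("need samples from at least two domains")
    counts = [int((domains == c).sum()) for c in classes]
    if min(counts) < 2:
        raise ValueError("need at least 2 samples per domain")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, domains, test_size=test_fraction, random_state=seed,
        stratify=domains)
    mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0) + 1e-9
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit((x_tr - mu) / sd, y_tr)
    return float(clf.score((x_te - mu) / sd, y_te))
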