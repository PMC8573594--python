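"""Naive brute-force reference implementations used by the metric tests and
the acceptance suite. Deliberately independent of the package internals
(pure-python loops / BFS instead of scipy.ndimage)."""

from itertools import product

import numpy as np


def flood_components_26(mask):
    """26-connected components by BFS over voxel coordinates."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for o in offsets:
                w = tuple(np.add(v, o))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not labels[w]:
                        labels[w] = current
                        stack.append(w)
    return labels, current


def naive_counts(pred, true):
    """Voxel-wise TP/FP/FN/TN by explicit enumeration."""
    pred = np.asarray(pred, dtype=bool)
    true = np.asarray(true, dtype=bool)
    tp = fp = fn = tn = 0
    for v in zip(*np.nonzero(np.ones(pred.shape, dtype=bool))):
        p, t = pred[v], true[v]
        tp += p and t
        fp += p and not t
        fn += (not p) and t
        tn += (not p) and (not t)
    return tp, fp, fn, tn


def naive_report(pred, true):
    """(si, tpr, fpr, cluster_tpr, cluster_precision, cluster_f1)."""
    pred = np.asarray(pred, dtype=bool)
    true = np.asarray(true, dtype=bool)
    tp, fp, fn, tn = naive_counts(pred, true)
    si = 1.0 if (tp + fp + fn) == 0 else 2 * tp / ((tp + fn) + (tp + fp))
    tpr = tp / (tp + fn) if (tp + fn) else None
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    tl, nt = flood_components_26(true)
    pl, npred = flood_components_26(pred)
    hit_t = {tl[v] for v in zip(*np.nonzero(true & pred))}
    hit_p = {pl[v] for v in zip(*np.nonzero(true & pred))}
    ctpr = len(hit_t) / nt if nt else 0.0
    cprec = len(hit_p) / npred if npred else 0.0
    cf1 = 0.0 if ctpr + cprec == 0 else 2 * ctpr * cprec / (ctpr + cprec)
    return si, tpr, fpr, ctpr, cprec, cf1
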