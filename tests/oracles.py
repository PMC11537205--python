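"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: optimal one-to-one
matching is found by exhaustive search over assignments, and random matching
fixtures are built from perturbed disks.
"""

import numpy as np

from phenogate import InstanceMap
from phenogate.metrics import pairwise_iou


def optimal_one_to_one(pred, gt, threshold):
    """Exhaustive best one-to-one matching maximizing (pair count, total IoU)."""
    cand = pairwise_iou(pred, gt)
    cand = cand[cand["iou"] > threshold]
    edges = [(int(r.pred_id), int(r.gt_id), float(r.iou)) for r in cand.itertuples(index=False)]
    best = {"count": -1, "iou": -1.0, "pairs": []}

    def rec(i, used_p, used_g, pairs, total):
        if i == len(edges):
            if (len(pairs), total) > (best["count"], best["iou"]):
                best.update(count=len(pairs), iou=total, pairs=list(pairs))
            return
        p, g, iou = edges[i]
        rec(i + 1, used_p, used_g, pairs, total)  # skip edge
        if p not in used_p and g not in used_g:
            rec(i + 1, used_p | {p}, used_g | {g}, pairs + [(p, g, iou)], total + iou)

    rec(0, frozenset(), frozenset(), [], 0.0)
    return best["pairs"]


def random_blob_fixture(rng, shape=(48, 48), max_instances=6, res=0.5):
    """Ground-truth disks plus jittered/dropped/added predicted disks."""

    def paint(specs):
        labels = np.zeros(shape, dtype=np.int32)
        rr, cc = np.indices(shape)
        for i, (r0, c0, rad) in enumerate(specs, start=1):
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            labels[mask & (labels == 0)] = i
        return InstanceMap(labels, res)

    k = int(rng.integers(1, max_instances + 1))
    gt_specs = [
        (rng.uniform(6, shape[0] - 6), rng.uniform(6, shape[1] - 6), rng.uniform(3, 6))
        for _ in range(k)
    ]
    pred_specs = []
    for r0, c0, rad in gt_specs:
        if rng.random() < 0.15:  # missed instance
            continue
        pred_specs.append(
            (r0 + rng.normal(0, 2.0), c0 + rng.normal(0, 2.0), rad * rng.uniform(0.7, 1.3))
        )
    if rng.random() < 0.3:  # spurious prediction
        pred_specs.append(
            (rng.uniform(6, shape[0] - 6), rng.uniform(6, shape[1] - 6), rng.uniform(3, 6))
        )
    return paint(pred_specs), paint(gt_specs)


def friedman_no_ties_oracle(values):
    """Textbook untied Friedman statistic: 12/(nk(k+1)) * sum S_j^2 - 3n(k+1)."""
    from scipy.stats import rankdata

    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.vstack([rankdata(row) for row in values])
    S = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float(np.sum(S**2)) - 3.0 * n * (k + 1)
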