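"""Evaluation suite: lenient IoU instance matching, detection metrics,
per-class PPV/NPV/prevalence, parent-class bounded metrics, DQ+, and the
Friedman cross-site test.

Instance matching is one-to-one and *lenient*: a predicted and a ground-truth
instance may be paired whenever their IoU strictly exceeds the threshold
(default 0.25), accepted greedily in descending IoU order.  The lenient
threshold absorbs systematic differences in how tightly different label
sources crop instance boundaries.

When fine-grained predictions are scored against coarser parent labels, PPV
and NPV cannot be computed directly; :func:`bounded_metrics` computes the
optimistic upper bound on PPV and upper/lower bounds on NPV instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MappingError
from .image import DimensionError, InstanceMap
from .mapping import ClassMapping
from .rules import UNCLASSIFIED

DEFAULT_IOU_THRESHOLD = 0.25


@dataclass
class MatchResult:
    """One-to-one instance correspondences above an IoU threshold."""

    pairs: list[tuple[int, int, float]]  # (pred id, gt id, IoU)
    unmatched_pred: list[int]  # false positives
    unmatched_gt: list[int]  # false negatives
    threshold: float = DEFAULT_IOU_THRESHOLD

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def n_fn(self) -> int:
        return len(self.unmatched_gt)


def pairwise_iou(pred: InstanceMap, gt: InstanceMap) -> pd.DataFrame:
    """IoU for every (pred id, gt id) pair with nonzero pixel overlap."""
    if pred.shape != gt.shape:
        raise DimensionError(f"pred shape {pred.shape} != gt shape {gt.shape}")
    p = pred.labels.ravel()
    g = gt.labels.ravel()
    both = (p > 0) & (g > 0)
    if not both.any():
        return pd.DataFrame(columns=["pred_id", "gt_id", "iou"])
    # joint histogram of overlapping (pred, gt) label pairs
    pk, gk = p[both].astype(np.int64), g[both].astype(np.int64)
    key = pk * (int(g.max()) + 1) + gk
    uniq, inter = np.unique(key, return_counts=True)
    pred_ids = uniq // (int(g.max()) + 1)
    gt_ids = uniq % (int(g.max()) + 1)
    area_p = np.bincount(p, minlength=int(p.max()) + 1)
    area_g = np.bincount(g, minlength=int(g.max()) + 1)
    union = area_p[pred_ids] + area_g[gt_ids] - inter
    return pd.DataFrame(
        {"pred_id": pred_ids, "gt_id": gt_ids, "iou": inter / union}
    )


def match_instances(
    pred: InstanceMap,
    gt: InstanceMap,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching of predicted to ground-truth instances.

    Candidate pairs with IoU *strictly greater than* the threshold are
    accepted in descending IoU order, skipping pairs whose pred or gt is
    already taken; ties are broken by smaller gt id, then smaller pred id.
    Leftover predictions are false positives, leftover ground-truth instances
    false negatives.
    """
    if not (0 < iou_threshold < 1):
        raise ConfigurationError("iou_threshold must lie in (0, 1)")
    cand = pairwise_iou(pred, gt)
    cand = cand[cand["iou"] > iou_threshold]
    cand = cand.sort_values(
        by=["iou", "gt_id", "pred_id"], ascending=[False, True, True], kind="mergesort"
    )
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for row in cand.itertuples(index=False):
        pi, gi = int(row.pred_id), int(row.gt_id)
        if pi in used_p or gi in used_g:
            continue
        pairs.append((pi, gi, float(row.iou)))
        used_p.add(pi)
        used_g.add(gi)
    unmatched_pred = [int(i) for i in pred.ids if int(i) not in used_p]
    unmatched_gt = [int(i) for i in gt.ids if int(i) not in used_g]
    return MatchResult(pairs, unmatched_pred, unmatched_gt, iou_threshold)


def detection_metrics(match: MatchResult) -> dict[str, float]:
    """Precision, recall, F1 and mean IoU over the true-positive pairs."""
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"empty denominator for {name}; reporting 0", stacklevel=2)
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "F1") if (precision + recall) else 0.0
    mean_iou = float(np.mean([iou for *_, iou in match.pairs])) if match.pairs else 0.0
    if not match.pairs:
        warnings.warn("no matched pairs; mean IoU reported as 0", stacklevel=2)
    return {"precision": precision, "recall": recall, "f1": f1, "mean_iou_tp": mean_iou}


# -- classification metrics ---------------------------------------------------


def paired_classes(
    match: MatchResult,
    pred_classes: Mapping[int, str],
    gt_classes: Mapping[int, str],
    population: str = "matched",
) -> pd.DataFrame:
    """Aligned (pred_class, gt_class) rows for classification scoring.

    ``population="matched"`` (predicted-centroid regime) keeps matched pairs
    only; ``population="all_gt"`` (ground-truth-centroid regime) keeps every
    ground-truth instance, with unmatched ones paired to "unclassified".
    """
    rows = [
        {"pred_class": pred_classes[p], "gt_class": gt_classes[g]} for p, g, _ in match.pairs
    ]
    if population == "all_gt":
        rows += [
            {"pred_class": UNCLASSIFIED, "gt_class": gt_classes[g]} for g in match.unmatched_gt
        ]
    elif population != "matched":
        raise ConfigurationError(f"unknown population {population!r}")
    return pd.DataFrame(rows, columns=["pred_class", "gt_class"])


def confusion_matrix(pairs: pd.DataFrame, class_names: Sequence[str]) -> pd.DataFrame:
    """Confusion matrix (rows = ground truth, columns = prediction)."""
    cm = pd.crosstab(pairs["gt_class"], pairs["pred_class"], dropna=False)
    cm = cm.reindex(index=class_names, columns=class_names, fill_value=0)
    cm.index.name = "gt_class"
    cm.columns.name = "pred_class"
    return cm


def classification_metrics(
    pairs: pd.DataFrame,
    class_names: Sequence[str] | None = None,
    exclude_unclassified: bool = True,
) -> pd.DataFrame:
    """Per-class accuracy, PPV, NPV and prevalence from (pred, gt) pairs.

    For class c: PPV = TP/(TP+FP) over predictions of c, NPV = TN/(TN+FN)
    over predictions of not-c, prevalence = ground-truth share of c.  Rows
    whose ground truth is "unclassified" are excluded by default.
    """
    if pairs.empty:
        raise ConfigurationError("no (pred, gt) pairs to score")
    df = pairs
    if exclude_unclassified:
        df = df[df["gt_class"] != UNCLASSIFIED]
    if class_names is None:
        class_names = sorted((set(df["gt_class"]) | set(df["pred_class"])) - {UNCLASSIFIED})
    unknown = (set(df["gt_class"]) | set(df["pred_class"])) - set(class_names) - {UNCLASSIFIED}
    if unknown:
        raise ConfigurationError(f"classes outside the fixed list: {sorted(unknown)}")
    gt = df["gt_class"].to_numpy()
    pr = df["pred_class"].to_numpy()
    n = len(df)
    out = []
    for c in class_names:
        tp = int(np.sum((pr == c) & (gt == c)))
        fp = int(np.sum((pr == c) & (gt != c)))
        fn = int(np.sum((pr != c) & (gt == c)))
        tn = n - tp - fp - fn
        out.append(
            {
                "class": c,
                "accuracy": (tp + tn) / n if n else np.nan,
                "ppv": tp / (tp + fp) if (tp + fp) else np.nan,
                "npv": tn / (tn + fn) if (tn + fn) else np.nan,
                "prevalence": (tp + fn) / n if n else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("class")


# -- parent-class bounded metrics ---------------------------------------------


def bounded_metrics(
    pairs: pd.DataFrame,
    mapping: ClassMapping,
    fine_classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bounds on PPV/NPV when fine predictions meet only parent ground truth.

    ``pairs`` needs columns ``pred_class`` (fine) and ``gt_parent``.  For fine
    class c with parent P = mapping(c):

    - ``ppv_upper`` = #(pred=c and gt_parent=P) / #(pred=c) — optimistic, since
      a parent-level agreement may still be the wrong sibling.
    - Over the negatives (pred != c): rows with gt_parent != P are definite
      true negatives; rows with gt_parent = P are ambiguous (could be c or a
      sibling).  ``npv_lower`` treats every ambiguous row as a false negative;
      ``npv_upper`` additionally credits ambiguous rows predicted as a
      *sibling* of c (same parent) as true negatives.
    """
    for col in ("pred_class", "gt_parent"):
        if col not in pairs.columns:
            raise ConfigurationError(f"pairs must have a {col!r} column")
    if fine_classes is None:
        fine_classes = sorted(set(pairs["pred_class"]) - {UNCLASSIFIED})
    pr = pairs["pred_class"].to_numpy()
    gp = pairs["gt_parent"].to_numpy()
    out = []
    for c in fine_classes:
        P = mapping.parent(c)  # raises MappingError when unmapped
        sibs = mapping.siblings(c)
        pred_c = pr == c
        n_pred = int(pred_c.sum())
        ppv_upper = float(np.sum(pred_c & (gp == P)) / n_pred) if n_pred else np.nan
        neg = ~pred_c
        n_neg = int(neg.sum())
        if n_neg:
            definite_tn = int(np.sum(neg & (gp != P)))
            ambiguous_sibling = int(
                np.sum(neg & (gp == P) & np.isin(pr, sorted(sibs))))
            npv_lower = definite_tn / n_neg
            npv_upper = (definite_tn + ambiguous_sibling) / n_neg
        else:
            npv_lower = npv_upper = np.nan
        out.append(
            {
                "class": c,
                "parent": P,
                "ppv_upper": ppv_upper,
                "npv_lower": npv_lower,
                "npv_upper": npv_upper,
            }
        )
    return pd.DataFrame(out).set_index("class")


def prevalence_normalized_ppv(ppv_upper: float, prevalence: float) -> float:
    """Upper-bound PPV divided by class prevalence; NaN when prevalence is 0.

    A ratio of 1.0 is chance level: a predictor ignoring the input scores
    PPV equal to prevalence.
    """
    if prevalence is None or not np.isfinite(prevalence) or prevalence <= 0:
        return float("nan")
    return float(ppv_upper) / float(prevalence)


# -- DQ+ ----------------------------------------------------------------------


def dq_plus(
    match: MatchResult,
    pred_classes: Mapping[int, str],
    gt_classes: Mapping[int, str],
    parent_mode: bool = False,
    mapping: ClassMapping | None = None,
    classes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-class detection quality DQ+ = TP / (TP + FP/2 + FN/2).

    Fine mode scores predictions against same-granularity ground truth with
    the full panoptic detection-quality term.  Parent mode (``mapping``
    required) scores fine predictions of class c against parent labels
    optimistically: a match whose ground-truth parent equals mapping(c) counts
    as TP even though it might belong to a sibling, and the FN term is dropped
    because an unexplained parent-class instance cannot be attributed to any
    specific fine class.  The parent-mode value is therefore an upper bound on
    the fine-mode DQ+ of the same class.  Classes with no predictions and no
    ground truth get NaN.
    """
    if parent_mode and mapping is None:
        raise ConfigurationError("parent_mode requires a class mapping")
    if classes is None:
        classes = sorted(set(pred_classes.values()) - {UNCLASSIFIED})
    matched_pred = {p: g for p, g, _ in match.pairs}
    out: dict[str, float] = {}
    for c in classes:
        target = mapping.parent(c) if parent_mode else c
        tp = sum(
            1 for p, g in matched_pred.items() if pred_classes[p] == c and gt_classes[g] == target
        )
        fp = sum(1 for p in match.unmatched_pred if pred_classes[p] == c)
        fp += sum(
            1 for p, g in matched_pred.items() if pred_classes[p] == c and gt_classes[g] != target
        )
        if parent_mode:
            fn = 0
        else:
            fn = sum(1 for g in match.unmatched_gt if gt_classes[g] == c)
            fn += sum(
                1 for p, g in matched_pred.items() if gt_classes[g] == c and pred_classes[p] != c
            )
        denom = tp + 0.5 * fp + 0.5 * fn
        out[c] = tp / denom if denom > 0 else float("nan")
    return out


# -- Friedman test ------------------------------------------------------------


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across k treatments over n matched blocks.

    Rows are blocks, columns treatments.  Within-block average ranks with the
    standard tie correction; the statistic is chi-square distributed with k-1
    degrees of freedom.  Identical treatments within every block give
    statistic 0 and p = 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ConfigurationError("values must be an n x k matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ConfigurationError("need at least 2 blocks and 2 treatments")
    if not np.isfinite(values).all():
        raise ConfigurationError("missing or non-finite cells are not allowed")

    ranks = np.vstack([stats.rankdata(row) for row in values])
    rbar = ranks.mean(axis=0)
    chisq = 12.0 * n / (k * (k + 1)) * float(np.sum((rbar - (k + 1) / 2.0) ** 2))
    # tie correction
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    stat = chisq / correction
    p = float(stats.chi2.sf(stat, k - 1))
    return float(stat), p
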