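"""Classification dataset construction: centred patches, patient-level folds,
and class-balanced batch sampling.

Patches are 41x41 pixels at 0.5 um/px (20.5 x 20.5 um of tissue), centred on
the instance centroid (rounded to the nearest pixel, ties to even), padded by
edge replication at borders, and individually min-max normalized to [0, 1]
jointly across the color channels.  Constant patches map to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError
from .rules import UNCLASSIFIED

DEFAULT_PATCH_PX = 41
DEFAULT_RESOLUTION = 0.5


@dataclass
class PatchRecord:
    """One training/evaluation example: normalized pixels plus provenance."""

    pixels: np.ndarray  # (patch_px, patch_px, 3) float32 in [0, 1]
    label: str
    instance_id: int
    slide_id: str = ""
    patient_id: str = ""
    site_id: str = ""
    fold: int | None = None


def patch_physical_extent_um(patch_px: int = DEFAULT_PATCH_PX, resolution: float = DEFAULT_RESOLUTION) -> float:
    """Physical side length of a patch in micrometres."""
    return patch_px * resolution


def _normalize01(patch: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    lo, hi = float(patch.min()), float(patch.max())
    if hi - lo < eps:
        return np.zeros_like(patch, dtype=np.float32)
    return ((patch - lo) / (hi - lo)).astype(np.float32)


def extract_patches(
    color_image: np.ndarray,
    cells: pd.DataFrame,
    patch_px: int = DEFAULT_PATCH_PX,
    drop_unclassified: bool = True,
) -> list[PatchRecord]:
    """Extract centred, normalized patches for each cell-table row.

    ``color_image`` must already be at the target resolution.  Rows whose
    class is "unclassified" are skipped by default (they carry no trainable
    label).  Centroids are rounded to the nearest integer pixel with ties to
    even; out-of-bounds regions are filled by edge replication.
    """
    if patch_px % 2 == 0:
        raise ConfigurationError("patch_px must be odd (a unique centre pixel is required)")
    img = np.asarray(color_image, dtype=np.float32)
    if img.ndim == 2:
        img = img[..., None]
    half = patch_px // 2
    padded = np.pad(img, ((half, half), (half, half), (0, 0)), mode="edge")

    if "class" not in cells.columns:
        raise ConfigurationError("cell table must have a 'class' column")
    records: list[PatchRecord] = []
    for label in cells.to_dict("records"):
        cls = label["class"]
        if drop_unclassified and cls == UNCLASSIFIED:
            continue
        r = int(np.round(label["centroid_row"]))
        c = int(np.round(label["centroid_col"]))
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise ConfigurationError(f"centroid ({r}, {c}) outside image bounds {img.shape[:2]}")
        patch = padded[r : r + patch_px, c : c + patch_px]
        records.append(
            PatchRecord(
                pixels=_normalize01(patch),
                label=str(cls),
                instance_id=int(label["instance_id"]),
                slide_id=str(label.get("slide_id", "")),
                patient_id=str(label.get("patient_id", "")),
                site_id=str(label.get("site_id", "")),
            )
        )
    return records


# -- patient-level cross-validation folds ------------------------------------


@dataclass
class FoldSpec:
    """Per-fold disjoint patient lists for train/validation/test."""

    folds: list[dict[str, list[str]]]

    def __len__(self) -> int:
        return len(self.folds)

    def split(self, fold: int) -> tuple[list[str], list[str], list[str]]:
        f = self.folds[fold]
        return f["train"], f["val"], f["test"]

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps({"folds": self.folds}, indent=2))

    @classmethod
    def from_json(cls, path) -> "FoldSpec":
        from pathlib import Path

        return cls(json.loads(Path(path).read_text())["folds"])


def make_patient_folds(
    patients: Sequence[str] | Mapping[str, str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldSpec:
    """Patient-level cross-validation folds with tag stratification.

    ``patients`` is either a list of patient ids or a mapping from patient id
    to a stratification tag (e.g. ``"ileum/diseased"``).  Patients are
    shuffled within tag groups and dealt round-robin into ``n_folds`` groups,
    spreading every tag across groups as evenly as counts permit.  Fold ``i``
    tests on group ``i``, validates on group ``i+1 (mod n_folds)`` and trains
    on the rest, so each patient is tested exactly once and, with 20 patients
    and 5 folds, every fold is a 12/4/4 split.  Slides inherit their patient's
    split, so one patient's slides never straddle splits within a fold.
    """
    if isinstance(patients, Mapping):
        tags = {str(p): str(t) for p, t in patients.items()}
    else:
        tags = {str(p): "" for p in patients}
    ids = sorted(tags)
    if len(ids) < n_folds:
        raise ConfigurationError(f"{len(ids)} patients cannot fill {n_folds} folds")

    rng = np.random.default_rng(seed)
    groups: list[list[str]] = [[] for _ in range(n_folds)]
    slot = int(rng.integers(n_folds))  # rotate the deal so group sizes stay even
    for tag in sorted(set(tags.values())):
        members = [p for p in ids if tags[p] == tag]
        rng.shuffle(members)
        for p in members:
            groups[slot % n_folds].append(p)
            slot += 1

    folds = []
    for i in range(n_folds):
        test = sorted(groups[i])
        val = sorted(groups[(i + 1) % n_folds])
        train = sorted(p for j, g in enumerate(groups) if j not in (i, (i + 1) % n_folds) for p in g)
        folds.append({"train": train, "val": val, "test": test})
    return FoldSpec(folds)


def assign_slides_to_splits(roster: pd.DataFrame, spec: FoldSpec, fold: int) -> pd.DataFrame:
    """Annotate a slide roster (columns slide_id, patient_id) with its split for one fold."""
    train, val, test = spec.split(fold)
    lookup = {**{p: "train" for p in train}, **{p: "val" for p in val}, **{p: "test" for p in test}}
    out = roster.copy()
    out["split"] = out["patient_id"].map(lookup)
    return out


# -- class-balanced batch sampling -------------------------------------------


def balanced_batch_indices(
    labels: Sequence[str],
    batch_size: int = 256,
    class_names: Sequence[str] | None = None,
    seed: int = 0,
) -> Iterator[np.ndarray]:
    """Endless stream of index batches with equal per-class sampling odds.

    Each batch slot draws a class uniformly from ``class_names`` and then an
    example uniformly (with replacement) within that class, so each example
    has an equal likelihood of coming from any class regardless of the class
    imbalance of ``labels``.
    """
    labels = np.asarray(labels, dtype=object)
    if class_names is None:
        class_names = sorted(set(labels))
    pools = {c: np.flatnonzero(labels == c) for c in class_names}
    for c, pool in pools.items():
        if pool.size == 0:
            raise SamplingError(f"class {c!r} has no examples to sample from")
    rng = np.random.default_rng(seed)
    k = len(class_names)
    pool_list = [pools[c] for c in class_names]
    while True:
        cls_draw = rng.integers(k, size=batch_size)
        batch = np.empty(batch_size, dtype=np.int64)
        for ci in range(k):
            slots = np.flatnonzero(cls_draw == ci)
            if slots.size:
                pool = pool_list[ci]
                batch[slots] = pool[rng.integers(pool.size, size=slots.size)]
        yield batch
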