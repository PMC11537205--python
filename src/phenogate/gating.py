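"""Per-instance marker gating: mean intensities -> stain calls -> class labels.

The cell table is a plain :class:`pandas.DataFrame` with one row per instance:

- ``instance_id`` — positive integer id from the instance map
- ``centroid_row``, ``centroid_col`` — unweighted mean pixel coordinates (0-based)
- ``mean_<channel>`` — arithmetic mean stain intensity over the instance's pixels
- ``call_<channel>`` — boolean positivity call (mean strictly above threshold)
- ``class`` — assigned class, or ``"unclassified"`` when no rule matches
- ``slide_id``, ``patient_id``, ``site_id`` — provenance (optional)

Positivity is a strict inequality (mean > threshold), so a mean exactly at the
threshold is a negative call; the boundary is thereby deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .image import InstanceMap, MultiplexImage, check_same_shape
from .rules import RuleTable, UNCLASSIFIED

MEAN_PREFIX = "mean_"
CALL_PREFIX = "call_"


@dataclass
class ThresholdSet:
    """Per-channel positivity thresholds, scoped to one slide.

    Thresholds are intended to be picked per stain channel *per slide* (stain
    intensity scales drift between acquisitions), hence the slide scoping.
    """

    thresholds: dict[str, float]
    slide_id: str | None = None

    def require(self, channels) -> None:
        missing = [c for c in channels if c not in self.thresholds]
        if missing:
            raise ConfigurationError(
                f"no threshold for gating channel(s) {missing}"
                + (f" (slide {self.slide_id})" if self.slide_id else "")
            )

    def to_json(self, path: str | Path) -> None:
        slide = self.slide_id if self.slide_id is not None else "default"
        Path(path).write_text(json.dumps({slide: self.thresholds}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path, slide_id: str | None = None) -> "ThresholdSet":
        payload = json.loads(Path(path).read_text())
        if slide_id is None:
            if len(payload) != 1:
                raise ConfigurationError(
                    f"threshold file holds {sorted(payload)}; pass slide_id to pick one"
                )
            slide_id = next(iter(payload))
        if slide_id not in payload:
            raise ConfigurationError(f"slide {slide_id!r} absent from threshold file")
        return cls({k: float(v) for k, v in payload[slide_id].items()}, slide_id)


def mean_intensity_per_instance(
    image: MultiplexImage,
    instances: InstanceMap,
    provenance: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Compute per-instance centroids and per-channel mean intensities.

    Returns an empty (0-row) table when the instance map holds no instances.
    """
    check_same_shape(image, instances)
    labels = instances.labels
    ids = instances.ids
    columns = ["instance_id", "centroid_row", "centroid_col"] + [
        MEAN_PREFIX + c for c in image.channel_names
    ]
    if ids.size == 0:
        df = pd.DataFrame(columns=columns)
        df["instance_id"] = df["instance_id"].astype(np.int64)
        return _attach_provenance(df, provenance)

    flat = labels.ravel()
    nbins = int(ids.max()) + 1
    counts = np.bincount(flat, minlength=nbins)[ids]
    rows_idx, cols_idx = np.indices(labels.shape)
    data: dict[str, np.ndarray] = {
        "instance_id": ids.astype(np.int64),
        "centroid_row": np.bincount(flat, weights=rows_idx.ravel(), minlength=nbins)[ids] / counts,
        "centroid_col": np.bincount(flat, weights=cols_idx.ravel(), minlength=nbins)[ids] / counts,
    }
    for name in image.channel_names:
        sums = np.bincount(flat, weights=image.channel(name).ravel().astype(np.float64), minlength=nbins)
        data[MEAN_PREFIX + name] = sums[ids] / counts
    return _attach_provenance(pd.DataFrame(data), provenance)


def _attach_provenance(df: pd.DataFrame, provenance: Mapping[str, str] | None) -> pd.DataFrame:
    for key in ("slide_id", "patient_id", "site_id"):
        if provenance and key in provenance:
            df[key] = provenance[key]
    return df


def apply_thresholds(
    table: pd.DataFrame,
    thresholds: ThresholdSet,
    channels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fill boolean stain-call columns: positive iff mean strictly exceeds threshold.

    ``channels`` selects the gating channels to call (default: every channel
    with a mean column); a gating channel without a threshold is a
    configuration error naming the channel.
    """
    table = table.copy()
    present = [c[len(MEAN_PREFIX):] for c in table.columns if c.startswith(MEAN_PREFIX)]
    channels = present if channels is None else sorted(channels)
    missing_means = [c for c in channels if c not in present]
    if missing_means:
        raise ConfigurationError(f"no mean-intensity column for channel(s) {missing_means}")
    thresholds.require(channels)
    for ch in channels:
        table[CALL_PREFIX + ch] = table[MEAN_PREFIX + ch].to_numpy() > thresholds.thresholds[ch]
    return table


def assign_class(table: pd.DataFrame, rules: RuleTable) -> pd.DataFrame:
    """Assign each instance the class of the first matching rule (or "unclassified")."""
    table = table.copy()
    call_cols = {c[len(CALL_PREFIX):]: c for c in table.columns if c.startswith(CALL_PREFIX)}
    needed = rules.referenced_channels - set(call_cols)
    if needed:
        raise ConfigurationError(f"rules reference uncalled channel(s) {sorted(needed)}")
    n = len(table)
    assigned = np.full(n, UNCLASSIFIED, dtype=object)
    unresolved = np.ones(n, dtype=bool)
    calls = {ch: table[col].to_numpy(dtype=bool) for ch, col in call_cols.items()}
    for rule in rules:
        mask = unresolved.copy()
        for ch in rule.positive:
            mask &= calls[ch]
        for ch in rule.negative:
            mask &= ~calls[ch]
        assigned[mask] = rule.class_name
        unresolved &= ~mask
    table["class"] = assigned
    return table


def gate(
    image: MultiplexImage,
    instances: InstanceMap,
    rules: RuleTable,
    thresholds: ThresholdSet,
    provenance: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full gating pipeline: mean intensities, stain calls, class assignment."""
    table = mean_intensity_per_instance(image, instances, provenance)
    if len(table) == 0:
        table["class"] = pd.Series(dtype=object)
        return table
    table = apply_thresholds(table, thresholds, channels=rules.referenced_channels)
    return assign_class(table, rules)
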