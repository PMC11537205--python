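"""Core raster containers: named multichannel intensity images and instance label maps.

A :class:`MultiplexImage` holds one 2-D float array per named stain channel plus
the physical resolution in micrometres per pixel.  An :class:`InstanceMap` is a
single integer label image in which 0 is background and each positive value
delineates one cell or nucleus instance; instances never overlap and ids need
not be contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile


class ChannelError(KeyError):
    """A required stain channel is absent from the image."""


class DimensionError(ValueError):
    """Array shapes that must agree do not."""


@dataclass
class MultiplexImage:
    """Named multichannel intensity image with physical resolution.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2-D non-negative float array.  All
        arrays must share one shape.
    resolution_um_per_px
        Pixel pitch in micrometres per pixel (isotropic).
    """

    channels: dict[str, np.ndarray]
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise DimensionError(f"channel arrays disagree in shape: {sorted(shapes)}")
        self.channels = {k: np.asarray(v, dtype=np.float32) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            return (0, 0)
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(f"channel {name!r} not present; have {self.channel_names}") from None

    def to_tiff(self, path: str | Path) -> None:
        """Write all channels as one multipage TIFF; channel names go in page metadata."""
        arr = np.stack([self.channels[k] for k in self.channels], axis=0)
        tifffile.imwrite(
            path,
            arr,
            metadata={
                "axes": "CYX",
                "channel_names": list(self.channels),
                "resolution_um_per_px": self.resolution_um_per_px,
            },
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultiplexImage":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        names = meta.get("channel_names")
        res = float(meta.get("resolution_um_per_px", 1.0))
        if arr.ndim == 2:
            arr = arr[None]
        if names is None:
            names = [f"ch{i}" for i in range(arr.shape[0])]
        return cls(dict(zip(names, arr)), res)


@dataclass
class InstanceMap:
    """Integer label image; 0 = background, positive values = instance ids."""

    labels: np.ndarray
    resolution_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError("instance map must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("instance labels must be non-negative")
        self.labels = self.labels.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of instance ids present (background excluded)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.ids.size)

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Unweighted mean (row, col) of member pixels per instance, 0-based."""
        out: dict[int, tuple[float, float]] = {}
        rows, cols = np.nonzero(self.labels)
        ids = self.labels[rows, cols]
        order = np.argsort(ids, kind="stable")
        ids, rows, cols = ids[order], rows[order], cols[order]
        bounds = np.searchsorted(ids, np.unique(ids))
        uids = np.unique(ids)
        for i, uid in enumerate(uids):
            lo = bounds[i]
            hi = bounds[i + 1] if i + 1 < len(bounds) else len(ids)
            out[int(uid)] = (float(rows[lo:hi].mean()), float(cols[lo:hi].mean()))
        return out

    def to_tiff(self, path: str | Path) -> None:
        labels = self.labels
        if labels.size and labels.max() > np.iinfo(np.uint16).max:
            tifffile.imwrite(path, labels.astype(np.int32))
        else:
            tifffile.imwrite(path, labels.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path: str | Path, resolution_um_per_px: float = 1.0) -> "InstanceMap":
        return cls(tifffile.imread(path), resolution_um_per_px)


def check_same_shape(image: MultiplexImage, instances: InstanceMap) -> None:
    if image.channels and image.shape != instances.shape:
        raise DimensionError(
            f"image shape {image.shape} does not match instance map shape {instances.shape}"
        )
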