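"""Instance localization: nuclear-channel merging, a classical fallback
segmenter, mask ingestion, and resolution resampling.

The fallback segmenter (Gaussian smoothing, global threshold, connected
components, optional distance-transform watershed) is a self-contained
classical pipeline so the whole toolchain runs without any pretrained deep
segmentation weights; externally produced instance masks can be ingested
instead via :func:`ingest_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed
from skimage.transform import resize

from .errors import ConfigurationError
from .image import ChannelError, InstanceMap, MultiplexImage


@dataclass
class SegmentationConfig:
    smoothing_sigma_um: float = 0.64
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_instance_area_um2: float = 4.0
    split_touching: bool = True
    include_goblets: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold_method {self.threshold_method!r}")
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise ConfigurationError("fixed_threshold is required iff threshold_method='fixed'")
        if self.smoothing_sigma_um < 0 or self.min_instance_area_um2 < 0:
            raise ConfigurationError("sigma and min area must be non-negative")


def merge_nuclear_channels(image: MultiplexImage, include_goblets: bool = True) -> np.ndarray:
    """Pixelwise DAPI + Muc2 sum (goblet regime), or DAPI alone (nuclei-only).

    DAPI marks nuclei; Muc2 marks the goblets of goblet cells, which are their
    own instances here, so summing the two channels yields one foreground map
    covering every instance kind.
    """
    dapi = image.channel("DAPI")
    if not include_goblets:
        return dapi.copy()
    if "Muc2" not in image.channels:
        raise ChannelError("Muc2 channel required when include_goblets=True")
    return dapi + image.channel("Muc2")


def segment_fallback(
    merged: np.ndarray,
    config: SegmentationConfig,
    resolution_um_per_px: float,
) -> InstanceMap:
    """Classical instance segmentation of a merged nuclear-intensity image.

    Gaussian smoothing at ``smoothing_sigma_um`` (converted to pixels), global
    threshold (Otsu or fixed), connected components; when ``split_touching``,
    merged blobs are split by a distance-transform watershed seeded at local
    maxima.  Instances below ``min_instance_area_um2`` are removed and ids are
    relabelled contiguously from 1.
    """
    merged = np.asarray(merged, dtype=np.float64)
    if merged.size == 0:
        raise ConfigurationError("merged image is empty")
    sigma_px = config.smoothing_sigma_um / resolution_um_per_px
    smoothed = gaussian(merged, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else merged

    if config.threshold_method == "otsu":
        if np.allclose(smoothed, smoothed.flat[0]):
            return InstanceMap(np.zeros(merged.shape, dtype=np.int32), resolution_um_per_px)
        thr = threshold_otsu(smoothed)
    else:
        thr = float(config.fixed_threshold)
    fg = smoothed > thr
    if not fg.any():
        return InstanceMap(np.zeros(merged.shape, dtype=np.int32), resolution_um_per_px)

    if config.split_touching:
        dist = ndi.distance_transform_edt(fg)
        # peaks at least one typical radius apart; min_distance in pixels
        from skimage.feature import peak_local_max

        min_dist = max(2, int(round(1.5 / resolution_um_per_px)))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=fg, exclude_border=False)
        markers = np.zeros(fg.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = cc_label(fg, connectivity=2)
        else:
            labels = watershed(-dist, markers=markers, mask=fg)
    else:
        labels = cc_label(fg, connectivity=2)

    min_px = config.min_instance_area_um2 / (resolution_um_per_px**2)
    if min_px > 0:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_px]
        if small.size:
            labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return InstanceMap(labels.astype(np.int32), resolution_um_per_px)


def ingest_mask(path: str | Path, resolution_um_per_px: float = 1.0) -> InstanceMap:
    """Load and validate an externally produced instance mask (TIFF/PNG)."""
    import imageio.v3 as iio

    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        m = InstanceMap.from_tiff(p, resolution_um_per_px)
    else:
        m = InstanceMap(iio.imread(p), resolution_um_per_px)
    return m


def resample_image(
    array: np.ndarray | InstanceMap,
    from_res: float,
    to_res: float,
):
    """Resample between physical resolutions (micrometres per pixel).

    Intensity arrays use cubic interpolation (small negative overshoots are
    clipped at 0 — intensities are physical); instance maps use
    nearest-neighbour so no new label values can appear.  Output shape is
    ``round(shape * from_res / to_res)``.
    """
    if from_res <= 0 or to_res <= 0:
        raise ConfigurationError("resolutions must be positive")
    is_map = isinstance(array, InstanceMap)
    data = array.labels if is_map else np.asarray(array)
    if from_res == to_res:
        out = data.copy()
    else:
        new_shape = tuple(int(round(s * from_res / to_res)) for s in data.shape[:2])
        if data.ndim == 3:
            new_shape = new_shape + (data.shape[2],)
        if is_map:
            out = resize(
                data, new_shape, order=0, preserve_range=True, anti_aliasing=False
            ).astype(data.dtype)
        else:
            out = resize(
                data.astype(np.float64), new_shape, order=3, preserve_range=True, anti_aliasing=False
            )
            out = np.clip(out, 0, None).astype(np.float32)
    if is_map:
        return InstanceMap(out, to_res)
    return out


def resample_multiplex(image: MultiplexImage, to_res: float) -> MultiplexImage:
    """Resample every channel of a multiplex image to a new resolution."""
    channels = {
        k: resample_image(v, image.resolution_um_per_px, to_res) for k, v in image.channels.items()
    }
    return MultiplexImage(channels, to_res)
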